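"""Beam-in-solid embedding and axonal strain.

Embedded beam nodes carry no mass or stiffness (null-beam semantics: they
never feed back forces); each beam node simply follows the trilinearly
interpolated displacement field of its host solid element. Axonal strain of
a beam element is then available two ways:

* dynamically — move both endpoints with the interpolated field, take the
  stretch ratio lambda = current length / reference length, and convert it
  with the chosen measure (Green ``(lambda^2-1)/2`` by default, engineering
  ``lambda-1``, logarithmic ``ln lambda``);
* statically — project the host element's Green-Lagrange tensor onto the
  reference beam axis, ``a^T E a`` (the classical strain-tensor
  post-processing route).

Under a homogeneous (affine) deformation the two routes agree exactly; on
inhomogeneous fields they differ because the dynamic route tracks the
rotated, stretched fiber itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    DisplacementHistory,
    HexMesh,
    NaturalCoordinate,
    PointNotFoundError,
    shape_eval_many,
)
from .tracts import TractSet

__all__ = [
    "EmbeddedFiberSet",
    "AxonalStrainHistory",
    "embed_fibers",
    "axonal_strain_dynamic",
    "axonal_strain_static",
    "strain_from_stretch",
]

log = logging.getLogger(__name__)

MEASURES = ("green", "engineering", "logarithmic")
SNAP_TOL_MM = 0.5  # out-of-mesh beam nodes within this distance are snapped


@dataclass
class EmbeddedFiberSet:
    """Embedding table of a fiber bundle in a hexahedral mesh.

    Flat arrays over beam *nodes* and beam *elements*:

    node_element / node_xi : host element index and natural coordinates per
        beam node.
    beam_nodes : (n_beams, 2) indices into the flat node arrays.
    ref_lengths : reference beam lengths (mm), all positive.
    tract / fiber_index : per-beam tract label and global fiber index.
    fiber_tract / fiber_of : per-fiber label bookkeeping for metric grouping.
    dropped : list of (tract, fiber-within-tract) records for fibers with
        unlocatable nodes — never silently discarded.
    """

    node_element: np.ndarray
    node_xi: np.ndarray
    node_ref_coords: np.ndarray
    beam_nodes: np.ndarray
    ref_lengths: np.ndarray
    beam_tract: np.ndarray
    beam_fiber: np.ndarray
    fiber_tract: np.ndarray
    dropped: list = field(default_factory=list)
    snapped: int = 0

    @property
    def n_beams(self) -> int:
        return self.beam_nodes.shape[0]

    @property
    def n_fibers(self) -> int:
        return self.fiber_tract.shape[0]

    def __post_init__(self):
        if np.any(self.ref_lengths <= 0):
            raise ValueError("reference beam lengths must be positive")


def embed_fibers(mesh: HexMesh, tracts: TractSet,
                 snap_tol_mm: float = SNAP_TOL_MM) -> EmbeddedFiberSet:
    """Map every beam node of a tract set to (host element, xi).

    Nodes on shared faces go to the lowest-index containing element. Nodes
    outside the mesh but within ``snap_tol_mm`` of the nearest element are
    snapped onto it (clipped xi, logged); a fiber with any node farther out
    is dropped and recorded. A summary (fibers, beams, dropped) is logged.
    """
    node_el: list[int] = []
    node_xi: list[np.ndarray] = []
    node_ref: list[np.ndarray] = []
    beam_nodes: list[tuple[int, int]] = []
    ref_len: list[float] = []
    beam_tract: list[str] = []
    beam_fiber: list[int] = []
    fiber_tract: list[str] = []
    dropped: list[tuple[str, int]] = []
    snapped = 0

    fiber_id = 0
    for tract, i, fiber in tracts.fibers():
        locs = []
        n_snap = 0
        ok = True
        for p in fiber.nodes:
            try:
                nc = mesh.locate_point(p)
            except PointNotFoundError as err:
                if err.distance_mm <= snap_tol_mm:
                    # snap: clip the best candidate's xi onto the element
                    nc = mesh.locate_point(p, pad=_mm_to_xi_pad(mesh, err, snap_tol_mm))
                    n_snap += 1
                else:
                    ok = False
                    break
            locs.append(nc)
        if not ok:
            dropped.append((tract, i))
            continue
        snapped += n_snap
        base = len(node_el)
        for nc, p in zip(locs, fiber.nodes):
            node_el.append(nc.element_index)
            node_xi.append(nc.xi)
            node_ref.append(p)
        for b in range(fiber.n_beams):
            beam_nodes.append((base + b, base + b + 1))
            ref_len.append(float(fiber.lengths()[b]))
            beam_tract.append(tract)
            beam_fiber.append(fiber_id)
        fiber_tract.append(tract)
        fiber_id += 1

    emb = EmbeddedFiberSet(
        node_element=np.asarray(node_el, dtype=np.int64),
        node_xi=np.asarray(node_xi, dtype=float).reshape(-1, 3),
        node_ref_coords=np.asarray(node_ref, dtype=float).reshape(-1, 3),
        beam_nodes=np.asarray(beam_nodes, dtype=np.int64).reshape(-1, 2),
        ref_lengths=np.asarray(ref_len, dtype=float),
        beam_tract=np.asarray(beam_tract, dtype=object),
        beam_fiber=np.asarray(beam_fiber, dtype=np.int64),
        fiber_tract=np.asarray(fiber_tract, dtype=object),
        dropped=dropped,
        snapped=snapped,
    )
    log.info(
        "embedded %d fibers / %d beams; dropped %d fiber(s); snapped %d node(s)",
        emb.n_fibers, emb.n_beams, len(dropped), snapped,
    )
    return emb


def _mm_to_xi_pad(mesh: HexMesh, err: PointNotFoundError, snap_tol_mm: float) -> float:
    """Natural-coordinate padding equivalent to the mm snap tolerance."""
    e = err.nearest_element
    half = np.ptp(mesh.element_coords(e), axis=0).min() / 2.0
    return max(snap_tol_mm / max(half, 1e-12), 1e-6) * 2.0


def strain_from_stretch(lam: np.ndarray, measure: str = "green") -> np.ndarray:
    """Convert stretch ratio(s) lambda to axial strain under a measure."""
    lam = np.asarray(lam, dtype=float)
    if measure == "green":
        return 0.5 * (lam**2 - 1.0)
    if measure == "engineering":
        return lam - 1.0
    if measure == "logarithmic":
        return np.log(lam)
    raise ValueError(f"unknown strain measure {measure!r}; choose from {MEASURES}")


@dataclass
class AxonalStrainHistory:
    """Scalar axonal strain per beam element per time step.

    ``peaks`` is the max over the stored history; ``measure`` records the
    strain convention used.
    """

    times: np.ndarray
    strain: np.ndarray  # (n_times, n_beams)
    measure: str
    beam_tract: np.ndarray
    beam_fiber: np.ndarray
    fiber_tract: np.ndarray

    @property
    def peaks(self) -> np.ndarray:
        return self.strain.max(axis=0)

    def peaks_by_tract(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        pk = self.peaks
        for tract in dict.fromkeys(self.beam_tract.tolist()):
            out[tract] = pk[self.beam_tract == tract]
        return out

    def fiber_peaks(self) -> list[np.ndarray]:
        """Per-fiber arrays of per-beam peak strain, fiber order preserved."""
        pk = self.peaks
        return [pk[self.beam_fiber == f] for f in range(len(self.fiber_tract))]


def _interpolated_positions(emb: EmbeddedFiberSet, mesh: HexMesh,
                            disp: DisplacementHistory) -> np.ndarray:
    """Current beam-node positions, (n_times, n_nodes, 3)."""
    N, _ = shape_eval_many(emb.node_xi)  # (n_nodes, 8)
    conn = mesh.elements[emb.node_element]  # (n_nodes, 8)
    u = disp.displacements[:, conn, :]  # (nt, n_nodes, 8, 3)
    interp = np.einsum("tnia,ni->tna", u, N)
    return emb.node_ref_coords[None, :, :] + interp


def axonal_strain_dynamic(
    emb: EmbeddedFiberSet,
    mesh: HexMesh,
    disp: DisplacementHistory,
    measure: str = "green",
) -> AxonalStrainHistory:
    """Axonal strain tracked from moved beam endpoints.

    Each beam node's current position is its reference position plus the
    trilinearly interpolated nodal displacement of its host element; the
    stretch ratio of each beam element is converted to strain under
    ``measure``. Raises if any current length is non-positive (invalid
    kinematics).
    """
    disp.check_mesh(mesh)
    if measure not in MEASURES:
        raise ValueError(f"unknown strain measure {measure!r}")
    pos = _interpolated_positions(emb, mesh, disp)
    vec = pos[:, emb.beam_nodes[:, 1], :] - pos[:, emb.beam_nodes[:, 0], :]
    cur = np.linalg.norm(vec, axis=2)  # (nt, n_beams)
    if np.any(cur <= 0):
        raise ValueError("non-positive current beam length: invalid kinematics")
    lam = cur / emb.ref_lengths[None, :]
    return AxonalStrainHistory(
        times=disp.times,
        strain=strain_from_stretch(lam, measure),
        measure=measure,
        beam_tract=emb.beam_tract,
        beam_fiber=emb.beam_fiber,
        fiber_tract=emb.fiber_tract,
    )


def axonal_strain_static(E_host: np.ndarray, axis: np.ndarray,
                         measure: str = "green") -> float:
    """Axonal strain by projecting a solid strain tensor onto a fiber axis.

    Green measure returns ``a^T E a``; engineering returns
    ``sqrt(1 + 2 a^T E a) - 1``; logarithmic ``ln sqrt(1 + 2 a^T E a)``.
    """
    a = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(a) - 1.0) > 1e-8:
        raise ValueError("axis must be a unit vector")
    e_axial = float(a @ np.asarray(E_host, dtype=float) @ a)
    if measure == "green":
        return e_axial
    lam2 = 1.0 + 2.0 * e_axial
    if lam2 <= 0:
        raise ValueError("1 + 2 a^T E a <= 0: strain tensor not admissible")
    if measure == "engineering":
        return float(np.sqrt(lam2) - 1.0)
    if measure == "logarithmic":
        return float(0.5 * np.log(lam2))
    raise ValueError(f"unknown strain measure {measure!r}")
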