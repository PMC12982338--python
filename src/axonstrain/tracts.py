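"""Axonal fiber tracts as beam chains.

Tractography streamlines (TRK/TCK, world mm RAS) are resampled at a fixed
arc-length step — 1.0 mm by default — into chains of beam elements; bundles
of fibers are grouped under tract abbreviations (e.g. CC_B, TR_P_L, SLF3_R).
Because streamline start/end sides are arbitrary, beam direction vectors are
sign-unified before averaging: a vector v is kept when the product of its
components v_x*v_y*v_z is non-negative and flipped to -v otherwise, so
antipodal pairs collapse to one representative and fiber reversal cannot
cancel the mean. The per-solid-element mean of the unified beam directions
becomes the material axis of that element, exportable as LS-DYNA
*ELEMENT_SOLID_ORTHO cards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

from .mesh import HexMesh, PointNotFoundError

__all__ = [
    "Streamline",
    "Fiber",
    "TractSet",
    "MaterialAxisField",
    "read_streamlines",
    "write_streamlines",
    "resample_to_beams",
    "canonicalize_direction",
    "canonicalize_directions",
    "assign_material_axes",
    "affine_transform_tracts",
    "export_solid_ortho",
    "read_solid_ortho",
]

log = logging.getLogger(__name__)

DEFAULT_STEP_MM = 1.0  # tractography resampling step


@dataclass(frozen=True)
class Streamline:
    """An ordered polyline in world (RAS) mm coordinates."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("streamline needs >= 2 points of dimension 3")
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0):
            raise ValueError("consecutive streamline points must differ")
        object.__setattr__(self, "points", pts)

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Fiber:
    """A chain of beam elements representing one axonal fiber.

    ``nodes`` are the beam nodes (mm); beam element i connects nodes i and
    i+1. All reference lengths must be positive.
    """

    nodes: np.ndarray
    tract: str = ""

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3 or self.nodes.shape[0] < 2:
            raise ValueError("fiber needs >= 2 beam nodes")
        if np.any(self.lengths() <= 0):
            raise ValueError("beam reference lengths must be positive")

    @property
    def n_beams(self) -> int:
        return self.nodes.shape[0] - 1

    def lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)

    def directions(self, unit: bool = True) -> np.ndarray:
        d = np.diff(self.nodes, axis=0)
        if unit:
            d = d / np.linalg.norm(d, axis=1, keepdims=True)
        return d

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[:-1] + self.nodes[1:])


class TractSet(dict):
    """Mapping tract abbreviation -> list of :class:`Fiber`.

    A thin dict subclass; fibers carry their tract label redundantly for
    flat exports.
    """

    def add(self, tract: str, fiber: Fiber) -> None:
        fiber.tract = tract
        self.setdefault(tract, []).append(fiber)

    @property
    def n_fibers(self) -> int:
        return sum(len(v) for v in self.values())

    @property
    def n_beams(self) -> int:
        return sum(f.n_beams for v in self.values() for f in v)

    def fibers(self):
        """Iterate (tract, fiber_index_within_tract, fiber)."""
        for tract in self:
            for i, f in enumerate(self[tract]):
                yield tract, i, f


# ---------------------------------------------------------------------------
# streamline I/O (nibabel handles the TRK voxel->RAS affine)

def read_streamlines(path) -> list[Streamline]:
    """Read a TRK or TCK file; points are returned in world mm (RAS).

    TRK voxel/affine handling is applied by nibabel; TCK data are already
    mm RAS.
    """
    tf = nib.streamlines.load(str(path))
    sls = [Streamline(np.asarray(s)) for s in tf.streamlines]
    if not sls:
        raise ValueError(f"{path}: no streamlines")
    return sls


def write_streamlines(path, streamlines: list[Streamline]) -> None:
    """Write streamlines (world mm RAS) to TRK or TCK by file extension."""
    t = nib.streamlines.Tractogram(
        [s.points for s in streamlines], affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(t, str(path))


# ---------------------------------------------------------------------------
# resampling

def resample_to_beams(sl: Streamline, step: float = DEFAULT_STEP_MM) -> Fiber:
    """Resample a streamline at fixed arc-length steps into a beam chain.

    Nodes are placed every ``step`` mm of arc length along the polyline.
    The trailing remainder is merged into the previous beam when shorter
    than ``step/2`` (avoids near-zero-length beams that destabilize strain
    ratios) and kept as a short final beam otherwise. Endpoints are always
    preserved. A streamline shorter than ``step`` yields a single beam
    between its endpoints.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pts = sl.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= step:
        return Fiber(np.vstack([pts[0], pts[-1]]))
    n_full = int(np.floor(total / step))
    remainder = total - n_full * step
    targets = np.arange(1, n_full + 1) * step
    if remainder < step / 2.0:
        # merge remainder: the node at n_full*step is replaced by the endpoint
        targets = targets[:-1]
    interior = _points_at_arclength(pts, s, targets)
    return Fiber(np.vstack([pts[0], interior, pts[-1]]))


def _points_at_arclength(pts, s, targets):
    idx = np.searchsorted(s, targets, side="right") - 1
    idx = np.clip(idx, 0, len(pts) - 2)
    seg_len = s[idx + 1] - s[idx]
    frac = (targets - s[idx]) / seg_len
    return pts[idx] + frac[:, None] * (pts[idx + 1] - pts[idx])


# ---------------------------------------------------------------------------
# direction sign unification

def canonicalize_direction(v, mode: str = "robust") -> np.ndarray:
    """Unify the sign of a beam direction vector.

    Keeps ``v`` when the product of its components ``v_x*v_y*v_z`` is
    non-negative, returns ``-v`` otherwise; idempotent, and antipodal pairs
    with nonzero product collapse to one representative. ``mode="robust"``
    (default) additionally resolves the product-zero boundary (any
    axis-aligned vector) by making the first nonzero component positive;
    ``mode="strict"`` leaves such vectors unchanged.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected a 3-vector")
    if not np.all(np.isfinite(v)) or np.all(v == 0):
        raise ValueError("direction must be finite and nonzero")
    return canonicalize_directions(v[None, :], mode=mode)[0]


def canonicalize_directions(v: np.ndarray, mode: str = "robust") -> np.ndarray:
    """Vectorized sign unification for an (n, 3) array of directions."""
    if mode not in ("strict", "robust"):
        raise ValueError(f"unknown mode {mode!r}")
    v = np.asarray(v, dtype=float)
    prod = v[:, 0] * v[:, 1] * v[:, 2]
    out = np.where(prod[:, None] < 0, -v, v)
    if mode == "robust":
        zero = prod == 0
        if np.any(zero):
            vz = out[zero]
            # first nonzero component made positive
            first = np.argmax(vz != 0, axis=1)
            sign = np.sign(vz[np.arange(len(vz)), first])
            out[zero] = vz * sign[:, None]
    return out


# ---------------------------------------------------------------------------
# material axes

@dataclass
class MaterialAxisField:
    """Per-solid-element fiber material axis.

    ``axes[e]`` is a unit vector for elements traversed by fibers; ``present``
    flags elements with an axis; ``degenerate`` flags elements whose beam
    directions cancelled (possible only in strict sign mode).
    """

    axes: np.ndarray
    present: np.ndarray
    degenerate: np.ndarray = None
    n_beams_per_element: np.ndarray = None

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.present), dtype=bool)
        norms = np.linalg.norm(self.axes[self.present], axis=1)
        if norms.size and np.max(np.abs(norms - 1.0)) > 1e-12:
            raise ValueError("present axes must be unit vectors")


def assign_material_axes(
    mesh: HexMesh,
    tracts: TractSet,
    mode: str = "robust",
    length_weighted: bool = False,
) -> MaterialAxisField:
    """Average sign-unified beam directions into per-element material axes.

    A beam element belongs to the solid element containing its midpoint.
    Each beam's unit direction is sign-unified, then averaged per solid
    element (optionally weighted by beam length) and renormalized. Elements
    traversed by no beam are flagged absent; elements whose directions
    mutually cancel (mean norm < 1e-8) are flagged degenerate with a
    warning.
    """
    ne = mesh.n_elements
    acc = np.zeros((ne, 3))
    cnt = np.zeros(ne)
    nbeams = np.zeros(ne, dtype=np.int64)
    for _, _, fiber in tracts.fibers():
        dirs = canonicalize_directions(fiber.directions(unit=True), mode=mode)
        w = fiber.lengths() if length_weighted else np.ones(fiber.n_beams)
        for mid, d, wi in zip(fiber.midpoints(), dirs, w):
            try:
                nc = mesh.locate_point(mid)
            except PointNotFoundError:
                continue
            acc[nc.element_index] += wi * d
            cnt[nc.element_index] += wi
            nbeams[nc.element_index] += 1
    present = cnt > 0
    axes = np.zeros((ne, 3))
    degenerate = np.zeros(ne, dtype=bool)
    mean = np.zeros((ne, 3))
    mean[present] = acc[present] / cnt[present, None]
    norm = np.linalg.norm(mean, axis=1)
    ok = present & (norm >= 1e-8)
    degenerate = present & ~ok
    if np.any(degenerate):
        log.warning("material axes: %d element(s) with cancelling directions",
                    int(degenerate.sum()))
    axes[ok] = mean[ok] / norm[ok, None]
    present = ok
    return MaterialAxisField(axes=axes, present=present, degenerate=degenerate,
                             n_beams_per_element=nbeams)


def affine_transform_tracts(tracts: TractSet, matrix: np.ndarray) -> TractSet:
    """Apply a 4x4 affine to every fiber node; fiber counts are conserved."""
    M = np.asarray(matrix, dtype=float)
    if M.shape != (4, 4):
        raise ValueError("expected a 4x4 affine matrix")
    out = TractSet()
    for tract, _, fiber in tracts.fibers():
        pts = fiber.nodes @ M[:3, :3].T + M[:3, 3]
        out.add(tract, Fiber(pts))
    return out


# ---------------------------------------------------------------------------
# LS-DYNA keyword export

def _orthonormal_completion(a: np.ndarray) -> np.ndarray:
    """Second material axis: global z projected orthogonal to ``a``.

    Falls back to global y when the axis is (anti)parallel to z. Any
    completion is valid for transversely isotropic use.
    """
    z = np.array([0.0, 0.0, 1.0])
    d = z - (z @ a) * a
    n = np.linalg.norm(d)
    if n < 1e-8:
        y = np.array([0.0, 1.0, 0.0])
        d = y - (y @ a) * a
        n = np.linalg.norm(d)
    return d / n


def export_solid_ortho(field: MaterialAxisField, mesh: HexMesh, path) -> int:
    """Write *ELEMENT_SOLID_ORTHO cards (1-based ids, AOPT by vectors a, d).

    Elements without an axis are skipped; the skipped count is logged and
    returned.
    """
    skipped = 0
    with open(path, "w") as fh:
        fh.write("*KEYWORD\n*ELEMENT_SOLID_ORTHO\n")
        part_ids = {lab: i + 1 for i, lab in
                    enumerate(dict.fromkeys(mesh.part_labels))}
        for e in range(mesh.n_elements):
            if not field.present[e]:
                skipped += 1
                continue
            a = field.axes[e]
            d = _orthonormal_completion(a)
            conn = mesh.node_ids[mesh.elements[e]] + 1
            fh.write(f"{e + 1:8d}{part_ids[mesh.part_labels[e]]:8d}\n")
            fh.write("".join(f"{n:8d}" for n in conn) + "\n")
            fh.write("".join(f"{x:16.8e}" for x in a) + "\n")
            fh.write("".join(f"{x:16.8e}" for x in d) + "\n")
        fh.write("*END\n")
    if skipped:
        log.info("export_solid_ortho: skipped %d element(s) without an axis", skipped)
    return skipped


def read_solid_ortho(path) -> dict[int, np.ndarray]:
    """Re-read an *ELEMENT_SOLID_ORTHO file: 0-based element id -> a-vector."""
    axes: dict[int, np.ndarray] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    in_block = False
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("*"):
            in_block = ln.upper().startswith("*ELEMENT_SOLID_ORTHO")
            i += 1
            continue
        if in_block:
            eid = int(ln[:8])
            a = np.array([float(x) for x in lines[i + 2].split()])
            axes[eid - 1] = a
            i += 4
        else:
            i += 1
    return axes
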