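"""Synthetic meshes, bundles and deformation histories with known oracles.

Everything downstream (embedding, strain tracking, metrics, cluster
validation, CORA) can be exercised against closed-form ground truth:
structured box meshes, straight/arc/helix fiber bundles resampled at the
standard 1.0 mm step, and displacement histories drawn from analytic
deformation fields — affine, simple shear, rigid rotation, or a twist field
(the canonical inhomogeneous case where fiber directions rotate with the
deformation). Pulse amplitudes follow a haversine shape (zero-start,
smooth), the conventional idealization of impact loading.

All generators are deterministic under a fixed seed; oracles are returned
alongside their fixtures rather than recomputed by the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterDefinition
from .mesh import DisplacementHistory, HexMesh, green_lagrange, principal_strains
from .tracts import Fiber, Streamline, TractSet, resample_to_beams

__all__ = [
    "DeformationSpec",
    "haversine_pulse",
    "make_box_mesh",
    "make_bundle",
    "make_history",
    "make_cluster_fixture",
    "make_cora_pair",
]


def haversine_pulse(times: np.ndarray, peak: float, duration: float) -> np.ndarray:
    """Zero-start smooth pulse: peak * sin^2(pi t / duration) on [0, duration]."""
    t = np.asarray(times, dtype=float)
    amp = peak * np.sin(np.pi * np.clip(t, 0.0, duration) / duration) ** 2
    amp[t > duration] = 0.0
    return amp


@dataclass
class DeformationSpec:
    """A time-modulated closed-form deformation field.

    kind:
        "affine"         x(t) = X + amp(t) * (A - I) X  (A a fixed matrix)
        "simple_shear"   u_x = amp(t) * X_y
        "rigid_rotation" rotation by angle amp(t) about ``axis`` + translation
        "twist"          rotation about z by amp(t) * X_z / length_scale
    amplitude is a haversine pulse (peak, duration in seconds); amp(0) = 0.
    """

    kind: str = "simple_shear"
    peak: float = 0.5
    duration: float = 0.01
    matrix: np.ndarray | None = None
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    length_scale: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        kinds = ("affine", "simple_shear", "rigid_rotation", "twist")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind == "affine" and self.matrix is None:
            raise ValueError("affine kind needs a matrix")
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        self.translation = np.asarray(self.translation, dtype=float)

    # -- field evaluation ----------------------------------------------
    def amplitude(self, times) -> np.ndarray:
        return haversine_pulse(np.atleast_1d(times), self.peak, self.duration)

    def gradient_matrix(self, amp: float) -> np.ndarray:
        """Deformation gradient F(amp) for the homogeneous kinds."""
        if self.kind == "affine":
            return np.eye(3) + amp * (np.asarray(self.matrix) - np.eye(3))
        if self.kind == "simple_shear":
            F = np.eye(3)
            F[0, 1] = amp
            return F
        if self.kind == "rigid_rotation":
            return _rotation_matrix(self.axis, amp)
        raise ValueError(f"{self.kind} has no homogeneous gradient")

    def displace(self, X: np.ndarray, t: float) -> np.ndarray:
        """Displacements of reference points X (n,3) at time t."""
        amp = float(self.amplitude(t)[0])
        X = np.asarray(X, dtype=float)
        if self.kind in ("affine", "simple_shear"):
            return X @ (self.gradient_matrix(amp) - np.eye(3)).T
        if self.kind == "rigid_rotation":
            R = _rotation_matrix(self.axis, amp)
            return X @ R.T + amp * self.translation - X
        # twist about z: rotation angle proportional to height
        theta = amp * X[:, 2] / self.length_scale
        c, s = np.cos(theta), np.sin(theta)
        x = c * X[:, 0] - s * X[:, 1]
        y = s * X[:, 0] + c * X[:, 1]
        return np.column_stack([x - X[:, 0], y - X[:, 1], np.zeros(len(X))])

    # -- oracles --------------------------------------------------------
    def strain_oracle(self, t: float) -> np.ndarray | None:
        """Analytic Green-Lagrange tensor for homogeneous kinds, else None."""
        if self.kind == "twist":
            return None
        amp = float(self.amplitude(t)[0])
        return green_lagrange(self.gradient_matrix(amp))

    def mps_oracle(self, t: float) -> float | None:
        E = self.strain_oracle(t)
        return None if E is None else float(principal_strains(E)[0])

    def axial_strain_oracle(self, direction, t: float) -> float | None:
        """Green axial strain of a fiber along ``direction`` (homogeneous kinds)."""
        E = self.strain_oracle(t)
        if E is None:
            return None
        a = np.asarray(direction, dtype=float)
        a = a / np.linalg.norm(a)
        return float(a @ E @ a)

    def numerical_strain_oracle(self, X: np.ndarray, t: float,
                                h: float | None = None) -> np.ndarray:
        """E at points X by dense central finite differences of the field.

        Independent of the mesh kinematics: differentiates the displacement
        field itself (step 1e-6 of the length scale by default). Works for
        every kind, including twist.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = h or 1e-6 * self.length_scale
        out = np.zeros((len(X), 3, 3))
        for i, x in enumerate(X):
            F = np.zeros((3, 3))
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                xp = (x + e) + self.displace((x + e)[None, :], t)[0]
                xm = (x - e) + self.displace((x - e)[None, :], t)[0]
                F[:, j] = (xp - xm) / (2 * h)
            out[i] = green_lagrange(F)
        return out if out.shape[0] > 1 else out[0]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


# ---------------------------------------------------------------------------
# generators

def make_box_mesh(nx: int, ny: int, nz: int, spacing: float = 1.0,
                  origin=(0.0, 0.0, 0.0), part_label: str = "brain",
                  perturb: float = 0.0, seed: int | None = None) -> HexMesh:
    """Structured box mesh: (nx+1)(ny+1)(nz+1) nodes, nx*ny*nz hexahedra.

    ``perturb`` jitters interior nodes uniformly by that fraction of the
    spacing (boundary nodes stay put), producing non-degenerate but
    irregular elements for inverse-mapping stress tests.
    """
    if min(nx, ny, nz) < 1 or spacing <= 0:
        raise ValueError("counts must be >= 1 and spacing positive")
    xs = np.arange(nx + 1) * spacing + origin[0]
    ys = np.arange(ny + 1) * spacing + origin[1]
    zs = np.arange(nz + 1) * spacing + origin[2]
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    if perturb > 0:
        rng = np.random.default_rng(seed)
        interior = (
            (coords[:, 0] > xs[0]) & (coords[:, 0] < xs[-1])
            & (coords[:, 1] > ys[0]) & (coords[:, 1] < ys[-1])
            & (coords[:, 2] > zs[0]) & (coords[:, 2] < zs[-1])
        )
        jitter = rng.uniform(-perturb, perturb, size=coords.shape) * spacing
        coords = coords + jitter * interior[:, None]
    return HexMesh(node_coords=coords, elements=np.array(elems),
                   part_labels=[part_label] * len(elems))


def make_bundle(kind: str = "straight", n_fibers: int = 10, *,
                start=(0.0, 0.5, 0.5), direction=(1.0, 0.0, 0.0),
                length: float = 8.0, radius: float = 5.0, pitch: float = 2.0,
                turns: float = 1.0, center=(0.0, 0.0, 0.0),
                spread: float = 0.5, jitter: float = 0.0,
                step: float = 1.0, tract: str = "BUNDLE",
                bounding_box=None, seed: int | None = None) -> TractSet:
    """A labelled bundle of resampled fibers with analytic geometry.

    kinds: "straight" (parallel lines along ``direction``), "arc"
    (semicircle of ``radius`` in the x-y plane), "helix" (radius/pitch/turns
    about z through ``center``). Fibers are offset randomly within
    ``spread`` mm of the base curve, optionally jittered pointwise, then
    arc-length resampled at ``step`` mm. Deterministic under ``seed``.
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    rng = np.random.default_rng(seed)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    tracts = TractSet()
    for _ in range(n_fibers):
        offset = rng.uniform(-spread, spread, size=3) if spread > 0 else np.zeros(3)
        if kind == "straight":
            s = np.linspace(0.0, length, max(int(np.ceil(length * 4)), 8))
            pts = np.asarray(start) + offset + np.outer(s, d)
        elif kind == "arc":
            th = np.linspace(0.0, np.pi, 64)
            pts = (np.asarray(center) + offset
                   + np.column_stack([radius * np.cos(th), radius * np.sin(th),
                                      np.zeros_like(th)]))
        elif kind == "helix":
            th = np.linspace(0.0, 2 * np.pi * turns, int(64 * turns) + 8)
            pts = (np.asarray(center) + offset
                   + np.column_stack([radius * np.cos(th), radius * np.sin(th),
                                      pitch * th / (2 * np.pi)]))
        else:
            raise ValueError(f"unknown bundle kind {kind!r}")
        if jitter > 0:
            pts = pts + rng.normal(0.0, jitter, size=pts.shape)
        if bounding_box is not None:
            lo, hi = (np.asarray(b, dtype=float) for b in bounding_box)
            if np.any(pts < lo) or np.any(pts > hi):
                raise ValueError("bundle geometry exits the stated bounding box")
        tracts.add(tract, resample_to_beams(Streamline(pts), step=step))
    return tracts


def make_history(mesh: HexMesh, spec: DeformationSpec,
                 times: np.ndarray) -> DisplacementHistory:
    """Sample a deformation field at the mesh nodes over ``times``."""
    times = np.asarray(times, dtype=float)
    disp = np.stack([spec.displace(mesh.node_coords, t) for t in times])
    return DisplacementHistory(times=times, displacements=disp)


def make_cluster_fixture(spec: DeformationSpec, times: np.ndarray,
                         n_markers: int = 7, scale: float = 10.0,
                         seed: int | None = None):
    """A marker cluster, its displacement histories, and the analytic strain.

    Markers sit on a non-coplanar arrangement (box corners minus one, at
    ``scale`` mm); the 8-tet connectivity fans out from the first marker.
    Returns (ClusterDefinition, {marker: (n_times, 3)}, E_oracle(t) list).
    """
    rng = np.random.default_rng(seed)
    base = np.array([
        [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1],
        [0.5, 0.5, 0.5],
    ], dtype=float)[:n_markers] * scale
    if n_markers < 4:
        raise ValueError("need >= 4 markers")
    base = base + rng.normal(0.0, 0.01 * scale, size=base.shape)
    ids = [f"NDT{i+1}" for i in range(n_markers)]
    # fan of tets from marker 0 through the remaining markers
    tets = []
    for combo in _tet_fan(n_markers):
        tets.append(tuple(ids[i] for i in combo))
        if len(tets) == 8:
            break
    cluster = ClusterDefinition(marker_ids=ids, marker_coords=base, tets=tets)
    times = np.asarray(times, dtype=float)
    hist = {ids[i]: np.stack([spec.displace(base[i:i+1], t)[0] for t in times])
            for i in range(n_markers)}
    oracle = [spec.strain_oracle(t) for t in times]
    return cluster, hist, oracle


def _tet_fan(n: int):
    from itertools import combinations
    seen = []
    for combo in combinations(range(1, n), 3):
        seen.append((0,) + combo)
    return seen


def make_cora_pair(kind: str = "identical", *, peak: float = 1.0,
                   duration: float = 0.01, n: int = 200,
                   scale: float = 2.0, shift: float = 0.0,
                   noise: float = 0.1, seed: int | None = None):
    """A (reference, test) time-history pair from a haversine base pulse.

    kinds: "identical", "scaled" (test = scale*ref), "shifted" (test delayed
    by ``shift`` seconds), "noisy" (additive white noise of sd ``noise`` *
    peak). Returns ((t, ref), (t, test)).
    """
    t = np.linspace(0.0, 2 * duration, n)
    ref = haversine_pulse(t, peak, duration)
    if kind == "identical":
        test = ref.copy()
    elif kind == "scaled":
        test = scale * ref
    elif kind == "shifted":
        test = haversine_pulse(t - shift, peak, duration)
    elif kind == "noisy":
        rng = np.random.default_rng(seed)
        test = ref + rng.normal(0.0, noise * peak, size=n)
    else:
        raise ValueError(f"unknown pair kind {kind!r}")
    return (t, ref), (t, test)
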