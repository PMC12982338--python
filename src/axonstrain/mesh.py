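"""Hexahedral mesh kinematics.

Trilinear 8-node hexahedra carry the brain-parenchyma solid domain. This
module provides the isoparametric machinery (shape functions, inverse
mapping / point location), and strain post-processing: deformation gradient
``F = I + du/dX``, Green-Lagrange strain ``E = (F^T F - I)/2`` and principal
strains per element per time step. Internal units are mm and seconds;
indices are 0-based.

The corner ordering follows the usual hexahedron convention (bottom face
counter-clockwise, then top face), with natural coordinates xi in [-1, 1]^3:

    corner 0: (-1,-1,-1)   corner 4: (-1,-1,+1)
    corner 1: (+1,-1,-1)   corner 5: (+1,-1,+1)
    corner 2: (+1,+1,-1)   corner 6: (+1,+1,+1)
    corner 3: (-1,+1,-1)   corner 7: (-1,+1,+1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HexMesh",
    "DisplacementHistory",
    "NaturalCoordinate",
    "StrainTensorHistory",
    "PointNotFoundError",
    "shape_eval",
    "deformation_gradient",
    "green_lagrange",
    "principal_strains",
    "element_strain_history",
    "mps_history",
]

# Natural coordinates of the 8 corners, row i = corner i.
_CORNERS = np.array(
    [
        [-1.0, -1.0, -1.0],
        [+1.0, -1.0, -1.0],
        [+1.0, +1.0, -1.0],
        [-1.0, +1.0, -1.0],
        [-1.0, -1.0, +1.0],
        [+1.0, -1.0, +1.0],
        [+1.0, +1.0, +1.0],
        [-1.0, +1.0, +1.0],
    ]
)


class PointNotFoundError(LookupError):
    """A query point lies outside every element of the mesh.

    Carries the nearest element index and the distance (in natural
    coordinates, clipped overshoot) so callers can decide whether to snap.
    """

    def __init__(self, point, nearest_element: int, distance_mm: float):
        self.point = np.asarray(point, dtype=float)
        self.nearest_element = nearest_element
        self.distance_mm = float(distance_mm)
        super().__init__(
            f"point {self.point.tolist()} outside mesh; nearest element "
            f"{nearest_element} at ~{distance_mm:.4g} mm"
        )


def shape_eval(xi) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions and their natural-coordinate gradients.

    Parameters
    ----------
    xi : array-like, shape (3,)
        Natural coordinates.

    Returns
    -------
    N : ndarray, shape (8,)
        Shape-function values; sum to 1.
    dN : ndarray, shape (8, 3)
        Gradients dN_i/dxi_j; columns sum to 0.
    """
    xi = np.asarray(xi, dtype=float)
    g = 1.0 + _CORNERS * xi  # (8,3) factors (1 + xi_c * xi)
    N = 0.125 * g[:, 0] * g[:, 1] * g[:, 2]
    dN = 0.125 * np.stack(
        [
            _CORNERS[:, 0] * g[:, 1] * g[:, 2],
            g[:, 0] * _CORNERS[:, 1] * g[:, 2],
            g[:, 0] * g[:, 1] * _CORNERS[:, 2],
        ],
        axis=1,
    )
    return N, dN


def shape_eval_many(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`shape_eval` for xi of shape (n, 3)."""
    xi = np.asarray(xi, dtype=float)
    g = 1.0 + _CORNERS[None, :, :] * xi[:, None, :]  # (n,8,3)
    N = 0.125 * g[..., 0] * g[..., 1] * g[..., 2]
    dN = 0.125 * np.stack(
        [
            _CORNERS[None, :, 0] * g[..., 1] * g[..., 2],
            g[..., 0] * _CORNERS[None, :, 1] * g[..., 2],
            g[..., 0] * g[..., 1] * _CORNERS[None, :, 2],
        ],
        axis=2,
    )  # (n,8,3)
    return N, dN


@dataclass(frozen=True)
class NaturalCoordinate:
    """Host element plus natural coordinates of an embedded point."""

    element_index: int
    xi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "xi", np.asarray(self.xi, dtype=float))


@dataclass
class HexMesh:
    """A trilinear hexahedral mesh.

    Parameters
    ----------
    node_coords : ndarray, shape (n_nodes, 3)
        Reference coordinates in mm.
    elements : ndarray, shape (n_elements, 8), int
        0-based node indices per element, corner ordering as in the module
        docstring.
    part_labels : sequence of str, optional
        One non-empty label per element; defaults to ``"default"``.
    node_ids : ndarray, optional
        External (file) node ids; defaults to 0..n-1.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    part_labels: list[str] = field(default_factory=list)
    node_ids: np.ndarray | None = None

    # containment tolerance in natural coordinates
    xi_tol: float = 1e-8

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise ValueError("node_coords must have shape (n_nodes, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError("elements must have shape (n_elements, 8)")
        if not self.part_labels:
            self.part_labels = ["default"] * self.n_elements
        if len(self.part_labels) != self.n_elements:
            raise ValueError("one part label per element required")
        if any(not lab for lab in self.part_labels):
            raise ValueError("part labels must be non-empty")
        if self.node_ids is None:
            self.node_ids = np.arange(self.n_nodes, dtype=np.int64)
        self._validate()
        self._grid = None

    # -- basic properties ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_coords(self, e: int) -> np.ndarray:
        """Reference corner coordinates of element ``e``, shape (8, 3)."""
        return self.node_coords[self.elements[e]]

    def _validate(self) -> None:
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= self.n_nodes:
            raise ValueError("element references a non-existent node")
        for e in range(self.n_elements):
            conn = self.elements[e]
            if len(set(conn.tolist())) != 8:
                raise ValueError(f"element {e} repeats a node")
        detJ = self.jacobian_dets_at_centroid()
        bad = np.nonzero(detJ <= 0)[0]
        if bad.size:
            raise ValueError(f"element(s) {bad.tolist()} have non-positive Jacobian")

    def jacobian_dets_at_centroid(self) -> np.ndarray:
        _, dN = shape_eval(np.zeros(3))
        X = self.node_coords[self.elements]  # (ne,8,3)
        J = np.einsum("eia,ib->eab", X, dN)  # dX/dxi per element
        return np.linalg.det(J)

    def element_volumes(self) -> np.ndarray:
        """Volumes by 2x2x2 Gauss quadrature (exact for trilinear hexes)."""
        gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        pts = np.array([[a, b, c] for a in gp for b in gp for c in gp])
        X = self.node_coords[self.elements]
        vol = np.zeros(self.n_elements)
        for xi in pts:
            _, dN = shape_eval(xi)
            J = np.einsum("eia,ib->eab", X, dN)
            vol += np.linalg.det(J)
        return vol

    def centroids(self) -> np.ndarray:
        return self.node_coords[self.elements].mean(axis=1)

    # -- point location --------------------------------------------------
    def _bbox_grid(self):
        """Axis-aligned bounding-box grid for candidate pre-filtering."""
        if self._grid is not None:
            return self._grid
        X = self.node_coords[self.elements]
        lo = X.min(axis=1)  # (ne,3)
        hi = X.max(axis=1)
        gmin = lo.min(axis=0)
        gmax = hi.max(axis=0)
        span = np.maximum(gmax - gmin, 1e-12)
        # ~cube-root cells per axis keeps candidate lists short
        ncell = max(1, int(round(self.n_elements ** (1.0 / 3.0))))
        cell = span / ncell
        buckets: dict[tuple[int, int, int], list[int]] = {}
        ilo = np.clip(((lo - gmin) / cell).astype(int), 0, ncell - 1)
        ihi = np.clip(((hi - gmin) / cell).astype(int), 0, ncell - 1)
        for e in range(self.n_elements):
            for i in range(ilo[e, 0], ihi[e, 0] + 1):
                for j in range(ilo[e, 1], ihi[e, 1] + 1):
                    for k in range(ilo[e, 2], ihi[e, 2] + 1):
                        buckets.setdefault((i, j, k), []).append(e)
        self._grid = (gmin, cell, ncell, buckets, lo, hi)
        return self._grid

    def _candidates(self, point: np.ndarray, pad: float) -> np.ndarray:
        gmin, cell, ncell, buckets, lo, hi = self._bbox_grid()
        idx = np.clip(((point - gmin) / cell).astype(int), 0, ncell - 1)
        cand = buckets.get(tuple(idx), [])
        if pad > 0 or not cand:
            # fall back to a direct AABB pass with padding
            mask = np.all((point >= lo - pad) & (point <= hi + pad), axis=1)
            cand = sorted(set(cand) | set(np.nonzero(mask)[0].tolist()))
        else:
            # restrict to boxes actually containing the point
            cand = [e for e in cand if np.all(point >= lo[e]) and np.all(point <= hi[e])]
        return np.asarray(sorted(cand), dtype=np.int64)

    def _newton_invert(self, e: int, point: np.ndarray,
                       tol: float = 1e-10, maxit: int = 50) -> np.ndarray | None:
        """Invert the trilinear map of element ``e`` at ``point``.

        Newton iteration from the element center; returns xi (possibly
        outside [-1,1]^3) or None on non-convergence / singular Jacobian.
        """
        X = self.element_coords(e)
        xi = np.zeros(3)
        for _ in range(maxit):
            N, dN = shape_eval(xi)
            r = N @ X - point
            if np.all(np.abs(r) < 1e-13 * (1.0 + np.abs(point)).max()):
                return xi
            J = X.T @ dN  # (3,3), dx/dxi
            try:
                dxi = np.linalg.solve(J, r)
            except np.linalg.LinAlgError:
                return None
            xi = xi - dxi
            if np.max(np.abs(dxi)) < tol:
                return xi
            if np.max(np.abs(xi)) > 10.0:  # diverging; point far outside
                return None
        return xi

    def locate_point(self, point, pad: float = 0.0) -> NaturalCoordinate:
        """Find the element containing ``point`` and its natural coordinates.

        Points on shared faces/edges are assigned to the containing element
        with the lowest index (deterministic tie-break). With ``pad > 0`` the
        containment test is relaxed by ``pad`` expressed in natural
        coordinates (used by callers that snap near-boundary points).

        Raises
        ------
        PointNotFoundError
            If no element contains the point within tolerance.
        """
        point = np.asarray(point, dtype=float)
        cand = self._candidates(point, pad=0.0)
        best: tuple[float, int, np.ndarray] | None = None
        tol = self.xi_tol + pad
        for e in cand:
            xi = self._newton_invert(int(e), point)
            if xi is None:
                continue
            over = float(np.max(np.abs(xi)) - 1.0)
            if over <= self.xi_tol:
                return NaturalCoordinate(int(e), np.clip(xi, -1.0, 1.0))
            if best is None or over < best[0]:
                best = (over, int(e), xi)
        if best is not None and best[0] <= tol:
            return NaturalCoordinate(best[1], np.clip(best[2], -1.0, 1.0))
        # widen the candidate search before giving up
        cand2 = self._candidates(point, pad=max(pad, 1.0))
        for e in cand2:
            if e in cand:
                continue
            xi = self._newton_invert(int(e), point)
            if xi is None:
                continue
            over = float(np.max(np.abs(xi)) - 1.0)
            if over <= self.xi_tol:
                return NaturalCoordinate(int(e), np.clip(xi, -1.0, 1.0))
            if best is None or over < best[0]:
                best = (over, int(e), xi)
        if best is not None and best[0] <= tol:
            return NaturalCoordinate(best[1], np.clip(best[2], -1.0, 1.0))
        if best is None:
            # distance estimate from centroids
            d = np.linalg.norm(self.centroids() - point, axis=1)
            raise PointNotFoundError(point, int(np.argmin(d)), float(d.min()))
        # convert natural-coordinate overshoot to a rough mm distance
        e = best[1]
        scale = np.linalg.norm(np.ptp(self.element_coords(e), axis=0)) / 2.0
        raise PointNotFoundError(point, e, best[0] * scale)

    def forward_map(self, nc: NaturalCoordinate) -> np.ndarray:
        """Map natural coordinates back to physical space (mm)."""
        N, _ = shape_eval(nc.xi)
        return N @ self.element_coords(nc.element_index)


@dataclass
class DisplacementHistory:
    """Nodal displacement time histories.

    times in seconds, strictly increasing; displacements in mm with shape
    (n_times, n_nodes, 3). No zero-start assumption is made.
    """

    times: np.ndarray
    displacements: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.displacements.shape[0] != self.times.size or self.displacements.shape[2] != 3:
            raise ValueError("displacements must have shape (n_times, n_nodes, 3)")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_nodes(self) -> int:
        return self.displacements.shape[1]

    def check_mesh(self, mesh: HexMesh) -> None:
        if self.n_nodes != mesh.n_nodes:
            raise ValueError(
                f"history has {self.n_nodes} nodes, mesh has {mesh.n_nodes}"
            )


def deformation_gradient(
    mesh: HexMesh,
    disp: DisplacementHistory,
    element: int,
    time_index: int,
    xi=None,
) -> np.ndarray:
    """Deformation gradient ``F = I + du/dX`` of one element at one time.

    ``xi`` defaults to the element centroid (0,0,0). Exact for affine
    displacement fields. Raises on a singular reference Jacobian.
    """
    if xi is None:
        xi = np.zeros(3)
    _, dN = shape_eval(xi)
    X = mesh.element_coords(element)
    J = X.T @ dN  # dx/dxi
    det = np.linalg.det(J)
    if abs(det) < 1e-30:
        raise np.linalg.LinAlgError(f"singular Jacobian in element {element}")
    dNdX = dN @ np.linalg.inv(J)  # (8,3): dN_i/dX_j
    u = disp.displacements[time_index][mesh.elements[element]]  # (8,3)
    return np.eye(3) + u.T @ dNdX


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain ``E = (F^T F - I)/2`` (symmetrized)."""
    F = np.asarray(F, dtype=float)
    E = 0.5 * (F.swapaxes(-1, -2) @ F - np.eye(3))
    return 0.5 * (E + E.swapaxes(-1, -2))


def principal_strains(E: np.ndarray) -> np.ndarray:
    """Eigenvalues of E in descending order (E1 >= E2 >= E3).

    Accepts a single tensor or a stack (..., 3, 3).
    """
    w = np.linalg.eigvalsh(np.asarray(E, dtype=float))
    return w[..., ::-1]


class StrainTensorHistory:
    """Per-element Green-Lagrange strain tensors over a displacement history.

    Attributes
    ----------
    times : ndarray (n_times,)
    E : ndarray (n_times, n_elements, 3, 3)
    mps : ndarray (n_times, n_elements)
        Maximum principal strain per element per time step.
    """

    def __init__(self, times: np.ndarray, E: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.E = np.asarray(E, dtype=float)
        self.mps = principal_strains(self.E)[..., 0]

    def peak_mps(self) -> np.ndarray:
        """Peak-over-time maximum principal strain per element."""
        return self.mps.max(axis=0)


def element_strain_history(
    mesh: HexMesh,
    disp: DisplacementHistory,
    gauss_average: bool = False,
) -> StrainTensorHistory:
    """Green-Lagrange strain of every element at every time step.

    By default strain is evaluated at the element centroid; with
    ``gauss_average=True`` the tensor is averaged over the 2x2x2 Gauss
    points instead (the solver's sampling rule is not prescribed, so the
    choice is exposed).
    """
    disp.check_mesh(mesh)
    if gauss_average:
        gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        eval_pts = np.array([[a, b, c] for a in gp for b in gp for c in gp])
    else:
        eval_pts = np.zeros((1, 3))

    X = mesh.node_coords[mesh.elements]  # (ne,8,3)
    nt, ne = disp.n_times, mesh.n_elements
    E_out = np.zeros((nt, ne, 3, 3))
    for xi in eval_pts:
        _, dN = shape_eval(xi)
        J = np.einsum("eia,ib->eab", X, dN)  # (ne,3,3)
        dNdX = np.einsum("ib,ebc->eic", dN, np.linalg.inv(J))  # (ne,8,3)
        u = disp.displacements[:, mesh.elements, :]  # (nt,ne,8,3)
        G = np.einsum("teia,eib->teab", u, dNdX)  # du/dX
        F = G + np.eye(3)
        E_out += green_lagrange(F)
    E_out /= len(eval_pts)
    return StrainTensorHistory(disp.times, E_out)


def mps_history(mesh: HexMesh, disp: DisplacementHistory, **kw) -> np.ndarray:
    """Per-element peak (over time) maximum principal strain."""
    return element_strain_history(mesh, disp, **kw).peak_mps()
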