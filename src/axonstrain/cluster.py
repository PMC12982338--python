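"""Marker-cluster strain and CORA time-history rating.

Cadaveric (PMHS) head-impact tests track radio-opaque markers (neutral
density targets, NDTs) with biplanar X-ray; a cluster of markers defines a
set of tetrahedra whose constant-strain deformation gradients give an
experimental estimate of local brain strain. The cluster strain history is
the per-time average over included tetrahedra of the maximum principal
Green-Lagrange strain and of the maximum shear strain (E1 - E3)/2.

Simulated and experimental histories are compared with the CORA correlation
method: a [0, 1] score combining shape (maximal normalized cross-correlation
over a bounded time shift), phase (penalty on that shift) and size (ratio of
curve magnitudes) sub-ratings. Scores map to the sliding rating scale
Unacceptable / Marginal / Fair / Good / Excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import green_lagrange, principal_strains

__all__ = [
    "ClusterDefinition",
    "ClusterStrainHistory",
    "cluster_strain",
    "CORAConfig",
    "CORAResult",
    "cora_score",
    "cora_rating",
    "validation_report",
    "RATING_BANDS",
]


# ---------------------------------------------------------------------------
# cluster strain

@dataclass
class ClusterDefinition:
    """Markers with reference coordinates plus tetrahedral connectivity.

    ``tets`` are 4-tuples of marker ids; ``excluded`` lists tets skipped in
    the cluster average (e.g. when a marker lacks data). Every referenced
    marker must exist and every tet must have positive reference volume.
    """

    marker_ids: list
    marker_coords: np.ndarray
    tets: list[tuple]
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.marker_coords = np.asarray(self.marker_coords, dtype=float)
        if self.marker_coords.shape != (len(self.marker_ids), 3):
            raise ValueError("one 3-D coordinate per marker required")
        self._index = {m: i for i, m in enumerate(self.marker_ids)}
        if len(self._index) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        for t, tet in enumerate(self.tets):
            if len(set(tet)) != 4:
                raise ValueError(f"tet {t} must reference 4 distinct markers")
            if any(m not in self._index for m in tet):
                raise ValueError(f"tet {t} references an unknown marker")
            if abs(self._tet_volume(t)) < 1e-12:
                raise ValueError(f"tet {t} is degenerate (near-zero volume)")

    def marker_index(self, marker) -> int:
        return self._index[marker]

    def _tet_matrix(self, t: int, coords: np.ndarray) -> np.ndarray:
        i0, i1, i2, i3 = (self._index[m] for m in self.tets[t])
        return np.column_stack(
            [coords[i1] - coords[i0], coords[i2] - coords[i0], coords[i3] - coords[i0]]
        )

    def _tet_volume(self, t: int) -> float:
        return float(np.linalg.det(self._tet_matrix(t, self.marker_coords)) / 6.0)

    @property
    def included_tets(self) -> list[int]:
        return [t for t in range(len(self.tets)) if t not in self.excluded]


@dataclass
class ClusterStrainHistory:
    """Times plus per-time cluster MPS and maximum shear strain."""

    times: np.ndarray
    mps: np.ndarray
    max_shear: np.ndarray

    def peak_mps(self) -> float:
        return float(self.mps.max())


def cluster_strain(cluster: ClusterDefinition,
                   marker_displacements: dict,
                   times: np.ndarray) -> ClusterStrainHistory:
    """Cluster strain from marker displacement histories.

    ``marker_displacements`` maps marker id -> (n_times, 3) displacements in
    mm on the common ``times`` base. Per tet and time the constant-strain
    deformation gradient is formed from the four marker motions,
    ``E = (F^T F - I)/2`` follows, and the cluster values are the averages
    over included tets of the maximum principal strain and of
    ``(E1 - E3)/2``.
    """
    times = np.asarray(times, dtype=float)
    nt = times.size
    disp = np.zeros((nt, len(cluster.marker_ids), 3))
    for m, u in marker_displacements.items():
        u = np.asarray(u, dtype=float)
        if u.shape != (nt, 3):
            raise ValueError(f"marker {m!r}: history must have shape (n_times, 3)")
        disp[:, cluster.marker_index(m), :] = u
    missing = set(cluster.marker_ids) - set(marker_displacements)
    if missing:
        raise ValueError(f"missing displacement histories for markers {sorted(missing)}")

    included = cluster.included_tets
    if not included:
        raise ValueError("all tets excluded")
    mps = np.zeros(nt)
    shear = np.zeros(nt)
    ref_inv = {t: np.linalg.inv(cluster._tet_matrix(t, cluster.marker_coords))
               for t in included}
    for k in range(nt):
        cur = cluster.marker_coords + disp[k]
        vals = []
        shr = []
        for t in included:
            F = cluster._tet_matrix(t, cur) @ ref_inv[t]
            w = principal_strains(green_lagrange(F))
            vals.append(w[0])
            shr.append((w[0] - w[2]) / 2.0)
        mps[k] = np.mean(vals)
        shear[k] = np.mean(shr)
    return ClusterStrainHistory(times=times, mps=mps, max_shear=shear)


# ---------------------------------------------------------------------------
# CORA correlation method

@dataclass
class CORAConfig:
    """Parameters of the CORA correlation method.

    The corridor sub-method is not implemented (not used here). All
    constants are explicit because published applications typically tune
    them; these are this package's defaults, not any particular study's.

    weights : (shape, size, phase) sub-rating weights, normalized internally.
    shape_power : exponent applied to the maximal cross-correlation.
    max_shift_fraction : allowed time shift as a fraction of the evaluation
        interval length.
    interval : "overlap" (common time span, default) or (t0, t1).
    """

    weights: tuple = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    shape_power: float = 1.0
    max_shift_fraction: float = 0.20
    interval: object = "overlap"
    n_resample: int = 1000


@dataclass(frozen=True)
class CORAResult:
    shape: float
    size: float
    phase: float
    total: float
    rating: str
    shift: float = 0.0


RATING_BANDS = [
    (0.00, 0.26, "Unacceptable"),
    (0.26, 0.44, "Marginal"),
    (0.44, 0.65, "Fair"),
    (0.65, 0.86, "Good"),
    (0.86, 1.00, "Excellent"),
]


def cora_rating(score: float) -> str:
    """Map a score to its sliding-scale band; shared edges go to the upper band."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    for lo, hi, label in reversed(RATING_BANDS):
        if score >= lo:
            return label
    raise AssertionError("unreachable")


def _resample_pair(ref_t, ref_y, test_t, test_y, config: CORAConfig):
    if config.interval == "overlap":
        t0 = max(ref_t[0], test_t[0])
        t1 = min(ref_t[-1], test_t[-1])
    else:
        t0, t1 = config.interval
    if t1 <= t0:
        raise ValueError("empty evaluation interval")
    t = np.linspace(t0, t1, config.n_resample)
    return t, np.interp(t, ref_t, ref_y), np.interp(t, test_t, test_y)


def cora_score(reference, test, config: CORAConfig | None = None) -> CORAResult:
    """CORA correlation-method score for a (reference, test) curve pair.

    Each curve is a ``(times, values)`` pair; both are linearly resampled to
    a common grid on the evaluation interval. Sub-ratings:

    * shape: maximal normalized cross-correlation over shifts up to
      ``max_shift_fraction`` of the interval, clipped to [0, 1] and raised to
      ``shape_power``;
    * phase: ``1 - |shift*| / max_shift``, where shift* is the argmax shift;
    * size: ``min(L_ref, L_test) / max(L_ref, L_test)`` with L the RMS curve
      magnitude on the interval;
    * total: weighted mean of the three.

    Raises if the reference is identically zero on the interval.
    """
    config = config or CORAConfig()
    ref_t, ref_y = (np.asarray(a, dtype=float) for a in reference)
    test_t, test_y = (np.asarray(a, dtype=float) for a in test)
    t, r, s = _resample_pair(ref_t, ref_y, test_t, test_y, config)
    if np.all(r == 0):
        raise ValueError("reference identically zero on the evaluation interval")

    n = t.size
    dt = t[1] - t[0]
    max_shift_samples = int(round(config.max_shift_fraction * n))
    shifts = np.arange(-max_shift_samples, max_shift_samples + 1)

    best_k, best_shift = -np.inf, 0
    for k in shifts:
        if k >= 0:
            a, b = r[: n - k] if k else r, s[k:]
        else:
            a, b = r[-k:], s[: n + k]
        num = np.dot(a, b)
        den2 = np.dot(a, a) * np.dot(b, b)
        # squared form keeps identical curves at exactly 1.0
        kxy = np.sign(num) * np.sqrt(num * num / den2) if den2 > 0 else 0.0
        if kxy > best_k:
            best_k, best_shift = float(kxy), int(k)

    shape = float(np.clip(best_k, 0.0, 1.0) ** config.shape_power)
    phase = 1.0 - abs(best_shift) / max_shift_samples if max_shift_samples else 1.0
    phase = float(np.clip(phase, 0.0, 1.0))
    L_ref = float(np.sqrt(np.mean(r**2)))
    L_test = float(np.sqrt(np.mean(s**2)))
    if max(L_ref, L_test) == 0:
        size = 1.0
    else:
        size = min(L_ref, L_test) / max(L_ref, L_test)
    w = np.asarray(config.weights, dtype=float)
    subs = np.array([shape, size, phase])
    # (w*subs).sum()/w.sum() is exactly 1.0 when every sub-rating is 1
    total = float(np.clip((w * subs).sum() / w.sum(), 0.0, 1.0))
    return CORAResult(shape=shape, size=size, phase=phase, total=total,
                      rating=cora_rating(total), shift=float(best_shift * dt))


def validation_report(pairs: dict, config: CORAConfig | None = None) -> pd.DataFrame:
    """Score many channel pairs and append the cross-channel average.

    ``pairs`` maps channel name -> (reference, test), each a (times, values)
    pair. Returns a DataFrame with per-channel sub-ratings, totals and
    labels, plus an ``"average"`` row (mean of totals with its own label),
    mirroring how multi-channel validation scores are reported.
    """
    config = config or CORAConfig()
    rows = {}
    for name, (ref, test) in pairs.items():
        res = cora_score(ref, test, config)
        rows[name] = {"shape": res.shape, "size": res.size, "phase": res.phase,
                      "total": res.total, "rating": res.rating}
    df = pd.DataFrame.from_dict(rows, orient="index")
    avg = float(df["total"].mean())
    df.loc["average"] = {"shape": np.nan, "size": np.nan, "phase": np.nan,
                         "total": avg, "rating": cora_rating(avg)}
    df.index.name = "channel"
    return df
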