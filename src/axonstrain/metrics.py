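"""Tract-level and global injury metrics.

Tract-level metrics act on per-beam peak axonal strains:

* the enhanced tract-wise susceptibility index ``phi`` — for each fiber,
  the fraction ``w`` of its beam elements whose peak axonal strain exceeds
  a threshold (0.10 by default); ``phi`` is the mean of ``w`` over the
  tract's fibers. The two-level (beam-within-fiber, fiber-within-tract)
  structure is deliberate: it differs from the naive pooled beam fraction
  whenever fiber lengths differ.
* AxS95 — the 95th percentile of per-beam peak axonal strain in a tract,
  used instead of the max to limit the influence of isolated numerical
  spikes.

Global metrics act on per-solid-element peak maximum principal strain
(MPS): MPS95 (95th percentile over elements) and CSDM, the cumulative
strain damage measure — the volume fraction of the element set whose peak
MPS exceeds a threshold (0.25 by default).

Percentiles use linear interpolation between closest ranks (position
``p*(n-1)`` on sorted data); "exceeds" is the strict inequality throughout
(configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FiberDamageWeight",
    "fiber_weight",
    "phi_tract",
    "axs95",
    "mps95",
    "csdm",
    "tract_metrics_table",
    "global_metrics",
    "GlobalMetrics",
]

EPS_THRESH = 0.10       # axonal strain threshold for fiber damage weights
CSDM_THRESHOLD = 0.25   # MPS threshold for CSDM (CSDM25)
PCTL = 95.0


@dataclass(frozen=True)
class FiberDamageWeight:
    """Damage rate of one fiber: w = n_exceed / n_beams, in [0, 1]."""

    fiber_index: int
    w: float
    n_beams: int
    n_exceed: int


def fiber_weight(peaks, eps_thresh: float = EPS_THRESH, *,
                 fiber_index: int = 0, strict: bool = True) -> FiberDamageWeight:
    """Fraction of one fiber's beams whose peak strain exceeds the threshold.

    Exceedance is strict (``> eps_thresh``) by default; a peak exactly at
    the threshold does not count.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        raise ValueError("fiber has no beam elements")
    if eps_thresh <= 0:
        raise ValueError("eps_thresh must be positive")
    n_exceed = int(np.sum(peaks > eps_thresh if strict else peaks >= eps_thresh))
    return FiberDamageWeight(fiber_index, n_exceed / peaks.size, peaks.size, n_exceed)


def phi_tract(weights) -> float:
    """Mean damage weight over a tract's fibers (sum of w / fiber count)."""
    if len(weights) == 0:
        raise ValueError("empty tract: phi undefined")
    return float(np.mean([w.w if isinstance(w, FiberDamageWeight) else w
                          for w in weights]))


def _percentile(values: np.ndarray, p: float = PCTL) -> float:
    # linear interpolation between closest ranks, position p*(n-1)/100
    return float(np.percentile(values, p, method="linear"))


def axs95(peaks, p: float = PCTL) -> float:
    """95th percentile of per-beam peak axonal strain within a tract."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        raise ValueError("empty tract: AxS95 undefined")
    return _percentile(peaks, p)


def mps95(peak_mps, p: float = PCTL) -> float:
    """95th percentile of per-element peak maximum principal strain."""
    peak_mps = np.asarray(peak_mps, dtype=float)
    if peak_mps.size == 0:
        raise ValueError("empty element set")
    return _percentile(peak_mps, p)


def csdm(peak_mps, volumes=None, threshold: float = CSDM_THRESHOLD, *,
         mode: str = "volume", strict: bool = True) -> float:
    """Cumulative strain damage measure.

    Fraction of the element set whose peak MPS exceeds ``threshold``:
    volume-weighted by default (classic definition), or the plain element
    count fraction with ``mode="count"``.
    """
    peak_mps = np.asarray(peak_mps, dtype=float)
    if peak_mps.size == 0:
        raise ValueError("empty element set")
    exceed = peak_mps > threshold if strict else peak_mps >= threshold
    if mode == "count":
        return float(exceed.mean())
    if mode != "volume":
        raise ValueError(f"unknown CSDM mode {mode!r}")
    if volumes is None:
        volumes = np.ones_like(peak_mps)
    volumes = np.asarray(volumes, dtype=float)
    if volumes.shape != peak_mps.shape:
        raise ValueError("volumes and peak_mps must have the same length")
    if np.any(volumes <= 0):
        raise ValueError("volumes must be positive")
    return float(volumes[exceed].sum() / volumes.sum())


def tract_metrics_table(strain_history, eps_thresh: float = EPS_THRESH,
                        p: float = PCTL) -> pd.DataFrame:
    """Per-tract phi and AxS95 from an :class:`~axonstrain.embedding.AxonalStrainHistory`.

    Returns a DataFrame indexed by tract abbreviation with columns
    ``phi``, ``axs95``, ``n_fibers``, ``n_beams``.
    """
    fiber_peaks = strain_history.fiber_peaks()
    fiber_tract = strain_history.fiber_tract
    rows = {}
    for tract in dict.fromkeys(fiber_tract.tolist()):
        idx = [i for i, t in enumerate(fiber_tract) if t == tract]
        weights = [fiber_weight(fiber_peaks[i], eps_thresh, fiber_index=i)
                   for i in idx]
        pooled = np.concatenate([fiber_peaks[i] for i in idx])
        rows[tract] = {
            "phi": phi_tract(weights),
            "axs95": axs95(pooled, p),
            "n_fibers": len(idx),
            "n_beams": int(pooled.size),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "tract"
    return df


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-domain strain metrics with the configuration that produced them."""

    mps95: float
    csdm: float
    threshold: float
    element_set: str
    mode: str

    def as_dict(self) -> dict:
        return {
            "mps95": self.mps95,
            "csdm": self.csdm,
            "threshold": self.threshold,
            "element_set": self.element_set,
            "mode": self.mode,
        }


def global_metrics(peak_mps, volumes=None, threshold: float = CSDM_THRESHOLD,
                   element_set: str = "all", mode: str = "volume",
                   p: float = PCTL) -> GlobalMetrics:
    """MPS95 and CSDM over an element set."""
    return GlobalMetrics(
        mps95=mps95(peak_mps, p),
        csdm=csdm(peak_mps, volumes, threshold, mode=mode),
        threshold=threshold,
        element_set=element_set,
        mode=mode,
    )
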