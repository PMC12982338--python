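"""End-to-end orchestration: embed -> strain -> metrics -> reports.

A :class:`RunConfig` names the inputs (mesh, displacements, tracts) and the
analysis parameters (resampling step, damage threshold, CSDM threshold,
strain measure, ...). :func:`run_pipeline` validates the config, runs the
chain, and writes the embedding table, per-beam peak summary, per-tract
metric table and global metrics, each stamped with metadata (tool version
and the config echoed verbatim). On any failure partial outputs are removed
and the error re-raised with module context.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .embedding import MEASURES, axonal_strain_dynamic, embed_fibers
from .io import (
    read_displacements_csv,
    read_displacements_h5,
    read_mesh_csv,
    write_embedding,
    write_peak_summary_csv,
)
from .mesh import element_strain_history
from .metrics import global_metrics, tract_metrics_table
from .synth import DeformationSpec, make_box_mesh, make_bundle, make_history
from .tracts import TractSet, read_streamlines, resample_to_beams

__all__ = ["RunConfig", "run_pipeline", "load_config", "synth_scenario"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    # inputs (either files ... )
    mesh_nodes: str | None = None
    mesh_elements: str | None = None
    displacements: str | None = None
    streamlines: str | None = None
    tract_label: str = "BUNDLE"
    # ( ... or a named synthetic scenario)
    scenario: str | None = None
    scenario_peak: float = 0.3

    out_dir: str = "axonstrain_out"
    step_mm: float = 1.0
    eps_thresh: float = 0.10
    csdm_threshold: float = 0.25
    strain_measure: str = "green"
    percentile: float = 95.0
    csdm_mode: str = "volume"
    element_set: str = "all"
    time_unit: str = "s"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not (0 < self.eps_thresh):
            raise ValueError("eps_thresh must be positive")
        if not (0 < self.csdm_threshold):
            raise ValueError("csdm_threshold must be positive")
        if self.strain_measure not in MEASURES:
            raise ValueError(f"strain_measure must be one of {MEASURES}")
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must be in (0, 100]")
        if self.csdm_mode not in ("volume", "count"):
            raise ValueError("csdm_mode must be 'volume' or 'count'")
        if self.scenario is None:
            missing = [k for k in ("mesh_nodes", "mesh_elements",
                                   "displacements", "streamlines")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(f"missing inputs (or set scenario): {missing}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def synth_scenario(name: str, peak: float = 0.3, seed: int = 0):
    """Materialize a named synthetic scenario: (mesh, tracts, history).

    "shear_box": 6x6x6 box (1 mm spacing), a simple-shear pulse of the given
    peak, and a 20-fiber bundle aligned with the shear principal direction
    so axial strain tracks the element MPS. "twist_box": tall box under a
    twist pulse (the inhomogeneous case). "rigid_box": rigid rotation
    (null-strain control).
    """
    if name == "shear_box":
        mesh = make_box_mesh(6, 6, 6, 1.0)
        # fibers along the major principal direction of E at the pulse peak,
        # so every beam sees the element MPS as its axial strain
        g = peak
        E = np.array([[0.0, g / 2.0, 0.0], [g / 2.0, g * g / 2.0, 0.0],
                      [0.0, 0.0, 0.0]])
        w, V = np.linalg.eigh(E)
        d = V[:, np.argmax(w)]
        tracts = make_bundle("straight", 20, start=(0.8, 0.8, 0.8),
                             direction=d, length=4.0, spread=0.4,
                             step=1.0, tract="BUNDLE", seed=seed)
        spec = DeformationSpec(kind="simple_shear", peak=peak, duration=0.01)
    elif name == "twist_box":
        mesh = make_box_mesh(4, 4, 10, 1.0)
        tracts = make_bundle("helix", 10, radius=1.2, pitch=3.0, turns=2.0,
                             center=(2.0, 2.0, 0.5), spread=0.3, step=1.0,
                             tract="BUNDLE", seed=seed)
        spec = DeformationSpec(kind="twist", peak=peak, duration=0.01,
                               length_scale=10.0)
    elif name == "rigid_box":
        mesh = make_box_mesh(4, 4, 4, 1.0)
        tracts = make_bundle("straight", 10, start=(0.5, 0.6, 0.7),
                             direction=(1.0, 0.5, 0.25), length=3.0,
                             spread=0.3, step=1.0, tract="BUNDLE", seed=seed)
        spec = DeformationSpec(kind="rigid_rotation", peak=peak, duration=0.01,
                               axis=(0.0, 0.0, 1.0))
    else:
        raise ValueError(f"unknown scenario {name!r}")
    times = np.linspace(0.0, 0.01, 11)
    return mesh, tracts, make_history(mesh, spec, times)


def _load_inputs(cfg: RunConfig):
    if cfg.scenario is not None:
        return synth_scenario(cfg.scenario, peak=cfg.scenario_peak, seed=cfg.seed)
    mesh = read_mesh_csv(cfg.mesh_nodes, cfg.mesh_elements)
    if str(cfg.displacements).endswith((".h5", ".hdf5")):
        disp = read_displacements_h5(cfg.displacements, time_unit=cfg.time_unit)
    else:
        disp = read_displacements_csv(cfg.displacements, time_unit=cfg.time_unit)
    sls = read_streamlines(cfg.streamlines)
    tracts = TractSet()
    for sl in sls:
        tracts.add(cfg.tract_label, resample_to_beams(sl, step=cfg.step_mm))
    disp.check_mesh(mesh)
    return mesh, tracts, disp


def run_pipeline(cfg: RunConfig) -> dict:
    """Run embed -> dynamic strain -> metrics and write the report bundle.

    Returns a dict with the tract metric DataFrame, the global metrics and
    the output paths. Raises (after removing partial outputs) on any error.
    """
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = {
        "tool": "axonstrain",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.as_dict(),
    }
    try:
        mesh, tracts, disp = _load_inputs(cfg)
        emb = embed_fibers(mesh, tracts)
        if emb.n_beams == 0:
            raise ValueError("no fibers could be embedded in the mesh")
        hist = axonal_strain_dynamic(emb, mesh, disp, measure=cfg.strain_measure)
        tract_table = tract_metrics_table(hist, eps_thresh=cfg.eps_thresh,
                                          p=cfg.percentile)
        solid = element_strain_history(mesh, disp)
        if cfg.element_set != "all":
            keep = np.array([lab == cfg.element_set for lab in mesh.part_labels])
            if not keep.any():
                raise ValueError(f"no elements with part label {cfg.element_set!r}")
        else:
            keep = np.ones(mesh.n_elements, dtype=bool)
        gm = global_metrics(solid.peak_mps()[keep], mesh.element_volumes()[keep],
                            threshold=cfg.csdm_threshold,
                            element_set=cfg.element_set, mode=cfg.csdm_mode,
                            p=cfg.percentile)

        p_emb = out / "embedding.csv"
        write_embedding(p_emb, emb)
        written.append(p_emb)
        p_peaks = out / "beam_peaks.csv"
        write_peak_summary_csv(p_peaks, hist)
        written.append(p_peaks)
        p_tracts = out / "tract_metrics.csv"
        tract_table.to_csv(p_tracts, float_format="%.10g")
        written.append(p_tracts)
        p_report = out / "report.json"
        report = {
            "metadata": meta,
            "global_metrics": gm.as_dict(),
            "tract_metrics": {
                t: {k: (float(v) if k in ("phi", "axs95") else int(v))
                    for k, v in row.items()}
                for t, row in tract_table.iterrows()
            },
            "n_fibers": int(emb.n_fibers),
            "n_beams": int(emb.n_beams),
            "n_dropped_fibers": len(emb.dropped),
            "n_snapped_nodes": int(emb.snapped),
        }
        with open(p_report, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        written.append(p_report)
        log.info("pipeline complete: %d fibers, %d beams, %d dropped",
                 emb.n_fibers, emb.n_beams, len(emb.dropped))
        return {"tract_metrics": tract_table, "global_metrics": gm,
                "report": report, "outputs": [str(p) for p in written],
                "history": hist, "embedding": emb}
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        log.exception("pipeline failed; partial outputs removed")
        raise
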