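# axonstrain

Tract-embedded axonal strain analysis for brain finite-element kinematics.

Concussion-scale head impacts injure the brain along white-matter pathways,
and strain *along the axonal fiber direction* predicts mild traumatic brain
injury better than isotropic measures like maximum principal strain.
`axonstrain` is a solver-agnostic toolkit for the post-solver half of that
analysis, aimed at researchers in computational injury biomechanics who have
(a) tractography streamlines and (b) nodal displacement histories from any
explicit FE code, and want tract-level injury metrics out the other end.

It provides:

* **Embedding** — tractography streamlines (TRK/TCK) resampled at 1.0 mm
  into massless beam chains and embedded in a hexahedral mesh
  (beam-in-solid kinematics: each beam node follows the trilinearly
  interpolated displacement field of its host element);
* **Strain tracking** — dynamic axonal strain per beam from its moved
  endpoints (Green `(λ²−1)/2` by default), alongside the classical static
  projection `aᵀEa` of the solid strain tensor for comparison, plus
  per-element Green–Lagrange / principal strain histories;
* **Injury metrics** — the tract susceptibility index
  `φ = (1/N_fibers) Σ_fibers (n_beams exceeding ε_thresh / n_beams)`
  with `ε_thresh = 0.10`, tract-wise AxS95 (95th percentile of per-beam
  peak strain), and global MPS95 and CSDM (volume fraction with peak
  MPS > 0.25);
* **Validation machinery** — marker-cluster strain via constant-strain
  tetrahedra and CORA correlation-method scoring with the standard
  Unacceptable/Marginal/Fair/Good/Excellent bands;
* **Outcome statistics** — top-five-tract summaries, Spearman/Kendall rank
  correlations with exact small-sample permutation p-values, and
  rotation-axis contribution tables;
* **Material-axis export** — per-element fiber axes (sign-unified so
  antipodal fiber directions cannot cancel) written as LS-DYNA
  `*ELEMENT_SOLID_ORTHO` cards;
* **Synthetic scenarios** — box meshes, fiber bundles and deformation
  pulses with closed-form strain oracles, so the whole chain is testable
  without any external data.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Run the bundled shear-box scenario — a 6×6×6 mm box under a simple-shear
haversine pulse (peak γ = 0.3), with a 20-fiber bundle aligned with the
principal stretch direction:

```sh
axonstrain run --scenario shear_box --peak 0.3 --out-dir out/
```

```
        phi     axs95  n_fibers  n_beams
tract
BUNDLE  1.0  0.174178        20       80
MPS95 0.174178  CSDM 0 (threshold 0.25, volume)
```

Reading it: at γ = 0.3 the peak Green–Lagrange principal strain is
γ²/4 + √((γ²/4)² + γ²/4) = 0.174, every beam of the aligned bundle sees
that value as its axial strain, so every fiber's damage fraction exceeds
the ε_thresh = 0.10 threshold and φ = 1.0. The same 0.174 appears as AxS95
and MPS95 (the field is homogeneous), and CSDM is 0 because no element
exceeds the 0.25 MPS threshold. Re-running with `--peak 0.05` gives
φ = 0 — the threshold crossing the damage index is built around.

Scoring a test curve that is exactly twice its reference:

```sh
axonstrain cora --reference ref.csv --test test.csv
# total 0.833 (Good); shape 1.000 size 0.500 phase 1.000
```

Shape and phase are perfect; the size sub-rating is the min/max RMS
magnitude ratio, 0.5 for a doubled curve.

The same operations are available as a library (`axonstrain.embed_fibers`,
`axonal_strain_dynamic`, `tract_metrics_table`, `cora_score`,
`rank_correlation`, ...), and other subcommands (`embed`, `strain`,
`metrics`, `cluster`, `outcomes`, `synth`, `export-keywords`) compose via
CSV/HDF5/TCK files.

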