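# Methods

## Scope and model

`axonstrain` post-processes brain finite-element kinematics. It does not
solve the equations of motion: it takes a hexahedral mesh (the brain
parenchyma), a nodal displacement history from any solver, and a set of
tractography-derived fiber bundles, and computes how much the axonal fibers
are stretched — the quantity most closely associated with diffuse axonal
injury and concussion risk.

The mechanical core is purely kinematic:

* **Solid strain.** Each 8-node hexahedron carries a trilinear
  isoparametric map. The deformation gradient at the element centroid is
  `F = I + ∂u/∂X` with shape-function gradients mapped through the element
  Jacobian; the Green–Lagrange tensor is `E = (FᵀF − I)/2` and the maximum
  principal strain (MPS) is its largest eigenvalue. Both are exact for
  affine displacement fields and vanish identically under rigid motion —
  the two properties the test suite leans on hardest.
* **Beam-in-solid embedding.** Fibers are chains of massless beam elements
  (null-beam semantics: no force feedback). Each beam node is located in
  its host element by inverting the trilinear map; thereafter it simply
  follows the interpolated displacement field, exactly the kinematic
  content of an embedded-constraint coupling in an explicit FE code.
* **Axonal strain.** Dynamic route: stretch ratio of each beam from its
  moved endpoints, converted by a configurable measure — Green
  `(λ²−1)/2` (default), engineering `λ−1`, or logarithmic `ln λ`. Static
  route (for comparison): projection `aᵀEa` of the host element's tensor
  onto the reference fiber axis. Under homogeneous deformation the two are
  algebraically identical; under inhomogeneous fields (e.g. a twist) the
  dynamic route tracks the rotating fiber and the two diverge, which is the
  reason to embed fibers at all. The solver convention behind a reported
  beam "axial strain" varies between codes, so the measure is a parameter
  and is recorded in every output.

## Tract machinery

Streamlines (TRK/TCK via nibabel, world mm RAS) are resampled by arc length
at a 1.0 mm step, the standard tractography step size. A trailing remainder
shorter than half a step is merged into the previous beam — near-zero-length
beams make strain ratios ill-conditioned — otherwise it is kept as a short
final beam; endpoints are always preserved.

Because streamline orientation (start vs end) is arbitrary, direction
vectors are sign-unified before any averaging: `v` is kept if the product
`v_x·v_y·v_z ≥ 0` and flipped otherwise. This maps antipodal pairs to one
representative, so reversing any fiber cannot change a mean direction. The
product is exactly zero for axis-aligned vectors; "strict" mode leaves them
untouched (for fidelity to the rule as stated), while the default "robust"
mode adds a first-nonzero-component-positive tie-break so such vectors
cannot cancel either. Per-solid-element material axes are the renormalized
mean of the unified unit directions of the beams whose midpoints fall in the
element (midpoint membership is deterministic and cheap; segment clipping
would be a refinement). Averaging is unweighted by default with a
length-weighted option, since either convention is defensible. Axes export
as `*ELEMENT_SOLID_ORTHO` cards with the second axis completed from global z
(fallback y) — any orthonormal completion is valid for transversely
isotropic materials.

## Injury metrics

* **Fiber damage weight** `w` = fraction of a fiber's beams whose peak
  axonal strain exceeds `ε_thresh` (default 0.10, the commonly used
  functional-impairment threshold). "Exceeds" is strict; a peak exactly at
  threshold does not count (configurable).
* **φ (tract susceptibility index)** = mean of `w` over the tract's
  fibers. The two-level structure matters: pooling all beams of a tract
  would weight long fibers more heavily, and a regression test pins the
  difference.
* **AxS95** = 95th percentile of per-beam peak strain within a tract,
  computed over per-beam peaks (a pooled time–beam mode exists). The 95th
  percentile rather than the max suppresses isolated numerical spikes.
* **MPS95 / CSDM** over the solid elements: 95th percentile of per-element
  peak MPS, and the fraction of the element set whose peak MPS exceeds a
  threshold (default 0.25). CSDM is volume-weighted by default (the classic
  definition) with an element-count mode; the element set is a part-label
  filter, default all elements supplied.

Percentiles use linear interpolation between closest ranks (position
`p·(n−1)` on sorted data). Conventions differ across tools, so the choice
is stated and tested (100 equally spaced peaks 0.01…1.00 → 0.9505).

## Cluster validation and CORA

Marker (NDT) clusters are evaluated with constant-strain tetrahedra: per
tet and time step, `F` comes from the four marker motions against the
reference geometry — exact for affine fields, which is also why the cluster
average is connectivity-independent in that case. Cluster MPS and maximum
shear `(E1−E3)/2` are averaged over included tets; tets can be excluded
when a marker lacks data. Degenerate (near-zero-volume) reference tets are
rejected by name.

The CORA correlation method scores a reference/test curve pair in [0, 1]
from three sub-ratings: shape (maximal normalized cross-correlation over
time shifts up to a bounded fraction of the evaluation interval), phase
(linear penalty on the best shift), and size (min/max ratio of RMS curve
magnitudes, so a test curve doubled in amplitude scores 0.5). The total is
a weighted mean; scores map to the sliding bands Unacceptable [0, 0.26),
Marginal [0.26, 0.44), Fair [0.44, 0.65), Good [0.65, 0.86), Excellent
[0.86, 1.0], with shared edges assigned to the upper band. Published
applications tune the constants, so every one is a `CORAConfig` field; the
package defaults are equal weights, shape exponent 1, and a 20% maximum
shift fraction — package defaults, not a reproduction of any particular
study's setting. The corridor sub-method is deliberately not implemented.

## Outcome statistics

Case-level summaries use the mean of the top five tract values (ties at
the cutoff broken lexicographically for determinism). Association with a
three-level ordinal outcome (0 none / 1 prolonged or post-concussive /
2 concussion or acute signs) uses Spearman's rho on average ranks and
Kendall's τ-b. With n ≤ 9 cases, two-sided p-values are exact: one variable
is permuted exhaustively (40320 arrangements at n = 8); the asymptotic
approximation takes over above. The rotation-axis contribution analysis
correlates each tract's case-wise metric with per-axis angular-acceleration
peaks (Pearson by default, Spearman optional), takes absolute values so
negative associations contribute magnitude, and normalizes each tract's row
to sum to 1; tracts with a constant metric (e.g. zero in every case) are
reported missing rather than zero. The correlation type and the
absolute-value convention are recorded in the result's metadata because
both choices are genuinely open.

## Synthetic fixtures

The generators produce every input with closed-form truth: structured box
meshes (optionally node-jittered for inverse-mapping stress tests),
straight/arc/helix bundles resampled at 1.0 mm, and displacement histories
from affine, simple-shear, rigid-rotation and twist fields modulated by a
haversine pulse (smooth, zero-start — the conventional idealization of an
impact). Homogeneous kinds ship analytic `E(t)` and axial-strain oracles;
the twist field's oracle is dense central finite differences of the field
itself (step 10⁻⁶ of the length scale), independent of the mesh kinematics
it checks. What the fixtures do **not** emulate: brain-shaped geometry,
heterogeneous material response, solver dynamics (wave propagation,
contact, CSF), or measured head kinematics. Passing tests therefore
demonstrate that the post-processing chain is exact on fields where
exactness is provable and well-behaved on inhomogeneous ones — not that any
particular head-impact simulation is accurate.

## Numerical choices

* Inverse isoparametric mapping: Newton from ξ = 0, tolerance 1e-10 in
  natural coordinates, 50 iterations max, candidates pre-filtered by an
  axis-aligned bounding-box grid. Points on shared faces go to the
  lowest-index containing element.
* Strain sampling point: element centroid by default; an 8-point Gauss
  average is available (`gauss_average=True`) because solvers differ in
  where they report element strain.
* Beam nodes outside the mesh but within 0.5 mm are snapped to the nearest
  element (tract–mesh registration slop is unavoidable); farther nodes drop
  the whole fiber, always logged and counted, never silent.
* Units: mm and seconds internally; ms inputs convert at ingest. Indices
  are 0-based internally, 1-based only in keyword-file export.
* Reported problem sizes: the bundled scenarios use 5³–6³-element boxes
  with 20–50-fiber bundles and ~10-step pulse histories — small enough to
  be exhaustively checkable against their oracles while exercising every
  code path end to end.

## Known limitations

No force coupling or beam constitutive response (fibers are pure strain
trackers); no fiber tracking or atlas clustering (upstream tools); no mesh
morphing; VTU mesh input is not wired up — the CSV/HDF5 dialects are the
supported interchange. Exact permutation p-values grow factorially and cut
over to asymptotics above n = 9.
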