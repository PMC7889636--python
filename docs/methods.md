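# Methods

## Scope and reduction

The package models blood flow in the murine circle of Willis and its
afferent/efferent vessels as a lumped (0-D) network rather than a 3-D
finite-volume computation. The reduction keeps exactly the ingredients
that the downstream statistics consume: mass conservation at every
junction, the laminar rigid-wall no-slip momentum balance in its fully
developed limit, the inlet/outlet boundary-condition scheme, and the
three section-plane metrics. What is lost relative to a 3-D solver is
secondary flow, curvature and branching losses, and any non-Newtonian
rheology; consequences are noted under *Limitations*.

## Network model

A vascular network is a directed graph of straight segments with length
L [mm] and lumen area A [mm²] (equivalent radius r = √(A/π)); centerline
curvature is folded into L. Twenty-two numbered cross-sectional planes
sit two per major vessel run (BA 1–2, ICA_L 3–4, ICA_R 5–6, ACA_L 7–8,
ACA_R 9–10, MCA_L 11–12, MCA_R 13–14, PcoA_R 15–16, PcoA_L 17–18,
PCA_L 19–20, PCA_R 21–22). Planes 1 (basilar base), 3 and 6 (left/right
ICA at the cervical C1 level) are anatomically anchored; the remaining
placements are a package convention, chosen so that every reported
plane pair (5,6) and (15,16) lies on a single vessel run, and are
overridable through the section registry. Seven angles are registered
at their bifurcations (ACA–MCA left/right, ACA–PcoA left/right,
ICA–PcoA left/right, PCA_L–PCA_R); angles are evaluated from locally
stored endpoint tangents, not global chords, so a bifurcation angle can
be prescribed without moving nodes.

The template has 8 ordered outlets; numbers 7 and 8 are the posterior
cerebral efferents, which sit closest to the basilar bifurcation and
are extended by 1 mm (same lumen) before any solve, mirroring the
acquisition protocol's added outlet sections.

Internal units: mm, mm², mm³/s, mmHg, g/mm³, mm²/s. With these, a
pressure assembled from g·mm⁻¹·s⁻² is numerically a pascal, so a single
constant (133.322 Pa/mmHg) handles all conversions.

## Steady solver

Each segment carries the Hagen–Poiseuille conductance
G = πr⁴/(8μL). Inlet k injects v_k·A_k (velocities in cm/s are
converted to mm/s); the total inflow is split over outlets in
proportion to outlet area, so the global balance holds exactly by
construction. Nodal pressures solve the weighted graph Laplacian with
this Neumann data; the first outlet is grounded at 0 mmHg (only
pressure differences are physical). The solve is dense
(`numpy.linalg.solve`) — CoW networks have ~20 nodes. A post-solve
assertion requires interior residuals below 10⁻⁹ of total inflow.

Default blood properties are ρ = 1.05 g/cm³ and ν = 3.33 mm²/s
(μ = ρν ≈ 3.5 mPa·s), standard murine whole-blood values; the source
study states the flow model but not property values, so both are
configurable (`blood: {mu_mPas, rho_g_per_cm3}` in run configs).

## Pulsatile solver

The inlet waveform is a dimensionless modulation of the measured mean
velocity: factor 1 plus complex harmonics c_k at ω_k = 2πk/T,
T = 0.137 s. The referenced murine velocity waveform is not reproduced
in the available text, so the default is a parametric stand-in: a
wrapped-Gaussian systolic pulse normalised to mean 1 with peak ≈ 1.6×
mean, truncated to 8 harmonics, strictly positive over the cycle, and
fully overridable from config (period, per-harmonic amplitude/phase).

Because the reduced model is linear — rigid walls and the convective
term (v·∇)v dropped, the standard Womersley regime — each harmonic is
solved independently with complex impedances
Z(ω) = (iωρL/πr²)·[1 − 2J₁(Λ)/(ΛJ₀(Λ))]⁻¹, Λ = i^{3/2}α, α = r√(ω/ν).
ω = 0 reduces to the Poiseuille resistance; α > 600 raises an explicit
overflow error (Bessel growth) with guidance to subdivide. The
area-proportional outlet split is frequency-independent, hence it holds
at every instant of the cycle.

The protocol step Δt = 0.005 s does not divide T = 0.137 s
(T/Δt = 27.4). The default grid therefore uses ceil(T/Δt) = 28 uniform
intervals, which makes cycle averages of every harmonic k ≤ 8 exactly
zero and hence cycle-averaged flows exactly equal to the steady
solution; the literal 0.005 s grid is available behind
`strict_grid=True` (averages then carry an O(Δt) windowing error).

For typical murine radii (0.1–0.3 mm) and this cycle, α evaluates to
≈ 0.4–0.7 at the fundamental — the viscous-dominated regime — rather
than "order tens"; the package reports α per segment so users can judge,
and the quantity is covered by unit tests rather than assumed.

## Metrics

* Mass flow Q_i = ρ · (volumetric flow through the plane's segment),
  reported in mg/s, signed by the plane normal (oriented with the
  segment; a flag flips it).
* Peak velocity: steady mode is the Poiseuille profile peak, exactly
  2× the plane-mean velocity; transient mode reconstructs the radial
  Womersley profile per harmonic (flow-normalised shape
  [1 − J₀(Λy)/J₀(Λ)]/F(α)), takes the spatial maximum of |u| at each of
  the 28 snapshots on a 200-point radial grid, and cycle-averages. At
  the α values above, the instantaneous profile is near-parabolic and
  the peak stays on the axis, so the cycle-averaged peak essentially
  equals the steady peak — flows and resistances average to the steady
  values exactly in this linear model, a documented fidelity gap with
  respect to a 3-D solver where the two modes differ by a few percent.
* Hydraulic resistance R_ij = ΔP_ij/Q_i in mmHg·s·g⁻¹. ΔP defaults to
  the *total* pressure drop (static, interpolated linearly along the
  segment, plus dynamic head ρv̄²/2 from the plane-mean velocity),
  matching the "average total blood pressure" wording; a static-only
  variant exists because solver conventions are ambiguous on this
  point. For same-area plane pairs the two variants coincide.
* The 73-parameter registry is 7 angles + 22 areas + 11 mass flows
  (one per two-plane vessel run) + 22 peak velocities + 11 resistances
  (consecutive same-run plane pairs). This is the only decomposition
  consistent with resistance "between planes 5 and 6" and mass flow
  "between planes 15 and 16" being single reported quantities.
  A zero-flow branch makes its R undefined; it is logged and stored as
  a missing value without aborting the metric set.

## Synthetic cohort

The generator is calibrated to the published per-arm summary
statistics (mean ± SE at n = 7/5/10/9). Per-animal variation uses the
population SD implied by the printed SE, sd = SE·√n.

Two paths:

* **Geometry path** (`sample_animal`): plane areas and angles are drawn
  per feature and truncated to physical ranges (> 0, (0°, 180°)) by
  resampling; inlet velocities are drawn with a latent left/right
  coupling (correlation 0.9) so bilateral differences are a clean
  within-animal contrast. These animals feed the solvers, which induce
  physically consistent geometry–hemodynamics correlations.
* **Distribution path** (`direct_feature_matrix`): feature matrices are
  drawn directly from the group Normals, untruncated — truncation would
  bias heavy-tailed rows (e.g. the basilar area of the 2-month diabetic
  arm, sd ≈ 0.5× mean) by ~2% and break exact moment recovery. This
  path carries the quantitative fidelity checks; the geometry path is
  property-tested.

Features are sampled independently across columns (only marginal
means/SEs are published; any correlation structure would be invented),
except the explicit L/R velocity coupling. A covariance hook can be
added by swapping the per-column sampler.

Rows the source leaves to its supplement are filled with placeholder
distributions, tagged `source=placeholder` in the packaged table:
identical across arms (so synthetic group differences come only from
published effects), anchored to the published control row where one
exists, otherwise to per-vessel class defaults. The inlet-velocity
placeholders encode the published qualitative pattern: controls
12 cm/s bilaterally, the 1-month diabetic arm 20% lower on both sides,
the 2-month diabetic arm 20% lower on the right side only — this is
what makes flow asymmetry 2d-specific. The asymmetry can be switched
off per config.

Template calibration: internal-carotid length (2.0 mm) and the 0.25/0.75
plane fractions were set by inverting the Poiseuille formula so that the
control-mean template's steady R between planes 5 and 6 lands near the
published control mean; the worked example in the README shows the
resulting 55.4 vs 57.2 ± 4.7.

Seeds: one master seed; every animal, stage and replicate derives a
31-bit child seed by SHA-256 hashing of (master, stage, identifier), so
results are independent of execution order.

## Statistics

* **Normality**: KS statistic with plug-in mean/SD (the Lilliefors
  situation). The classical KS null is anti-conservative here, so the
  p-value is Monte-Carlo calibrated (default 10⁴ same-size
  standard-normal samples, same estimator, seeded).
* **t-tests**: pooled-variance Student by default (the named test),
  Welch behind a flag. A summary-statistics entry point
  (mean, SE, n per group) lets printed table rows be re-tested
  directly. No multiple-testing correction by default — raw per-feature
  p-values across the 73 parameters mirror the original analysis; a
  Benjamini–Hochberg switch exists.
* **Asymmetry**: paired t on within-animal L−R differences. All-zero
  differences return t = 0, p = 1; a constant non-zero offset has zero
  variance and raises a degenerate-sample error rather than returning
  an infinite statistic.
* **PLS-DA**: NIPALS PLS2 on autoscaled X (centred, unit variance;
  constant columns are guarded) against centred one-hot arm membership,
  convergence 10⁻¹⁰ on the score vector, X- and Y-deflation between
  components, two components by default. Successive score vectors are
  orthogonal (< 10⁻⁸ cosine, property-tested). scikit-learn's PLS and a
  cross-covariance-SVD formulation serve as independent cross-checks in
  tests only.
* **Stepwise elimination**: backward removal of the lowest-VIP feature
  while stratified 5-fold CV classification accuracy (class = argmax of
  the PLS regression prediction) does not drop more than `tol` (default
  0.05) below the best accuracy seen; `tol=∞` strips to one feature.
  Model stability is judged on the *pre-elimination* CV accuracy,
  because post-selection accuracy is optimistically biased by the
  search itself.
* **ANOVA**: two-way (pathology: control/diabetes × duration: 1/2
  months) on each PLS score axis, Type II sums of squares via
  statsmodels OLS. The default model is additive: with the study's 31
  animals this yields residual df = 28, the only model variant
  consistent with the reported F(1,28); the interaction term is
  available behind a flag (df = 27). Constant score vectors return
  F = 0, p = 1.

## Problem sizes used by tests and the acceptance script

Generator fidelity uses 10⁵ draws per published row (1% mean, 3% SD
tolerances) plus a coverage check of the 2·SE band over 100 cohorts at
the printed arm sizes. Conservation sweeps 100 randomly perturbed
anatomies (steady; pulsatile on a quarter of them, all 28 snapshots).
The type-I error rate uses 5000 null cohorts at n = 10 vs 9 drawn from
the published control distribution. The end-to-end pattern (2-month
comparison flags more features than the 1-month one; asymmetry rejects
predominantly in the 2-month diabetic arm) is evaluated over 100
seeded cohort replicates.

## Limitations

* The solver is 0-D: no velocity fields off the tube axis, no wall
  shear stress, no curvature or junction losses, rigid walls, Newtonian
  blood, and steady/pulsatile metrics that coincide up to the
  profile-shape factor discussed above.
* Distribution-path cohorts have independent features; solver-path
  cohorts induce physical correlations but their hemodynamic marginals
  are set by the template geometry, which is calibrated only at the
  anchored planes.
* Placeholder table rows are conventions, clearly tagged; quantitative
  recovery claims are restricted to the published rows.
* Passing tests demonstrate fidelity to the printed group statistics
  and internal physical/statistical consistency — not agreement with
  new animal data.
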