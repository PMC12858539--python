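# Methods

This note documents the models, conventions and design choices behind
`coroshear`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what passing tests do and do not demonstrate.

## Reduced-order flow model

The package deliberately replaces 3D finite-volume CFD with a quasi-steady
Poiseuille closure on the vessel centerline. At every instant the flow is
treated as fully developed laminar pipe flow at the local radius r(s):

- wall shear magnitude |τ_w| = 4μQ(t)/(π r³), directed along the axial
  surface tangent (sign follows Q);
- pressure gradient dP/ds = −8μQ(t)/(π r⁴), integrated by the trapezoidal
  rule along the centerline;
- a lumped Borda–Carnot-type expansion loss
  ΔP_exp = K·(ρ/2)(Q/A_ref)²(A_ref/A_min − 1)², applied as a step at the
  minimal lumen area (default K = 1), representing post-stenotic
  separation losses the viscous term cannot capture;
- lumen velocity u(ρ) = 2Q/(π r²)(1 − (ρ/r)²) with optional rigid swirl
  u_θ = Ωρ for nonzero helicity.

Assumptions: Newtonian blood (μ = 0.0035 Pa·s, ρ = 1056 kg/m³), rigid
no-slip walls, axisymmetric single-branch geometry, quasi-steady response
(no Womersley phase lag; unsteady inertia is neglected). The payoff is that
every index has an exact closed form, so the index implementations are
verified against oracles rather than against another solver. A Womersley
provider could be added behind the same `WallFieldSeries` interface without
touching the index code.

Transient runs simulate three cardiac cycles and retain the last. The
reduced model is periodic by construction, so this is a convention mirror
(and an exercise of the retention logic used for ingested series), not a
numerical necessity.

The outlet is a prescribed constant pressure; no lumped resistance or
myocardial-mass allometry is modeled. Hyperemia is a direct 2–4× scaling
of the baseline waveform. The constant inlet pressure default is 93 mmHg.

## Geometry and waveform defaults

The stenosis profile r(s) = R₀(1 − δ·e^{−(s−s₀)²/2σ²}) is smooth,
differentiable, and makes severity δ equal the diameter-stenosis fraction
by construction (area stenosis = 1 − (1−δ)²). Defaults: R₀ = 2 mm, length
60 mm, throat at 30 mm, σ = 4 mm, δ = 0.5. The axial grid snaps one point
onto the throat so the stored minimum radius is exact.

The waveform is an offset sinusoid Q(t) = Q̄(1 + a·sin 2πt/T) with
Q̄ = 1 mL/s, T = 0.8 s, a = 0.5 by default. One parameter spans the
unidirectional (a ≤ 1) and zero-mean oscillatory (separate field mode)
regimes; it is not an anatomical coronary waveform shape, and no claim is
made that it is.

## Index definitions and numerics

Time integration is trapezoidal on the uniform retained-cycle grid
(endpoints included). For smooth periodic integrands this is spectrally
accurate; for the rectified |τ| integrand of TAWSS it is second order,
which the convergence tests measure.

- TAWSS = (1/T)∫|τ_w|dt; OSI = ½(1 − |∫τ_w dt|/∫|τ_w|dt) ∈ [0, ½];
  RRT = [(1−2·OSI)·TAWSS]⁻¹ ≡ T/|∫τ_w dt|.
- WSSG and GON need surface gradients: per vertex, a tangent frame is
  built with p along the time-averaged shear direction (axial fallback
  where shear vanishes) and q = n × p; gradients come from a least-squares
  fit over the structured 1-ring (axial and circumferential grid
  neighbors). WSSG = √((∂τ_p/∂p)² + (∂τ_q/∂q)²) of the time-averaged
  field; GON = 1 − |∫G dt|/∫|G|dt with the instantaneous gradient vector
  G(t) = (∂τ_p/∂p, ∂τ_q/∂q). The stencil weights are precomputed once and
  applied to all timesteps.
- Vorticity/helicity are computed by finite-difference curl on the
  structured (s, ρ, θ) lattice in cylindrical components (second-order
  edge stencils, so the parabolic profile differentiates exactly); the
  generated series also stores the analytic vorticity for oracle use.
  Axial derivatives treat the lattice as quasi-parallel, which is exact
  for straight tubes and an approximation under strong taper.
- CT-FFR = time-mean P(s_distal)/time-mean P(inlet), with s_distal =
  lesion end + 2.5 cm (configurable in [2, 3] cm), clamped to the vessel
  end with a flag when the vessel is shorter.

Undefined values are flagged, not silently propagated: zero-shear vertices
give NaN OSI/GON; RRT at (1−2·OSI) < 10⁻⁹ is reported as +inf (fully
oscillatory shear is singular by definition). Segment aggregation uses
only finite members and reports flagged counts. This policy follows from
the observation that near-singular RRT values do occur in practice
(reference-normalized RRT distributions have enormous variance), so the
singular set must be explicit.

## Segmentation and normalization

Arc length is 0 at the ostium, meters internally, millimeters at the
interface. Lesion extent is where the mesh-measured radius drops below
(1 − ε) of the reference radius, ε = 0.05 by default (no standard boundary
rule exists; ε is exposed). The extent is tiled into ceil(extent/sub_length)
contiguous half-open sub-segments of the configured 2–4 mm length; the most
distal segment carries the remainder. A `merge_small_remainder` option
folds a < 1 mm remainder into the neighboring segment instead. Segment
means are area-weighted on the surface and volume-weighted in the lumen.

Normalization is statistic-matched — lesion min/reference min, max/max,
mean/mean — rather than dividing every statistic by the reference mean.
With a common mean denominator, normalized minima could never exceed
normalized means within the same index, a pattern reference-normalized
cohort tables do show; the statistic-matched reading is the one consistent
with such data, and a mean-denominator mode would be a small variant.
Outcome labels use the ΔDS% bands: ≥ +5 progression, ≤ −5 regression
(boundaries inclusive), else stable.

## Synthetic cohort generator

One row per lesion sub-segment; defaults: 209 segments over 34 vessels and
22 patients (6–7 segments per vessel), class fractions 53/128/28
(stable/progression/regression) out of 209. Covariates are drawn
multivariate-normal on a latent scale and exponentiated where positivity is
required, with moments (e.g. N.Min.TAWSS 1.27 ± 1.06, N.Max.Helicity
1.75 ± 2.89) chosen to emulate right-skewed reference-normalized index
distributions; the correlation matrix is identity by default and
configurable. Outcomes are drawn sequentially: progression is Bernoulli
with logit α_p + xᵀβ_p (generating β_p = log 0.38 on N.Min.TAWSS, log 1.44
on N.Max.Helicity); non-progression rows draw regression with logit
α_r + xᵀβ_r (β_r = log 0.10 on N.Ave.GON, log 0.13 on N.Ave.Vorticity).
Intercepts are calibrated per cohort by root-finding so the expected class
fractions match the targets. Consequences worth knowing:

- the progression one-vs-rest model is exactly logistic, so its fit
  recovers β_p directly;
- the regression coefficients live in the conditional (non-progression)
  model; a marginal one-vs-rest fit attenuates them, which is why the
  recovery study fits regression vs stable on the non-progression subset;
- ΔDS% is drawn uniformly inside the band matching the drawn label, so
  `label_outcome` round-trips; each segment row receives its own outcome
  draw (segments are treated as independent analysis units, matching how
  the rows are modeled downstream).

The generator emulates distributional shape, nesting structure and effect
sizes — not spatial correlation along a vessel, measurement error in plaque
volumetry, or between-patient boundary-condition variability. Passing
recovery tests therefore show the estimator chain is correct under the
stated generating model, not that real lesion data would yield these
effects.

## Statistical stage

Logistic fits use maximum likelihood (statsmodels) with Wald SE/Z/p and
OR = e^β with 95% CI = e^{β±1.96·SE}. Separation is detected (failed
convergence, runaway |β| > 20, or non-finite SE) and raised as an explicit
error; a Firth-penalized Newton solver (Jeffreys prior) is available via
`firth=True`. Group comparisons are one-way ANOVA with per-group
mean ± SD. ROC analysis uses the empirical curve: trapezoidal AUC (equal
to pairwise concordance with ties scored ½), Youden-maximizing threshold
with ties broken toward higher specificity, and percentile CIs from a
class-stratified bootstrap (2000 resamples by default, seeded). The
bootstrap was preferred over analytic AUC CIs as assumption-light and
exactly reproducible; both model contrasts (one-vs-rest and
conditional-subset) are reachable through the API since the appropriate
reference group is a modeling choice.

## Problem sizes and runtime

Default test and pipeline sizes are chosen for second-scale runs: tubes of
60–120 axial × 16–32 circumferential vertices, 16–48 samples per cycle,
12–50 radial lattice samples, 200-replicate recovery studies at n = 209,
and 100–2000 bootstrap resamples depending on context. All are parameters;
nothing in the method is tied to these values.

## Known limitations

- No Womersley/unsteady inertia, no non-Newtonian rheology, no turbulence
  or transitional modeling in severe stenoses; the quasi-steady closure
  understates oscillatory phenomena a 3D solver would produce.
- Single-branch tubes only: bifurcations enter via Murray splits on stated
  child diameters and via the configurable reference-segment bound, not as
  geometry; bifurcation-region exclusion masks are caller-supplied.
- The legacy-VTK reader targets files written by this package, not
  arbitrary VTK output; ingested CFD series must match its layout.
- Lesion rows are treated as independent (no cluster-robust errors); the
  patient id column is retained so users can add clustering corrections.
- Remodeling index and plaque burden are pass-through columns with no
  internal formula.
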