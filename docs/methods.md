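# Methods

This note documents the models implemented in `ribpet`, the defaults they
ship with, the design choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Physical decay of the implanted mixture

A ¹¹C ion beam stopping in tissue implants, besides the projectiles, small
amounts of ¹⁰C (projectile fragmentation) and ¹⁵O (target fragmentation).
The total activity decays as `Σᵢ wᵢ 2^(−t/T½,ᵢ)` with defaults

| isotope | half-life | raw fraction |
|---|---|---|
| ¹¹C | 20.34 min (1220.4 s) | 0.96 |
| ¹⁰C | 19 s | 0.03 |
| ¹⁵O | 2.04 min | 0.005 |

The raw fractions sum to 0.995; they are renormalised to unit sum at
construction (the model treats them as fractions of the implanted fragments)
and the raw values are kept for reference. Fractions are taken as fixed
weights of the decay model as quoted, without distinguishing end-of-spill
from time-averaged composition. Activity units are arbitrary (counts per
frame); no becquerel calibration is attempted since it would depend on the
reconstruction. Beyond t ≈ 120 s the ¹⁰C term is gone (>6 half-lives) and
the mixture is ¹¹C-dominated: the non-¹¹C share of the total is below 1%,
which is the form in which the "¹¹C dominance" property is asserted (a
comparison against a *unit-amplitude* pure-¹¹C curve would differ by the
constant ¹¹C weight, a pure normalisation).

## Washout kinetics

Model: `A(t) = A₀ · A_phys(t) · [Wₛ e^(−kₛt) + (1−Wₛ) e^(−k_f t)]` with
0 ≤ Wₛ ≤ 1 and the label convention kₛ ≤ k_f (fits are re-sorted, swapping
Wₛ ↔ 1−Wₛ, so label switching cannot occur).

**Fitting.** Weighted least squares, weights `1/max(counts, 1)` (Poisson
variance ≈ mean; the weighting of the original analysis is not published, so
this is the natural counting-statistics choice). Bounds: Wₛ ∈ [0, 1],
10⁻⁸ ≤ k ≤ 1 s⁻¹. Deterministic multi-start initialisation over
kₛ ∈ {10⁻⁴, 10⁻³}, k_f ∈ {10⁻², 10⁻¹} s⁻¹, Wₛ ∈ {0.3, 0.7}, plus starts
seeded from a preliminary single-exponential fit that straddle the
degenerate kₛ = k_f ridge; the best χ² wins. Non-convergence returns
`converged=False` rather than raising. The default fit window is the first
30 min after the end of irradiation (configurable). Pooled group fits
concatenate the animals' samples (per-animal fitting plus parameter pooling
is available by calling the single-series fit in a loop).

**Model selection.** The decision rule is the standard nested F:
`F = ((χ²₁−χ²₂)/(n_free₂−n_free₁)) / (χ²₂/dof₂)`, p from F(Δdof, dof₂),
double model chosen at p < 0.05. The bare ratio χ²₁/χ²₂ is reported
alongside because it is sometimes quoted directly, but a bare ratio has no
reference distribution, so it never drives the decision.

**A known calibration property.** Under a *single*-exponential truth the
two-component model is degenerate: Wₛ = 1 lies on the parameter boundary and
k_f is unidentified. The χ² improvement then has a non-standard null
distribution — a point mass at zero (≈ 27% of replicates in our Monte
Carlo) plus a continuous part lighter than χ²(2) — so the nominal
F(2, dof) calibration is **conservative**: the measured rejection rate at
α = 0.05 is ≈ 2%, not 5%. A 60-restart global-optimisation cross-check
confirms this is a property of the statistic, not of the optimiser. The
practical consequence is only that the test errs on the side of the simpler
model; power on clearly double-exponential data remains essentially 100% at
the default signal levels.

**Outlier screening** uses the 1.5×IQR-from-the-median rule
(linear-interpolation quartiles) applied to the fitted rate constants within
a group; a degenerate IQR of zero excludes nothing and warns. Group contrasts
of fitted parameters use the two-sided pooled-variance t-test; a zero pooled
variance with unequal means is flagged and reported as p → 0.

## Analytic beam model

The beam module is a parameterised analytic stand-in for Monte Carlo
transport, used to generate synthetic dose/activity inputs with the right
qualitative anatomy; it is not dosimetry.

- **Ranges.** Bragg–Kleeman `R_p = 0.022·E^1.77` mm (proton, water, E in
  MeV), scaled by A/Z². At equal energy per nucleon, isotope ranges of one
  element scale exactly as their mass numbers — 11/12 ≈ 0.917 for ¹¹C vs
  ¹²C, the ~91% figure that motivates the activity/dose peak proximity of
  radioactive beams.
- **Pristine curves.** The differentiated Bragg–Kleeman stopping power
  `∝ (R−z)^(1/p−1)` (exponent ≈ −0.435, an integrable end-of-range
  singularity) is bin-integrated exactly on a uniform 0.1 mm grid and
  convolved with a Gaussian range spread. The grid is padded proximally
  before convolution so the smearing conserves the integral (to <0.1%)
  instead of leaking mass across the entrance plane.
- **Range spread.** Intrinsic straggling σ = 0.012·R^0.95/√A mm combines in
  quadrature with a beam energy-spread term (default 0.5 mm). The second
  term reflects the sizeable momentum spread of a secondary beam produced by
  in-flight fragmentation; without it a 1 mm-spaced pristine set cannot form
  a flat SOBP (inter-peak ripple ≈ ±11%). With it the default 12 mm SOBP is
  flat to ±2%.
- **SOBP weights** solve a nonnegative least-squares problem against a flat
  unit target over the modulation width ending at the deepest pristine peak,
  with pristine shifts at 1 mm spacing plus one extra proximal member (which
  absorbs the proximal-boundary edge effect; with it the solved weights are
  monotonically nonincreasing from distal to proximal, the classic
  ridge-filter property, verified in tests rather than assumed).
- **Implanted activity** is the superposition of per-component stopping
  Gaussians — each SOBP component contributes a Gaussian at *its own* end of
  range with the effective range spread — plus a flat in-flight production
  tail proportional to the fraction of projectiles still in flight (default
  amplitude 0.1 of the stopped peak), blurred with the PET point-spread
  sigma (default 0.8 mm). A single Gaussian at the weight-averaged range
  would misplace the activity peak by several millimetres for a modulated
  field and destroy the peak/fall-off alignment; the superposition is both
  the physical picture and the form that reproduces it (the default pair
  aligns to 0.23 mm).
- **Spill structure.** Defaults: 2.5×10⁶ particles per 200 ms spill every
  3.2 s (duty cycle 6.25%). `simulate_buildup` deposits one production
  quantum per spill and decays it with the mixture physics; after the last
  spill the curve is pure physical decay by construction. A rough
  energy-over-mass dose-rate estimate (logged, not asserted) lands near
  1 Gy/min for the default fluence over a 15×12 mm elliptical field.
- The measured 80→20% distal fall-off width of the normalised pristine peak
  is ≈1.3σ (verified to scale linearly with σ). This is narrower than the
  1.68σ of a pure error-function edge because the normalisation reference is
  the singular peak, not a plateau.

Out of scope by design: nuclear fragmentation cross-sections, lateral
scattering, CT-based heterogeneity, detector response.

## Profile metrics

Volumes are (x lateral, y vertical, z beam depth) with voxel-centre
coordinates from spacing and origin. The BEV profile sums, per depth slice,
voxels whose x and y centres lie within ±aperture (default ±1 mm, inclusive
boundaries — the voxel-centre rule is exactly testable against a brute-force
loop). The peak depth refines the maximal sample with a 3-point parabola
(ties resolve to the deeper sample; plateaus skip refinement). The distal
fall-off depth normalises to the maximum and searches from the deepest
sample *backwards*, guaranteeing the distal crossing even when the entrance
region also passes the level; crossings are linearly interpolated, and
level = 1 degenerates to the peak-sample depth. No attenuation or
partial-volume corrections are applied (for small targets they change the
profile shape negligibly). Shifting a volume by whole voxels shifts every
metric by exactly that distance (tested).

## Cohort statistics

Caliper volumes use `V = (4/3)π·a·b·c` with `c = (a+b)/2`, the measured
lengths entering exactly as recorded (no semi-axis halving) — this matches
how such caliper formulas are conventionally applied, and the unit case
a = b = 1 gives 4π/3. Growth summaries are per-group, per-day mean ± SEM;
censored animals simply stop contributing (no imputation). The SE of the
median uses the asymptotic normal factor √(π/2) = 1.2533 times s/√n; a
caption quoting "1.2533·σ/n" is read as a typesetting loss of the radical,
since 1.2533 *is* the factor relative to σ/√n. Grip metrics keep weeks ≥ 6
(no radiation effect expected in the first month) and report the per-animal
median force plus the fraction of timepoints below 100 force units; the
threshold and cutoff are configurable, and forces are stored in as-recorded
units (the 100 "N" threshold is implausibly large for a mouse in SI newtons,
so no unit conversion is attempted). Two-sample contrasts use Mood's median
test (2×2 above/below the pooled median, chi-square) and the Mann–Whitney U
(exact small-sample null, cross-checked against full enumeration);
correlations use Pearson's r with a Fisher-z 95% CI, with constant inputs
flagged as degenerate rather than raised.

## Synthetic cohort generator

The generator is the package's stand-in for a study's raw data; its defaults
*are* the simulated study conditions, chosen once:

- **Groups**: 27 controls, 7 low-dose (5 Gy), 8 high-dose (20 Gy); the grip
  arm adds 8 tumour-free controls.
- **Washout truths** (not published values — modelling choices recorded in
  every manifest): A₀ = 2×10⁴ counts/frame; low dose Wₛ = 0.5, high dose
  Wₛ = 0.95, both with kₛ = 8×10⁻⁴ s⁻¹ and k_f = 1.2×10⁻² s⁻¹. This encodes
  the qualitative dose contrast — a strong fast washout component at low
  dose that essentially disappears at high dose, consistent with early
  vascular shutdown — without asserting any published rate constants.
  Per-animal lognormal jitter (CV 20%) on the rates, Poisson counting noise,
  60 s frames over 30 min.
- **Growth**: exponential for controls (rate 0.2/day, CV 30% across
  animals, V₀ = 50 mm³), monotone regression (0.12/day) at high dose,
  regression with recurrence from day 14 at low dose; caliper axes
  back-computed from volume (a = b) with 10% lognormal noise; euthanasia
  (censoring) at 15 mm diameter, keeping the triggering measurement.
- **Grip/spine**: irradiated animals draw a lognormal spine-count fraction
  (median 0.05, log-σ 0.4); grip force = 130 − 600·fraction + N(0, 15) at
  biweekly timepoints over 26 weeks; controls share the baseline. The
  injected effect gives a clearly negative spine-grip correlation and a
  Mood-test-detectable group deficit at the default group sizes.

All randomness flows from a single integer seed through per-stream
`numpy.random.Generator`s, so identical specs are byte-identical — the
round-trip tests (generate → analyse → recover truth) rely on this.

**What passing tests show — and don't.** The generator produces exactly the
statistical structure the estimators assume: Poisson counts on the true
model curve, separable beam-shaped volumes, lognormal biological
variability. Passing recovery tests therefore demonstrate correctness of the
implementation and calibration of the statistics *under the assumed model*,
not robustness to real-data features the generator omits: reconstruction
artefacts and sensitivity inhomogeneity, prompt-radiation background,
anatomical heterogeneity and repositioning shifts, washout model
misspecification, or non-lognormal inter-animal variability.

## Numerical choices and problem sizes

Depth grids use 0.1 mm steps; SOBP flatness is judged over the modulation
width; NNLS comes from scipy. Fits use lmfit's Levenberg–Marquardt with
default tolerances; noiseless round trips recover two-component parameters
to ~10⁻⁶ relative. The headline consistency runs use 100 synthetic animals
per dose group for recovery/selection statistics, 500 replicates for the
null-calibration Monte Carlo, and 10⁶ normal draws for the SE-of-median
confirmation — sizes chosen so Monte Carlo error is well below the asserted
margins while the whole suite stays desk-scale.

## Known limitations

- The analytic beam model is qualitative: ranges from the Bragg–Kleeman
  power law are not calibrated to any measured beamline (no energy
  degradation chain, no nozzle materials), and no target ever depends on an
  absolute measured peak position.
- The F-test's nominal calibration is conservative for boundary nulls (see
  above); consumers who need exact size under the single-exponential null
  should calibrate by parametric bootstrap.
- Washout fits assume independent Poisson frames; correlated reconstruction
  noise would invalidate the stated standard errors.
- Mood's median test uses the chi-square approximation (with small samples
  it is itself approximate); the Mann–Whitney switches to its exact null
  only where scipy does.
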