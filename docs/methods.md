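# Methods

`bindkinetics` implements the standard multi-spectroscopic workflow for
characterizing the binding of a small molecule (the *quencher*) to a
fluorescent transport protein, modelled on a serum-albumin titration:
fixed protein (2 µM), quencher stepped from 0 to 100 µM, intrinsic
fluorescence excited at 279 nm and read at 341 nm, at several temperatures.

## Models

**Inner-filter correction.** Absorption of excitation and emission light by
the sample attenuates the measured signal. With decadic absorbances A_ex and
A_em (1 cm path, centred-cuvette approximation),

    F_corr = F_obs · 10^((A_ex + A_em)/2).

The correction is the identity at zero absorbance, symmetric in the two
absorbances, and never decreases the intensity. Secondary inner-filter
geometry effects are not modelled.

**Stern–Volmer quenching.** F₀/F = 1 + K_SV·[Q]. K_SV (L·mol⁻¹) is the
slope of an ordinary least-squares line of F₀/F on [Q]; the apparent
bimolecular quenching rate constant is K_q = K_SV/τ₀ with τ₀ the unquenched
lifetime (default 10⁻⁸ s, typical of serum albumin; supplied, not fitted).
The intercept is left free by default — robust to small F₀ normalization
error — with a diagnostics warning when it departs from 1 by more than 5%
(configurable); an intercept-constrained mode is available. The [Q]=0 point
contributes the trivial (0, 1) datum and is included in the regression.

**Mechanism classification.** Static quenching (ground-state complex) shows
K_SV strictly decreasing with temperature and K_q above the
diffusion-controlled ceiling of ~2×10¹⁰ L·mol⁻¹·s⁻¹; collisional quenching
shows the opposite. The classifier demands a strict monotone K_SV trend
(ties → non-monotonic → indeterminate) and, at a single temperature, falls
back to the K_q magnitude alone.

**Double-log binding fit.** For an n:1 complex under static quenching,
log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q]. OLS over the informative points
([Q] > 0, 0 < F < F₀) gives log₁₀K_b (intercept) and the apparent site
number n (slope). Points unusable on the log scale are excluded — never
clipped — and listed with reasons, so every input point is accounted for.
Base-10 logarithms throughout this fit. The affinity bands reported
alongside (< 10⁴ weak-to-moderate, 10⁴–10⁶ moderate-to-strong, > 10⁶
strong, L·mol⁻¹) are conventional order-of-magnitude labels and are
configurable in the stoichiometry call's tolerance.

**van't Hoff thermodynamics.** ln K_b = −ΔH/(RT) + ΔS/R (natural log here,
by convention), fitted by OLS of ln K_b on 1/T; ΔG(T) = ΔH − T·ΔS. R =
8.314 J·mol⁻¹·K⁻¹; public values in kJ. K_b is treated as dimensionless
inside the logarithm (implicit 1 mol·L⁻¹ standard state). A two-temperature
ladder is exact by construction and flagged as such. Force classification
follows the Ross–Subramanian sign rules: (ΔH > h_tol, ΔS > 0) hydrophobic;
(ΔH < −h_tol, ΔS < 0) hydrogen-bond/van der Waals; (|ΔH| ≤ h_tol, ΔS > 0)
electrostatic; otherwise mixed. h_tol = 4 kJ·mol⁻¹ quantifies "ΔH ≈ 0";
the literature rule is qualitative, so the band is explicit and
configurable.

**Spectral evidence.** Band maxima are located by a 3-point quadratic
refinement of the discrete maximum (ties break toward the lower axis value;
edge maxima are returned at the grid value; flat windows return their
leftmost point flagged). Shifts below half the grid step are reported as
"none". On nanometre axes a positive shift is "red"; on wavenumber axes the
energy ordering reverses, so a negative cm⁻¹ shift is labelled "red".
Synchronous-fluorescence shifts (Δλ = 60 nm → tryptophan, 15 nm → tyrosine)
are measured between the first and last titration points — matching the
qualitative reading such experiments receive — with a per-point trend table
emitted alongside. FTIR amide windows are 1600–1700 (amide I) and
1500–1600 cm⁻¹ (amide II); UV windows 210–235 and 260–300 nm; the molar
absorptivity ε = A(≈279 nm)/(c·l) is computed from the highest-concentration
spectrum. No baseline correction, smoothing, or amide-I secondary-structure
deconvolution is performed.

**Competition analysis.** Site assignment compares log₁₀K_b between a blank
and site-marker conditions (phenylbutazone → Sudlow site I, diazepam →
site II): a probe that lowers log K_b by ≥ 0.2 claims its site. Metal-ion
conditions are labelled enhanced / reduced / unchanged at |Δlog K_b| ≥ 0.15.
Both thresholds are configurable and echoed in the output; the defaults
leave a wide margin between responsive conditions (Δ ≈ 0.3–0.6) and
unresponsive ones (Δ ≈ 0.03–0.05) in the reference system. Comparisons use
log K_b, which is invariant under uniform intensity rescaling.

## Synthetic data

The generator inverts each forward model exactly, so every analysis can be
validated by round-trip recovery:

- attenuation: F = F₀/(1 + K_SV·[Q]) (Stern–Volmer mode) or
  F = F₀/(1 + K_b·[Q]ⁿ) (binding mode); an optional (ΔH, ΔS) pair drives
  K_b(T) through the van't Hoff relation across the temperature ladder;
- inner-filter distortion: A_ex = A_protein + ε_ligand·[Q]·l rising 0.08 →
  0.42 over the default titration (ε_ligand = 3400 M⁻¹cm⁻¹, 1 cm path),
  A_em = 0; the observation is F·10^(−(A_ex+A_em)/2), the literal inverse of
  the correction;
- noise: multiplicative Gaussian with relative σ (capped at 20%), fully
  seeded — multiplicative rather than additive because fluorescence detector
  error scales with signal and this keeps F positive at plausible σ;
- spectra: Gaussian bands on regular 1-unit grids with centres on-grid
  (emission 341 nm; synchronous tryptophan band drifting +2 nm, tyrosine
  stationary; amide I 1646 → 1642 cm⁻¹ with amide II stationary — only the
  amide I response is part of the emulated system; UV helix band near
  220 nm gaining intensity with a +2 nm drift, aromatic band at 279 nm
  reaching A = 0.112, i.e. ε = 56 000 M⁻¹cm⁻¹ at 2 µM protein). Band heights
  follow the titration attenuation model.

Defaults are the study conditions (F₀ = 641, 11-point 0–100 µM grid,
303/310/318 K); they are statements of the emulated experiment, not tuning
knobs.

What the simulator does *not* emulate: wavelength-dependent detector
response, scattering and baseline drift, photobleaching, secondary
inner-filter geometry, band asymmetry, or correlated noise. Passing tests
therefore demonstrate correctness of the estimators and classification
rules under the stated statistical model, not robustness to every artifact
of real instruments.

## Numerical choices

- All regressions are plain OLS (scipy); R² is computed from residuals and
  clamped to [0, 1]; a zero-variance response is treated as a perfect flat
  fit (slope 0, R² 1) rather than NaN.
- K_q = K_SV/τ₀ and K_b = 10^(log K_b) are maintained as exact identities
  in the result objects.
- CSV parsing uses correctly-rounded float conversion, and writers emit
  full-precision `repr` values, so a write/read cycle round-trips
  bit-exactly (concentration unit conversion µM ↔ mol·L⁻¹ is the one
  lossy step; series generated in mol·L⁻¹ and written in µM round-trip
  exactly on the default decimal grids).
- Peak interpolation offsets are clamped to ±1 grid step and window bounds.

## Noise behaviour of the double-log fit

The double-log intercept is an extrapolation to log₁₀[Q] = 0 (1 mol·L⁻¹),
roughly 4.5 decades beyond the titration range, so intensity noise is
amplified: at 1% relative noise and the 11-point grid, the replicate spread
of log K_b stays below 0.1 only when the quenched fractions K_b·[Q] are
well above the noise floor (K_b ≳ 3×10⁴ L·mol⁻¹ for this grid; measured
sd ≈ 0.03 at K_b = 10⁵). For a weak binder (K_b ~ 10² – 10³) the smallest
quenched fractions are comparable to 1% noise and the spread grows to
0.2–3 log units. The test suite asserts the sub-0.1 spread in the
signal-dominated regime and, separately, that the spread grows monotonically
as binding weakens. Practical consequence: for weak binders, reported
log K_b values are only as trustworthy as the effective intensity noise is
small (the R² ≈ 0.999 typical of published tables corresponds to effective
noise well below 1%).

## Known limitations

- No cooperative / multi-class binding models, nonlinear direct fits of
  F([Q]), heat-capacity (curved van't Hoff) models, or lifetime fitting.
- The linearized double-log model assumes pure static quenching; mixed
  mechanisms bias K_b.
- Site and metal calls are threshold rules on fitted constants; they carry
  no structural information.
- Spectrum ingestion handles the package's CSV dialect only (no JCAMP-DX or
  vendor formats).
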