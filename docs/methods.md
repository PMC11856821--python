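# Methods

## Dose model

All per-examination quantities are deterministic products of the
scanner-reported indices and a size-dependent conversion factor.

The effective diameter is the geometric mean of the anteroposterior and
lateral dimensions of the largest transverse cross-section,
Deff = √(AP·LAT), in mm. Using the *largest* cross-section is a
deliberate convention: the trunk is not a cylinder, so a single-slice
Deff overestimates the size correction for the rest of the scan range.
The engine accepts any caller-supplied AP/LAT pair, so a per-slice mean
diameter can be substituted upstream without code changes; the default
convention is the largest slice because that is what a manual caliper
measurement on a picture-archive workstation produces.

The conversion factor k maps the phantom-referenced CTDIvol to a
size-specific dose. We use the AAPM Report 204 effective-diameter
parameterisation k = a·exp(−b·Deff_cm) with the report's published
coefficients (body32: a = 3.704369, b = 0.03671937 cm⁻¹; head16:
a = 1.874799, b = 0.03871313 cm⁻¹). Rationale: a single pair of
auditable constants rather than a transcribed table. A table-
interpolation mode is also provided, reading a packaged
`(phantom, deff_cm, k)` CSV — the fit evaluated on a 1-cm grid, 6–55 cm,
rounded to two decimals, matching the report's printed precision — so a
site can swap in its own grid (e.g. water-equivalent-diameter based,
AAPM 220 style). Fit and packaged table agree to ≤ 0.01 everywhere by
construction, and the test suite asserts it. k = 1 at
Deff = ln(a)/b ≈ 35.66 cm for the body phantom; the model requires k to
be strictly decreasing and the validity range to contain that crossing.

Records store dimensions in mm (the unit of dose-report exports and
caliper tools); k evaluation converts to cm internally. Diameters
outside the 6–55 cm validity range are clamped to the nearest edge with
a warning by default because the audit's inclusion criteria (BMI 18–35)
exclude the cachectic and severely obese anyway; a strict mode
(`clamp=False`, CLI `--strict-range`) raises instead.

`ctdi_bias` reports the fractional under/over-estimation of the
size-specific dose by CTDIvol as 1 − 1/k (positive = CTDIvol
underestimates, i.e. the patient is smaller than the k = 1 crossing).
This is one of two common conventions (the other is k − 1, normalising
by CTDIvol rather than by SSDE); the sign convention is fixed and
documented here, and the quantity is an output of the model, not a
fitted value.

The DLP→ED coefficients f ship as abdomen_pelvis = 0.015 and
chest = 0.014 mSv/(mGy·cm) — the conventional adult trunk values — and
are fully overridable in the YAML config, since sites may adopt newer
tissue-weighting revisions.

The stochastic-risk helper applies the linear no-threshold slope of 5%
additional probability of stochastic effects per sievert (so 10 mSv →
0.05%). It is a communication aid, not a dosimetric quantity.

## Cohort statistics

- Normality is screened per variable per group with Shapiro–Wilk at
  α = 0.05; a two-group comparison uses Student's t only when *both*
  groups pass, otherwise Mann–Whitney U (two-sided). The t-test is the
  Welch form — equal variances are not assumed between sexes. The
  reported Mann–Whitney statistic is centred (U − n₁n₂/2) so that it is
  antisymmetric under group exchange, like the t statistic.
- Correlations are Spearman rank correlations throughout (dose
  variables are right-skewed). p-values use the large-sample
  approximation; below n = 30 a seeded pairing-permutation test
  (9 999 resamples) replaces it.
- The BMI inclusion window is the closed interval [18, 35] kg/m²; the
  boundary cases are covered by tests. Exclusion criteria that require
  image review (ascites, artifacts, prior surgery…) are represented as
  caller-supplied flag codes in the `exclusion_flags` column, so the
  policy stays auditable from tabular data alone.
- The scan-length audit uses three bins (reduced / increased /
  unchanged, change = diagnostic − topogram); a diameter exactly equal
  to the 320 mm reference is counted in the "not smaller" census bin.
  The census reports the deviation from the reference under both
  natural bases — (ref − mean)/ref and mean(|Deff − ref|)/ref — because
  summary reports in the field are often ambiguous about which is
  meant.
- No multiple-testing correction is applied: each test is reported at
  its nominal α = 0.05, matching standard practice in single-centre
  dose audits; the report output states this.

## Synthetic cohort

The generator emulates a single-centre adult abdominal/pelvic CT audit
(n = 247, 113 women / 134 men) and is the test bed for every cohort
operation. Per record:

1. Sex ~ Bernoulli(113/247).
2. (height, weight) from a per-sex bivariate normal (correlation 0.5,
   configurable) rejected outside BMI ∈ [18, 35]. Targets: women
   162.06 ± 6.33 cm, 69.19 ± 13.24 kg; men 176.77 ± 6.77 cm,
   79.67 ± 17.40 kg. Because BMI truncation shifts the retained means
   (most visibly male weight, ≈ +1.5 kg), the pre-truncation locations
   are adjusted by a deterministic fixed-point iteration on a fixed
   pilot sample so the *truncated* means reproduce the targets; at
   n = 5000 the per-sex means recover to well within 2 standard errors.
3. Deff_cm = 0.79·BMI + 9.4 + N(0, σ). The slope/intercept are the
   published anthropometric regression of effective diameter on BMI;
   the residual σ = 2.5 cm was calibrated once, by Monte-Carlo
   bisection (`calibrate_residual_sd`), so the expected sample Spearman
   ρ(BMI, Deff) at n = 247 is 0.78, and then frozen as the default. No
   published residual variance exists for this regression, so the
   correlation is the calibration target.
4. AP/LAT solve AP·LAT = Deff², LAT/AP = r with log r ~
   N(ln(350.30/240.63), 0.10) — the mean aspect ratio of the published
   mean dimensions, preserving the geometric-mean identity exactly.
5. CTDIvol = 1.57·exp(0.065·Deff_cm)·exp(N(0, 0.13)) mGy. Attenuation-
   based tube-current modulation raises dose roughly exponentially with
   patient diameter (here doubling per ≈ 10.7 cm); base and noise are
   set so the mean CTDIvol is ≈ 11.4 mGy at the cohort's mean diameter
   and ρ(CTDIvol, Deff) ≈ 0.88.
6. Topogram length per sex (women 476.98 ± 44.19 mm, men
   493.10 ± 43.93 mm); scan-length change is a three-component mixture
   — reduction (p = 0.538, half-normal scale 75/68 mm women/men),
   increase (p = 0.457, scale 35/67 mm), unchanged (p = 0.005) — whose
   per-sex means and SDs match the published scan-length table.
   DLP = CTDIvol × diagnostic length (cm).
7. Age per sex is generated for the summary tables only; no dose
   mechanism depends on it.

Everything is drawn from one `numpy` Generator, so a fixed (config,
seed) pair yields a bit-identical cohort.

What the generator does **not** emulate: within-patient diameter
variation along z (each record has a single Deff), scanner/protocol
heterogeneity, pitch and over-ranging in DLP, the weak age–dose
dependence, and any non-Gaussian anthropometric shape. Passing
parameter-recovery tests therefore demonstrates that the pipeline
measures what the generator encodes — not that real cohorts satisfy
the model. Under the defaults the cohort mean EDss/ED ratio falls in
1.15–1.30 (typically ≈ 1.21), the analogue of the ≈ 20% gap between
traditional and size-specific indices in adult abdominal audits, and
the fraction of diameters below the 320 mm reference averages ≈ 71%.

## Numerical and design notes

- All computation is double precision; rounding (2 decimals for
  mGy/mSv, whole percent for ratios) is applied only in the report
  renderer.
- The per-record identity EDss/ED = DLPss/DLP = SSDE/CTDIvol = k is
  exact algebra and is asserted to 1e−12 in property tests; it is the
  package's main internal consistency check.
- The metrics CSV is the 14 schema columns followed by the 9 derived
  columns at full precision — one flat, stable contract; rounded
  presentation tables are a separate artifact of the `audit` command.
- Malformed input rows are collected with row numbers and field names,
  never silently dropped; duplicate `exam_id`s beyond the first are
  treated as row errors.
- Empty strata are marked absent rather than zero; single-record strata
  report a mean with SD unavailable.
- Problem sizes in the test and acceptance runs (200 replicates of
  n = 247; one n = 5000 cohort for moment recovery) were chosen so the
  Monte-Carlo standard error of each recovered quantity is several
  times smaller than its acceptance band.

## Known limitations

- Geometric Deff, not water-equivalent diameter: for the trunk the two
  differ by a few percent; the table mode is the extension point.
- Single-slice Deff overestimates the whole-scan correction for
  patients measured at their widest slice (see above).
- ED via DLP·f is a population-level estimate; organ-dose Monte Carlo
  is out of scope.
- The synthetic cohort is a statistical stand-in, not patient data; all
  cohort-level "recovered" numbers are self-consistency checks of the
  pipeline against its own generative model.
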