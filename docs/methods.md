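# Methods notes

This note records the models, algorithmic choices and defaults behind
`domchar`, and what the synthetic validation does and does not demonstrate.

## Mass scale and ion convention

All arithmetic uses monoisotopic masses (C 12 exactly, H 1.0078250319,
N 14.0030740052, O 15.9949146221, S 31.97207069, P 30.97376151). Spectra
are assumed to contain singly deprotonated anions [M−H]⁻ only — standard
for negative-mode electrospray of DOM — so neutral mass = observed m/z +
1.00727646 Da (an H atom minus its electron). Adducts and multiple charging
are out of scope. The first ¹³C isotopologue sits at +1.0033548 Da with
intensity ≈ 0.0107 × C × parent.

## Formula descriptors and categories

DBE = 1 + C − H/2 + (N + P)/2, with phosphorus counted trivalent (the
common DOM convention). AImod discounts half the oxygens as potential
carbonyl bonds; a non-positive denominator or negative value is clamped
to 0, since "negative aromaticity" has no structural meaning.

Categories are assigned with an explicit precedence that resolves the
overlaps a bare threshold list permits: saturated (DBE = 0) first, then
aromatic (AImod ≥ 0.5), then unsaturated-with-N (1.5 ≤ H/C ≤ 2 and N > 0),
then unsaturated O-rich/O-poor, then highly unsaturated (AImod < 0.5,
H/C < 1.5). The with-N class takes precedence over the O split because it
is reported as its own column in composition tables. Formulas with DBE > 0
but H/C > 2 (possible only with heteroatoms) fall outside every window and
are routed to saturated as the nearest class; this is logged and affects a
negligible fraction of real libraries. Category percentages are computed on
formula **counts**, while heteroatom-group abundances and the weighted
descriptors (MW_w, DBE_w, AImod_w, H/C_w, O/C_w) are **intensity**-weighted
— the two bases are deliberately different, matching how such tables are
conventionally reported. MW_w uses neutral (not ion) mass.

Exclusivity percentages are relative to the total number of distinct
formulas in the dataset, not to the sample's own count.

## Formula enumeration

Candidates for a neutral mass are all compositions within the element
bounds (defaults C 1–100, H 0–200, N 0–4, O 0–80, S 0–2, P 0–1) passing
the screens: 0.3 ≤ H/C ≤ 2.5, O/C ≤ 1.2, integer non-negative DBE, and the
nitrogen rule. For CHNOSP with trivalent-P bookkeeping, integer DBE and the
nitrogen-rule parity are the same condition, h ≡ n + p (mod 2), checked
once. The fully saturated endpoint h = 2C+2+N+P is always admitted even
when small C puts its H/C above 2.5 (CH₄ is a valid composition).

Enumeration is backed by a database of every valid composition under the
bounds, built vectorized and sorted by exact mass (~2·10⁶ entries under the
defaults, built in a few seconds and cached per bounds), so each query is a
binary search. A naive six-nested-loop enumerator in the test suite serves
as the independence oracle.

Under the default bounds the minimum exact-mass split between two valid
compositions of the same nominal mass is a few tenths of a mDa (e.g.
C₁₀HP vs N₄O₆ differ by 0.197 mDa), so a 0.5 ppm window above ~400 Da can
contain more than one legal candidate; resolution of those ties is the job
of the series-support step below.

## Noise filtering, recalibration, alignment

`mdl_filter` estimates the noise level from the lowest-intensity band of
the spectrum (default: lowest quartile) and removes peaks below
median(band) + level × 1.4826·MAD(band), default level 4. This presumes the
input is a raw exported mass list whose low-intensity end is dominated by a
narrow instrument-noise band. Peak-picked lists are usually already
signal-to-noise thresholded; on such input a quantile band falls inside the
analyte intensity distribution and the filter would remove real low-
abundance peaks. The high-level `assign_samples` chain therefore leaves
MDL off by default (`mdl_level=None`) and relies on the duplicate-consensus
rule for noise rejection; pass `mdl_level=4` explicitly for raw lists.

`recalibrate` subtracts the median ppm offset of peaks matched to
user-supplied reference formulas (pre-match tolerance 2 ppm, minimum 5
matches, otherwise skipped with a warning). The median makes the estimate
robust to mismatched references.

`align` pools all replicates, sorts by m/z and single-links consecutive
masses closer than the tolerance (default 0.5 ppm). Each group may hold at
most one peak per replicate; when a replicate contributes several, the peak
nearest the group's intensity-weighted mean stays and the rest become
singleton groups. The group mass is the intensity-weighted mean, which
roughly halves the random mass error of duplicate measurements.

## Candidate resolution

Series support for a candidate counts how many other mass groups hold a
composition differing by 1–10 units of CH₂, CO₂, H₂, H₂O or O. The
reference set is iterated to a fixed point: the first pass counts against
the compositions of *unambiguous* (single-candidate) groups, later passes
against the current winners. Seeding with the unambiguous assignments
matters: counting against the full candidate pool lets wrong candidates in
dense composition regions support each other. Iteration is bounded
(default 5 passes); a two-cycle between equivalent resolutions is accepted
silently, other non-convergence keeps the last pass and logs a warning.
Ties break by smaller |ppm error|, then fewer heteroatoms, then
lexicographic formula string, making resolution deterministic.

The N/S/P plausibility rule removes candidates above the per-element caps
(N ≤ 4, S ≤ 2, P ≤ 1) or, when two or more heteroatom species co-occur,
above the combined cap N+S+P ≤ 5 — unless the candidate's predicted ¹³C
satellite is found at +1.0033548 Da with intensity within 0.5–2.0 × the
prediction. Contaminant removal is exposed as a user-supplied exclusion
mass list; no contaminant database is bundled.

Finally, a formula contributes to a sample only when present in **every**
replicate of that sample; formulas surviving in no sample are dropped, and
sample columns are normalized to unit sum.

## Ordination and envfit

PCoA is classical metric scaling: Gower double-centering of −D²/2,
symmetric eigendecomposition, scores = eigenvectors × √eigenvalue for
positive eigenvalues. Negative eigenvalues (expected with Bray–Curtis) are
reported but not corrected — no Lingoes/Cailliez adjustment — so users can
judge their size. Axis signs are fixed by making each axis's largest-
magnitude coordinate positive.

`envfit` regresses a descriptor on the first two axis scores (configurable)
and permutes the descriptor across samples to obtain
p = (1 + #{permuted r² ≥ observed}) / (1 + n_perm), default 10,000
permutations, significance at p < 0.1. The +1 smoothing guarantees p > 0
and exact validity of the test. Permutations are vectorized, so the 1,000-
repeat null calibration in the validation suite runs in seconds. A constant
descriptor has no defined direction and returns a flagged null result.

## Bioactivity

Percent inhibition is 100 × (1 − signal/negative control). The default IC50
estimator interpolates the 50% crossing linearly in log10(concentration)
between the bracketing dilutions, matching how screening dilution series
are usually read; a four-parameter logistic fit is available
(`method="logistic"`) and the two agree within 10% on clean Hill-slope-1
curves. Curves never reaching 50% at the top concentration are censored
as ">Cmax" (printed ">200" for the standard 200 µg/mL series). Replicate
curves are fitted independently and reported as mean ± sd; a sample is
censored only when all replicates are. Censored values are excluded from
descriptor–activity regressions and counted. TEAC conversion inverts the
Trolox calibration line ((activity − intercept)/slope) and normalizes by
dry weight; it requires ≥ 3 calibration points and a non-degenerate slope.

## Synthetic-data model

The generator emulates a typical multi-source DOM screening design:
16 samples in four source groups measured in duplicate, ~2,000 formulas per
sample over a 100–1000 Da scan range, < 0.1 ppm mass error, ~10% noise
peaks. Group category weights default to the characteristic contrasts
between peat, freshwater, porewater and deep oceanic water (aromatic-rich
terrestrial vs highly-unsaturated-rich marine); weight rows are normalized
to sum exactly 1.

Choices such data do not pin down, fixed here once:

- **Intensities** are lognormal(0, 1) — FT-ICR intensity distributions are
  heavy-tailed — with multiplicative lognormal replicate noise (σ = 0.1)
  and normalized to unit sum per sample.
- **Noise peaks** are uniform in m/z with intensities resampled from the
  lowest decile of the replicate's signal; `noise_peak_fraction` is the
  fraction of the final list (n_noise = f/(1−f) × n_signal).
- **Formula sharing**: half of each sample's formulas are reused from its
  group's shared pool and a quarter from a dataset-wide pool, so samples
  overlap the way polarity fractions of the same source waters do; without
  sharing, Bray–Curtis saturates near 1 and ordination is structureless.
- **Bioactivity link**: −log10(IC50) = −log10(150 µg/mL) + 4.0 × aromatic
  formula fraction, giving IC50s from ~2 µg/mL (peat-like) to ~110 µg/mL
  (deep-water-like), inside the span of typical screening tables. Plates
  are 2-fold dilutions from 200 µg/mL, duplicate wells, 4-parameter
  logistic response (floor 0, ceiling 100, Hill 1) with 3% Gaussian read
  noise and zero-mean negative controls.
- The generator only emits formulas that pass the assigner's own screens
  and caps, and draws neutral masses so the anion also stays inside the
  scan range: ground truth represents *assignable* compositions.

What passing the recovery tests shows — and does not. The synthetic model
has no isotopologue fine structure, no adducts or charge states, no
correlated (space-charge) mass errors, no intensity-dependent detection
limit, and its homologous-series structure is weaker than in real DOM. The
~96% recall/precision measured at the default conditions therefore
characterizes the algorithm under idealized, known-truth conditions; on
real spectra, performance depends on calibration quality and the true
prevalence of isobaric interferences, which no synthetic test can settle.
Genuinely ambiguous mass coincidences (sub-0.5-ppm splits such as
C₁₀HP/N₄O₆) bound achievable recall below 100% with full CHNOSP bounds;
with CHO-only bounds and no noise, recovery is exact.

## Problem sizes in the validation suite

The bundled recovery studies use 4 samples × 2,000 formulas for the
assignment benchmark, 2 × 200 formulas for the zero-noise CHO round trip,
1,000 null repeats × 10,000 permutations for the envfit calibration, and
100 end-to-end runs of 8 samples × 150 formulas for the link-recovery power
study — sizes chosen so the whole validation runs in minutes on one CPU
while keeping Monte-Carlo error well below the decision margins. All are
parameters of `domchar.validation` and can be scaled up.

## Known limitations

- Negative-mode, singly charged, deprotonated ions only.
- The MDL noise model assumes a narrow noise band; see above.
- Series-support resolution is only as good as the series structure of the
  data; on sparse libraries ties fall through to the ppm criterion.
- envfit fits linear directions; nonlinear descriptor–ordination relations
  are not detected.
- IC50 interpolation assumes a locally monotone series around 50%; strongly
  non-monotone curves trigger a warning and use the lowest crossing.
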