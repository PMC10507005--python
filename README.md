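# domchar

Molecular-level characterization of dissolved organic matter (DOM) and its
relation to bioassay activity.

DOM is one of the most complex molecular mixtures on Earth: a single
ultrahigh-resolution negative-mode mass spectrum of a solid-phase-extracted
water sample resolves thousands of exact masses, each of which must be
translated into an elemental composition (CHNOSP) before any ecology or
bioprospecting question can be asked. `domchar` implements that full
computational chain as a tested, reusable Python library:

1. **Formula assignment** (`domchar.assign`) — method-detection-limit noise
   filtering, m/z recalibration against reference formulas, cross-spectrum
   alignment at 0.5 ppm, exhaustive CHNOSP enumeration under chemical
   screens (0.3 ≤ H/C ≤ 2.5, O/C ≤ 1.2, integer non-negative DBE, nitrogen
   rule), N/S/P heteroatom plausibility caps with ¹³C isotope-pattern
   rescue, homologous-series (CH₂, CO₂, H₂, H₂O, O) resolution of ambiguous
   masses, and a duplicate-consensus rule: only formulas present in every
   replicate of a sample are kept.
2. **Composition** (`domchar.compose`) — per-formula descriptors

   DBE = 1 + C − H/2 + (N + P)/2
   AImod = (1 + C − O/2 − S − (N + P + H)/2) / (C − O/2 − N − S − P)

   and classification into nine compound categories (aromatic AImod ≥ 0.5;
   highly unsaturated AImod < 0.5 and H/C < 1.5; unsaturated 1.5 ≤ H/C ≤ 2,
   with a separate N-containing class; saturated DBE = 0; each split at
   O/C > 0.5 into O-rich/O-poor), plus intensity-weighted sample summaries
   (MW_w, DBE_w, AImod_w), heteroatom-group abundances (CHO/CHON/CHOS/CHOP/
   Others) and exclusive-formula statistics.
3. **Ordination** (`domchar.ordinate`) — Bray–Curtis dissimilarities,
   principal coordinate analysis, and post-hoc descriptor fitting with a
   permutation test (10,000 permutations, significance at p < 0.1),
   implemented from first principles.
4. **Bioactivity** (`domchar.bioactivity`) — % inhibition against a negative
   control, IC50 from dilution series (log-linear interpolation or
   four-parameter logistic; censored as ">200" when inhibition never
   reaches 50%), Trolox-equivalent antioxidant capacity (TEAC) per gram dry
   weight, and descriptor–activity regressions with significance stars.
5. **Synthetic data** (`domchar.synth`) — a generator that emulates the
   study design end to end (source-group-specific category weights for
   terrestrial vs marine DOM, lognormal intensities, duplicate spectra with
   Gaussian ppm error, unassignable noise peaks, dose–response plates whose
   IC50 is linked to aromatic content), so every stage is validated by
   parameter recovery against known ground truth.

The package is aimed at environmental chemists and marine natural-product
researchers who work with FT-ICR MS peak lists of DOM extracts and want a
scriptable, reproducible version of this processing chain.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/02_assign_formulas.py` simulates four samples with 500
formulas each (duplicate spectra, 0.1 ppm mass error, 10% noise peaks) and
recovers the formulas:

```
assigned table: 1931 formulas x 4 samples
  peat_1         recall 0.952   precision 0.952
  freshwater_1   recall 0.976   precision 0.976
  porewater_1    recall 0.972   precision 0.972
  deepwater_1    recall 0.978   precision 0.980

mean |ppm error| of assignments: 0.057 ppm
formulas with homologous-series support: 70%
```

Recall/precision are measured against the generator's ground truth; the
random-m/z noise peaks never replicate and are removed by the
duplicate-consensus rule. `python examples/05_bioactivity_ic50.py` then
closes the loop from composition to activity:

```
-log10(IC50) vs aromatic %:  slope +0.0401, R2 = 1.00** (p = 1.2e-09, n = 8)
TEAC example: 30% scavenging, 0.5 g DW -> 120 umol Trolox eq. g^-1
```

The positive, significant slope recovers the aromatic-content/activity link
built into the simulated plates; `**` marks p < 0.01.

A thin CLI mirrors the library (`domchar synth/assign/compose/ordinate/
bioassay/run`); `domchar run --config run.json` executes all stages from a
single JSON configuration and writes a manifest with seeds, parameters and
row counts.

## Layout

```
src/domchar/     formula, synth, assign, compose, ordinate, bioactivity,
                 validation, pipeline, io, cli
examples/        one narrative script per capability
tests/           pytest suite (unit, property and stage-level recovery tests)
docs/methods.md  model and algorithm notes, parameter defaults, limitations
```
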