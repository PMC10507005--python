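"""Recover molecular formulas from noisy replicate peak lists.

Renders duplicate spectra with realistic mass error and noise, runs the
full assignment chain (alignment at 0.5 ppm, CHNOSP enumeration under
chemical screens, N,S,P rule, homologous-series resolution, duplicate
consensus) and scores the result against the known ground truth.
"""

from domchar.assign import assign_samples
from domchar.synth import SynthConfig, generate_formula_library, render_peak_lists

config = SynthConfig(n_samples=4, n_formulas_per_sample=500, seed=7)
truth = generate_formula_library(config)
peaks = render_peak_lists(truth, config)

result = assign_samples(peaks)
print(f"assigned table: {result.table.shape[0]} formulas x "
      f"{result.table.shape[1]} samples")

for sid in truth.samples:
    true_set = truth.formula_set(sid)
    got = set(result.table.index[result.table[sid] > 0])
    tp = len(true_set & got)
    print(f"  {sid:<14} recall {tp / len(true_set):.3f}   "
          f"precision {tp / len(got):.3f}")

ann = result.annotations
print(f"\nmean |ppm error| of assignments: {ann['ppm_error'].abs().mean():.3f} ppm")
print(f"formulas with homologous-series support: "
      f"{(ann['series_support'] > 0).mean() * 100:.0f}%")
print("\nRecall/precision near 1 show the chain recovers the true formula set;")
print("random-m/z noise peaks are rejected by the duplicate-consensus rule.")
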