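"""Quantify bioassay plates and relate activity to composition.

Fits IC50 per replicate dilution series (log-linear interpolation around
the 50% crossing, censoring at >200 ug/mL), converts a radical-scavenging
readout to Trolox equivalents, and regresses -log10(IC50) on the aromatic
content of each sample.
"""

import numpy as np

from domchar.bioactivity import TeacResult, ic50_table, regress, teac
from domchar.compose import summarize_all
from domchar.synth import SynthConfig, generate_dataset

config = SynthConfig(n_samples=8, n_formulas_per_sample=400, seed=23)
truth, _, plate = generate_dataset(config)

table1 = ic50_table(plate)
print("sample            IC50 (ug/mL)     true IC50")
for (sid, _), row in table1.iterrows():
    print(f"{sid:<17} {row['label']:<15} {truth.true_ic50[sid]:>8.1f}")

summary = summarize_all(truth.table())
aromatic = summary["A_Or"] + summary["A_Op"]
response = -np.log10(table1.reset_index().set_index("sample_id")["ic50_mean"])
fit = regress(aromatic, response)
print(f"\n-log10(IC50) vs aromatic %:  slope {fit.slope:+.4f}, "
      f"R2 = {fit.r2:.2f}{fit.stars} (p = {fit.p_value:.2g}, n = {fit.n})")

cal = TeacResult(slope=0.5, intercept=0.0, r2=1.0)
print(f"TEAC example: 30% scavenging, 0.5 g DW -> "
      f"{teac(30.0, cal, 0.5):.0f} umol Trolox eq. g^-1")
print("\nThe positive significant slope recovers the built-in link between")
print("aromatic content and bioactivity; censored samples print as '>200'.")
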