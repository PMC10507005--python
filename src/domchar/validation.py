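"""Parameter-recovery studies on synthetic data.

These utilities quantify how well each stage recovers known ground truth:
formula-assignment recall/precision, the calibration of the envfit
permutation test under the null, IC50 recovery, and the power of the
end-to-end chain to detect a configured composition-bioactivity link.
They are used by the test suite and by the reproduction script, and are
part of the public API so users can rerun them under their own conditions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .assign import assign_samples
from .bioactivity import ic50_table, regress
from .compose import summarize_all
from .ordinate import envfit, pcoa
from .synth import (
    SynthConfig,
    generate_bioassay_plate,
    generate_formula_library,
    render_peak_lists,
)

__all__ = [
    "assignment_recovery",
    "envfit_type1_rate",
    "ic50_recovery_error",
    "link_recovery_power",
]


def assignment_recovery(
    config: SynthConfig, **assign_kwargs
) -> dict[str, float]:
    """Recall and precision of the assignment chain against ground truth.

    Both are aggregated over all samples: recall = true formulas recovered /
    true formulas generated; precision = true formulas recovered / formulas
    reported. A formula counts as recovered in a sample when it appears with
    nonzero intensity in that sample's column.
    """
    truth = generate_formula_library(config)
    peaks = render_peak_lists(truth, config)
    assign_kwargs.setdefault("bounds", config.element_bounds)
    assign_kwargs.setdefault("scan_range", config.mass_range_da)
    result = assign_samples(peaks, **assign_kwargs)
    tp = n_true = n_reported = 0
    for sid in truth.samples:
        true_set = truth.formula_set(sid)
        got = (
            set(result.table.index[result.table[sid] > 0])
            if sid in result.table.columns
            else set()
        )
        tp += len(true_set & got)
        n_true += len(true_set)
        n_reported += len(got)
    return {
        "recall": tp / n_true if n_true else float("nan"),
        "precision": tp / n_reported if n_reported else float("nan"),
        "n_true": n_true,
        "n_reported": n_reported,
    }


def envfit_type1_rate(
    n_samples: int = 12,
    n_perm: int = 10_000,
    n_repeats: int = 1_000,
    alpha: float = 0.1,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the envfit permutation test under the null.

    Samples are placed in ordination space from independent Gaussian
    coordinates; the fitted descriptor is drawn independently of the scores,
    so every rejection at level alpha is a false positive.
    """
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng([seed, 41])
    hits = 0
    for _ in range(n_repeats):
        pts = rng.normal(size=(n_samples, 3))
        ordination = pcoa(squareform(pdist(pts)))
        y = rng.normal(size=n_samples)
        fit = envfit(ordination, y, n_perm=n_perm, alpha=alpha, rng=rng)
        hits += int(fit.p_value < alpha)
    return hits / n_repeats


def ic50_recovery_error(
    midpoints: tuple[float, ...] = (3.0, 10.0, 25.0, 80.0, 150.0),
    method: str = "logistic",
) -> float:
    """Worst relative error (%) recovering noise-free logistic midpoints."""
    from .bioactivity import DoseResponse, ic50

    conc = 200.0 / 2 ** np.arange(10)
    worst = 0.0
    for mid in midpoints:
        curve = DoseResponse(
            sample_id="s", assay="a", concentration=conc,
            inhibition=100.0 / (1.0 + mid / conc),
        )
        est = ic50(curve, method=method).ic50
        worst = max(worst, abs(est - mid) / mid * 100.0)
    return worst


def link_recovery_power(
    n_runs: int = 100,
    seed: int = 0,
    n_samples: int = 8,
    n_formulas_per_sample: int = 150,
    alpha: float = 0.05,
    **synth_kwargs,
) -> dict[str, float]:
    """Power of the end-to-end chain to detect the composition-activity link.

    Each run generates a dataset with the default positive link between
    aromatic content and -log10(IC50), pushes it through assignment,
    composition summaries and IC50 fitting, and regresses -log10(IC50) on
    the recovered aromatic percentage. Returns the fraction of runs with a
    positive slope significant at ``alpha``, plus the median recovered r^2.
    """
    hits = 0
    r2s = []
    for run in range(n_runs):
        config = SynthConfig(
            n_samples=n_samples,
            n_formulas_per_sample=n_formulas_per_sample,
            seed=seed + 1000 * run + 1,
            **synth_kwargs,
        )
        truth = generate_formula_library(config)
        peaks = render_peak_lists(truth, config)
        plate = generate_bioassay_plate(truth, config)
        table = assign_samples(peaks, bounds=config.element_bounds,
                               scan_range=config.mass_range_da).table
        summary = summarize_all(table)
        aromatic = summary["A_Or"] + summary["A_Op"]
        ic = ic50_table(plate).reset_index().set_index("sample_id")
        response = -np.log10(ic["ic50_mean"])
        fit = regress(aromatic, response)
        r2s.append(fit.r2)
        hits += int(fit.slope > 0 and fit.p_value < alpha)
    return {
        "power": hits / n_runs,
        "median_r2": float(np.median(r2s)),
        "n_runs": n_runs,
    }
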