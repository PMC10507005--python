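"""Compound-class assignment and per-sample compositional summaries.

Each molecular formula is placed in exactly one of nine categories built
from four structural classes — saturated (DBE = 0), aromatic (AImod >= 0.5),
unsaturated (1.5 <= H/C <= 2) and highly unsaturated (AImod < 0.5,
H/C < 1.5) — split into oxygen-rich (O/C > 0.5) and oxygen-poor
(O/C <= 0.5) variants, with a separate "with N" class for N-bearing
unsaturated formulas. Heteroatom groups (CHO/CHON/CHOS/CHOP/Others) are a
second, independent partition.

Sample summaries deliberately mix two weighting bases: molecular-category
percentages are fractions of the formula COUNT, while heteroatom-group
abundances and the weighted descriptors (MW_w, DBE_w, AImod_w, H/C_w,
O/C_w) are intensity-weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula import MolecularFormula, aimod, dbe, hc_ratio, oc_ratio

logger = logging.getLogger(__name__)

#: The nine molecular categories, in summary-table column order.
CATEGORIES = (
    "A_Or", "A_Op",          # aromatic, O-rich / O-poor
    "HUn_Or", "HUn_Op",      # highly unsaturated
    "Un_Or", "Un_Op", "Un_withN",  # unsaturated (with-N split out)
    "Sat_Or", "Sat_Op",      # saturated
)

HETEROATOM_GROUPS = ("CHO", "CHON", "CHOS", "CHOP", "Others")


def _o_suffix(f: MolecularFormula) -> str:
    return "Or" if oc_ratio(f) > 0.5 else "Op"


def classify(f: MolecularFormula) -> str:
    """Assign a formula to exactly one of the nine molecular categories.

    Precedence resolves the overlaps the raw threshold list permits:
    saturated first (DBE = 0), then aromatic (AImod >= 0.5), then
    unsaturated-with-N, then unsaturated O-rich/O-poor, then highly
    unsaturated. Formulas with DBE > 0 but H/C > 2 (possible with N or P)
    fall outside every threshold window and are routed to saturated as the
    closest class.
    """
    if dbe(f) == 0:
        return f"Sat_{_o_suffix(f)}"
    if aimod(f) >= 0.5:
        return f"A_{_o_suffix(f)}"
    hc = hc_ratio(f)
    if 1.5 <= hc <= 2.0:
        if f.n > 0:
            return "Un_withN"
        return f"Un_{_o_suffix(f)}"
    if hc < 1.5:
        return f"HUn_{_o_suffix(f)}"
    # DBE > 0 with H/C > 2: nearest class is saturated.
    logger.debug("formula %s has H/C > 2 with DBE > 0; routed to saturated", f)
    return f"Sat_{_o_suffix(f)}"


def heteroatom_group(f: MolecularFormula) -> str:
    """CHO/CHON/CHOS/CHOP for single-heteroatom formulas, else Others."""
    kinds = (f.n > 0) + (f.s > 0) + (f.p > 0)
    if kinds == 0:
        return "CHO"
    if kinds > 1:
        return "Others"
    if f.n > 0:
        return "CHON"
    if f.s > 0:
        return "CHOS"
    return "CHOP"


@dataclass
class CompositionDescriptors:
    """Per-formula descriptor bundle."""

    hc_ratio: float
    oc_ratio: float
    dbe: float
    aimod: float
    heteroatom_group: str
    category: str


def describe(f: MolecularFormula) -> CompositionDescriptors:
    return CompositionDescriptors(
        hc_ratio=hc_ratio(f),
        oc_ratio=oc_ratio(f),
        dbe=dbe(f),
        aimod=aimod(f),
        heteroatom_group=heteroatom_group(f),
        category=classify(f),
    )


def descriptor_frame(formulas: list[MolecularFormula]) -> pd.DataFrame:
    """DataFrame of descriptors indexed by canonical formula string."""
    rows = {}
    for f in formulas:
        d = describe(f)
        rows[str(f)] = {
            "neutral_mass": f.neutral_mass,
            "hc_ratio": d.hc_ratio,
            "oc_ratio": d.oc_ratio,
            "dbe": d.dbe,
            "aimod": d.aimod,
            "heteroatom_group": d.heteroatom_group,
            "category": d.category,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class SampleSummary:
    """One summary-table row: size, exclusivity, weighted means, category mix."""

    sample_id: str
    n_formulas: int
    pct_exclusive: float
    mw_w: float
    dbe_w: float
    aimod_w: float
    hc_w: float
    oc_w: float
    category_pct: dict[str, float] = field(default_factory=dict)
    heteroatom_pct: dict[str, float] = field(default_factory=dict)


def summarize_sample(
    table: pd.DataFrame,
    sample_id: str,
    descriptors: pd.DataFrame | None = None,
    pct_exclusive: float = float("nan"),
) -> SampleSummary:
    """Intensity-weighted descriptors and compositional mix for one sample.

    ``table`` is the formula-by-sample relative-intensity matrix (rows are
    canonical formula strings). Weighted descriptors use intensity weights,
    category percentages use formula counts, heteroatom-group percentages
    use intensity shares. Weights are renormalized internally, so the result
    is invariant to rescaling the column.
    """
    if sample_id not in table.columns:
        raise KeyError(f"sample {sample_id!r} not in table")
    col = table[sample_id]
    present = col[col > 0]
    if present.empty:
        raise ValueError(f"sample {sample_id!r} has no formulas")
    if descriptors is None:
        descriptors = descriptor_frame(
            [MolecularFormula.from_string(s) for s in present.index]
        )
    desc = descriptors.loc[present.index]
    w = present.to_numpy(float)
    w = w / w.sum()

    cat_counts = desc["category"].value_counts()
    category_pct = {
        c: 100.0 * cat_counts.get(c, 0) / len(present) for c in CATEGORIES
    }
    het_w = (
        pd.Series(w, index=present.index)
        .groupby(desc["heteroatom_group"])
        .sum()
    )
    heteroatom_pct = {g: 100.0 * het_w.get(g, 0.0) for g in HETEROATOM_GROUPS}

    return SampleSummary(
        sample_id=sample_id,
        n_formulas=int(len(present)),
        pct_exclusive=pct_exclusive,
        mw_w=float(w @ desc["neutral_mass"].to_numpy()),
        dbe_w=float(w @ desc["dbe"].to_numpy()),
        aimod_w=float(w @ desc["aimod"].to_numpy()),
        hc_w=float(w @ desc["hc_ratio"].to_numpy()),
        oc_w=float(w @ desc["oc_ratio"].to_numpy()),
        category_pct=category_pct,
        heteroatom_pct=heteroatom_pct,
    )


def exclusivity(table: pd.DataFrame) -> pd.DataFrame:
    """Exclusive-formula counts and percentages per sample.

    A formula is exclusive to a sample when its intensity is nonzero there
    and zero in every other sample. Percentages are relative to the total
    number of distinct formulas in the whole dataset.
    """
    if table.shape[1] < 2:
        raise ValueError("exclusivity needs at least two samples")
    present = table.to_numpy() > 0
    n_present = present.sum(axis=1)
    total = int((n_present > 0).sum())
    rows = []
    for j, sample in enumerate(table.columns):
        n_excl = int((present[:, j] & (n_present == 1)).sum())
        rows.append(
            {
                "sample_id": sample,
                "n_exclusive": n_excl,
                "pct_exclusive": 100.0 * n_excl / total,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def summarize_all(
    table: pd.DataFrame, descriptors: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Summary-table rows for every sample, in canonical column order."""
    if descriptors is None:
        descriptors = descriptor_frame(
            [MolecularFormula.from_string(s) for s in table.index]
        )
    excl = (
        exclusivity(table)["pct_exclusive"]
        if table.shape[1] >= 2
        else pd.Series(np.nan, index=table.columns)
    )
    rows = []
    for sample in table.columns:
        s = summarize_sample(
            table, sample, descriptors=descriptors, pct_exclusive=float(excl[sample])
        )
        row = {
            "sample_id": s.sample_id,
            "n_formulas": s.n_formulas,
            "pct_exclusive": s.pct_exclusive,
            "MW_w": s.mw_w,
            "DBE_w": s.dbe_w,
            "AImod_w": s.aimod_w,
            "HC_w": s.hc_w,
            "OC_w": s.oc_w,
        }
        row.update(s.category_pct)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def heteroatom_table(
    table: pd.DataFrame, descriptors: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Intensity-share (%) of each heteroatom group per sample."""
    if descriptors is None:
        descriptors = descriptor_frame(
            [MolecularFormula.from_string(s) for s in table.index]
        )
    rows = []
    for sample in table.columns:
        s = summarize_sample(table, sample, descriptors=descriptors)
        rows.append({"sample_id": sample, **s.heteroatom_pct})
    return pd.DataFrame(rows).set_index("sample_id")
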