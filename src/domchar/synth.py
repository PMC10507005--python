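"""Ground-truth generator for DOM-like molecular and bioassay data.

The generator emulates the inputs of a molecular-level DOM characterization
study: per-sample libraries of CHNOSP formulas whose compound-category mix
is controlled per source group (terrestrial, aromatic-rich sources vs
marine, highly-unsaturated-rich ones), lognormal peak intensities,
duplicate spectra with Gaussian ppm mass error and unassignable noise
peaks, and dose-response plates whose half-inhibition point is tied
monotonically to a chosen compositional descriptor. Because every formula,
intensity and IC50 is known, each downstream stage can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assign import DEFAULT_ELEMENT_BOUNDS, PeakList, passes_nsp_rule
from .compose import CATEGORIES, classify
from .formula import (
    C13_ABUNDANCE,
    C13_C12_DELTA,
    PROTON_MASS,
    MolecularFormula,
    aimod,
    dbe,
    parity_valid,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "InfeasibleWeightsError",
    "DEFAULT_GROUP_WEIGHTS",
    "generate_formula_library",
    "render_peak_lists",
    "generate_bioassay_plate",
    "generate_dataset",
]


class InfeasibleWeightsError(ValueError):
    """Raised when a category quota cannot be filled under the bounds."""


def _normalize(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


#: Category-weight presets per source group. The four rows mirror the
#: published contrasts between source waters: peat and freshwater are
#: aromatic-rich, deep oceanic water is dominated by highly unsaturated
#: O-poor formulas, and porewater carries the largest unsaturated and
#: N-containing shares. Order of keys follows :data:`~domchar.compose.CATEGORIES`.
DEFAULT_GROUP_WEIGHTS: dict[str, dict[str, float]] = {
    "peat": _normalize(
        dict(zip(CATEGORIES, [10.9, 37.5, 10.8, 36.2, 0.2, 4.4, 0.0, 0.0, 0.0]))
    ),
    "freshwater": _normalize(
        dict(zip(CATEGORIES, [11.0, 20.2, 36.7, 29.7, 0.8, 1.6, 0.0, 0.0, 0.0]))
    ),
    "porewater": _normalize(
        dict(zip(CATEGORIES, [3.8, 11.7, 24.7, 42.5, 4.4, 12.8, 3.4, 0.0, 0.1]))
    ),
    "deepwater": _normalize(
        dict(zip(CATEGORIES, [0.1, 3.3, 27.7, 57.9, 4.6, 5.9, 2.8, 0.5, 0.0]))
    ),
}

#: IC50 (ug/mL) of a hypothetical sample whose link descriptor is zero.
IC50_BASE_UG_ML = 150.0
#: Top concentration of the two-fold dilution series (ug/mL).
TOP_CONCENTRATION_UG_ML = 200.0
N_DILUTIONS = 8


@dataclass
class SynthConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults reproduce the emulated study's conditions: 16 samples in four
    source groups measured in duplicate over a 100-1000 Da scan range, about
    2000 formulas per sample, < 0.1 ppm mass error, and ~10% unassignable
    noise peaks per spectrum.
    """

    n_samples: int = 16
    n_formulas_per_sample: int = 2000
    element_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_BOUNDS)
    )
    mass_range_da: tuple[float, float] = (100.0, 1000.0)
    intensity_lognormal_mu_sigma: tuple[float, float] = (0.0, 1.0)
    ppm_error_sd: float = 0.1
    noise_peak_fraction: float = 0.1
    category_weights_per_group: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(w) for g, w in DEFAULT_GROUP_WEIGHTS.items()}
    )
    bioactivity_link_coefficient: float = 4.0
    link_descriptor: str = "aromatic_fraction"
    #: fraction of each sample's formulas reused from its group's shared
    #: pool, and from the dataset-wide pool; the remainder is drawn fresh.
    #: Natural DOM samples share most of their formulas, so ordination
    #: separates sources by intensity pattern and partial overlap.
    within_group_overlap: float = 0.5
    cross_group_overlap: float = 0.25
    replicate_count: int = 2
    replicate_intensity_sigma: float = 0.1
    bioassay_noise_sd: float = 3.0
    include_isotope_satellites: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_formulas_per_sample < 1:
            raise ValueError("n_samples and n_formulas_per_sample must be >= 1")
        lo, hi = self.mass_range_da
        if not (0 < lo < hi):
            raise ValueError(f"invalid mass range {self.mass_range_da}")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if not 0 <= self.noise_peak_fraction < 1:
            raise ValueError("noise_peak_fraction must be in [0, 1)")
        if (
            not 0 <= self.within_group_overlap <= 1
            or not 0 <= self.cross_group_overlap <= 1
            or self.within_group_overlap + self.cross_group_overlap > 1
        ):
            raise ValueError("overlap fractions must be in [0, 1] and sum to <= 1")
        if not self.category_weights_per_group:
            raise ValueError("need at least one source group")
        for group, weights in self.category_weights_per_group.items():
            unknown = set(weights) - set(CATEGORIES)
            if unknown:
                raise ValueError(f"unknown categories {unknown} for group {group!r}")
            if any(v < 0 for v in weights.values()):
                raise ValueError(f"negative weight in group {group!r}")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"weights for group {group!r} must sum to 1")


@dataclass
class GroundTruth:
    """Known composition and bioactivity of the synthetic dataset.

    ``samples`` maps sample id to a frame (formula, relative_intensity,
    category); ``descriptors`` holds per-sample summary descriptors of the
    true library; ``true_ic50`` is the dose-response midpoint implied by the
    configured descriptor link.
    """

    samples: dict[str, pd.DataFrame]
    sample_groups: dict[str, str]
    descriptors: pd.DataFrame
    true_ic50: pd.Series

    def formula_set(self, sample_id: str) -> set[str]:
        return set(self.samples[sample_id]["formula"])

    def table(self) -> pd.DataFrame:
        """Ground-truth formula-by-sample relative-intensity matrix."""
        cols = {
            sid: df.set_index("formula")["relative_intensity"]
            for sid, df in self.samples.items()
        }
        return pd.DataFrame(cols).fillna(0.0)


def _h_window(cat: str, c: int, n: int, o: int, s: int, p: int,
              h_bounds: tuple[int, int]) -> tuple[int, int]:
    """Integer H range targeting one molecular category (before parity)."""
    h_lo = max(h_bounds[0], int(np.ceil(0.3 * c)))
    h_hi = min(h_bounds[1], int(np.floor(2.5 * c)), 2 * c + 2 + n + p)
    h_sat = 2 * c + 2 + n + p
    if cat.startswith("Sat"):
        return h_sat, h_sat
    if cat.startswith("A_"):
        # AImod >= 0.5 solved for H (given a positive denominator).
        return h_lo, min(h_hi, int(np.floor(2 + c - 0.5 * o - s)))
    if cat.startswith("Un"):
        return max(h_lo, int(np.ceil(1.5 * c))), min(h_hi, 2 * c, h_sat - 1)
    # Highly unsaturated: H/C < 1.5 and not aromatic.
    return max(h_lo, int(np.floor(2 + c - 0.5 * o - s)) + 1), min(
        h_hi, int(np.ceil(1.5 * c)) - 1, h_sat - 1
    )


def _draw_formula(
    cat: str,
    config: SynthConfig,
    rng: np.random.Generator,
) -> MolecularFormula | None:
    """One rejection-sampling attempt at a formula of the target category."""
    b = config.element_bounds
    lo_mass = config.mass_range_da[0] + PROTON_MASS  # keep the anion in range
    hi_mass = config.mass_range_da[1]

    c_lo = max(b["C"][0], 4)
    c_hi = min(b["C"][1], int(hi_mass / 12.5))
    if c_lo > c_hi:
        return None
    c = int(rng.integers(c_lo, c_hi + 1))

    # Heteroatoms: mostly CHO, occasional N/S/P, forced N for the with-N class.
    n_lo = 1 if cat == "Un_withN" else b["N"][0]
    n = int(rng.integers(n_lo, b["N"][1] + 1)) if rng.random() < (
        1.0 if cat == "Un_withN" else 0.30
    ) else max(b["N"][0], 0)
    n = min(max(n, n_lo), b["N"][1])
    s = int(rng.integers(b["S"][0], b["S"][1] + 1)) if rng.random() < 0.15 else b["S"][0]
    p = int(rng.integers(b["P"][0], b["P"][1] + 1)) if rng.random() < 0.08 else b["P"][0]

    # Oxygen window from the O-rich / O-poor split.
    o_cap = min(b["O"][1], int(np.floor(1.2 * c)))
    if cat.endswith("_Or"):
        o_lo, o_hi = int(np.floor(0.5 * c)) + 1, o_cap
    elif cat.endswith("_Op"):
        o_lo, o_hi = b["O"][0], min(o_cap, int(np.floor(0.5 * c)))
    else:  # Un_withN: no oxygen split
        o_lo, o_hi = b["O"][0], o_cap
    if o_lo > o_hi:
        return None
    o = int(rng.integers(o_lo, o_hi + 1))

    h_lo, h_hi = _h_window(cat, c, n, o, s, p, b["H"])
    if h_lo > h_hi:
        return None
    # Enforce the valence-parity screen: h = n + p (mod 2).
    want = (n + p) % 2
    if h_lo % 2 != want:
        h_lo += 1
    if h_lo > h_hi:
        return None
    h = int(rng.integers(0, (h_hi - h_lo) // 2 + 1)) * 2 + h_lo

    f = MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p)
    if not (lo_mass <= f.neutral_mass <= hi_mass):
        return None
    if not parity_valid(f) or not passes_nsp_rule(f):
        return None
    hc = f.h / f.c
    if not (0.3 <= hc <= 2.5) or f.o / f.c > 1.2:
        return None
    if classify(f) != cat:
        return None
    return f


def _category_quota(weights: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n formulas over the categories."""
    raw = {cat: n * weights.get(cat, 0.0) for cat in CATEGORIES}
    quota = {cat: int(np.floor(v)) for cat, v in raw.items()}
    short = n - sum(quota.values())
    for cat in sorted(raw, key=lambda k: raw[k] - quota[k], reverse=True)[:short]:
        quota[cat] += 1
    return quota


def generate_formula_library(config: SynthConfig) -> GroundTruth:
    """Draw per-sample formula libraries matching each group's category mix.

    Formulas are rejection-sampled within the element bounds and mass range
    until every category quota (largest-remainder apportionment of the group
    weights) is filled; a quota that stays unfilled after a bounded number
    of attempts raises :class:`InfeasibleWeightsError`. Intensities are
    lognormal, normalized to sum 1 per sample. Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    groups = list(config.category_weights_per_group)
    mu, sigma = config.intensity_lognormal_mu_sigma

    # shared formula pools: one per group plus a dataset-wide background,
    # so samples overlap the way fractions of the same source waters do
    global_pool: dict[str, list[MolecularFormula]] = {}
    group_pools: dict[str, dict[str, list[MolecularFormula]]] = {}
    global_members: set[tuple[int, ...]] = set()
    group_members: dict[str, set[tuple[int, ...]]] = {}

    def _reuse(pool: list[MolecularFormula], want: int,
               seen: set) -> list[MolecularFormula]:
        avail = [f for f in pool if f.counts() not in seen]
        if not avail or want <= 0:
            return []
        k = min(want, len(avail))
        idx = rng.choice(len(avail), size=k, replace=False)
        return [avail[j] for j in np.sort(idx)]

    samples: dict[str, pd.DataFrame] = {}
    sample_groups: dict[str, str] = {}
    desc_rows = {}
    for i in range(config.n_samples):
        group = groups[i % len(groups)]
        sample_id = f"{group}_{i // len(groups) + 1}"
        quota = _category_quota(
            config.category_weights_per_group[group], config.n_formulas_per_sample
        )
        pool_g = group_pools.setdefault(group, {})
        members_g = group_members.setdefault(group, set())
        seen: set[tuple[int, ...]] = set()
        formulas: list[MolecularFormula] = []
        cats: list[str] = []
        for cat, want in quota.items():
            if want == 0:
                continue
            reused: list[MolecularFormula] = []
            reused += _reuse(pool_g.get(cat, []),
                             int(round(config.within_group_overlap * want)), seen)
            for f in reused:
                seen.add(f.counts())
            more = _reuse(global_pool.get(cat, []),
                          int(round(config.cross_group_overlap * want)), seen)
            for f in more:
                seen.add(f.counts())
            reused += more
            for f in reused:
                formulas.append(f)
                cats.append(cat)
            got = len(reused)
            attempts = 0
            max_attempts = 2000 * want + 10000
            while got < want:
                attempts += 1
                if attempts > max_attempts:
                    raise InfeasibleWeightsError(
                        f"could not fill category {cat!r} for sample {sample_id!r} "
                        f"({got}/{want} after {attempts} attempts); "
                        "weights are infeasible under the element bounds"
                    )
                f = _draw_formula(cat, config, rng)
                if f is None or f.counts() in seen:
                    continue
                seen.add(f.counts())
                formulas.append(f)
                cats.append(cat)
                if f.counts() not in members_g:
                    pool_g.setdefault(cat, []).append(f)
                    members_g.add(f.counts())
                if f.counts() not in global_members:
                    global_pool.setdefault(cat, []).append(f)
                    global_members.add(f.counts())
                got += 1
        intensity = rng.lognormal(mu, sigma, size=len(formulas))
        intensity /= intensity.sum()
        df = pd.DataFrame(
            {
                "formula": [str(f) for f in formulas],
                "relative_intensity": intensity,
                "category": cats,
            }
        )
        samples[sample_id] = df
        sample_groups[sample_id] = group

        w = intensity
        n_count = len(formulas)
        aromatic = sum(cat.startswith("A_") for cat in cats) / n_count
        desc_rows[sample_id] = {
            "aromatic_fraction": aromatic,
            "aimod_w": float(np.dot(w, [aimod(f) for f in formulas])),
            "dbe_w": float(np.dot(w, [dbe(f) for f in formulas])),
        }

    descriptors = pd.DataFrame.from_dict(desc_rows, orient="index")
    link = descriptors[config.link_descriptor]
    log10_ic50 = np.log10(IC50_BASE_UG_ML) - config.bioactivity_link_coefficient * link
    true_ic50 = pd.Series(10.0 ** log10_ic50, index=descriptors.index, name="ic50")
    return GroundTruth(
        samples=samples,
        sample_groups=sample_groups,
        descriptors=descriptors,
        true_ic50=true_ic50,
    )


def render_peak_lists(truth: GroundTruth, config: SynthConfig) -> list[PeakList]:
    """Render noisy replicate peak lists from the ground-truth libraries.

    Each replicate observes every true formula at its singly-deprotonated
    m/z perturbed by Gaussian ppm error, with multiplicative lognormal
    intensity noise. Unassignable noise peaks (uniform m/z over the scan
    range, intensities resampled from the lowest decile of that replicate's
    signal intensities) are appended so that they make up
    ``noise_peak_fraction`` of the final list on average. Optional 13C
    satellite peaks appear at +1.0033548 Da with intensity
    0.0107 x C x parent.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    lo, hi = config.mass_range_da
    out: list[PeakList] = []
    for sample_id, df in truth.samples.items():
        formulas = [MolecularFormula.from_string(t) for t in df["formula"]]
        mz_true = np.array([f.mz_deprotonated for f in formulas])
        carbons = np.array([f.c for f in formulas])
        base_intensity = df["relative_intensity"].to_numpy()
        for rep in range(1, config.replicate_count + 1):
            ppm = rng.normal(0.0, config.ppm_error_sd, size=mz_true.size) if config.ppm_error_sd > 0 else np.zeros(mz_true.size)
            mz = mz_true * (1.0 + ppm * 1e-6)
            if config.replicate_intensity_sigma > 0:
                intensity = base_intensity * np.exp(
                    rng.normal(0.0, config.replicate_intensity_sigma, size=mz.size)
                )
            else:
                intensity = base_intensity.copy()

            if config.include_isotope_satellites:
                mz = np.concatenate([mz, mz + C13_C12_DELTA])
                intensity = np.concatenate(
                    [intensity, C13_ABUNDANCE * carbons * intensity[: mz_true.size]]
                )

            f = config.noise_peak_fraction
            if f > 0:
                n_noise = rng.poisson(mz_true.size * f / (1.0 - f))
                if n_noise:
                    decile = np.quantile(intensity, 0.10)
                    low = intensity[intensity <= decile]
                    noise_mz = rng.uniform(lo, hi, size=n_noise)
                    noise_int = rng.choice(low, size=n_noise, replace=True)
                    mz = np.concatenate([mz, noise_mz])
                    intensity = np.concatenate([intensity, noise_int])

            order = np.argsort(mz)
            out.append(
                PeakList(
                    sample_id=sample_id,
                    replicate_id=rep,
                    mz=mz[order],
                    intensity=intensity[order],
                )
            )
    return out


def generate_bioassay_plate(truth: GroundTruth, config: SynthConfig) -> pd.DataFrame:
    """Simulate duplicate dose-response plates for every sample.

    Percent inhibition follows a four-parameter logistic (floor 0, ceiling
    100, Hill slope 1) with midpoint at the sample's true IC50, plus
    Gaussian read noise. A two-fold dilution series starts at 200 ug/mL;
    negative-control wells (concentration 0) have zero expected inhibition.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    conc = TOP_CONCENTRATION_UG_ML / 2.0 ** np.arange(N_DILUTIONS)
    rows = []
    for sample_id, ic50 in truth.true_ic50.items():
        for rep in range(1, config.replicate_count + 1):
            for c in conc:
                expected = 100.0 / (1.0 + ic50 / c)
                noise = rng.normal(0.0, config.bioassay_noise_sd) if config.bioassay_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": sample_id,
                        "assay": "viability_inhibition",
                        "concentration_ug_ml": c,
                        "replicate": rep,
                        "percent_inhibition": expected + noise,
                    }
                )
            ctrl = rng.normal(0.0, config.bioassay_noise_sd) if config.bioassay_noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample_id": sample_id,
                    "assay": "viability_inhibition",
                    "concentration_ug_ml": 0.0,
                    "replicate": rep,
                    "percent_inhibition": ctrl,
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(
    config: SynthConfig,
) -> tuple[GroundTruth, list[PeakList], pd.DataFrame]:
    """Library, rendered replicate peak lists and bioassay plate in one call."""
    truth = generate_formula_library(config)
    peaks = render_peak_lists(truth, config)
    plate = generate_bioassay_plate(truth, config)
    return truth, peaks, plate
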