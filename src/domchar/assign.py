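"""From raw replicate peak lists to a consensus molecular-formula table.

The chain mirrors standard ultrahigh-resolution DOM processing: noise
removal against a method detection limit (MDL), recalibration of the m/z
axis on reference formulas, alignment of masses across spectra at a ppm
tolerance, exhaustive CHNOSP formula enumeration under chemical screens,
heteroatom (N,S,P) plausibility rules with isotope-pattern rescue, and
homologous-series-guided resolution of ambiguous assignments. Only
formulas observed in every replicate of at least one sample survive into
the final relative-intensity table.

Formula enumeration is backed by a cached database of every valid
composition under the element bounds, sorted by exact mass, so that each
query is a binary search rather than a nested loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formula import (
    C13_ABUNDANCE,
    C13_C12_DELTA,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    MolecularFormula,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PeakList",
    "AssignmentCandidate",
    "AssignedTable",
    "DEFAULT_ELEMENT_BOUNDS",
    "DEFAULT_NSP_CAPS",
    "EmptyPeakListError",
    "mdl_filter",
    "recalibrate",
    "align",
    "enumerate_candidates",
    "apply_nsp_rule",
    "passes_nsp_rule",
    "verify_isotope",
    "resolve_candidates",
    "assign_samples",
]

#: Default per-element (min, max) counts; generous enough to cover every
#: formula a broadband 100-1000 Da negative-mode DOM spectrum can hold.
DEFAULT_ELEMENT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (1, 100),
    "H": (0, 200),
    "N": (0, 4),
    "O": (0, 80),
    "S": (0, 2),
    "P": (0, 1),
}

#: Heteroatom plausibility caps: per-element maxima plus a combined cap
#: applied when two or more heteroatom species co-occur.
DEFAULT_NSP_CAPS: dict[str, int] = {"N": 4, "S": 2, "P": 1, "combined": 5}

#: Homologous-series building blocks (element-count deltas over C,H,N,O,S,P).
SERIES_UNITS: dict[str, tuple[int, int, int, int, int, int]] = {
    "CH2": (1, 2, 0, 0, 0, 0),
    "CO2": (1, 0, 0, 2, 0, 0),
    "H2": (0, 2, 0, 0, 0, 0),
    "H2O": (0, 2, 0, 1, 0, 0),
    "O": (0, 0, 0, 1, 0, 0),
}
SERIES_MAX_MULTIPLE = 10

# Validity screens for enumerated formulas (van Krevelen window plus
# integer, non-negative DBE and the valence-parity nitrogen rule).
HC_MIN, HC_MAX = 0.3, 2.5
OC_MAX = 1.2


class EmptyPeakListError(ValueError):
    """A filter removed every peak."""


@dataclass
class PeakList:
    """One replicate measurement: sorted m/z values and intensities."""

    sample_id: str
    replicate_id: int | str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz)
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size

    @property
    def rep_key(self) -> str:
        return f"{self.sample_id}|{self.replicate_id}"

    def filter_range(self, lo: float, hi: float) -> "PeakList":
        """Keep peaks with lo <= m/z <= hi (the instrument scan range)."""
        keep = (self.mz >= lo) & (self.mz <= hi)
        return replace(self, mz=self.mz[keep], intensity=self.intensity[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})


@dataclass
class AssignmentCandidate:
    """One formula hypothesis for an aligned mass."""

    formula: MolecularFormula
    ppm_error: float
    series_support: int = 0
    isotope_verified: bool | None = None


@dataclass
class AssignedTable:
    """Formula-by-sample relative intensities plus per-formula annotations."""

    table: pd.DataFrame
    annotations: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def formulas(self) -> list[str]:
        return list(self.table.index)

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns)


# ---------------------------------------------------------------------------
# Stage 1: noise filtering


def mdl_filter(
    peaks: PeakList,
    mdl_level: float = 4.0,
    noise_band_quantile: float = 0.25,
) -> tuple[PeakList, float]:
    """Remove instrumental noise below a method-detection-limit threshold.

    The noise level is estimated from the lowest-intensity band of the
    spectrum (by default the lowest quartile): threshold =
    median(band) + mdl_level x robust SD(band), with the robust SD taken as
    1.4826 x MAD. Peaks at or above the threshold are retained. Returns the
    filtered list and the threshold used.
    """
    if len(peaks) == 0:
        raise EmptyPeakListError("cannot MDL-filter an empty peak list")
    band_size = max(1, int(np.ceil(noise_band_quantile * len(peaks))))
    band = np.sort(peaks.intensity)[:band_size]
    med = float(np.median(band))
    robust_sd = 1.4826 * float(np.median(np.abs(band - med)))
    threshold = med + mdl_level * robust_sd
    keep = peaks.intensity >= threshold
    if not keep.any():
        raise EmptyPeakListError(
            f"MDL threshold {threshold:.4g} removed all {len(peaks)} peaks"
        )
    return replace(peaks, mz=peaks.mz[keep], intensity=peaks.intensity[keep]), threshold


# ---------------------------------------------------------------------------
# Stage 2: recalibration


@dataclass
class RecalibrationResult:
    peaks: PeakList
    offset_ppm: float
    n_matched: int
    applied: bool


def recalibrate(
    peaks: PeakList,
    reference_formulas: list[MolecularFormula],
    pre_tol_ppm: float = 2.0,
    min_matches: int = 5,
) -> RecalibrationResult:
    """Remove the systematic m/z offset using known reference formulas.

    Each reference's deprotonated m/z is matched to the nearest observed
    peak within ``pre_tol_ppm``; the median ppm offset over the matches is
    subtracted from the whole axis. With fewer than ``min_matches`` matches
    the spectrum is returned unchanged and a warning is issued.
    """
    if len(peaks) == 0:
        raise EmptyPeakListError("cannot recalibrate an empty peak list")
    offsets = []
    for ref in reference_formulas:
        target = ref.mz_deprotonated
        i = int(np.searchsorted(peaks.mz, target))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(peaks):
                ppm = (peaks.mz[j] - target) / target * 1e6
                if abs(ppm) <= pre_tol_ppm and (best is None or abs(ppm) < abs(best)):
                    best = ppm
        if best is not None:
            offsets.append(best)
    if len(offsets) < min_matches:
        warnings.warn(
            f"recalibration skipped for {peaks.rep_key}: only {len(offsets)} "
            f"reference matches (need {min_matches})",
            stacklevel=2,
        )
        return RecalibrationResult(peaks, 0.0, len(offsets), applied=False)
    offset = float(np.median(offsets))
    corrected = replace(peaks, mz=peaks.mz * (1.0 - offset * 1e-6),
                        intensity=peaks.intensity.copy())
    return RecalibrationResult(corrected, offset, len(offsets), applied=True)


# ---------------------------------------------------------------------------
# Stage 3: alignment across spectra


def align(replicates: list[PeakList], tol_ppm: float = 0.5) -> pd.DataFrame:
    """Group masses of equal origin across all replicates and samples.

    Single-linkage grouping on the pooled, sorted m/z values: consecutive
    masses closer than ``tol_ppm`` join one group. Each group holds at most
    one peak per replicate (the peak nearest the group's intensity-weighted
    mean is kept; surplus peaks become singleton groups). Returns a long
    frame with columns group_id, mz_group, sample_id, replicate_id, mz,
    intensity.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    frames = [
        pd.DataFrame(
            {
                "sample_id": pl.sample_id,
                "replicate_id": pl.replicate_id,
                "mz": pl.mz,
                "intensity": pl.intensity,
            }
        )
        for pl in replicates
        if len(pl)
    ]
    if not frames:
        return pd.DataFrame(
            columns=["group_id", "mz_group", "sample_id", "replicate_id", "mz", "intensity"]
        )
    df = pd.concat(frames, ignore_index=True).sort_values(
        "mz", kind="mergesort", ignore_index=True
    )
    mz = df["mz"].to_numpy()
    breaks = np.empty(mz.size, dtype=bool)
    breaks[0] = True
    if mz.size > 1:
        breaks[1:] = np.diff(mz) / mz[:-1] * 1e6 > tol_ppm
    gid = np.cumsum(breaks) - 1
    df["group_id"] = gid

    def _weighted_means(g: np.ndarray) -> np.ndarray:
        w = df["intensity"].to_numpy()
        wsum = np.bincount(g, weights=w)
        msum = np.bincount(g, weights=w * mz)
        csum = np.bincount(g)
        plain = np.bincount(g, weights=mz) / csum
        return np.where(wsum > 0, msum / np.where(wsum > 0, wsum, 1.0), plain)

    centers = _weighted_means(gid)
    # Enforce one peak per replicate per group: nearest to the center wins,
    # the rest are split off as singleton groups.
    rep_codes = pd.factorize(
        df["sample_id"].astype(str) + "|" + df["replicate_id"].astype(str)
    )[0]
    dist = np.abs(mz - centers[gid])
    order = np.lexsort((dist, rep_codes, gid))
    pair = gid[order].astype(np.int64) * (rep_codes.max() + 1) + rep_codes[order]
    first = np.ones(pair.size, dtype=bool)
    first[1:] = pair[1:] != pair[:-1]
    loser_idx = order[~first]
    if loser_idx.size:
        gid = gid.copy()
        gid[loser_idx] = gid.max() + 1 + np.arange(loser_idx.size)
        # re-index contiguously, preserving mass order
        gid = pd.factorize(gid)[0]
        df["group_id"] = gid
        centers = _weighted_means(gid)
    df["mz_group"] = centers[df["group_id"].to_numpy()]
    return df[["group_id", "mz_group", "sample_id", "replicate_id", "mz", "intensity"]]


# ---------------------------------------------------------------------------
# Stage 4: formula enumeration


def _validate_bounds(bounds: dict[str, tuple[int, int]]) -> dict[str, tuple[int, int]]:
    b = {el: tuple(bounds.get(el, DEFAULT_ELEMENT_BOUNDS[el])) for el in DEFAULT_ELEMENT_BOUNDS}
    limits = {"C": 127, "H": 255, "N": 7, "O": 127, "S": 3, "P": 3}
    for el, (lo, hi) in b.items():
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid bounds for {el}: {(lo, hi)}")
        if hi > limits[el]:
            raise ValueError(f"bounds for {el} exceed supported maximum {limits[el]}")
    if b["C"][0] < 1:
        b["C"] = (1, b["C"][1])
    return b


_SHIFTS = {"C": 0, "H": 7, "N": 15, "O": 18, "S": 25, "P": 27}


def _encode(c, h, n, o, s, p):
    return (
        np.asarray(c, dtype=np.int64)
        | (np.asarray(h, dtype=np.int64) << _SHIFTS["H"])
        | (np.asarray(n, dtype=np.int64) << _SHIFTS["N"])
        | (np.asarray(o, dtype=np.int64) << _SHIFTS["O"])
        | (np.asarray(s, dtype=np.int64) << _SHIFTS["S"])
        | (np.asarray(p, dtype=np.int64) << _SHIFTS["P"])
    )


class FormulaDatabase:
    """All valid CHNOSP compositions under bounds and screens, sorted by mass."""

    def __init__(self, bounds: dict[str, tuple[int, int]], mass_max: float = 1200.0):
        self.bounds = _validate_bounds(bounds)
        self.mass_max = mass_max
        self._build()

    def _build(self) -> None:
        b = self.bounds
        mC, mH, mN, mO, mS, mP = (MONOISOTOPIC_MASS[e] for e in "CHNOSP")
        cols: dict[str, list[np.ndarray]] = {k: [] for k in "chnosp"}
        masses: list[np.ndarray] = []
        c_hi = min(b["C"][1], int(self.mass_max / 12.0))
        for n in range(b["N"][0], b["N"][1] + 1):
            for s in range(b["S"][0], b["S"][1] + 1):
                for p in range(b["P"][0], b["P"][1] + 1):
                    base = n * mN + s * mS + p * mP
                    for c in range(b["C"][0], c_hi + 1):
                        rem = self.mass_max - base - c * mC
                        if rem < 0:
                            break
                        h_sat = 2 * c + 2 + n + p  # DBE = 0 endpoint
                        h_lo = max(b["H"][0], int(np.ceil(HC_MIN * c)))
                        h_hi = min(b["H"][1], int(np.floor(HC_MAX * c)), h_sat)
                        # valence parity (integer DBE / nitrogen rule)
                        if h_lo % 2 != (n + p) % 2:
                            h_lo += 1
                        if h_lo > h_hi:
                            continue
                        h = np.arange(h_lo, h_hi + 1, 2)
                        # the fully saturated composition is kept even when
                        # small C puts its H/C above the van Krevelen ceiling
                        if h_sat > h_hi and h_sat <= b["H"][1]:
                            h = np.append(h, h_sat)
                        o_hi = min(b["O"][1], int(np.floor(OC_MAX * c)))
                        if o_hi < b["O"][0]:
                            continue
                        o = np.arange(b["O"][0], o_hi + 1)
                        grid = (
                            base + c * mC + h[:, None] * mH + o[None, :] * mO
                        )
                        ok = grid <= self.mass_max
                        if not ok.any():
                            continue
                        hh, oo = np.nonzero(ok)
                        cols["c"].append(np.full(hh.size, c, dtype=np.int16))
                        cols["h"].append(h[hh].astype(np.int16))
                        cols["n"].append(np.full(hh.size, n, dtype=np.int16))
                        cols["o"].append(o[oo].astype(np.int16))
                        cols["s"].append(np.full(hh.size, s, dtype=np.int16))
                        cols["p"].append(np.full(hh.size, p, dtype=np.int16))
                        masses.append(grid[ok])
        if masses:
            mass = np.concatenate(masses)
            order = np.argsort(mass)
            self.mass = mass[order]
            for k in cols:
                setattr(self, k, np.concatenate(cols[k])[order])
        else:
            self.mass = np.empty(0)
            for k in cols:
                setattr(self, k, np.empty(0, dtype=np.int16))

    def query(self, neutral_mass: float, tol_ppm: float) -> list[AssignmentCandidate]:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = int(np.searchsorted(self.mass, neutral_mass - tol, side="left"))
        hi = int(np.searchsorted(self.mass, neutral_mass + tol, side="right"))
        out = []
        for i in range(lo, hi):
            f = MolecularFormula(
                c=int(self.c[i]), h=int(self.h[i]), n=int(self.n[i]),
                o=int(self.o[i]), s=int(self.s[i]), p=int(self.p[i]),
            )
            ppm = (neutral_mass - self.mass[i]) / self.mass[i] * 1e6
            out.append(AssignmentCandidate(formula=f, ppm_error=float(ppm)))
        out.sort(key=lambda cand: abs(cand.ppm_error))
        return out


_DB_CACHE: dict[tuple, FormulaDatabase] = {}


def _get_database(
    bounds: dict[str, tuple[int, int]] | None, mass_max: float = 1200.0
) -> FormulaDatabase:
    b = _validate_bounds(bounds or DEFAULT_ELEMENT_BOUNDS)
    key = (tuple(sorted(b.items())), mass_max)
    if key not in _DB_CACHE:
        _DB_CACHE[key] = FormulaDatabase(b, mass_max)
    return _DB_CACHE[key]


def enumerate_candidates(
    neutral_mass: float,
    tol_ppm: float = 0.5,
    bounds: dict[str, tuple[int, int]] | None = None,
) -> list[AssignmentCandidate]:
    """All formulas whose exact neutral mass lies within ``tol_ppm``.

    Candidates satisfy the element bounds, 0.3 <= H/C <= 2.5, O/C <= 1.2,
    integer non-negative DBE and the nitrogen-rule parity for the
    deprotonated ion. An empty list means the mass stays unassigned. Sorted
    by absolute ppm error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    db = _get_database(bounds)
    if neutral_mass > db.mass_max:
        return []
    return db.query(neutral_mass, tol_ppm)


# ---------------------------------------------------------------------------
# Stage 5: heteroatom plausibility and isotope verification


def passes_nsp_rule(
    f: MolecularFormula, caps: dict[str, int] | None = None
) -> bool:
    """True when the heteroatom content is chemically plausible for DOM."""
    caps = caps or DEFAULT_NSP_CAPS
    if f.n > caps["N"] or f.s > caps["S"] or f.p > caps["P"]:
        return False
    species = (f.n > 0) + (f.s > 0) + (f.p > 0)
    if species >= 2 and f.n + f.s + f.p > caps["combined"]:
        return False
    return True


def apply_nsp_rule(
    candidates: list[AssignmentCandidate],
    caps: dict[str, int] | None = None,
) -> list[AssignmentCandidate]:
    """Drop heteroatom-implausible candidates unless isotope-verified."""
    return [
        cand
        for cand in candidates
        if passes_nsp_rule(cand.formula, caps) or cand.isotope_verified is True
    ]


def verify_isotope(
    candidate: AssignmentCandidate,
    peaks: PeakList,
    parent_mz: float,
    parent_intensity: float,
    tol_ppm: float = 2.0,
    band: tuple[float, float] = (0.5, 2.0),
) -> bool:
    """Check the first 13C isotopologue of a candidate assignment.

    True iff a peak sits at parent m/z + 1.0033548 Da (within ``tol_ppm``)
    with intensity inside ``band`` x the predicted satellite intensity
    0.0107 x C x parent.
    """
    target = parent_mz + C13_C12_DELTA
    tol = target * tol_ppm * 1e-6
    lo = int(np.searchsorted(peaks.mz, target - tol, side="left"))
    hi = int(np.searchsorted(peaks.mz, target + tol, side="right"))
    if lo >= hi:
        return False
    window = peaks.intensity[lo:hi]
    predicted = C13_ABUNDANCE * candidate.formula.c * parent_intensity
    if predicted <= 0:
        return False
    best = window[np.argmin(np.abs(peaks.mz[lo:hi] - target))]
    return band[0] * predicted <= best <= band[1] * predicted


# ---------------------------------------------------------------------------
# Stage 6: series-support resolution and the consensus table

_NEIGHBOR_DELTAS = np.array(
    [
        [sign * k * d for d in delta]
        for delta in SERIES_UNITS.values()
        for k in range(1, SERIES_MAX_MULTIPLE + 1)
        for sign in (1, -1)
    ],
    dtype=np.int64,
)


def _support_counts(
    fields: np.ndarray, ref_codes: np.ndarray
) -> np.ndarray:
    """Series support per candidate: how many homologous neighbors exist.

    ``fields`` is (M, 6) int element counts; ``ref_codes`` the sorted encoded
    compositions of the reference set (all candidates on the first pass,
    current winners afterwards).
    """
    if fields.size == 0:
        return np.zeros(0, dtype=int)
    support = np.zeros(fields.shape[0], dtype=int)
    chunk = 4096
    for start in range(0, fields.shape[0], chunk):
        fl = fields[start : start + chunk]
        nb = fl[:, None, :] + _NEIGHBOR_DELTAS[None, :, :]  # (m, D, 6)
        valid = (nb >= 0).all(axis=2) & (nb[:, :, 0] >= 1)
        codes = _encode(
            nb[:, :, 0].clip(0), nb[:, :, 1].clip(0), nb[:, :, 2].clip(0),
            nb[:, :, 3].clip(0), nb[:, :, 4].clip(0), nb[:, :, 5].clip(0),
        )
        pos = np.searchsorted(ref_codes, codes)
        found = (pos < ref_codes.size) & (
            ref_codes[np.minimum(pos, ref_codes.size - 1)] == codes
        )
        support[start : start + chunk] = (valid & found).sum(axis=1)
    return support


def _candidate_fields(cands: list[MolecularFormula]) -> np.ndarray:
    return np.array([f.counts() for f in cands], dtype=np.int64).reshape(-1, 6)


def resolve_candidates(
    aligned: pd.DataFrame,
    candidates: dict[int, list[AssignmentCandidate]],
    *,
    max_passes: int = 5,
    require_duplicates: bool = True,
    normalize: bool = True,
) -> AssignedTable:
    """Pick one formula per mass group and build the consensus table.

    Series support counts, for each candidate, the homologous-series
    neighbors (CH2, CO2, H2, H2O, O at multiples 1-10) present among the
    other groups' candidates; the first pass counts against all candidates,
    later passes against the provisional winners, iterating to a fixed
    point (bounded by ``max_passes``). Ties break by smaller |ppm error|,
    then fewer heteroatoms, then lexicographic formula. Formulas not seen in
    every replicate of at least one sample are dropped; sample columns are
    normalized to unit sum.
    """
    group_ids = [g for g, cl in candidates.items() if cl]
    flat: list[tuple[int, AssignmentCandidate]] = [
        (g, cand) for g in group_ids for cand in candidates[g]
    ]
    if not flat:
        return AssignedTable(
            table=pd.DataFrame(), annotations=pd.DataFrame(), provenance={}
        )
    fields = _candidate_fields([cand.formula for _, cand in flat])
    cand_group = np.array([g for g, _ in flat])

    # winner selection, iterated to a fixed point
    tie_key = [
        (abs(cand.ppm_error), cand.formula.heteroatom_count, str(cand.formula))
        for _, cand in flat
    ]
    idx_by_group: dict[int, list[int]] = {}
    for i, g in enumerate(cand_group):
        idx_by_group.setdefault(int(g), []).append(i)

    # Initial reference set: compositions of unambiguous (single-candidate)
    # groups, so series support is counted against confident assignments
    # rather than against other groups' unresolved alternatives. Falls back
    # to the full candidate pool when no group is unambiguous.
    singleton_idx = np.array(
        [idxs[0] for idxs in idx_by_group.values() if len(idxs) == 1], dtype=int
    )
    winners: dict[int, int] | None = None
    previous: dict[int, int] | None = None
    support = np.zeros(len(flat), dtype=int)
    for pass_no in range(max_passes):
        if winners is None:
            base = fields[singleton_idx] if singleton_idx.size else fields
            ref_codes = np.unique(_encode(*base.T))
        else:
            widx = np.fromiter(winners.values(), dtype=int)
            ref_codes = np.unique(_encode(*fields[widx].T))
        support = _support_counts(fields, ref_codes)
        new_winners = {
            g: min(idxs, key=lambda i: (-support[i],) + tie_key[i])
            for g, idxs in idx_by_group.items()
        }
        if new_winners == winners:
            break
        if new_winners == previous:
            # two-cycle between equivalent resolutions: accept the latest
            logger.debug("series-support resolution settled into a 2-cycle")
            winners = new_winners
            break
        previous, winners = winners, new_winners
    else:
        logger.warning(
            "series-support resolution did not converge in %d passes", max_passes
        )
    assert winners is not None

    # replicate structure: which replicates exist for each sample
    reps_per_sample = aligned.groupby("sample_id")["replicate_id"].agg(set).to_dict()
    members = {g: sub for g, sub in aligned.groupby("group_id")}

    sample_ids = sorted(reps_per_sample)
    rows: dict[str, dict[str, float]] = {}
    ann: dict[str, dict] = {}
    provenance: dict[str, dict[str, list]] = {}
    for g, i in winners.items():
        cand = flat[i][1]
        name = str(cand.formula)
        sub = members.get(g)
        if sub is None:
            continue
        row = rows.setdefault(name, dict.fromkeys(sample_ids, 0.0))
        prov = provenance.setdefault(name, {})
        for sample, ssub in sub.groupby("sample_id"):
            seen = set(ssub["replicate_id"])
            if require_duplicates and seen != reps_per_sample[sample]:
                continue
            row[sample] += float(ssub["intensity"].mean())
            prov.setdefault(sample, []).extend(sorted(seen))
        prev = ann.get(name)
        entry = {
            "neutral_mass": cand.formula.neutral_mass,
            "ppm_error": cand.ppm_error,
            "series_support": int(support[i]),
        }
        if prev is None or abs(entry["ppm_error"]) < abs(prev["ppm_error"]):
            entry["series_support"] = max(
                entry["series_support"], prev["series_support"] if prev else 0
            )
            ann[name] = entry

    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=sample_ids
    )
    keep = table.sum(axis=1) > 0
    table = table.loc[keep].sort_index()
    annotations = (
        pd.DataFrame.from_dict(ann, orient="index").loc[table.index]
        if len(table)
        else pd.DataFrame(columns=["neutral_mass", "ppm_error", "series_support"])
    )
    provenance = {k: v for k, v in provenance.items() if k in set(table.index)}
    if normalize and len(table):
        sums = table.sum(axis=0)
        zero = sums == 0
        if zero.any():
            logger.warning("samples with no consensus formulas: %s",
                           list(table.columns[zero]))
        table = table.div(sums.where(~zero, 1.0), axis=1)
    return AssignedTable(table=table, annotations=annotations, provenance=provenance)


# ---------------------------------------------------------------------------
# Full pipeline


def assign_samples(
    peak_lists: list[PeakList],
    *,
    tol_ppm: float = 0.5,
    bounds: dict[str, tuple[int, int]] | None = None,
    scan_range: tuple[float, float] = (100.0, 1000.0),
    mdl_level: float | None = None,
    mdl_noise_band: float = 0.25,
    recalibration_references: list[MolecularFormula] | None = None,
    exclusion_masses: list[float] | None = None,
    exclusion_tol_ppm: float | None = None,
    nsp_caps: dict[str, int] | None = None,
    isotope_rescue: bool = True,
    max_passes: int = 5,
    require_duplicates: bool = True,
) -> AssignedTable:
    """Run the full assignment chain on replicate peak lists.

    Steps: scan-range filter, optional MDL noise filter (meant for raw
    exported mass lists; peak-picked lists are usually already
    signal-to-noise thresholded), optional recalibration against reference
    formulas, optional removal of known contaminant masses, cross-spectrum
    alignment, formula enumeration on duplicate-consensus mass groups,
    N,S,P plausibility filtering with isotope-pattern rescue, and
    series-support resolution into the final relative-intensity table.
    """
    processed: list[PeakList] = []
    provenance: dict = {"recalibration": {}, "mdl_threshold": {}}
    for pl in peak_lists:
        cur = pl.filter_range(*scan_range)
        if mdl_level is not None:
            cur, thr = mdl_filter(cur, mdl_level=mdl_level,
                                  noise_band_quantile=mdl_noise_band)
            provenance["mdl_threshold"][cur.rep_key] = thr
        if recalibration_references:
            res = recalibrate(cur, recalibration_references)
            cur = res.peaks
            provenance["recalibration"][cur.rep_key] = {
                "offset_ppm": res.offset_ppm,
                "n_matched": res.n_matched,
                "applied": res.applied,
            }
        if exclusion_masses:
            tol = exclusion_tol_ppm if exclusion_tol_ppm is not None else tol_ppm
            keep = np.ones(len(cur), dtype=bool)
            for m in exclusion_masses:
                keep &= np.abs(cur.mz - m) > m * tol * 1e-6
            cur = replace(cur, mz=cur.mz[keep], intensity=cur.intensity[keep])
        processed.append(cur)

    aligned = align(processed, tol_ppm=tol_ppm)
    if aligned.empty:
        return AssignedTable(pd.DataFrame(), pd.DataFrame(), provenance)

    reps_per_sample = aligned.groupby("sample_id")["replicate_id"].agg(set).to_dict()
    peaks_by_rep = {pl.rep_key: pl for pl in processed}

    # Only mass groups with full replicate support in some sample can ever
    # reach the table; skip enumeration for the rest.
    def _has_consensus(sub: pd.DataFrame) -> bool:
        if not require_duplicates:
            return True
        for sample, ssub in sub.groupby("sample_id"):
            if set(ssub["replicate_id"]) == reps_per_sample[sample]:
                return True
        return False

    candidates: dict[int, list[AssignmentCandidate]] = {}
    for g, sub in aligned.groupby("group_id"):
        if not _has_consensus(sub):
            continue
        neutral = float(sub["mz_group"].iloc[0]) + PROTON_MASS
        cands = enumerate_candidates(neutral, tol_ppm=tol_ppm, bounds=bounds)
        if not cands:
            continue
        screened = []
        for cand in cands:
            if not passes_nsp_rule(cand.formula, nsp_caps):
                if isotope_rescue:
                    verified = False
                    for _, peak_row in sub.iterrows():
                        rk = f"{peak_row['sample_id']}|{peak_row['replicate_id']}"
                        pl = peaks_by_rep.get(rk)
                        if pl is not None and verify_isotope(
                            cand, pl, float(peak_row["mz"]), float(peak_row["intensity"])
                        ):
                            verified = True
                            break
                    cand.isotope_verified = verified
                else:
                    cand.isotope_verified = False
            screened.append(cand)
        screened = apply_nsp_rule(screened, nsp_caps)
        if screened:
            candidates[int(g)] = screened

    result = resolve_candidates(
        aligned,
        candidates,
        max_passes=max_passes,
        require_duplicates=require_duplicates,
    )
    result.provenance.update(provenance)
    return result
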