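import numpy as np
import pandas as pd
import pytest

from domchar.assign import (
    AssignmentCandidate,
    EmptyPeakListError,
    PeakList,
    align,
    apply_nsp_rule,
    assign_samples,
    enumerate_candidates,
    mdl_filter,
    recalibrate,
    resolve_candidates,
    verify_isotope,
)
from domchar.formula import C13_C12_DELTA, MolecularFormula

from _oracles import brute_force_candidates
from conftest import CHO_BOUNDS

SMALL_BOUNDS = {
    "C": (1, 25),
    "H": (0, 60),
    "N": (0, 3),
    "O": (0, 25),
    "S": (0, 2),
    "P": (0, 1),
}


def _peaklist(mz, intensity=None, sample="s", rep=1):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return PeakList(sample_id=sample, replicate_id=rep, mz=mz, intensity=intensity)


# ---------------------------------------------------------------- MDL filter


def test_mdl_retains_everything_when_intensities_equal():
    pl = _peaklist(np.linspace(100, 900, 50), np.full(50, 7.0))
    filtered, threshold = mdl_filter(pl)
    assert len(filtered) == 50
    assert threshold == pytest.approx(7.0)


def test_mdl_separates_bimodal_noise_from_signal(rng):
    mz = np.sort(rng.uniform(100, 1000, 1250))
    intensity = np.concatenate([np.full(1000, 100.0), rng.normal(1.0, 0.1, 250)])
    rng.shuffle(intensity)
    pl = _peaklist(mz, intensity)
    filtered, threshold = mdl_filter(pl, mdl_level=4.0)
    assert len(filtered) == 1000
    assert np.all(filtered.intensity == 100.0)
    assert 1.0 < threshold < 100.0


def test_mdl_level_zero_cuts_at_noise_median(rng):
    intensity = rng.uniform(1, 10, 200)
    pl = _peaklist(np.linspace(100, 900, 200), intensity)
    filtered, threshold = mdl_filter(pl, mdl_level=0.0)
    band = np.sort(intensity)[:50]
    assert threshold == pytest.approx(np.median(band))
    assert np.all(filtered.intensity >= threshold)


def test_mdl_empty_input_raises():
    with pytest.raises(EmptyPeakListError):
        mdl_filter(_peaklist([]))


# ------------------------------------------------------------- recalibration

REFS = [
    MolecularFormula.from_string(t)
    for t in ["C10H12O5", "C15H16O7", "C20H22O9", "C25H26O11", "C30H30O13", "C18H20O8"]
]
REF_MZ = np.sort([f.mz_deprotonated for f in REFS])


def test_recalibration_recovers_injected_shift():
    mz = REF_MZ
    shifted = _peaklist(mz * (1 + 1.0e-6))  # +1.0 ppm systematic error
    res = recalibrate(shifted, REFS)
    assert res.applied
    assert res.offset_ppm == pytest.approx(1.0, abs=0.05)
    np.testing.assert_allclose(res.peaks.mz, mz, rtol=1e-9)


def test_recalibration_identity_when_no_shift():
    mz = REF_MZ
    res = recalibrate(_peaklist(mz), REFS)
    assert res.offset_ppm == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(res.peaks.mz, mz, rtol=1e-12)


def test_recalibration_median_robust_to_balanced_shifts():
    mz = REF_MZ
    scale = 1 + np.array([1, 1, 1, -1, -1, -1]) * 1e-6
    res = recalibrate(_peaklist(mz * scale), REFS)
    assert res.offset_ppm == pytest.approx(0.0, abs=1e-9)


def test_recalibration_skipped_with_few_matches():
    pl = _peaklist([500.0, 600.0])
    with pytest.warns(UserWarning, match="skipped"):
        res = recalibrate(pl, REFS[:2])
    assert not res.applied
    np.testing.assert_array_equal(res.peaks.mz, pl.mz)


# ----------------------------------------------------------------- alignment


def test_align_exact_duplicates_form_pairs():
    mz = [200.0, 300.0, 400.0]
    a = _peaklist(mz, rep=1)
    b = _peaklist(mz, rep=2)
    grouped = align([a, b])
    sizes = grouped.groupby("group_id").size()
    assert len(sizes) == 3
    assert (sizes == 2).all()


@pytest.mark.parametrize(
    "mz2, n_groups",
    [
        (400.00040, 2),  # 1.0 ppm apart: split
        (400.00015, 1),  # 0.375 ppm apart: join
    ],
)
def test_align_tolerance_boundary(mz2, n_groups):
    a = _peaklist([400.00000], rep=1)
    b = _peaklist([mz2], rep=2)
    grouped = align([a, b], tol_ppm=0.5)
    assert grouped["group_id"].nunique() == n_groups


def test_align_one_peak_per_replicate_keeps_nearest():
    # replicate 1 contributes two peaks near the group; the closer one stays
    a = _peaklist([400.00000, 400.00012], [1.0, 1.0], rep=1)
    b = _peaklist([400.00001], [10.0], rep=2)
    grouped = align([a, b], tol_ppm=0.5)
    main = grouped.groupby("group_id").size().idxmax()
    members = grouped[grouped["group_id"] == main]
    assert len(members) == 2
    assert 400.00012 not in set(members["mz"])


def test_align_group_mass_is_intensity_weighted():
    a = _peaklist([400.00000], [3.0], rep=1)
    b = _peaklist([400.00010], [1.0], rep=2)
    grouped = align([a, b], tol_ppm=0.5)
    assert grouped["mz_group"].iloc[0] == pytest.approx(400.000025, abs=1e-9)


# --------------------------------------------------------------- enumeration


def test_enumeration_contains_worked_example_formulas():
    cands = enumerate_candidates(260.03209, tol_ppm=0.5)
    assert "C13H8O6" in {str(c.formula) for c in cands}
    cho = enumerate_candidates(918.42491, tol_ppm=0.5, bounds=CHO_BOUNDS)
    assert {str(c.formula) for c in cho} == {"C47H66O18"}


def test_enumeration_smallest_alkane():
    cands = enumerate_candidates(16.0313, tol_ppm=5.0)
    assert [str(c.formula) for c in cands] == ["CH4"]


def test_enumeration_matches_nested_loop_brute_force(rng):
    """The database-backed enumerator returns exactly the brute-force set."""
    for _ in range(50):
        mass = float(rng.uniform(100, 340))
        got = {
            c.formula.counts()
            for c in enumerate_candidates(mass, tol_ppm=5.0, bounds=SMALL_BOUNDS)
        }
        expected = brute_force_candidates(mass, 5.0, SMALL_BOUNDS)
        assert got == expected, f"mismatch at mass {mass}"


def test_enumeration_monotone_in_tolerance(rng):
    for _ in range(20):
        mass = float(rng.uniform(150, 900))
        wide = {str(c.formula) for c in enumerate_candidates(mass, tol_ppm=1.0)}
        narrow = {str(c.formula) for c in enumerate_candidates(mass, tol_ppm=0.3)}
        assert narrow <= wide


def test_enumeration_empty_result_is_not_an_error():
    # a mass far from any valid composition
    assert enumerate_candidates(100.00001, tol_ppm=0.1) == []


# ------------------------------------------------------- N,S,P rule, isotope


def _cand(text, ppm=0.0, verified=None):
    return AssignmentCandidate(
        formula=MolecularFormula.from_string(text),
        ppm_error=ppm,
        isotope_verified=verified,
    )


def test_nsp_rule_cap_violation_removed():
    kept = apply_nsp_rule([_cand("C10H15N6O5", 0.1)], caps={"N": 4, "S": 2, "P": 1, "combined": 5})
    assert kept == []


def test_nsp_rule_cho_always_retained():
    cand = _cand("C13H8O6")
    assert apply_nsp_rule([cand]) == [cand]


def test_nsp_combined_cap_with_isotope_rescue():
    unverified = _cand("C20H29N3O5S2P", verified=False)
    verified = _cand("C20H29N3O5S2P", verified=True)
    assert apply_nsp_rule([unverified]) == []
    assert apply_nsp_rule([verified]) == [verified]


def test_isotope_verification_positive_and_negative():
    parent = MolecularFormula.from_string("C20H22O9")
    parent_mz, parent_int = parent.mz_deprotonated, 50.0
    satellite = parent_mz + C13_C12_DELTA
    predicted = 0.0107 * 20 * parent_int
    good = _peaklist([parent_mz, satellite], [parent_int, predicted])
    cand = _cand("C20H22O9")
    assert verify_isotope(cand, good, parent_mz, parent_int)
    no_satellite = _peaklist([parent_mz], [parent_int])
    assert not verify_isotope(cand, no_satellite, parent_mz, parent_int)
    wrong_intensity = _peaklist([parent_mz, satellite], [parent_int, 5 * predicted])
    assert not verify_isotope(cand, wrong_intensity, parent_mz, parent_int)


# ------------------------------------------------------ resolution and table


def _ladder_peaklists():
    formulas = [MolecularFormula(c=c, h=12 + 2 * (c - 10), o=5) for c in range(10, 21)]
    mz = np.array([f.mz_deprotonated for f in formulas])
    return formulas, [
        _peaklist(mz, np.ones_like(mz), sample="s", rep=r) for r in (1, 2)
    ]


def test_homologous_ladder_fully_assigned_with_series_support():
    formulas, peaks = _ladder_peaklists()
    result = assign_samples(peaks, bounds=CHO_BOUNDS)
    assert set(result.table.index) == {str(f) for f in formulas}
    interior = [str(f) for f in formulas[1:-1]]
    assert (result.annotations.loc[interior, "series_support"] >= 1).all()


def test_formula_in_single_replicate_dropped():
    formulas, (rep1, rep2) = _ladder_peaklists()
    extra = MolecularFormula.from_string("C30H32O8")
    rep1 = _peaklist(
        np.append(rep1.mz, extra.mz_deprotonated),
        np.append(rep1.intensity, 1.0),
        rep=1,
    )
    result = assign_samples([rep1, rep2], bounds=CHO_BOUNDS)
    assert str(extra) not in result.table.index


def test_tie_break_prefers_smaller_ppm_error():
    aligned = pd.DataFrame(
        {
            "group_id": [0, 0],
            "mz_group": [500.0, 500.0],
            "sample_id": ["s", "s"],
            "replicate_id": [1, 2],
            "mz": [500.0, 500.0],
            "intensity": [1.0, 1.0],
        }
    )
    candidates = {0: [_cand("C20H22O9", ppm=0.3), _cand("C25H26O5", ppm=0.1)]}
    result = resolve_candidates(aligned, candidates)
    assert list(result.table.index) == ["C25H26O5"]


def test_zero_noise_cho_round_trip_is_exact(cho_zero_noise):
    """With no mass error and no noise peaks, assignment recovers the
    ground-truth CHO library perfectly in every sample."""
    _, truth, peaks = cho_zero_noise
    result = assign_samples(peaks, bounds=CHO_BOUNDS)
    for sid in truth.samples:
        true_set = truth.formula_set(sid)
        got = set(result.table.index[result.table[sid] > 0])
        assert got == true_set


def test_assigned_columns_sum_to_one(cho_zero_noise):
    _, _, peaks = cho_zero_noise
    result = assign_samples(peaks, bounds=CHO_BOUNDS)
    np.testing.assert_allclose(result.table.sum(axis=0), 1.0, atol=1e-9)
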