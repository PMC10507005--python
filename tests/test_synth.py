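import numpy as np
import pandas as pd
import pytest

from domchar.compose import CATEGORIES, classify
from domchar.formula import C13_C12_DELTA, MolecularFormula, dbe
from domchar.synth import (
    DEFAULT_GROUP_WEIGHTS,
    InfeasibleWeightsError,
    SynthConfig,
    generate_bioassay_plate,
    generate_formula_library,
    render_peak_lists,
)

from conftest import CHO_BOUNDS


def _weights(**overrides):
    w = dict.fromkeys(CATEGORIES, 0.0)
    w.update(overrides)
    return w


def test_group_weight_presets_are_normalized():
    for group, weights in DEFAULT_GROUP_WEIGHTS.items():
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12), group
        assert set(weights) == set(CATEGORIES)


def test_generation_deterministic_under_fixed_seed():
    config = SynthConfig(n_samples=2, n_formulas_per_sample=100, seed=9)
    t1 = generate_formula_library(config)
    t2 = generate_formula_library(config)
    for sid in t1.samples:
        pd.testing.assert_frame_equal(t1.samples[sid], t2.samples[sid])
    p1 = render_peak_lists(t1, config)
    p2 = render_peak_lists(t2, config)
    for a, b in zip(p1, p2):
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)
    pd.testing.assert_frame_equal(
        generate_bioassay_plate(t1, config), generate_bioassay_plate(t2, config)
    )


def test_all_saturated_cho_library_has_dbe_zero():
    config = SynthConfig(
        n_samples=1,
        n_formulas_per_sample=50,
        element_bounds=dict(CHO_BOUNDS),
        category_weights_per_group={"g": _weights(Sat_Or=0.5, Sat_Op=0.5)},
        seed=3,
    )
    truth = generate_formula_library(config)
    (df,) = truth.samples.values()
    for text in df["formula"]:
        assert dbe(MolecularFormula.from_string(text)) == 0.0


def test_category_composition_matches_weights():
    weights = _weights(A_Op=0.5, HUn_Op=0.5)
    config = SynthConfig(
        n_samples=1,
        n_formulas_per_sample=2000,
        category_weights_per_group={"g": weights},
        seed=4,
    )
    truth = generate_formula_library(config)
    (df,) = truth.samples.values()
    observed = (
        pd.Series([classify(MolecularFormula.from_string(t)) for t in df["formula"]])
        .value_counts(normalize=True)
    )
    for cat, w in weights.items():
        assert observed.get(cat, 0.0) == pytest.approx(w, abs=0.02), cat


def test_generated_formulas_respect_bounds_and_mass_range():
    config = SynthConfig(n_samples=2, n_formulas_per_sample=300, seed=6)
    truth = generate_formula_library(config)
    lo, hi = config.mass_range_da
    for df in truth.samples.values():
        assert df["formula"].is_unique
        assert df["relative_intensity"].sum() == pytest.approx(1.0, abs=1e-9)
        for text in df["formula"]:
            f = MolecularFormula.from_string(text)
            assert lo <= f.neutral_mass <= hi
            for el, cnt in zip("CHNOSP", f.counts()):
                b = config.element_bounds[el]
                assert b[0] <= cnt <= b[1]


def test_infeasible_weights_raise():
    # saturated O-rich is impossible when oxygen is capped at zero
    bounds = dict(CHO_BOUNDS, O=(0, 0))
    config = SynthConfig(
        n_samples=1,
        n_formulas_per_sample=20,
        element_bounds=bounds,
        category_weights_per_group={"g": _weights(Sat_Or=1.0)},
        seed=1,
    )
    with pytest.raises(InfeasibleWeightsError):
        generate_formula_library(config)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SynthConfig(mass_range_da=(0.0, 100.0)).validate()
    with pytest.raises(ValueError):
        SynthConfig(replicate_count=0).validate()
    with pytest.raises(ValueError):
        SynthConfig(
            category_weights_per_group={"g": _weights(A_Op=0.6, HUn_Op=0.6)}
        ).validate()


def test_zero_noise_rendering_is_exact(cho_zero_noise):
    _, truth, peaks = cho_zero_noise
    for pl in peaks:
        expected = np.sort(
            [
                MolecularFormula.from_string(t).mz_deprotonated
                for t in truth.samples[pl.sample_id]["formula"]
            ]
        )
        np.testing.assert_allclose(pl.mz, expected, atol=1e-12)


def test_rendered_mz_of_known_formula():
    config = SynthConfig(
        n_samples=1,
        n_formulas_per_sample=1,
        element_bounds=dict(CHO_BOUNDS),
        category_weights_per_group={"g": _weights(A_Op=1.0)},
        ppm_error_sd=0.0,
        noise_peak_fraction=0.0,
        seed=8,
    )
    truth = generate_formula_library(config)
    # overwrite with the worked example formula
    (sid,) = truth.samples
    truth.samples[sid] = pd.DataFrame(
        {"formula": ["C13H8O6"], "relative_intensity": [1.0], "category": ["A_Op"]}
    )
    (pl, *_) = render_peak_lists(truth, config)
    assert pl.mz[0] == pytest.approx(259.02481, abs=1e-5)


def test_noise_peak_count_bookkeeping():
    config = SynthConfig(
        n_samples=1,
        n_formulas_per_sample=1000,
        noise_peak_fraction=0.2,
        ppm_error_sd=0.0,
        seed=13,
    )
    truth = generate_formula_library(config)
    peaks = render_peak_lists(truth, config)
    # expect 1000 signal + Poisson(250) noise peaks per replicate
    for pl in peaks:
        assert abs(len(pl) - 1250) < 5 * np.sqrt(250)


def test_isotope_satellites_rendered_at_expected_position_and_intensity():
    config = SynthConfig(
        n_samples=1,
        n_formulas_per_sample=5,
        element_bounds=dict(CHO_BOUNDS),
        category_weights_per_group={"g": _weights(HUn_Op=1.0)},
        ppm_error_sd=0.0,
        noise_peak_fraction=0.0,
        replicate_intensity_sigma=0.0,
        include_isotope_satellites=True,
        seed=21,
    )
    truth = generate_formula_library(config)
    (df,) = truth.samples.values()
    (pl, *_) = render_peak_lists(truth, config)
    assert len(pl) == 10  # parent + satellite per formula
    for _, row in df.iterrows():
        f = MolecularFormula.from_string(row["formula"])
        target = f.mz_deprotonated + C13_C12_DELTA
        i = np.argmin(np.abs(pl.mz - target))
        assert pl.mz[i] == pytest.approx(target, abs=1e-9)
        assert pl.intensity[i] == pytest.approx(
            0.0107 * f.c * row["relative_intensity"], rel=1e-9
        )


def test_bioassay_wells_follow_logistic_exactly_without_noise():
    config = SynthConfig(
        n_samples=4, n_formulas_per_sample=50, bioassay_noise_sd=0.0, seed=2
    )
    truth = generate_formula_library(config)
    plate = generate_bioassay_plate(truth, config)
    wells = plate[plate["concentration_ug_ml"] > 0]
    for _, row in wells.iterrows():
        ic50 = truth.true_ic50[row["sample_id"]]
        expected = 100.0 / (1.0 + ic50 / row["concentration_ug_ml"])
        assert row["percent_inhibition"] == pytest.approx(expected, abs=1e-12)
    controls = plate[plate["concentration_ug_ml"] == 0]
    assert (controls["percent_inhibition"] == 0).all()


def test_zero_link_coefficient_gives_equal_ic50s():
    config = SynthConfig(
        n_samples=4, n_formulas_per_sample=50, bioactivity_link_coefficient=0.0, seed=2
    )
    truth = generate_formula_library(config)
    assert truth.true_ic50.nunique() == 1
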