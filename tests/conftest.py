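import numpy as np
import pytest

from domchar.synth import SynthConfig, generate_formula_library, render_peak_lists

#: CHO-only element bounds used by the exact round-trip fixtures.
CHO_BOUNDS = {
    "C": (1, 100),
    "H": (0, 200),
    "N": (0, 0),
    "O": (0, 80),
    "S": (0, 0),
    "P": (0, 0),
}

CHO_WEIGHTS = {
    "cho": {
        "A_Or": 0.10, "A_Op": 0.30,
        "HUn_Or": 0.20, "HUn_Op": 0.30,
        "Un_Or": 0.02, "Un_Op": 0.07, "Un_withN": 0.0,
        "Sat_Or": 0.005, "Sat_Op": 0.005,
    }
}


@pytest.fixture(scope="session")
def cho_zero_noise():
    """Small noise-free CHO-only dataset with known formulas."""
    config = SynthConfig(
        n_samples=2,
        n_formulas_per_sample=200,
        element_bounds=dict(CHO_BOUNDS),
        category_weights_per_group={k: dict(v) for k, v in CHO_WEIGHTS.items()},
        ppm_error_sd=0.0,
        noise_peak_fraction=0.0,
        replicate_intensity_sigma=0.0,
        seed=101,
    )
    truth = generate_formula_library(config)
    peaks = render_peak_lists(truth, config)
    return config, truth, peaks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
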