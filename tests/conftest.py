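import numpy as np
import pytest

from trnascreen.simulate import SimConfig, TruthSpec, make_library_truth, simulate_library


@pytest.fixture(scope="session")
def small_screen():
    """One-condition screen: 16 strains, 2 lethal, planted rate and yield
    effects, 3 bio x 2 tech replicates, default noise."""
    cfg = SimConfig(n_strains=16, n_tech_reps=6, seed=11)
    spec = TruthSpec(frac_lethal=0.125, frac_yield_effect=0.125, frac_rate_effect=0.125)
    truth, plates = simulate_library(cfg, spec)
    return cfg, truth, plates


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(n_strains=4, n_tech_reps=3, noise_sd=0.0, cv_bio=0.0,
                     cv_well=0.0, seed=1)
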