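import numpy as np
import pandas as pd
import pytest

from rspgait import SimTrialConfig, simulate_trial
from rspgait.synthgrf import Asymmetry


@pytest.fixture(scope="session")
def symmetric_trial():
    """Noise-free symmetric trial: t_c=0.2 s, t_a=0.12 s, v=3 m/s, impulse balance."""
    cfg = SimTrialConfig(seed=7)
    return cfg, *simulate_trial(cfg)


@pytest.fixture(scope="session")
def asymmetric_trial():
    """Noise-free trial with +/-5% t_c and +/-3% t_a between-leg offsets."""
    cfg = SimTrialConfig(seed=11, asymmetry=Asymmetry(t_c=0.05, t_a=0.03))
    return cfg, *simulate_trial(cfg)


@pytest.fixture(scope="session")
def balanced_design():
    """Fully crossed covariate table: every subject sees every configuration.

    Balance makes the fixed-effect GLS estimator identical to OLS whatever
    the random-intercept variance, which several equivalence tests rely on.
    """
    rows = []
    for subject in range(1, 7):
        for model in ("Catapult", "Sprinter", "Xtend"):
            for cat in ("-1", "Rec", "+1"):
                for height in (-2.0, 0.0, 2.0):
                    for speed in (3.0, 5.0, 7.0):
                        rows.append((subject, model, cat, height, speed))
    return pd.DataFrame(
        rows,
        columns=["subject", "rsp_model", "stiffness_cat", "height_offset_cm", "speed_mps"],
    )
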