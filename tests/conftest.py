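import numpy as np
import pandas as pd
import pytest

import mzipmod as m
from mzipmod.core import DesignSpec


@pytest.fixture(scope="session")
def study_table() -> pd.DataFrame:
    """Default-calibration synthetic study (n=348, 2% missing moderator)."""
    return m.generate_study(m.GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def big_study() -> pd.DataFrame:
    """Larger complete study for recovery-flavored pipeline checks."""
    return m.generate_study(
        m.GeneratorConfig(n_participants=2000, seed=42, p_missing_moderator=0.0)
    )


SATURATED = DesignSpec(
    ("intercept", "hs_drink", "arm", "hs_drink:arm"),
    ("intercept", "hs_drink", "arm", "hs_drink:arm"),
)


@pytest.fixture(scope="session")
def saturated_instance():
    """50-row ZIP data on a saturated binary design (4 covariate cells).

    On a saturated design the conventional-ZIP and marginalized
    parameterizations span the same mixture family, so their maximized
    log-likelihoods must coincide.
    """
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {
            "hs_drink": rng.integers(0, 2, 50).astype(float),
            "arm": rng.integers(0, 2, 50),
        }
    )
    params = m.MZIPParams(
        np.log([5.0, 1.5, 1.3, 0.7]),
        np.array([-1.0, 0.5, -0.3, 0.2]),
        SATURATED.mean_terms,
        SATURATED.zero_terms,
    )
    y = m.simulate_mzip_outcome(df, SATURATED, params, seed=7)
    X, Z = SATURATED.matrices(df)
    return y.astype(float), X, Z, params, df
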