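import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_group_design():
    from dasev.data import DesignMatrix

    return DesignMatrix.two_group(["a"] * 3 + ["b"] * 3)


@pytest.fixture
def toy_matrix():
    """6 features x 6 samples covering the main filtering regimes."""
    from dasev.data import AbundanceMatrix

    e = np.e
    values = np.array(
        [
            [0.0, e, e**2, 0.0, e**2, e**3],   # mixed per group: kept
            [0.0, e, e**2, 2.0, e**2, e**3],   # no PMV in group 1
            [0.0, 0.0, e, 0.0, 0.0, e],        # only 2 non-PMVs
            [0.0, 0.0, 0.0, 2.0, 3.0, 4.0],    # perfect separation
            [1.0, 2.0, 0.0, 0.0, 3.0, 5.0],    # kept
            [0.0, 7.0, 8.0, 0.0, 6.0, 9.0],    # kept
        ]
    )
    fids = [f"f{i}" for i in range(1, 7)]
    sids = [f"s{i}" for i in range(1, 7)]
    return AbundanceMatrix(values, fids, sids)


@pytest.fixture
def default_hp():
    from dasev.prior import PriorHyperparams

    return PriorHyperparams(d0=8.0, s0=np.sqrt(0.75))
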