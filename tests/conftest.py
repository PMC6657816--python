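import numpy as np
import pytest

from primedyn import ModelParameters, baseline_strategies


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default nonprimed-population fixture."""
    return ModelParameters()


@pytest.fixture(scope="session")
def strategies(params):
    """Baseline-calibrated strategy set (td_b=75, c_pb=0.3), singles only."""
    return baseline_strategies(params)


@pytest.fixture(scope="session")
def all_strategies(params):
    """Baseline-calibrated strategies including the combined pairs."""
    return baseline_strategies(params, include_pairs=True)


def random_params(rng: np.random.Generator, **fixed) -> ModelParameters:
    """A random valid parameter set for cross-model consistency checks."""
    g_I = rng.uniform(0.01, 0.15)
    m_I = g_I * rng.uniform(1.2, 3.0)
    t_P = rng.uniform(0.0, 40.0)
    values = dict(
        g_I=g_I,
        m_I=m_I,
        m_R=m_I * rng.uniform(0.1, 0.9),
        s_R=rng.uniform(0.005, 0.1),
        L=rng.uniform(0.0, 10.0),
        t_P=t_P,
        t_TS=t_P + rng.uniform(0.0, 40.0),
        TD=rng.uniform(0.0, 150.0),
        c_P=rng.uniform(0.0, 0.6),
        S0=rng.uniform(10.0, 1000.0),
    )
    values.update(fixed)
    return ModelParameters(**values)
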