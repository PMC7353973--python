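import pytest
from hypothesis import HealthCheck, settings

from twopatch import ConservedTotal, ModelParams, PatchParams
from twopatch.experiments import figure_presets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    return figure_presets()


@pytest.fixture(scope="session")
def fig1_params(presets):
    """Demography-free base parameterization (p=0)."""
    return presets["fig1"].params


@pytest.fixture(scope="session")
def fig1_total(presets):
    return presets["fig1"].total


@pytest.fixture(scope="session")
def fig3_params(presets):
    """Demographic base parameterization (p=1, beta=0 by default)."""
    return presets["fig3"].params


@pytest.fixture(scope="session")
def symmetric_params():
    """Two identical patches; every H/L asymmetry must vanish."""
    return ModelParams(
        high=PatchParams(r=1.5, K=80.0),
        low=PatchParams(r=1.5, K=80.0),
        alpha=0.05,
        c=0.05,
        mu=0.1,
        beta=1.0,
        lam=2.0,
        p=0,
    )


@pytest.fixture(scope="session")
def total_15():
    return ConservedTotal(C_T=15.0)
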