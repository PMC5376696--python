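import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "macrospot",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("macrospot")


@pytest.fixture(scope="session")
def scenario():
    """The packaged dual-probe membrane (10x10 blocks, clones G1-G7 with
    known truth), generated once per session."""
    from macrospot.simulate import dual_probe_scenario

    return dual_probe_scenario(20170105)


@pytest.fixture
def small_design():
    from macrospot.design import make_design

    return make_design(2, 2)
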