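import pytest

from drivestress import builtin_protocol


@pytest.fixture(scope="session")
def simulated_protocol():
    return builtin_protocol("simulated")


@pytest.fixture(scope="session")
def real_protocol():
    return builtin_protocol("real")


@pytest.fixture(scope="session")
def synthetic_session_dir(tmp_path_factory, simulated_protocol):
    """One small synthetic session (R-R + thermal frames) shared by tests."""
    from drivestress import default_hrv_scenario, write_session
    from drivestress.synthetic import ThermalScenario

    out = tmp_path_factory.mktemp("session")
    write_session(
        out,
        simulated_protocol,
        default_hrv_scenario(simulated_protocol, seed=11),
        ThermalScenario(seed=12, dropout_rate=0.05),
    )
    return out
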