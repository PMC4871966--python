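import pytest
from hypothesis import HealthCheck, settings

import tumordde as td

settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig2():
    return td.preset("fig2")


@pytest.fixture(scope="session")
def fig3():
    return td.preset("fig3")


@pytest.fixture(scope="session")
def fig4():
    return td.preset("fig4")


@pytest.fixture(scope="session")
def fig6():
    return td.preset("fig6")


@pytest.fixture(scope="session")
def fig2_traj(fig2):
    """The canonical constant-therapy run: gamma = 4, x0 = 2, dt = 0.01."""
    return td.integrate(fig2.params, fig2.schedule,
                        td.HistoryFunction.constant(2.0), 200.0, 0.01)


@pytest.fixture(scope="session")
def fig4_orbits(fig4):
    """Periodic orbit of the fig4 preset by both routes."""
    op = td.find_periodic_operator(fig4.schedule, fig4.params)
    pc = td.find_periodic_poincare(fig4.schedule, fig4.params,
                                   td.HistoryFunction.constant(2.0))
    return op, pc
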