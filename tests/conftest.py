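"""Shared simulation fixtures (session-scoped: runs are deterministic)."""

import pytest

from gitransit.synthetic import make_fixture
from gitransit.transit import Protocol, simulate


@pytest.fixture(scope="session")
def metoprolol_runs():
    """Metoprolol-like profiles at 50/100/200 rpm (pH 1.6, 10-min infusion)."""
    drug, form = make_fixture("metoprolol_like")
    return {
        rpm: simulate(drug, form, Protocol(initial_gastric_ph=1.6, infusion_min=10.0, paddle_rpm=rpm))
        for rpm in (50.0, 100.0, 200.0)
    }


@pytest.fixture(scope="session")
def dipyridamole_runs():
    """Dipyridamole-like profiles at 50/100/200 rpm (pH 1.6, 10-min infusion)."""
    drug, form = make_fixture("dipyridamole_like")
    return {
        rpm: simulate(drug, form, Protocol(initial_gastric_ph=1.6, infusion_min=10.0, paddle_rpm=rpm))
        for rpm in (50.0, 100.0, 200.0)
    }


@pytest.fixture(scope="session")
def naftopidil_runs():
    """Ordinary/OD naftopidil with the water-disintegration protocol."""
    drug, ordinary = make_fixture("naftopidil_ordinary")
    _, od = make_fixture("naftopidil_od")
    out = {}
    for rpm in (50.0, 100.0):
        proto = Protocol(
            initial_gastric_ph=1.6,
            infusion_min=10.0,
            paddle_rpm=rpm,
            water_disintegration=True,
        )
        out[rpm] = {
            "ordinary": simulate(drug, ordinary, proto),
            "od": simulate(drug, od, proto),
        }
    return out
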