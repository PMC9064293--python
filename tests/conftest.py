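"""Shared fixtures: measurement-scale constants used across the suite."""

import pytest

#: tension scale of gastrula tissue interfaces, N/m
GAMMA = 0.22e-3
#: plausible tissue-medium density difference, kg/m^3
DELTA_RHO = 50.0
G = 9.80665


@pytest.fixture(scope="session")
def paper_scale():
    return {"gamma": GAMMA, "delta_rho": DELTA_RHO, "g": G}
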