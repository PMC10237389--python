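"""Shared fixtures: expensive analyses are computed once per session."""

import numpy as np
import pytest

import nfkbid as nk


@pytest.fixture(scope="session")
def on_off():
    return nk.make_on_off()


@pytest.fixture(scope="session")
def raw_on_off(on_off):
    """Noise-free on–off measurements at the nominal (fitted) parameters."""
    return nk.simulate_measurements(nk.FITTED, on_off)


@pytest.fixture(scope="session")
def linear_report(on_off):
    """Linear identifiability analysis on the on–off protocol."""
    return nk.LinearAnalysis(nk.FITTED, on_off).run()


#: parameter overrides for the qualitative-regime variants
REGIME_VARIANTS = {
    "nominal": {},
    "limit_cycle": dict(a2=0.02, c5a=1e-5, i1a=1e-4),
    "relaxation": dict(a2=0.01, c5a=1e-5, i1a=1e-4),
    "a20_removed": dict(k2=0.0),
    "strong_feedbacks": dict(k2=3.57, i1a=0.01),
}


@pytest.fixture(scope="session")
def regimes():
    """Tonic-TNF classification of all regime variants (computed once)."""
    out = {}
    for name, overrides in REGIME_VARIANTS.items():
        params = nk.FITTED.with_updates(**overrides)
        out[name] = nk.classify_response(params, horizon_hours=48.0)
    return out


@pytest.fixture(scope="session")
def mc_result(on_off):
    """Scaled-down Monte Carlo identifiability run (k=20, 4 noise levels)."""
    return nk.run_monte_carlo(
        nk.FITTED, on_off, sigma_levels=(1.0, 1.1, 1.2, 1.3), k=20,
        base_seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
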