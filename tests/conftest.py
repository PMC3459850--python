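"""Shared fixtures: small parameter sets and reusable simulation runs.

The heavier emergent-behaviour tests share session-scoped simulation records
so each configuration is simulated once per test session.
"""

import pytest

import myxoripple as mx


@pytest.fixture()
def params_small():
    """Tiny population for fast geometric / stepping tests."""
    return mx.ModelParams(n_agents=60, domain_x=120.0, domain_y=60.0, seed=1)


@pytest.fixture()
def rng():
    return mx.RandomSource(12345)


@pytest.fixture(scope="session")
def small_run_params():
    """Reduced-domain parameters at the default (near-confluent) density,
    used for all emergent-behaviour tests to keep runtimes manageable."""
    return mx.ModelParams(domain_x=250.0, domain_y=50.0, n_agents=3000, seed=5)


@pytest.fixture(scope="session")
def ripple_record(small_run_params):
    """Rippling run (p0 = 0.10) with a 5% non-responsive tracer
    subpopulation, shared across emergent-behaviour tests."""
    return mx.run_simulation(small_run_params, duration=300.0, seed=11,
                             tracer_frac=0.05, n_tracked=400,
                             keep_final_state=False)
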