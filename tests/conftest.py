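"""Shared fixtures: synthetic trials and posterior fits reused across tests.

The expensive posterior fits are session-scoped; every test that needs a
converged fit shares the same one instead of re-sampling.
"""

from __future__ import annotations

import numpy as np
import pytest

import turfrsm


@pytest.fixture(scope="session")
def recovery_trial():
    """Half-length variant of the recovery-study design (30 monthly events)."""
    return turfrsm.simulate_trial(
        turfrsm.recovery_study_config(seed=20, n_months=30)
    )


@pytest.fixture(scope="session")
def recovery_fit(recovery_trial):
    """Full-protocol posterior fit (4 chains x 1000, 500 warmup, thin 2)."""
    t = recovery_trial
    return turfrsm.fit_rsm(
        t.observations, t.layout,
        chains=4, iterations=1000, warmup=500, thin=2, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_trial():
    """Very small trial for fast end-to-end plumbing tests."""
    cfg = turfrsm.recovery_study_config(
        seed=5, n_cultivars=4, n_reps=2, n_months=8, n_raters=2,
    )
    return turfrsm.simulate_trial(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
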