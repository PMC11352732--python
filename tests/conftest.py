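"""Shared fixtures: small phantoms, echo times, and a session-scoped
reduced-scale trained estimator used by the integration and acceptance tests
(training it once keeps the whole suite inside a sensible runtime)."""

from __future__ import annotations

import numpy as np
import pytest

from met2star import phantom, sddl

TE_MS = (14.0, 28.0, 42.0)
TR_S = 2.0


@pytest.fixture(scope="session")
def te_ms():
    return TE_MS


@pytest.fixture(scope="session")
def template64():
    return phantom.generate_template(64, 64, subject_seed=7)


@pytest.fixture(scope="session")
def small_bank():
    """Tiny bank for fast unit tests: 3 subjects x 4 slices."""
    return phantom.make_template_bank(3, 4, 64, 64, seed=11)


@pytest.fixture(scope="session")
def trained_estimator():
    """Reduced-scale trained estimator shared across the session.

    600 subject-disjoint training slices, 20 epochs — the study conditions of
    the noise-robustness comparison.  The reduced profile doubles the
    learning rate so optimization reaches its validation-loss plateau inside
    the epoch budget (the full-scale protocol trains at 1e-4 to the lowest
    validation loss).  Training takes several minutes on one CPU, so it runs
    once per session.
    """
    bank = phantom.make_template_bank(12, 60, 64, 64, seed=100)
    cfg = sddl.TrainingConfig(seed=100, max_epochs=20, learning_rate=2e-4)
    ds = sddl.make_training_pairs(bank, TE_MS, cfg)
    assert len(ds.train_x) == 600 and len(ds.val_x) == 120
    est = sddl.build_estimator(len(TE_MS), 2, base_width=16, te_ms=TE_MS,
                               init_seed=100)
    return sddl.train(est, ds, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
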