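"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from coadaptbci import (RetrainPolicy, SyntheticConfig, generate_session,
                        run_session)
from coadaptbci.retraining import SEMISUPERVISED, SUPERVISED


@pytest.fixture(scope="session")
def small_session():
    """A 30-TPC default-difficulty session: (recording, labels, config)."""
    cfg = SyntheticConfig(seed=11, n_tpc=30)
    rec, labels = generate_session(cfg)
    return rec, labels, cfg


@pytest.fixture(scope="session")
def sup_result_small(small_session):
    rec, _, _ = small_session
    return run_session(rec, RetrainPolicy(mode=SUPERVISED))


@pytest.fixture(scope="session")
def comparison_80():
    """Paired supervised/semi-supervised replay of one 80-TPC stream."""
    cfg = SyntheticConfig(seed=13, n_tpc=80)
    rec, labels = generate_session(cfg)
    sup = run_session(rec, RetrainPolicy(mode=SUPERVISED))
    semi = run_session(rec, RetrainPolicy(mode=SEMISUPERVISED))
    return rec, labels, sup, semi


@pytest.fixture
def rng():
    return np.random.default_rng(0)
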