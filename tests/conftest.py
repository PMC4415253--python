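"""Shared small-scale fixtures for the unit tests.

Acceptance tests build their own full-scale fixtures in
``tests/test_acceptance.py``.
"""

import numpy as np
import pytest

from embayesr.simulate import SimConfig, simulate_replicate


@pytest.fixture(scope="session")
def toy_replicate():
    """A small mixture-architecture replicate (fast, session-wide)."""
    cfg = SimConfig(
        n_individuals=600,
        n_markers=800,
        n_qtl=12,
        qtl_counts_per_component=(4, 4, 4),
        h2=0.45,
        seed=7,
    )
    return simulate_replicate(cfg)


@pytest.fixture(scope="session")
def toy_split(toy_replicate):
    rep = toy_replicate
    ref, val = rep.reference_idx, rep.validation_idx
    return dict(
        X_ref=rep.genotypes.dosages[ref],
        X_val=rep.genotypes.dosages[val],
        y_ref=rep.phenotypes[ref],
        tbv_val=rep.tbv[val],
        rep=rep,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
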