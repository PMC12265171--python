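"""Shared fixtures: small phantom layouts and cohorts, all generated at
test time (no stored data)."""

from __future__ import annotations

import numpy as np
import pytest

from deepsuvr.io import DESK_GRID
from deepsuvr.synthetic import SimConfig, make_cohort, make_layout


@pytest.fixture(scope="session")
def layout():
    return make_layout(DESK_GRID)


@pytest.fixture(scope="session")
def standard_masks(layout):
    return layout.standard_masks()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny unbiased cohort for plumbing tests (not for recovery runs)."""
    return make_cohort(SimConfig(n_participants=12, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
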