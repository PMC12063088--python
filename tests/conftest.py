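import numpy as np
import pandas as pd
import pytest

from npxspectrum.preprocess import assign_groups
from npxspectrum.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def make_cohort():
    """Factory for synthetic cohorts with overridable config fields."""

    def _make(**kwargs):
        defaults = dict(
            group_sizes={"HC": 20, "UC": 20, "CD_L1": 20, "CD_L2": 20, "CD_L3": 20},
            n_proteins=20,
            n_signal=5,
            effect_scale=0.8,
            residual_sd=0.5,
            seed=0,
        )
        defaults.update(kwargs)
        return generate_cohort(SyntheticConfig(**defaults))

    return _make


@pytest.fixture
def tiny_cohort(make_cohort):
    return make_cohort()


@pytest.fixture
def tiny_groups(tiny_cohort):
    _, meta, _ = tiny_cohort
    return assign_groups(meta)


@pytest.fixture
def continuum_cohort(make_cohort):
    """Three groups on a latent 0 / 0.5 / 1 continuum."""
    return make_cohort(
        group_sizes={"UC": 40, "CD_L2": 40, "CD_L1": 40},
        group_positions={"UC": 0.0, "CD_L2": 0.5, "CD_L1": 1.0},
        n_proteins=30,
        n_signal=8,
        effect_scale=1.2,
        residual_sd=0.8,
        seed=11,
    )
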