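"""Shared fixtures: one full-scale default simulation (session-scoped, the
study conditions), one small simulation for brute-force oracle checks, and a
derandomised hypothesis profile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ploidykit import PloidyModel, RunConfig, SimParams
from ploidykit.haplotypes import SamplingParams

settings.register_profile(
    "suite", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_model() -> PloidyModel:
    """The default study conditions: 12 x 100 kb triploid genome, 26x."""
    return PloidyModel.from_simulation(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_results(default_model):
    return default_model.fit()


@pytest.fixture(scope="session")
def small_model() -> PloidyModel:
    """A <=50 kb-per-contig instance for brute-force oracle comparisons."""
    cfg = RunConfig(
        sim=SimParams(n_contigs=2, contig_length=30_000,
                      orf_density_targets=((0.02, 3), (0.04, 3), (0.06, 3)),
                      organelle_length=6000, cnv_segments=[], seed=3),
        sampling=SamplingParams(n_per_class=2, seed=4),
    )
    return PloidyModel.from_simulation(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    """Fresh, constant-seeded generator per test: deterministic regardless
    of which subset of the suite runs."""
    return np.random.default_rng(20240917)
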