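"""Shared fixtures: seeded RNGs and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ktuplesvm.simulate import ReadSet, SeedSpec, SimulationConfig, generate_dataset

#: Master seed for every test that needs randomness.
MASTER_SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


def tiny_dataset(
    n_per_class: int = 4,
    genome_length: int = 600,
    seeds_class2: tuple[SeedSpec, ...] = (SeedSpec("ACGTAC", 0.05),),
    rng_seed: int = MASTER_SEED,
    coverage: float = 4.0,
) -> tuple[list[ReadSet], SimulationConfig]:
    """A small two-class dataset that runs in milliseconds."""
    config = SimulationConfig(
        n_per_class=n_per_class,
        genome_length=genome_length,
        seeds_class2=seeds_class2,
        read_length=50,
        coverage=coverage,
        rng_seed=rng_seed,
    )
    samples, _ = generate_dataset(config)
    return samples, config


@pytest.fixture
def small_samples():
    samples, _ = tiny_dataset()
    return samples


def noise_samples(
    n_per_class: int = 5, rng_seed: int = MASTER_SEED, genome_length: int = 400
) -> list[ReadSet]:
    """Signal-free dataset: both classes are pure background."""
    config = SimulationConfig(
        n_per_class=n_per_class,
        genome_length=genome_length,
        read_length=50,
        coverage=3.0,
        rng_seed=rng_seed,
    )
    samples, _ = generate_dataset(config)
    return samples
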