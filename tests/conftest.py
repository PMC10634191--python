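"""Shared fixtures: pools of simulated scenarios reused across suites."""

import random

import pytest

from edt.divergence import divergence_partition
from edt.simulate import random_scenario


def make_pool(specs, min_genes=5):
    """specs: iterable of kwargs for random_scenario; returns
    [(scenario, partition), ...].  n_genes is a budget, so seeds whose
    realized gene count falls short are resampled deterministically."""
    out = []
    for kw in specs:
        kw = dict(kw)
        for _ in range(200):
            s = random_scenario(**kw)
            if len(s.T.leaves) >= min(min_genes, kw["n_genes"]):
                break
            kw["seed"] += 1_000_000
        out.append((s, divergence_partition(s)))
    return out


def mixed_specs(n, seed0=0, genes=(5, 25), species=(3, 6), **fixed):
    """Deterministic mixed parameter grid for simulation pools."""
    rng = random.Random(987)
    specs = []
    for i in range(n):
        specs.append(
            dict(
                n_species=rng.randint(*species),
                n_genes=rng.randint(*genes),
                transfer_prob=rng.choice([0.0, 0.1, 0.25, 0.4]),
                dup_prob=rng.choice([0.05, 0.15, 0.3]),
                seed=seed0 + i,
                **fixed,
            )
        )
    return specs


@pytest.fixture(scope="session")
def pool():
    """Small mixed pool for per-module property tests."""
    return make_pool(mixed_specs(80, seed0=10_000))


@pytest.fixture(scope="session")
def pool_hgt_free():
    return make_pool(mixed_specs(60, seed0=20_000, hgt_free=True))


@pytest.fixture(scope="session")
def pool_binary():
    return make_pool(mixed_specs(60, seed0=30_000, binary_only=True))


@pytest.fixture(scope="session")
def big_pool():
    """The >= 500-scenario mixed pool of the acceptance criteria."""
    return make_pool(mixed_specs(500, seed0=1))
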