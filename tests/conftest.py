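"""Shared fixtures: small synthetic study conditions reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import paxkit as pk

# Derandomized hypothesis runs so the suite is reproducible everywhere.
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> pk.SimulationConfig:
    return pk.SimulationConfig(
        n_proteins=120,
        length_mean=200.0,
        length_sd=60.0,
        network_density=0.03,
        edge_consistency=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_proteome(small_cfg):
    return pk.make_proteome(small_cfg)


@pytest.fixture(scope="session")
def small_abundances(small_cfg, small_proteome):
    return pk.make_abundances(small_cfg, small_proteome)


@pytest.fixture(scope="session")
def small_network(small_cfg, small_abundances):
    return pk.make_network(small_cfg, small_abundances)


def noisy_replicate(ds: pk.AbundanceDataset, sd: float, seed: int,
                    name: str) -> pk.AbundanceDataset:
    """A replicate of a dataset with multiplicative log-normal noise."""
    rng = np.random.default_rng(seed)
    raw = {k: v * 10 ** rng.normal(0.0, sd) for k, v in ds.abundances.items()}
    out = pk.to_ppm(raw, organism=ds.organism, tissue=ds.tissue,
                    method=f"replicate sd={sd}", name=name)
    return out


@pytest.fixture(scope="session")
def dataset_trio(small_abundances):
    """Three replicates of one truth at distinct noise levels."""
    return [
        noisy_replicate(small_abundances, 0.10, 101, "good"),
        noisy_replicate(small_abundances, 0.80, 102, "noisy"),
        noisy_replicate(small_abundances, 0.30, 103, "medium"),
    ]
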