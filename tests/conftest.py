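"""Shared fixtures: one full-scale simulated dataset and its consensus
network, built once per session, plus a fast small-scale configuration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hybcoex import network as nw
from hybcoex import preprocess as pp
from hybcoex.io_core import NetworkParams
from hybcoex.synthetic import ClassSizes, SimulationConfig, simulate_dataset


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Six planted modules, ~700 probes; fast enough for per-test simulation."""
    defaults = dict(
        n_modules=6,
        module_sizes=(90, 80, 70, 60, 55, 50),
        n_background_genes=200,
        class_sizes={
            "F2": ClassSizes(60, 20, 25, 15),
            "HZ": ClassSizes(50, 15, 20, 10),
        },
        n_pure_per_subspecies=12,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def truth_assignment(data, probe_ids) -> pd.Series:
    """Planted module labels (truth module m -> label m+1, background -> 0)."""
    mod = data.truth.module_of_gene.reindex(
        data.truth.probe_to_gene.reindex(probe_ids)
    ).fillna(-1)
    return pd.Series((mod + 1).astype(int).to_numpy(), index=probe_ids)


def primary_probes(matrix) -> list[str]:
    """One probe per gene (drops duplicate probes and negative controls)."""
    return [p for p in matrix.probe_ids if p.endswith("_1")]


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_sim_config(seed=5))


@pytest.fixture(scope="session")
def consensus_setup(default_dataset):
    """Batch-adjusted default dataset with its fitted consensus network."""
    data = default_dataset
    cls = data.truth.class_of_sample
    combined = data.combined("log2")
    batches = pd.Series(
        data.samples["batch"].to_numpy(), index=data.samples["sample_id"]
    )
    adjusted = pp.eb_batch_adjust(combined, batches)
    fertile = {
        pop: [s for s in data.log2[pop].sample_ids if cls[s] == "fertile"]
        for pop in ("F2", "HZ")
    }
    pooled = adjusted.subset_samples(fertile["F2"] + fertile["HZ"])
    kept = nw.connectivity_filter(pooled, beta=5)
    net = nw.build_consensus_network(
        {pop: adjusted.subset_probes(kept).subset_samples(ids)
         for pop, ids in fertile.items()},
        NetworkParams(),
    )
    return {"data": data, "adjusted": adjusted, "fertile": fertile, "net": net}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
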