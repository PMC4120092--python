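"""Shared fixtures: simulated references and a full pipeline workspace.

Everything is generated at test time from fixed seeds; no stored data."""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ribocage.config import PipelineConfig
from ribocage.pipeline import run
from ribocage.simulate import (SimConfig, LibraryMeta, default_library_design,
                               generate_reference, simulate_libraries)


@pytest.fixture(scope="session")
def reference():
    """Default-condition reference (60 genes, decoys planted), seed 7."""
    return generate_reference(SimConfig(seed=7))


@pytest.fixture(scope="session")
def libraries(reference):
    """Simulated aligned pairs (with PCR duplicates) for every library."""
    return simulate_libraries(reference)


@pytest.fixture(scope="session")
def mini_config():
    """Small, fast configuration for unit-level tests."""
    return SimConfig(
        chrom_lengths={"chr1": 360_000, "chr2": 260_000},
        n_genes=18,
        class_fractions={"pc_enriched": 4 / 18, "glia": 3 / 18,
                         "other_neuron": 4 / 18, "background": 7 / 18},
        n_dendritic=4,
        library_design=default_library_design(target_pairs=3000),
        seed=11,
    )


@pytest.fixture(scope="session")
def mini_reference(mini_config):
    return generate_reference(mini_config)


@pytest.fixture(scope="session")
def mini_libraries(mini_reference):
    return simulate_libraries(mini_reference)


@pytest.fixture(scope="session")
def workspace(tmp_path_factory):
    """Complete pipeline run ('all') on the default fixture, seed 7."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(outdir=str(outdir))
    cfg.params["seed"] = 7
    run("all", cfg)
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
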