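"""Shared fixtures: a small end-to-end simulated study used across modules."""

from types import SimpleNamespace

import pytest

from dgetags import (
    build_reference_index,
    process_library,
    simulate_expression,
    simulate_reads,
    simulate_reference,
)
from dgetags.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def small_sim():
    """A three-library simulated study at desk-test scale (parents + F1)."""
    cfg = SimulationConfig(seed=42, n_genes=150, depth=30_000)
    ref = simulate_reference(cfg)
    truth = simulate_expression(cfg, ref)
    reads = simulate_reads(truth, ref, cfg, libraries=["Br", "Bo", "F1"])
    index = build_reference_index(ref.genes, ref.genome)
    results = {
        lib: process_library(reads[lib], lib, index, adaptors=[cfg.adaptor])
        for lib in reads
    }
    return SimpleNamespace(
        cfg=cfg, ref=ref, truth=truth, reads=reads, index=index, results=results
    )
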