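"""Shared fixtures: small synthetic worlds built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bacmap.assembly import (
    AssemblyParams,
    assemble_contigs,
    build_overlap_graph,
    detect_questionable,
)
from bacmap.synthetic import (
    SimulationConfig,
    simulate_chromosome,
    simulate_clone_library,
    simulate_fingerprints,
)


SMALL = dict(arm_length_kb=3000.0, n_genes=40, n_clones=400)


@pytest.fixture(scope="session")
def small_clean_world():
    """Noise-free, pure library over a 3 Mb arm: 400 clones, ~14x coverage."""
    cfg = SimulationConfig(
        **SMALL, seed=2, band_noise_sd=0.0, band_dropout=0.0,
        purity=1.0, contamination_rate=0.0,
    )
    chrom = simulate_chromosome(cfg)
    library = simulate_clone_library(chrom, cfg)
    fps = simulate_fingerprints(library, chrom, cfg)
    graph = build_overlap_graph(fps, insert_mean_kb=cfg.insert_mean_kb)
    detect_questionable(graph)
    contigs = assemble_contigs(graph)
    return dict(cfg=cfg, chrom=chrom, library=library, fps=fps,
                graph=graph, contigs=contigs)


@pytest.fixture(scope="session")
def small_noisy_world():
    """Default-noise library with decoys and chimeras over a 3 Mb arm."""
    cfg = SimulationConfig(**SMALL, seed=3)
    chrom = simulate_chromosome(cfg)
    library = simulate_clone_library(chrom, cfg)
    fps = simulate_fingerprints(library, chrom, cfg)
    graph = build_overlap_graph(fps, insert_mean_kb=cfg.insert_mean_kb)
    detect_questionable(graph)
    contigs = assemble_contigs(graph)
    return dict(cfg=cfg, chrom=chrom, library=library, fps=fps,
                graph=graph, contigs=contigs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
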