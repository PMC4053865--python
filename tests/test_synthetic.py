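"""The synthetic-chromosome generator: gradients, library, fingerprints,
references and pool signals, validated against their own ground truth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.stats import chisquare, linregress

from bacmap.pools import build_pool_design, deconvolve_pools
from bacmap.synthetic import (
    PoolNoise,
    SimulationConfig,
    genes_to_clones,
    simulate_chromosome,
    simulate_clone_library,
    simulate_fingerprints,
    simulate_pool_signals,
    simulate_references,
)

TINY = dict(arm_length_kb=3000.0, n_genes=40, n_clones=400)


class TestConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(purity=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(insert_mean_kb=90.0)  # outside 100-200 window
        with pytest.raises(ValueError):
            SimulationConfig(density_ratio_tel_cen=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(purity=0.99, contamination_rate=0.05)


class TestChromosome:
    def test_no_genes_still_has_sites(self):
        cfg = SimulationConfig(**{**TINY, "n_genes": 0})
        ch = simulate_chromosome(cfg)
        assert ch.genes == []
        assert ch.site_maps["HindIII"].size > 0

    def test_degenerate_island_config(self):
        with pytest.raises(ValueError, match="island"):
            simulate_chromosome(
                SimulationConfig(**{**TINY, "n_genes": 1}, island_fraction=1.0)
            )

    def test_seed_determinism(self):
        cfg = SimulationConfig(**TINY, seed=9)
        a, b = simulate_chromosome(cfg), simulate_chromosome(cfg)
        assert np.array_equal(a.site_maps["HindIII"], b.site_maps["HindIII"])
        assert [g.position_kb for g in a.genes] == [g.position_kb for g in b.genes]

    def test_gene_gradient_fifth_ratio(self):
        """Mean telomeric/centromeric fifth gene-count ratio ~ 2.36."""
        ratios = []
        for seed in range(200):
            ch = simulate_chromosome(SimulationConfig(seed=seed))
            pos = ch.gene_positions
            L = ch.arm_length_kb
            ratios.append(np.sum(pos >= 0.8 * L) / max(np.sum(pos < 0.2 * L), 1))
        assert np.mean(ratios) == pytest.approx(2.36, rel=0.15)

    def test_gradient_recovery_regression(self):
        """Windowed gene counts regress positively on position."""
        counts = np.zeros(20)
        for seed in range(100):
            ch = simulate_chromosome(SimulationConfig(**TINY, seed=seed))
            h, _ = np.histogram(ch.gene_positions, bins=20, range=(0, 3000))
            counts += h
        res = linregress(np.arange(20), counts)
        assert res.slope > 0
        assert res.pvalue < 0.01

    def test_flat_rate_uniformity(self):
        """With equal end rates, windowed site counts pass a chi-square
        uniformity test at alpha=0.01 in at least 95% of seeds."""
        passed = 0
        for seed in range(100):
            cfg = SimulationConfig(
                **TINY, seed=seed, hindiii_rate_cen=50.0, hindiii_rate_tel=50.0
            )
            sites = simulate_chromosome(cfg).site_maps["HindIII"]
            h, _ = np.histogram(sites, bins=15, range=(0, 3000))
            if chisquare(h).pvalue > 0.01:
                passed += 1
        assert passed >= 95

    def test_island_members_close(self):
        ch = simulate_chromosome(SimulationConfig(seed=4))
        by_island: dict[int, list[float]] = {}
        for g in ch.genes:
            if g.island_id is not None:
                by_island.setdefault(g.island_id, []).append(g.position_kb)
        assert by_island
        sizes = {len(v) for v in by_island.values()}
        assert sizes <= {2, 3}
        for pos in by_island.values():
            assert max(pos) - min(pos) <= 113.0

    def test_bin_bounds(self):
        ch = simulate_chromosome(SimulationConfig(**TINY))
        b = ch.bin_bounds
        assert b[0] == 0.0 and b[-1] == 1.0
        assert np.all(np.diff(b) > 0)


class TestCloneLibrary:
    def test_pure_library_ends_on_sites(self):
        cfg = SimulationConfig(
            **TINY, seed=5, purity=1.0, contamination_rate=0.0
        )
        ch = simulate_chromosome(cfg)
        lib = simulate_clone_library(ch, cfg)
        sites = set(np.round(ch.site_maps["HindIII"], 6))
        assert all(c.source == "target" for c in lib.clones)
        for c in lib.clones[:50]:
            assert round(c.start_kb, 6) in sites
            assert round(c.end_kb, 6) in sites

    def test_insert_size_and_coverage(self):
        """Mean insert 113 +/- 5 kb; coverage ~ 14.4 arm equivalents."""
        cfg = SimulationConfig(seed=6)
        ch = simulate_chromosome(cfg)
        lib = simulate_clone_library(ch, cfg)
        lengths = [c.end_kb - c.start_kb for c in lib.clones if c.source == "target"]
        assert np.mean(lengths) == pytest.approx(113.0, abs=5.0)
        equivalents = (
            len(lib) * np.mean(lengths) * cfg.purity / cfg.arm_length_kb
        )
        assert equivalents == pytest.approx(14.4, rel=0.05)

    def test_source_fractions(self):
        cfg = SimulationConfig(**TINY, seed=7)
        lib = simulate_clone_library(simulate_chromosome(cfg), cfg)
        frac_target = np.mean([c.source == "target" for c in lib.clones])
        assert frac_target == pytest.approx(cfg.purity, abs=0.01)

    def test_unique_plate_addresses(self):
        cfg = SimulationConfig(**TINY, seed=7)
        lib = simulate_clone_library(simulate_chromosome(cfg), cfg)
        addrs = {(c.plate, c.row, c.column) for c in lib.clones}
        assert len(addrs) == len(lib)

    def test_chimera_halves_far_apart(self):
        cfg = SimulationConfig(**TINY, seed=8, contamination_rate=0.05)
        lib = simulate_clone_library(simulate_chromosome(cfg), cfg)
        chims = [c for c in lib.clones if c.source == "chimera"]
        assert chims
        for c in chims:
            assert abs(c.start2_kb - c.start_kb) > 10 * cfg.insert_mean_kb

    def test_impossible_insert_window(self):
        cfg = SimulationConfig(
            **{**TINY, "n_clones": 10},
            insert_mean_kb=199.5,
            insert_range_kb=(199.0, 200.0),
            hindiii_rate_cen=0.2,
            hindiii_rate_tel=0.2,
            seed=1,
        )
        ch = simulate_chromosome(cfg)
        with pytest.raises(ValueError, match="insert"):
            simulate_clone_library(ch, cfg)


class TestFingerprints:
    def test_identical_intervals_identical_bands(self):
        cfg = SimulationConfig(
            **TINY, seed=9, band_noise_sd=0.0, band_dropout=0.0,
            purity=1.0, contamination_rate=0.0,
        )
        ch = simulate_chromosome(cfg)
        lib = simulate_clone_library(ch, cfg)
        c0 = lib.clones[0]
        twin = dataclasses.replace(c0, clone_id="twin")
        lib.clones.append(twin)
        fps = simulate_fingerprints(lib, ch, cfg)
        assert np.array_equal(fps[c0.clone_id].bands, fps["twin"].bands)

    def test_band_count_gradient(self):
        """Centromeric-fifth clones carry more bands than telomeric-fifth."""
        diffs = []
        for seed in range(20):
            cfg = SimulationConfig(
                **TINY, seed=seed, purity=1.0, contamination_rate=0.0
            )
            ch = simulate_chromosome(cfg)
            lib = simulate_clone_library(ch, cfg)
            fps = simulate_fingerprints(lib, ch, cfg)
            cen, tel = [], []
            for c in lib.clones:
                mid = 0.5 * (c.start_kb + c.end_kb)
                if mid < 0.2 * cfg.arm_length_kb:
                    cen.append(len(fps[c.clone_id]))
                elif mid >= 0.8 * cfg.arm_length_kb:
                    tel.append(len(fps[c.clone_id]))
            diffs.append(np.mean(cen) - np.mean(tel))
        assert np.mean(diffs) > 0
        assert np.mean([d > 0 for d in diffs]) >= 0.9

    def test_dropout_thinning(self):
        """5% dropout thins band counts to 95% +/- 1% of the noiseless set."""
        base = dict(**TINY, purity=1.0, contamination_rate=0.0, seed=10)
        cfg0 = SimulationConfig(**base, band_noise_sd=0.0, band_dropout=0.0)
        cfg1 = SimulationConfig(**base, band_noise_sd=0.0, band_dropout=0.05)
        ch = simulate_chromosome(cfg0)
        lib = simulate_clone_library(ch, cfg0)
        fp0 = simulate_fingerprints(lib, ch, cfg0)
        fp1 = simulate_fingerprints(lib, ch, cfg1)
        ratio = sum(len(fp1[c]) for c in fp1) / sum(len(fp0[c]) for c in fp0)
        assert ratio == pytest.approx(0.95, abs=0.01)


class TestReferences:
    def test_identity_when_fully_syntenic(self):
        cfg = SimulationConfig(
            **TINY, seed=11,
            non_syntenic_cen=0.0, non_syntenic_tel=0.0,
            syntenic_retention=(1.0, 1.0, 1.0), inversion_fraction=0.0,
        )
        ch = simulate_chromosome(cfg)
        refs = simulate_references(ch, cfg)
        truth = [g.gene_id for g in sorted(ch.genes, key=lambda g: g.position_kb)]
        for r, order in refs.orders.items():
            assert [g for g, _ in order] == truth
            assert all(v == "syntenic" for v in refs.homology[r].values())

    def test_non_syntenic_gradient(self):
        """Per-bin combined non-syntenic fraction rises centromere->telomere,
        spanning about 0.42 -> 0.58 in expectation."""
        per_bin = np.zeros(5)
        counts = np.zeros(5)
        for seed in range(8):
            cfg = SimulationConfig(seed=seed)
            ch = simulate_chromosome(cfg)
            refs = simulate_references(ch, cfg)
            b = ch.bin_bounds
            edges = np.array([b[0], b[1], b[2], b[3], b[5], b[6]]) * cfg.arm_length_kb
            for g in ch.genes:
                k = min(np.searchsorted(edges, g.position_kb, "right") - 1, 4)
                counts[k] += 1
                if all(
                    refs.homology[r][g.gene_id] != "syntenic"
                    for r in refs.orders
                ):
                    per_bin[k] += 1
        frac = per_bin / counts
        assert np.all(np.diff(frac) > -0.02)  # monotone up to sampling noise
        assert frac[0] == pytest.approx(0.42, abs=0.05)
        assert frac[-1] == pytest.approx(0.58, abs=0.05)

    def test_inversion_too_large(self):
        cfg = SimulationConfig(
            **{**TINY, "n_genes": 6}, seed=12, inversion_fraction=5.0,
            island_fraction=0.0,
        )
        ch = simulate_chromosome(cfg)
        with pytest.raises(ValueError, match="inversion"):
            simulate_references(ch, cfg)


class TestPoolSignals:
    def _world(self, noise, seed=13, n_probes=None):
        cfg = SimulationConfig(**TINY, seed=seed)
        ch = simulate_chromosome(cfg)
        lib = simulate_clone_library(ch, cfg)
        target = sorted(
            (c for c in lib.clones if c.source == "target"),
            key=lambda c: c.start_kb,
        )
        mtp = [c.clone_id for c in target[::10]]
        g2c = genes_to_clones(ch, lib, mtp)
        sig, design = simulate_pool_signals(lib, mtp, g2c, noise, cfg)
        return cfg, lib, mtp, g2c, sig, design

    def test_single_clone_gene_three_pools(self):
        # tight intensity spread makes threshold crossing deterministic, so
        # the design identity (one clone -> exactly its 3 pools) is exact
        noise = PoolNoise(
            false_positive=0.0, false_negative=0.0,
            background_sd=0.05, signal_sd=0.05,
        )
        cfg, lib, mtp, g2c, sig, design = self._world(noise)
        thresh = 0.5 * (noise.background_mean + noise.signal_mean)
        pos = np.asarray(sig.intensities) >= thresh
        for j, probe in enumerate(sig.probe_ids):
            if len(g2c[probe]) == 1:
                assert pos[:, j].sum() == 3
            elif len(g2c[probe]) == 0:
                assert pos[:, j].sum() == 0

    def test_two_clone_gene_resolvable(self):
        noise = PoolNoise(
            false_positive=0.0, false_negative=0.0,
            background_sd=0.05, signal_sd=0.05,
        )
        cfg, lib, mtp, g2c, sig, design = self._world(noise)
        two = [p for p in sig.probe_ids if len(g2c[p]) == 2]
        assert two
        calls = {c.probe_id: c for c in deconvolve_pools(sig, design, mtp)}
        by_id = lib.by_id()
        for p in two:
            call = calls[p]
            assert call.n_positive_pools >= 4
            a, b = (by_id[c] for c in g2c[p])
            if a.plate == b.plate:
                assert call.n_positive_pools <= 5
            # when resolvable, resolved clones are the true ones
            if call.status != "unresolved":
                assert set(call.clone_ids) <= set(g2c[p])

    def test_missing_address_rejected(self):
        cfg = SimulationConfig(**TINY, seed=14)
        ch = simulate_chromosome(cfg)
        lib = simulate_clone_library(ch, cfg)
        with pytest.raises(ValueError, match="address"):
            simulate_pool_signals(lib, ["nope"], {}, PoolNoise(), cfg)
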