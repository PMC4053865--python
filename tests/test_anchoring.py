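"""Zipper construction, marker anchoring, colinearity breaks and scaling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bacmap.anchoring import (
    DeletionBin,
    DeletionBinSet,
    Marker,
    ScalingInput,
    anchor_map,
    bins_from_truth,
    build_zipper,
    detect_colinearity_breaks,
    markers_from_truth,
    per_bin_expansion,
    scale_expansion,
    scaffolds_from_contigs,
)
from bacmap.assembly import Contig
from bacmap.scaffolding import Scaffold
from bacmap.synthetic import (
    ReferenceSet,
    SimulationConfig,
    simulate_chromosome,
    simulate_references,
)


def make_refs(order, moved=(), absent=(), primary_missing=()):
    """Three references over the same gene order with controlled labels."""
    orders, homology = {}, {}
    for r in ("refA", "refB", "refC"):
        homology[r] = {}
        entries = []
        for i, g in enumerate(order):
            if g in absent:
                homology[r][g] = "absent"
                continue
            if r == "refA" and g in primary_missing:
                homology[r][g] = "absent"
                continue
            if g in moved:
                homology[r][g] = "non_syntenic"
                entries.append((g, 1000.0 + i))
            else:
                homology[r][g] = "syntenic"
                entries.append((g, float(i)))
        orders[r] = sorted(entries, key=lambda t: t[1])
    return ReferenceSet(orders, homology, {r: [] for r in orders}, "refA")


class TestZipper:
    def test_identity_without_zipins(self):
        refs = make_refs([f"g{i}" for i in range(10)])
        z = build_zipper(refs)
        assert z.gene_ids() == [f"g{i}" for i in range(10)]
        assert not any(e.zipped_in for e in z.entries)

    def test_zip_in_rule(self):
        """All and only genes syntenic in both other references but missing
        from the primary are zipped in."""
        order = [f"g{i}" for i in range(12)]
        refs = make_refs(order, primary_missing={"g4", "g7"})
        z = build_zipper(refs)
        assert set(z.gene_ids()) == set(order)
        zipped = {e.gene_id for e in z.entries if e.zipped_in}
        assert zipped == {"g4", "g7"}
        # zipped-in genes land at their interpolated rank
        assert z.gene_ids() == order

    def test_inversion_reversal(self):
        order = [f"g{i:02d}" for i in range(30)]
        refs = make_refs(order)
        z = build_zipper(refs, inversion_interval=("g10", "g20"))
        ids = z.gene_ids()
        assert ids[:10] == order[:10]
        assert ids[10:21] == order[10:21][::-1]
        assert ids[21:] == order[21:]
        assert [e.zipper_index for e in z.entries] == list(range(30))

    def test_missing_inversion_endpoint(self):
        refs = make_refs(["a", "b", "c"])
        with pytest.raises(ValueError, match="absent"):
            build_zipper(refs, inversion_interval=("a", "zz"))


def toy_anchored_world(zipper_indices_per_scaffold):
    """Scaffolds with markers hitting given zipper indices, over a toy
    zipper of 100 genes in 5 equal bins."""
    order = [f"g{i:03d}" for i in range(100)]
    refs = make_refs(order)
    zipper = build_zipper(refs)
    bins = DeletionBinSet(
        [
            DeletionBin(f"bin_{n}", n, k / 5, (k + 1) / 5, 20 * k, 20 * k + 19)
            for k, n in enumerate(["I", "II", "III", "IV", "V"])
        ],
        {i: ["I", "II", "III", "IV", "V"][min(i // 20, 4)] for i in range(100)},
    )
    contigs, scaffolds, markers = [], [], []
    for s_i, zis in enumerate(zipper_indices_per_scaffold):
        clones = [f"s{s_i}c{k}" for k in range(len(zis))]
        ctg = Contig(f"ctg{s_i}", clones,
                     est_start_kb=[50.0 * k for k in range(len(zis))])
        ctg._last_clone_kb = 100.0
        contigs.append(ctg)
        scaffolds.append(Scaffold(f"scf{s_i}", [(ctg.contig_id, "+")], [], 1000.0))
        for k, zi in enumerate(zis):
            markers.append(
                Marker(f"m{s_i}_{k}", "UniGene", [clones[k]], ctg.contig_id,
                       f"g{zi:03d}", bins.bin_of_zipper_index[zi])
            )
    return zipper, bins, contigs, scaffolds, markers


class TestAnchorMap:
    def test_simple_forward_anchor(self):
        zipper, bins, contigs, scaffolds, markers = toy_anchored_world([[5, 7, 9]])
        amap = anchor_map(scaffolds, markers, zipper, bins, contigs, 10_000.0)
        row = amap.scaffold_table.iloc[0]
        assert row["status"] == "anchored"
        assert row["median_zipper"] == 7
        assert row["orientation"] == "+"
        assert row["bin"] == "I"

    def test_scaffold_order_follows_zipper(self):
        zipper, bins, contigs, scaffolds, markers = toy_anchored_world(
            [[60, 65, 70], [5, 9, 13], [30, 35, 40]]
        )
        amap = anchor_map(scaffolds, markers, zipper, bins, contigs, 10_000.0)
        t = amap.scaffold_table.sort_values("order_index")
        assert t["scaffold_id"].tolist() == ["scf1", "scf2", "scf0"]

    def test_reverse_orientation(self):
        zipper, bins, contigs, scaffolds, markers = toy_anchored_world(
            [[90, 85, 80]]
        )
        amap = anchor_map(scaffolds, markers, zipper, bins, contigs, 10_000.0)
        assert amap.scaffold_table.iloc[0]["orientation"] == "-"

    def test_conflicting_marker_excluded(self):
        zipper, bins, contigs, scaffolds, markers = toy_anchored_world(
            [[5, 7, 9], [50, 55, 60]]
        )
        markers.append(
            Marker("mx", "UniGene", ["s0c0", "s1c0"], None, "g020", "II")
        )
        amap = anchor_map(scaffolds, markers, zipper, bins, contigs, 10_000.0)
        assert any("mx" in c for c in amap.conflicts)
        assert "mx" not in set(amap.marker_table["marker_id"])

    def test_global_zipper_reversal_flips_anchoring(self):
        """Reversing the zipper reverses scaffold order and flips strands."""
        spec = [[5, 7, 9], [50, 55, 60], [80, 85, 90]]
        zipper, bins, contigs, scaffolds, markers = toy_anchored_world(spec)
        amap1 = anchor_map(scaffolds, markers, zipper, bins, contigs)
        # reverse the zipper (and the bin map accordingly)
        n = len(zipper.entries)
        for e in zipper.entries:
            e.zipper_index = n - 1 - e.zipper_index
        zipper.entries.reverse()
        bins.bin_of_zipper_index = {
            n - 1 - i: b for i, b in bins.bin_of_zipper_index.items()
        }
        amap2 = anchor_map(scaffolds, markers, zipper, bins, contigs)
        o1 = amap1.scaffold_table.sort_values("order_index")["scaffold_id"]
        o2 = amap2.scaffold_table.sort_values("order_index")["scaffold_id"]
        assert o1.tolist() == o2.tolist()[::-1]
        flip = {"+": "-", "-": "+"}
        s1 = amap1.scaffold_table.set_index("scaffold_id")["orientation"]
        s2 = amap2.scaffold_table.set_index("scaffold_id")["orientation"]
        for sid in s1.index:
            assert s2[sid] == flip[s1[sid]]


def break_oracle(query, positions, min_run):
    """Exhaustive oracle for one fully-informative reference: maximal runs
    of adjacent discordant steps (against the majority direction), reported
    when they span >= min_run genes."""
    vals = [positions[g] for g in query]
    import itertools

    n_up = sum(b > a for a, b in zip(vals, vals[1:]))
    sign = 1 if n_up * 2 >= len(vals) - 1 else -1
    disc = [1 if (b - a) * sign < 0 else 0 for a, b in zip(vals, vals[1:])]
    runs = []
    for key, grp in itertools.groupby(range(len(disc)), key=lambda i: disc[i]):
        grp = list(grp)
        if key and len(grp) + 1 >= min_run:
            runs.append((query[grp[0]], query[grp[-1] + 1]))
    return runs


class TestColinearityBreaks:
    def test_colinear_is_empty(self):
        order = [f"g{i}" for i in range(20)]
        refs = make_refs(order)
        res = detect_colinearity_breaks(order, refs)
        assert res["breaks"] == [] and res["single_ref"] == []

    def test_single_relocated_gene_is_singleton(self):
        order = [f"g{i:02d}" for i in range(20)]
        refs = make_refs(order)
        # relocate one gene in every reference
        for r in refs.orders:
            entries = dict(refs.orders[r])
            entries["g10"] = 35.0  # far downstream
            refs.orders[r] = sorted(entries.items(), key=lambda t: t[1])
        res = detect_colinearity_breaks(order, refs)
        assert res["breaks"] == []
        assert "g10" in res["singletons"]

    def test_planted_inversion_recovered_exactly(self):
        cfg = SimulationConfig(seed=11, shared_inversion=True)
        ch = simulate_chromosome(cfg)
        refs = simulate_references(ch, cfg)
        order = [g.gene_id for g in sorted(ch.genes, key=lambda g: g.position_kb)]
        res = detect_colinearity_breaks(order, refs)
        assert len(res["breaks"]) == 1
        g1, g2 = refs.query_inversion
        lo, hi = order.index(g1), order.index(g2)
        detectable = [
            g for g in order[lo : hi + 1]
            if sum(refs.homology[r].get(g) == "syntenic" for r in refs.orders) >= 2
        ]
        brk = res["breaks"][0]
        assert (brk.start_gene, brk.end_gene) == (detectable[0], detectable[-1])

    def test_primary_only_inversion_is_single_ref_class(self):
        cfg = SimulationConfig(seed=11)
        ch = simulate_chromosome(cfg)
        refs = simulate_references(ch, cfg)
        order = [g.gene_id for g in sorted(ch.genes, key=lambda g: g.position_kb)]
        res = detect_colinearity_breaks(order, refs)
        assert res["breaks"] == []
        assert len(res["single_ref"]) == 1
        assert res["single_ref"][0].refs == ["refA"]

    def test_matches_exhaustive_oracle(self, rng):
        """Detection equals the brute-force run oracle on random shuffled
        blocks over fully-informative references."""
        for trial in range(30):
            n = int(rng.integers(8, 30))
            order = [f"g{i:02d}" for i in range(n)]
            vals = list(range(n))
            # reverse a random block
            i = int(rng.integers(0, n - 3))
            j = int(rng.integers(i + 2, min(i + 8, n)))
            vals[i : j + 1] = vals[i : j + 1][::-1]
            positions = dict(zip(order, map(float, vals)))
            orders = {
                r: sorted(positions.items(), key=lambda t: t[1])
                for r in ("refA", "refB", "refC")
            }
            homology = {
                r: {g: "syntenic" for g in order}
                for r in ("refA", "refB", "refC")
            }
            refs = ReferenceSet(homology=homology, orders=orders,
                                inversion_intervals={}, primary="refA")
            res = detect_colinearity_breaks(order, refs, min_run=3, min_refs=2)
            want = break_oracle(order, positions, min_run=3)
            got = [(b.start_gene, b.end_gene) for b in res["breaks"]]
            assert got == want


class TestScaling:
    def test_zero_segment(self):
        s = ScalingInput(0.774, 314_000.0, 10_000.0, 0.0)
        assert scale_expansion(s) == 0.0

    def test_printed_formula(self):
        """1/0.774 x (314 Mb / 10 Mb) x 1 Mb ~ 40.6 Mb."""
        s = ScalingInput(0.774, 314_000.0, 10_000.0, 1_000.0)
        assert scale_expansion(s) == pytest.approx(40_568.0, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ScalingInput(0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ScalingInput(0.5, -1.0, 1.0, 1.0)

    def test_per_bin_expansion_recovers_gradient(self):
        """With a 2x telomere/centromere expansion gradient in the generator,
        per-bin wheat/reference ratios recover the 2x contrast within 20%."""
        # no planted inversion: it would scramble homolog positions across
        # the bin IV/V boundary and confound the span-based estimate
        cfg = SimulationConfig(seed=19, inversion_fraction=0.0)
        ch = simulate_chromosome(cfg)
        refs = simulate_references(ch, cfg)
        zipper = build_zipper(refs)
        bins = bins_from_truth(ch, zipper)
        # truth anchored map: one scaffold per bin with the bin's true length
        edges = np.array([0, 0.33, 0.55, 0.66, 0.83, 1.0]) * cfg.arm_length_kb
        rows = []
        for k, name in enumerate(["I", "II", "III", "IV", "V"]):
            rows.append({"scaffold_id": f"s{k}", "bin": name,
                         "length_kb": edges[k + 1] - edges[k],
                         "status": "anchored"})
        amap = type("A", (), {"scaffold_table": pd.DataFrame(rows)})()
        exp = per_bin_expansion(amap, bins, zipper, "refA")
        assert set(exp) == {"I", "II", "III", "IV", "V"}
        ratio = exp["V"] / exp["I"]
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestMarkersAndBins:
    def test_markers_from_truth(self):
        zipper, bins, contigs, scaffolds, _ = toy_anchored_world([[5, 7]])
        g2c = {"g005": ["s0c0"], "g007": ["s0c1"], "gx": []}
        contig_of = {"s0c0": "ctg0", "s0c1": "ctg0"}
        markers = markers_from_truth(g2c, contig_of, zipper, bins)
        by_id = {m.marker_id: m for m in markers}
        assert by_id["m_g005"].contig_id == "ctg0"
        assert by_id["m_g005"].deletion_bin == "I"
        assert by_id["m_gx"].zipper_gene is None

    def test_bins_partition_zipper(self):
        cfg = SimulationConfig(seed=20)
        ch = simulate_chromosome(cfg)
        refs = simulate_references(ch, cfg)
        zipper = build_zipper(refs)
        bins = bins_from_truth(ch, zipper)
        assert bins.established_names() == ["I", "II", "III", "IV", "V"]
        # every zipper entry with a truth position gets exactly one bin
        assert set(bins.bin_of_zipper_index) <= {
            e.zipper_index for e in zipper.entries
        }
        assert set(bins.bin_of_zipper_index.values()) <= set("I II III IV V".split())
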