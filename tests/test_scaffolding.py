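"""MTP selection, contig ends, end-to-end merging and assembly metrics."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from bacmap.assembly import Contig
from bacmap.evaluate import junction_truth
from bacmap.scaffolding import (
    assembly_metrics,
    find_contig_ends,
    merge_into_scaffolds,
    select_mtp,
)


def brute_force_nx0(lengths, q):
    """Independent oracle: sort descending, walk until cumulative >= q*total."""
    s = sorted(lengths, reverse=True)
    total = sum(s)
    cum = 0.0
    for i, x in enumerate(s):
        cum += x
        if cum >= q * total:
            return x, i + 1
    return s[-1], len(s)


class TestMetrics:
    def test_hand_example(self):
        m = assembly_metrics([10, 8, 5, 2])
        assert m.total_length_kb == 25
        assert (m.n50_kb, m.l50) == (8, 2)
        # cumulative 10, 18, 23 first reaches 22.5 at the third item
        assert (m.n90_kb, m.l90) == (5, 3)

    def test_single_item(self):
        m = assembly_metrics([42.0])
        assert m.n50_kb == m.n90_kb == 42.0
        assert m.l50 == m.l90 == 1

    def test_coverage_percentage(self):
        m = assembly_metrics([260_000.0], arm_length_kb=314_000.0)
        assert round(100 * m.coverage_fraction) == 83

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assembly_metrics([])

    def test_against_bruteforce_oracle(self, rng):
        for _ in range(1000):
            lengths = rng.integers(1, 10_000, size=int(rng.integers(1, 40))).tolist()
            m = assembly_metrics(lengths)
            n50, l50 = brute_force_nx0(lengths, 0.5)
            n90, l90 = brute_force_nx0(lengths, 0.9)
            assert (m.n50_kb, m.l50, m.n90_kb, m.l90) == (n50, l50, n90, l90)
        assert m.n50_kb >= m.n90_kb and m.l50 <= m.l90


def chain_graph(n, score=-30.0, extra=()):
    g = nx.Graph()
    for k in range(n):
        g.add_node(f"c{k}", n_bands=60, q_flag=False, q_reasons=[])
    for k in range(n - 1):
        g.add_edge(f"c{k}", f"c{k + 1}", log10_score=score, shared=40,
                   q_flag=False, parallel_support=2)
    for a, b, s in extra:
        g.add_edge(a, b, log10_score=s, shared=25, q_flag=False,
                   parallel_support=2)
    g.graph["kb_per_band"] = 1.0
    g.graph["insert_mean_kb"] = 60.0
    from bacmap.assembly import AssemblyParams

    g.graph["params"] = AssemblyParams()
    return g


class TestSelectMTP:
    def test_two_clone_contig(self):
        g = chain_graph(2)
        ctg = Contig("x", ["c0", "c1"], est_start_kb=[0, 20])
        mtp = select_mtp(ctg, g, 1e-25)
        assert mtp.clones == ["c0", "c1"]

    def test_shortcuts_shorten_path(self):
        # skip edges allow hopping two clones at a time
        extra = [(f"c{k}", f"c{k + 2}", -28.0) for k in range(8)]
        g = chain_graph(10, extra=extra)
        ctg = Contig("x", [f"c{k}" for k in range(10)])
        mtp = select_mtp(ctg, g, 1e-25)
        assert len(mtp.clones) == 6  # 0,2,4,6,8,9
        assert mtp.clones[0] == "c0" and mtp.clones[-1] == "c9"

    def test_hop_count_equals_bruteforce(self, rng):
        """Dijkstra hop count equals brute-force BFS on random interval graphs."""
        for trial in range(50):
            n = int(rng.integers(5, 25))
            starts = np.sort(rng.uniform(0, 100, size=n))
            lengths = rng.uniform(10, 30, size=n)
            g = nx.Graph()
            order = [f"v{k}" for k in range(n)]
            for k, v in enumerate(order):
                g.add_node(v, n_bands=60, q_flag=False, q_reasons=[])
            for i in range(n):
                for j in range(i + 1, n):
                    if starts[j] < starts[i] + lengths[i]:
                        g.add_edge(order[i], order[j], log10_score=-30.0,
                                   shared=30, q_flag=False, parallel_support=2)
            from bacmap.assembly import AssemblyParams

            g.graph["params"] = AssemblyParams()
            if not nx.has_path(g, order[0], order[-1]):
                continue
            ctg = Contig("x", order)
            mtp = select_mtp(ctg, g, 1e-25)
            want = nx.shortest_path_length(g, order[0], order[-1]) + 1
            assert len(mtp.chains[0]) == want

    def test_gap_reporting(self):
        g = chain_graph(6)
        g.remove_edge("c2", "c3")
        ctg = Contig("x", [f"c{k}" for k in range(6)])
        mtp = select_mtp(ctg, g, 1e-25)
        assert len(mtp.chains) == 2
        assert mtp.gaps == [("c2", "c3")]


class TestContigEnds:
    def test_three_clone_chain(self):
        g = chain_graph(3)
        ctg = Contig("x", ["c0", "c1", "c2"])
        mtp = select_mtp(ctg, g, 1e-25)
        left, right = find_contig_ends(ctg, mtp, g)
        assert left == {"c0"} and right == {"c2"}

    def test_interior_clone_never_in_ends(self):
        extra = [(f"c{k}", f"c{k + 2}", -20.0) for k in range(10)]
        g = chain_graph(12, extra=extra)
        ctg = Contig("x", [f"c{k}" for k in range(12)])
        mtp = select_mtp(ctg, g, 1e-25)
        left, right = find_contig_ends(ctg, mtp, g)
        interior = set(mtp.clones[1:-1])
        assert not (left & interior) and not (right & interior)

    def test_single_clone_contig(self):
        g = chain_graph(1)
        ctg = Contig("x", ["c0"])
        mtp = select_mtp(ctg, g, 1e-25)
        left, right = find_contig_ends(ctg, mtp, g)
        assert left == right == {"c0"}


def two_contig_world(score_best=-30.0, score_next=None, bridge=False,
                     confirm_best=False):
    """Two 4-clone contigs (+ optionally a third) with crafted junction
    evidence between their facing ends."""
    g = nx.Graph()
    contigs = []
    for name in ("A", "B", "C"):
        clones = [f"{name}{k}" for k in range(4)]
        for c in clones:
            g.add_node(c, n_bands=60, q_flag=False, q_reasons=[])
        for k in range(3):
            g.add_edge(clones[k], clones[k + 1], log10_score=-35.0, shared=45,
                       q_flag=False, parallel_support=2)
        ctg = Contig(name, clones, est_start_kb=[0, 20, 40, 60])
        ctg._last_clone_kb = 60.0
        contigs.append(ctg)
    from bacmap.assembly import AssemblyParams

    g.graph["params"] = AssemblyParams()
    g.graph["kb_per_band"] = 1.0
    g.graph["insert_mean_kb"] = 60.0
    # junction evidence: A right end (A3) to B left end (B0)
    if bridge:
        g.add_node("q1", n_bands=60, q_flag=True, q_reasons=["few_bands"])
        g.add_edge("A3", "q1", log10_score=score_best, shared=30,
                   q_flag=True, parallel_support=0)
        g.add_edge("q1", "B0", log10_score=score_best, shared=30,
                   q_flag=True, parallel_support=0)
    else:
        g.add_edge("A3", "B0", log10_score=score_best, shared=30,
                   q_flag=True, parallel_support=0)
    if confirm_best:
        # redundant contig-ending clone of A confirming the same junction
        g.add_node("A3b", n_bands=60, q_flag=False, q_reasons=[])
        g.add_edge("A3b", "A3", log10_score=-35.0, shared=45, q_flag=False,
                   parallel_support=2)
        contigs[0].clones.insert(3, "A3b")
        contigs[0].est_start_kb.insert(3, 55)
        g.add_edge("A3b", "B0", log10_score=score_best + 8, shared=20,
                   q_flag=True, parallel_support=0)
    if score_next is not None:
        g.add_edge("A3", "C0", log10_score=score_next, shared=25,
                   q_flag=True, parallel_support=0)
    return g, contigs


class TestMerge:
    def test_clear_margin_merges(self):
        g, contigs = two_contig_world(score_best=-30.0, score_next=-20.0)
        scaffolds = merge_into_scaffolds(contigs[:2], g)
        assert len(scaffolds) == 1
        assert [c for c, _ in scaffolds[0].contigs] in (["A", "B"], ["B", "A"])
        assert scaffolds[0].junctions[0].validation == "best_unvalidated"

    def test_margin_rule_blocks_close_competitors(self):
        """Best 1e-30 vs next-best 1e-27: 3 < 5 orders, no merge."""
        g, contigs = two_contig_world(score_best=-30.0, score_next=-27.0)
        scaffolds = merge_into_scaffolds(contigs, g)
        assert all(len(s.contigs) == 1 for s in scaffolds)

    def test_parallel_confirmation_beats_margin(self):
        """A parallel-confirmed junction merges even with a close competitor."""
        g, contigs = two_contig_world(
            score_best=-30.0, score_next=-27.0, confirm_best=True
        )
        scaffolds = merge_into_scaffolds(contigs, g)
        merged = [s for s in scaffolds if len(s.contigs) == 2]
        assert len(merged) == 1
        assert {c for c, _ in merged[0].contigs} == {"A", "B"}
        assert merged[0].junctions[0].validation == "parallel_confirmed"

    def test_bridge_clone_merges(self):
        g, contigs = two_contig_world(score_best=-30.0, bridge=True)
        scaffolds = merge_into_scaffolds(contigs[:2], g)
        assert len(scaffolds) == 1
        j = scaffolds[0].junctions[0]
        assert j.bridge_clone == "q1"

    def test_branch_flagged_clone_never_bridges(self):
        g, contigs = two_contig_world(score_best=-30.0, bridge=True)
        g.nodes["q1"]["q_reasons"] = ["branch_inducing"]
        scaffolds = merge_into_scaffolds(contigs[:2], g)
        assert all(len(s.contigs) == 1 for s in scaffolds)

    def test_synthetic_region_reassembled(self, small_noisy_world):
        """Contigs from one arm merge into scaffolds whose junctions connect
        true physical neighbours, and merging increases N50."""
        contigs = small_noisy_world["contigs"]
        g = small_noisy_world["graph"]
        lib = small_noisy_world["library"]
        g.graph["insert_mean_kb"] = small_noisy_world["cfg"].insert_mean_kb
        scaffolds = merge_into_scaffolds(contigs, g)
        jt = junction_truth(scaffolds, contigs, lib)
        assert jt["fraction_true"] >= 0.9
        cm = assembly_metrics([c.length_kb for c in contigs])
        sm = assembly_metrics([s.length_kb for s in scaffolds])
        assert sm.n50_kb >= cm.n50_kb

    def test_orientation_chain_consistency(self):
        g, contigs = two_contig_world(score_best=-30.0)
        scaffolds = merge_into_scaffolds(contigs[:2], g)
        (s,) = scaffolds
        # A joins via its right end, B via its left: both forward
        orient = dict(s.contigs)
        if s.contigs[0][0] == "A":
            assert orient == {"A": "+", "B": "+"}
        else:
            assert orient == {"B": "-", "A": "-"}
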