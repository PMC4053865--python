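"""Minimal tiling paths, end-to-end contig merging and assembly metrics.

A minimal tiling path (MTP) is the smallest chain of clones spanning a
contig while keeping every adjacent pair significantly overlapping; contig
ends are then characterized by the clones that overlap the terminal MTP
clone but no interior one.  Scaffolding proposes junctions between contig
ends — direct end-clone overlaps or single bridging clones recruited from
the questionable material parked during assembly — validates them by
parallel connections or by a significance margin over the next-best
alternative, and merges contigs greedily into oriented scaffolds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .assembly import Contig

__all__ = [
    "MTP",
    "Junction",
    "Scaffold",
    "AssemblyMetrics",
    "select_mtp",
    "find_contig_ends",
    "merge_into_scaffolds",
    "assembly_metrics",
]


@dataclass
class MTP:
    """Minimal tiling path of one contig.

    ``chains`` holds one clone chain per gap-free stretch (a single chain
    when the contig is spannable at the MTP cutoff); ``gaps`` lists the
    (last-of-chain, first-of-next-chain) clone pairs flanking unspanned
    stretches.  ``auxiliary`` holds clones added to restore the coverage
    guarantee (every non-MTP clone overlaps an MTP clone at the network
    cutoff) in the rare case the chain alone does not provide it.
    """

    contig_id: str
    clones: list[str]
    adjacency_log10: list[float] = field(default_factory=list)
    chains: list[list[str]] = field(default_factory=list)
    gaps: list[tuple[str, str]] = field(default_factory=list)
    auxiliary: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clones)


def _dijkstra_weight(log_floor: float = -320.0):
    def w(_a, _b, d):
        return 1.0 + 1e-9 * (d["log10_score"] - log_floor)

    return w


def select_mtp(
    contig: Contig,
    graph: nx.Graph,
    mtp_cutoff: float = 1e-25,
) -> MTP:
    """Shortest chain (by hop count, ties by total significance) from the
    first- to the last-ranked clone over overlaps at ``mtp_cutoff``.

    When the contig cannot be spanned at this stringency the best partial
    chains are returned per connected stretch and the gaps reported.
    """
    log_cut = math.log10(mtp_cutoff)
    sub = nx.Graph()
    sub.add_nodes_from(contig.clones)
    members = set(contig.clones)
    for a, b, d in graph.edges(data=True):
        if a in members and b in members and d["log10_score"] <= log_cut:
            sub.add_edge(a, b, **d)
    rank = contig.rank()
    first, last = contig.clones[0], contig.clones[-1]

    chains: list[list[str]] = []
    comps = sorted(
        nx.connected_components(sub), key=lambda c: min(rank[x] for x in c)
    )
    for comp in comps:
        src = min(comp, key=lambda x: (rank[x], x))
        dst = max(comp, key=lambda x: (rank[x], x))
        path = nx.dijkstra_path(sub.subgraph(comp), src, dst, weight=_dijkstra_weight())
        chains.append(path)
    gaps = [
        (a[-1], b[0]) for a, b in zip(chains, chains[1:])
    ]
    clones = [c for chain in chains for c in chain]
    adjacency = []
    for chain in chains:
        for a, b in zip(chain, chain[1:]):
            adjacency.append(float(sub.edges[a, b]["log10_score"]))

    # coverage guarantee at the permissive network cutoff
    params = graph.graph.get("params")
    net_log = math.log10(params.net_cutoff) if params is not None else -15.0
    in_mtp = set(clones)
    auxiliary: list[str] = []
    for c in contig.clones:
        if c in in_mtp:
            continue
        covered = any(
            graph.has_edge(c, m) and graph.edges[c, m]["log10_score"] <= net_log
            for m in in_mtp
        )
        if not covered:
            auxiliary.append(c)
            in_mtp.add(c)
    return MTP(contig.contig_id, clones, adjacency, chains, gaps, auxiliary)


def find_contig_ends(
    contig: Contig,
    mtp: MTP,
    graph: nx.Graph,
) -> tuple[set[str], set[str]]:
    """Contig-ending clone sets.

    An ending clone overlaps the first (respectively last) MTP clone but no
    interior MTP clone; the terminal MTP clones belong to their own end
    sets.  A single-clone contig is its own two ends.
    """
    if len(contig.clones) == 1:
        only = {contig.clones[0]}
        return only, set(only)
    first, last = mtp.clones[0], mtp.clones[-1]
    interior = set(mtp.clones) - {first, last}
    left, right = {first}, {last}
    for c in contig.clones:
        if c in interior:
            continue
        hits_interior = any(graph.has_edge(c, m) for m in interior)
        if hits_interior:
            continue
        if c != first and graph.has_edge(c, first):
            left.add(c)
        if c != last and graph.has_edge(c, last):
            right.add(c)
    return left, right


@dataclass
class Junction:
    """Evidence for one contig-end junction."""

    contig_a: str
    side_a: str  # left | right
    contig_b: str
    side_b: str
    log10_score: float
    bridge_clone: str | None
    clone_pair: tuple[str, str]
    validation: str  # parallel_confirmed | best_unvalidated | ambiguous
    n_connections: int


@dataclass
class Scaffold:
    scaffold_id: str
    contigs: list[tuple[str, str]]  # (contig_id, orientation in {+, -})
    junctions: list[Junction] = field(default_factory=list)
    length_kb: float = 0.0

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass
class AssemblyMetrics:
    n_items: int
    total_length_kb: float
    mean_length_kb: float
    max_length_kb: float
    n50_kb: float
    n90_kb: float
    l50: int
    l90: int
    mean_clones: float | None = None
    max_clones: int | None = None
    coverage_kb: float | None = None
    coverage_fraction: float | None = None


def assembly_metrics(
    lengths_kb: Sequence[float],
    arm_length_kb: float | None = None,
    clone_counts: Sequence[int] | None = None,
) -> AssemblyMetrics:
    """Contiguity metrics of an assembly.

    N50 is the length of the item at which the cumulative sorted-descending
    length first reaches 50% of the total; L50 its 1-based index; N90/L90
    analogously.  Coverage fraction is total length over the arm length.
    """
    lengths = np.asarray(sorted(lengths_kb, reverse=True), dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length list")
    total = float(lengths.sum())
    cum = np.cumsum(lengths)
    i50 = int(np.searchsorted(cum, 0.5 * total))
    i90 = int(np.searchsorted(cum, 0.9 * total))
    return AssemblyMetrics(
        n_items=int(lengths.size),
        total_length_kb=total,
        mean_length_kb=total / lengths.size,
        max_length_kb=float(lengths[0]),
        n50_kb=float(lengths[i50]),
        n90_kb=float(lengths[i90]),
        l50=i50 + 1,
        l90=i90 + 1,
        mean_clones=float(np.mean(clone_counts)) if clone_counts is not None else None,
        max_clones=int(np.max(clone_counts)) if clone_counts is not None else None,
        coverage_kb=total if arm_length_kb else None,
        coverage_fraction=(total / arm_length_kb) if arm_length_kb else None,
    )


# ---------------------------------------------------------------------------
# end-to-end merging


def _best_connections(
    graph: nx.Graph,
    ends_a: set[str],
    ends_b: set[str],
    relax_log: float,
    contig_of: Mapping[str, str],
) -> tuple[float, tuple[str, str], str | None, int]:
    """Best single connection between two end sets plus the count of
    vertex-disjoint connections (direct end-clone overlaps, or parked
    questionable clones bridging both sets; a bridge is as strong as its
    weaker link)."""
    best = (math.inf, ("", ""), None)
    used_pairs = []
    for a in ends_a:
        if not graph.has_node(a):
            continue
        for b in graph.neighbors(a):
            if b in ends_b:
                s = graph.edges[a, b]["log10_score"]
                if s <= relax_log:
                    used_pairs.append((s, a, b, None))
    # bridging clones: parked material only, never a member of any contig
    candidates: dict[str, tuple[float, str, str]] = {}
    for a in ends_a:
        if not graph.has_node(a):
            continue
        for z in graph.neighbors(a):
            if z in contig_of or z in ends_a or z in ends_b:
                continue
            # clones flagged for contradicting linear topology (chimeras)
            # are never recruited as bridges
            if "branch_inducing" in graph.nodes[z].get("q_reasons", ()):
                continue
            sa = graph.edges[a, z]["log10_score"]
            if sa > relax_log:
                continue
            for b in ends_b:
                if graph.has_edge(z, b):
                    sb = graph.edges[z, b]["log10_score"]
                    if sb > relax_log:
                        continue
                    s = max(sa, sb)  # weakest link
                    if z not in candidates or s < candidates[z][0]:
                        candidates[z] = (s, a, b)
    for z, (s, a, b) in candidates.items():
        used_pairs.append((s, a, b, z))
    if not used_pairs:
        return math.inf, ("", ""), None, 0
    used_pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    s, a, b, z = used_pairs[0]
    # distinct connecting overlaps (each direct edge or bridge clone counts
    # once) — the "parallel connections" that validate an elongation
    n_conn = len(used_pairs)
    return s, (a, b), z, n_conn


def merge_into_scaffolds(
    contigs: Sequence[Contig],
    graph: nx.Graph,
    margin_orders: float = 5.0,
    relax_cutoff: float = 1e-15,
    mtp_cutoff: float = 1e-25,
    min_parallel: int = 2,
    ends: Mapping[str, tuple[set[str], set[str]]] | None = None,
) -> list[Scaffold]:
    """End-to-end merge contigs into oriented scaffolds.

    For every pair of contig ends the best connection at the relaxed cutoff
    is scored (questionable clones and overlaps parked during assembly are
    eligible again, either directly or as single bridging clones).  Per
    contig end, the winning junction is the strongest parallel-confirmed
    candidate; lacking confirmation, the strongest candidate is accepted
    only when it beats the next best by at least ``margin_orders`` orders of
    magnitude, otherwise the end is left unmerged (ambiguous).  A junction
    is realized when both of its ends select it; merging proceeds greedily
    by ascending score with cycle rejection, junctions fix relative contig
    orientation, and every merge's evidence is retained on the scaffold.
    """
    relax_log = math.log10(relax_cutoff)
    contig_by_id = {c.contig_id: c for c in contigs}
    contig_of: dict[str, str] = {}
    for c in contigs:
        for cl in c.clones:
            contig_of[cl] = c.contig_id
    if ends is None:
        ends = {}
        for c in contigs:
            mtp = select_mtp(c, graph, mtp_cutoff)
            ends[c.contig_id] = find_contig_ends(c, mtp, graph)

    # score all end-pair candidates
    end_keys = [(c.contig_id, side) for c in contigs for side in ("left", "right")]
    cand: dict[tuple[str, str], list[Junction]] = {k: [] for k in end_keys}
    ids = [c.contig_id for c in contigs]
    for i, ca in enumerate(ids):
        for cb in ids[i + 1 :]:
            for sa in ("left", "right"):
                for sb in ("left", "right"):
                    ea = ends[ca][0 if sa == "left" else 1]
                    eb = ends[cb][0 if sb == "left" else 1]
                    s, pair, bridge, n_conn = _best_connections(
                        graph, ea, eb, relax_log, contig_of
                    )
                    if not math.isfinite(s):
                        continue
                    j = Junction(
                        ca, sa, cb, sb, s, bridge, pair,
                        "parallel_confirmed" if n_conn >= min_parallel else "best_unvalidated",
                        n_conn,
                    )
                    cand[(ca, sa)].append(j)
                    cand[(cb, sb)].append(j)

    chosen: dict[tuple[str, str], Junction | None] = {}
    for key, js in cand.items():
        if not js:
            chosen[key] = None
            continue
        js.sort(key=lambda j: (j.log10_score, j.contig_a, j.contig_b))
        confirmed = [j for j in js if j.validation == "parallel_confirmed"]
        if confirmed:
            chosen[key] = confirmed[0]
        elif len(js) == 1 or js[0].log10_score <= js[1].log10_score - margin_orders:
            chosen[key] = js[0]
        else:
            for j in js:
                j.validation = "ambiguous"
            chosen[key] = None

    accepted: list[Junction] = []
    for key, j in chosen.items():
        if j is None:
            continue
        other = (
            (j.contig_b, j.side_b) if key == (j.contig_a, j.side_a) else (j.contig_a, j.side_a)
        )
        if chosen.get(other) is j and key < other:
            accepted.append(j)
    accepted.sort(key=lambda j: (j.log10_score, j.contig_a, j.contig_b))

    # greedy union with end occupancy and cycle rejection
    parent = {cid: cid for cid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    end_used: set[tuple[str, str]] = set()
    realized: list[Junction] = []
    links: dict[str, dict[str, Junction]] = {cid: {} for cid in ids}
    for j in accepted:
        ka, kb = (j.contig_a, j.side_a), (j.contig_b, j.side_b)
        if ka in end_used or kb in end_used:
            continue
        ra, rb = find(j.contig_a), find(j.contig_b)
        if ra == rb:
            continue  # would close a cycle
        parent[ra] = rb
        end_used.add(ka)
        end_used.add(kb)
        links[j.contig_a][j.side_a] = j
        links[j.contig_b][j.side_b] = j
        realized.append(j)

    # walk chains to produce oriented scaffolds
    scaffolds: list[Scaffold] = []
    visited: set[str] = set()
    kb_per_band = graph.graph.get("kb_per_band", 1.0)
    insert_mean = graph.graph.get("insert_mean_kb", 113.0)
    for cid in ids:
        if cid in visited:
            continue
        deg = len(links[cid])
        if deg == 2:
            continue  # interior contig; start walks from chain ends only
        chain: list[tuple[str, str]] = []
        junctions: list[Junction] = []
        cur, cur_side = cid, None
        # leave via whichever side is linked (or none for isolated contigs)
        prev_j: Junction | None = None
        while True:
            visited.add(cur)
            if prev_j is None:
                out_side = "right" if "right" in links[cur] else (
                    "left" if "left" in links[cur] else None
                )
                orient = "+" if out_side in ("right", None) else "-"
            else:
                in_side = (
                    prev_j.side_a if prev_j.contig_a == cur else prev_j.side_b
                )
                orient = "+" if in_side == "left" else "-"
                out_side = "left" if in_side == "right" else "right"
                if out_side not in links[cur] or links[cur][out_side] is prev_j:
                    out_side = None
            chain.append((cur, orient))
            if out_side is None:
                break
            j = links[cur][out_side]
            junctions.append(j)
            nxt = j.contig_b if j.contig_a == cur else j.contig_a
            prev_j = j
            cur = nxt
        length = sum(contig_by_id[c].length_kb for c, _ in chain)
        for j in junctions:
            if j.bridge_clone is None:
                a, b = j.clone_pair
                m = graph.edges[a, b]["shared"] if graph.has_edge(a, b) else 0
                length -= m * kb_per_band
            else:
                length += insert_mean
        scaffolds.append(Scaffold("", chain, junctions, length))
    scaffolds.sort(key=lambda s: (-s.length_kb, s.contigs[0][0]))
    for k, s in enumerate(scaffolds):
        s.scaffold_id = f"scf{k + 1:03d}"
    return scaffolds
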