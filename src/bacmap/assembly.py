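"""Overlap-network construction and linear-topology contig assembly.

The assembly strategy mirrors adaptive fingerprint clustering: build a
network of all clone overlaps significant at a permissive Sulston cutoff,
annotate questionable material (Q-overlaps lacking parallel confirmation,
Q-clones that are promiscuous, poorly fingerprinted or branch-inducing),
then take connected components of the trusted subnetwork and demand that
each is topologically linear — every clone's neighbourhood must occupy a
contiguous run of ranks in the inferred clone order, as it would along a
one-dimensional chromosome.  Components that fail the test are re-clustered
at progressively stricter cutoffs until they become linear or bottom out as
branched.  Nothing is ever deleted: flagged clones and overlaps are parked
and remain available to the scaffolding stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.special import betainc
from scipy.sparse.linalg import eigsh

from .fingerprints import (
    FingerprintSet,
    ScoreParams,
    _greedy_match,
    _match_prob,
    sulston_log10,
)

__all__ = [
    "AssemblyParams",
    "Contig",
    "build_overlap_graph",
    "detect_questionable",
    "assemble_contigs",
    "order_clones",
    "branch_points",
    "assembly_partition",
    "BranchedTopologyError",
]

LOG10_FLOOR = -320.0  # scores below double-precision underflow are clamped

# Fragments straddling a clone end are sized in one clone of an overlapping
# pair but not the other, so each rank adjacency carries ~2 spuriously
# unshared bands (about one truncated in-range fragment per clone end).
# Subtracted when converting unshared-band counts to physical steps.
END_BAND_CORRECTION = 2.0


@dataclass(frozen=True)
class AssemblyParams:
    """Cutoff schedule and questionable-material thresholds.

    Cutoffs are Sulston probabilities and must satisfy
    ``net_cutoff >= q_clone_cutoff >= split_cutoff >= max_stringency``.
    """

    net_cutoff: float = 1e-15
    q_overlap_cutoff: float = 1e-15
    q_clone_cutoff: float = 1e-25
    split_cutoff: float = 1e-30
    max_stringency: float = 1e-33
    promiscuity_degree: int = 500
    promiscuity_score: float = 1e-50
    min_parallel: int = 2
    min_bands: int = 30

    def __post_init__(self) -> None:
        seq = (
            self.net_cutoff,
            self.q_clone_cutoff,
            self.split_cutoff,
            self.max_stringency,
        )
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(
                "cutoffs must be ordered net >= q_clone >= split >= max_stringency"
            )

    @property
    def stringency_schedule(self) -> tuple[float, ...]:
        """Distinct escalation cutoffs, permissive to strict."""
        out: list[float] = []
        for c in (
            self.net_cutoff,
            self.q_clone_cutoff,
            self.split_cutoff,
            self.max_stringency,
        ):
            if not out or c < out[-1]:
                out.append(c)
        return tuple(out)


@dataclass
class Contig:
    """An ordered clone chain with estimated coordinates."""

    contig_id: str
    clones: list[str]  # rank order
    est_start_bands: list[float] = field(default_factory=list)
    est_start_kb: list[float] = field(default_factory=list)
    linearity_status: str = "deferred"  # linear | branched | deferred

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def length_kb(self) -> float:
        return self.est_start_kb[-1] + self._last_clone_kb if self.est_start_kb else 0.0

    # filled by order_clones; length of the last clone in kb
    _last_clone_kb: float = 0.0

    def rank(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.clones)}


class BranchedTopologyError(RuntimeError):
    """Raised when a strict ordering is requested for a branched contig."""

    def __init__(self, branch_clones: list[str]):
        super().__init__(
            f"contig is branched at {len(branch_clones)} clone(s): "
            + ", ".join(branch_clones[:8])
        )
        self.branch_clones = branch_clones


# ---------------------------------------------------------------------------
# scoring helpers


def _log10_scores(
    m: np.ndarray, n_lo: np.ndarray, n_hi: np.ndarray, params: ScoreParams
) -> np.ndarray:
    """Vectorized log10 Sulston scores; underflowed values recomputed exactly."""
    p = -np.expm1(n_hi * math.log1p(-1.0 / params.band_space))
    # binomial survival P(X >= m) via the regularized incomplete beta
    sf = betainc(m, n_lo - m + 1.0, p)
    out = np.full(m.shape, 0.0)
    pos = sf > 0
    out[pos] = np.log10(sf[pos])
    for idx in np.nonzero(~pos)[0]:
        val = sulston_log10(int(m[idx]), int(n_lo[idx]), int(n_hi[idx]), params)
        out[idx] = max(val, LOG10_FLOOR)
    out[m == 0] = 0.0
    return out


def min_significant_m(n: int, cutoff: float, params: ScoreParams) -> int:
    """Smallest shared-band count significant at ``cutoff`` for two n-band clones."""
    target = math.log10(cutoff)
    lo, hi = 1, n
    if sulston_log10(n, n, n, params) > target:
        return n + 1  # even full identity is not significant
    while lo < hi:
        mid = (lo + hi) // 2
        if sulston_log10(mid, n, n, params) <= target:
            hi = mid
        else:
            lo = mid + 1
    return lo


# ---------------------------------------------------------------------------
# overlap network


def build_overlap_graph(
    fps: FingerprintSet,
    params: AssemblyParams = AssemblyParams(),
    score_params: ScoreParams = ScoreParams(),
    insert_mean_kb: float = 113.0,
    method: str = "auto",
) -> nx.Graph:
    """Network of clone overlaps significant at ``params.net_cutoff``.

    Nodes are all clones (clones below ``min_bands`` are included but
    q-flagged); edges carry the log10 Sulston score, the shared-band count
    and the parallel support (number of common network neighbours of the two
    ends).  For large inputs an inverted-index prefilter over coarse band
    bins avoids the all-pairs sweep; ``method`` may force ``"exact"`` or
    ``"prefilter"``.

    With fewer than two usable fingerprints the returned graph has no edges.
    """
    g = nx.Graph()
    ids = list(fps)
    bands = {cid: fps[cid].bands for cid in ids}
    for cid in ids:
        n = len(bands[cid])
        usable = n >= params.min_bands
        g.add_node(cid, n_bands=n, q_flag=not usable,
                   q_reasons=[] if usable else ["few_bands"])
    usable_ids = [cid for cid in ids if not g.nodes[cid]["q_flag"]]
    mean_bands = (
        float(np.mean([len(bands[c]) for c in usable_ids])) if usable_ids else 1.0
    )
    g.graph["score_params"] = score_params
    g.graph["params"] = params
    g.graph["kb_per_band"] = insert_mean_kb / max(mean_bands, 1.0)

    if len(usable_ids) < 2:
        return g

    if method == "exact" or (method == "auto" and len(usable_ids) <= 600):
        pairs = _all_pairs(usable_ids)
    else:
        pairs = _prefilter_pairs(usable_ids, bands, params, score_params)

    tol = score_params.tolerance
    rows_i: list[str] = []
    rows_j: list[str] = []
    ms: list[int] = []
    for i, j in pairs:
        m = _greedy_match(bands[i], bands[j], tol)
        if m > 0:
            rows_i.append(i)
            rows_j.append(j)
            ms.append(m)
    if ms:
        m_arr = np.asarray(ms, dtype=np.float64)
        na = np.asarray([len(bands[c]) for c in rows_i], dtype=np.float64)
        nb = np.asarray([len(bands[c]) for c in rows_j], dtype=np.float64)
        n_lo, n_hi = np.minimum(na, nb), np.maximum(na, nb)
        logs = _log10_scores(m_arr, n_lo, n_hi, score_params)
        log_cut = math.log10(params.net_cutoff)
        for i, j, m, ls in zip(rows_i, rows_j, ms, logs):
            if ls <= log_cut:
                g.add_edge(i, j, log10_score=float(ls), shared=int(m),
                           q_flag=False, parallel_support=0)
    _fill_parallel_support(g)
    return g


def _all_pairs(ids: Sequence[str]) -> Iterable[tuple[str, str]]:
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            yield ids[a], ids[b]


def _prefilter_pairs(
    ids: Sequence[str],
    bands: dict[str, np.ndarray],
    params: AssemblyParams,
    score_params: ScoreParams,
) -> list[tuple[str, str]]:
    """Candidate pairs via two half-offset coarse band grids.

    Any two bands within the matching tolerance share a coarse bin of width
    ``2 x tolerance`` in at least one of the two grids, so the summed
    co-occupancy count upper-bounds the true matched count (up to duplicate
    bands collapsing within a bin, absorbed by a safety margin on the
    per-pair threshold).
    """
    tol = score_params.tolerance
    width = 2 * tol
    n_bins = score_params.gel_length // width + 2
    rows, cols = [], []
    counts = np.array([len(bands[c]) for c in ids])
    for r, cid in enumerate(ids):
        b = bands[cid]
        g0 = np.unique(b // width)
        g1 = np.unique((b + tol) // width) + n_bins
        occ = np.concatenate([g0, g1])
        rows.extend([r] * occ.size)
        cols.extend(occ.tolist())
    A = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.float32), (rows, cols)),
        shape=(len(ids), 2 * n_bins),
    )
    # per-band-count thresholds for possible significance, with margin
    margin = 4
    uniq_n = np.unique(counts)
    thr_by_n = {
        int(n): max(
            4, min_significant_m(int(n), params.net_cutoff, score_params) - margin
        )
        for n in uniq_n
    }
    global_thr = min(thr_by_n.values())
    pairs: list[tuple[str, str]] = []
    block = 512
    for start in range(0, len(ids), block):
        stop = min(start + block, len(ids))
        C = (A[start:stop] @ A.T).tocoo()
        for r, c, v in zip(C.row, C.col, C.data):
            i = start + r
            if c <= i or v < global_thr:
                continue
            if v >= thr_by_n[int(min(counts[i], counts[c]))]:
                pairs.append((ids[i], ids[c]))
    return pairs


def _fill_parallel_support(g: nx.Graph) -> None:
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    for a, b in g.edges:
        g.edges[a, b]["parallel_support"] = len(adj[a] & adj[b])


# ---------------------------------------------------------------------------
# questionable material


def detect_questionable(g: nx.Graph, params: AssemblyParams | None = None) -> dict:
    """Annotate Q-overlaps and Q-clones; nothing is removed.

    An overlap is questionable when its parallel support (common network
    neighbours of its two clones) falls below ``min_parallel``.  A clone is
    questionable when its fingerprint is too small, when it is promiscuous
    (more than ``promiscuity_degree`` overlaps stronger than
    ``promiscuity_score``), or when assembly later identifies it as
    branch-inducing (those flags are added by :func:`assemble_contigs`).
    """
    if params is None:
        params = g.graph["params"]
    log_prom = math.log10(params.promiscuity_score)
    strong_deg = {n: 0 for n in g.nodes}
    for a, b, d in g.edges(data=True):
        if d["log10_score"] <= log_prom:
            strong_deg[a] += 1
            strong_deg[b] += 1
        d["q_flag"] = d["parallel_support"] < params.min_parallel
    for n, deg in strong_deg.items():
        if deg > params.promiscuity_degree:
            g.nodes[n]["q_flag"] = True
            if "promiscuous" not in g.nodes[n]["q_reasons"]:
                g.nodes[n]["q_reasons"].append("promiscuous")
    # Clones contradicting one-dimensional topology: a clone whose trusted
    # neighbourhood falls apart into two or more mutually non-overlapping
    # groups bridges regions that share no other connection — the network
    # signature of a chimeric (or foreign) clone.
    trusted = _trusted_subgraph(g, params.net_cutoff)
    for v in list(trusted.nodes):
        nbrs = list(trusted.neighbors(v))
        if len(nbrs) < 4:
            continue
        comps = [
            c for c in nx.connected_components(trusted.subgraph(nbrs))
            if len(c) >= 2
        ]
        if len(comps) >= 2:
            g.nodes[v]["q_flag"] = True
            if "branch_inducing" not in g.nodes[v]["q_reasons"]:
                g.nodes[v]["q_reasons"].append("branch_inducing")
    return {
        "q_clones": [n for n, d in g.nodes(data=True) if d["q_flag"]],
        "q_overlaps": [
            (a, b) for a, b, d in g.edges(data=True) if d["q_flag"]
        ],
    }


# ---------------------------------------------------------------------------
# ordering


def _spectral_order(sub: nx.Graph, nodes: list[str]) -> list[str]:
    """Seriation of one connected component by the Fiedler vector of the
    shared-band-weighted Laplacian; ties broken by clone id, orientation
    canonicalized so the lexicographically smaller end comes first."""
    nodes = sorted(nodes)
    n = len(nodes)
    if n <= 2:
        return nodes
    index = {c: i for i, c in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for a, b, d in sub.edges(data=True):
        ia, ib = index[a], index[b]
        w = float(d.get("shared", 1))
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    if n <= 400:
        evals, evecs = np.linalg.eigh(L.toarray())
        fiedler = evecs[:, 1]
    else:
        v0 = np.linspace(-1.0, 1.0, n)
        evals, evecs = eigsh(
            (L + sp.eye(n) * 1e-3).tocsc(), k=2, sigma=0.0, v0=v0
        )
        fiedler = evecs[:, np.argsort(evals)[1]]
    order = sorted(range(n), key=lambda i: (fiedler[i], nodes[i]))
    ordered = [nodes[i] for i in order]
    if ordered[0] > ordered[-1]:
        ordered.reverse()
    return ordered


def _c1_violations(sub: nx.Graph, ordered: list[str]) -> list[str]:
    """Clones whose closed neighbourhood is not a contiguous rank run."""
    rank = {c: i for i, c in enumerate(ordered)}
    out = []
    for c in ordered:
        rs = [rank[c]] + [rank[x] for x in sub.neighbors(c)]
        if max(rs) - min(rs) + 1 != len(rs):
            out.append(c)
    return out


def _split_neighbourhood(
    sub: nx.Graph, ordered: list[str], clone: str, gap: int
) -> bool:
    """True when the clone's neighbour ranks form >= 2 blocks separated by
    more than ``gap`` ranks — the signature of a chimera bridging two
    distant regions rather than boundary fuzz."""
    rank = {c: i for i, c in enumerate(ordered)}
    rs = sorted(rank[x] for x in sub.neighbors(clone))
    if len(rs) < 2:
        return False
    diffs = np.diff(rs)
    return bool(np.any(diffs > gap))


def order_clones(
    contig: Contig | Sequence[str],
    graph: nx.Graph,
    kb_per_band: float | None = None,
    strict: bool = False,
) -> Contig:
    """Order a contig's clones and estimate start coordinates.

    The order is a spectral seriation of the shared-band similarity matrix
    (the Fiedler vector of an interval graph recovers the interval order),
    deterministic up to the canonical orientation.  Start coordinates
    accumulate the unshared-band count between rank neighbours, converted to
    kb with the calibrated kb-per-band factor, and are non-decreasing by
    construction.  With ``strict=True`` a branched topology raises
    :class:`BranchedTopologyError` carrying the branch-point clones.
    """
    clones = list(contig.clones) if isinstance(contig, Contig) else list(contig)
    cid = contig.contig_id if isinstance(contig, Contig) else "ctg"
    sub = graph.subgraph(clones)
    ordered = _spectral_order(sub, clones)
    viol = _c1_violations(sub, ordered)
    if strict and viol:
        raise BranchedTopologyError(viol)
    if kb_per_band is None:
        kb_per_band = graph.graph.get("kb_per_band", 1.0)
    starts_b = [0.0]
    for a, b in zip(ordered, ordered[1:]):
        n_a = graph.nodes[a]["n_bands"]
        m = graph.edges[a, b]["shared"] if sub.has_edge(a, b) else 0
        step = max(n_a - m - (END_BAND_CORRECTION if m else 0), 0)
        starts_b.append(starts_b[-1] + step)
    out = Contig(
        cid,
        ordered,
        est_start_bands=starts_b,
        est_start_kb=[s * kb_per_band for s in starts_b],
        linearity_status="linear" if not viol else "branched",
    )
    out._last_clone_kb = graph.nodes[ordered[-1]]["n_bands"] * kb_per_band
    return out


def branch_points(contig: Contig, graph: nx.Graph) -> list[str]:
    """Clones violating the consecutive-ones property under the contig order."""
    sub = graph.subgraph(contig.clones)
    return _c1_violations(sub, contig.clones)


# ---------------------------------------------------------------------------
# assembly


def _trusted_subgraph(g: nx.Graph, cutoff: float, nodes=None) -> nx.Graph:
    log_cut = math.log10(cutoff)
    keep_nodes = [
        n
        for n in (nodes if nodes is not None else g.nodes)
        if not g.nodes[n]["q_flag"]
    ]
    sub = nx.Graph()
    sub.add_nodes_from((n, g.nodes[n]) for n in keep_nodes)
    keep = set(keep_nodes)
    for a, b, d in g.edges(data=True):
        if a in keep and b in keep and not d["q_flag"] and d["log10_score"] <= log_cut:
            sub.add_edge(a, b, **d)
    return sub


def _flag_branch_clone(g: nx.Graph, clone: str) -> None:
    g.nodes[clone]["q_flag"] = True
    if "branch_inducing" not in g.nodes[clone]["q_reasons"]:
        g.nodes[clone]["q_reasons"].append("branch_inducing")


def assemble_contigs(
    g: nx.Graph,
    params: AssemblyParams | None = None,
    small_comp_limit: int = 40,
) -> list[Contig]:
    """Assemble linear-topology contigs under the adaptive cutoff schedule.

    Connected components of the trusted (un-flagged) subnetwork at the
    network cutoff are ordered and checked for linearity.  A non-linear
    component is repaired by flagging branch-inducing clones (clones whose
    neighbourhood splits into distant rank blocks; for small components, the
    unique clone whose removal restores linearity); when no such repair
    applies the component is re-clustered at the next stricter cutoff, and a
    component still non-linear at maximum stringency is kept as a contig
    with ``linearity_status='branched'``.  Only components with >= 2 clones
    become contigs; flags are annotations on the input graph, so the clone
    partition (contigs + flagged + singletons) always equals the input set.
    """
    if params is None:
        params = g.graph["params"]
    schedule = params.stringency_schedule
    results: list[Contig] = []
    queue: list[tuple[frozenset, int]] = [(frozenset(
        n for n in g.nodes if not g.nodes[n]["q_flag"]
    ), 0)]
    while queue:
        nodes, level = queue.pop()
        sub = _trusted_subgraph(g, schedule[level], nodes)
        for comp in nx.connected_components(sub):
            comp = set(comp)
            if len(comp) < 2:
                continue
            csub = sub.subgraph(comp)
            ordered = _spectral_order(csub, list(comp))
            viol = _c1_violations(csub, ordered)
            if not viol:
                results.append(_make_contig(g, csub, ordered, "linear"))
                continue
            gap = max(3, min(30, len(comp) // 10))
            branchers = [
                c for c in viol if _split_neighbourhood(csub, ordered, c, gap)
            ]
            if len(branchers) > max(2, len(comp) // 20):
                # a mass of apparent branch points means the order itself is
                # unreliable; escalate instead of flagging wholesale
                branchers = []
            if branchers:
                for c in branchers:
                    _flag_branch_clone(g, c)
                queue.append((frozenset(comp) - set(branchers), level))
                continue
            if len(comp) <= small_comp_limit:
                fixers = []
                for c in comp:
                    rest = comp - {c}
                    rsub = csub.subgraph(rest)
                    ok = all(
                        not _c1_violations(
                            rsub.subgraph(cc), _spectral_order(rsub.subgraph(cc), list(cc))
                        )
                        for cc in nx.connected_components(rsub)
                        if len(cc) >= 2
                    )
                    if ok:
                        fixers.append(c)
                if len(fixers) == 1:
                    _flag_branch_clone(g, fixers[0])
                    queue.append((frozenset(comp) - set(fixers), level))
                    continue
            if level + 1 < len(schedule):
                queue.append((frozenset(comp), level + 1))
            else:
                results.append(_make_contig(g, csub, ordered, "branched"))
    results.sort(key=lambda c: (-len(c.clones), c.clones[0]))
    out = []
    for k, c in enumerate(results):
        c.contig_id = f"ctg{k + 1:04d}"
        out.append(c)
    return out


def _make_contig(
    g: nx.Graph, csub: nx.Graph, ordered: list[str], status: str
) -> Contig:
    kb_per_band = g.graph.get("kb_per_band", 1.0)
    starts_b = [0.0]
    for a, b in zip(ordered, ordered[1:]):
        n_a = g.nodes[a]["n_bands"]
        m = csub.edges[a, b]["shared"] if csub.has_edge(a, b) else 0
        step = max(n_a - m - (END_BAND_CORRECTION if m else 0), 0)
        starts_b.append(starts_b[-1] + step)
    contig = Contig(
        "ctg",
        ordered,
        est_start_bands=starts_b,
        est_start_kb=[s * kb_per_band for s in starts_b],
        linearity_status=status,
    )
    contig._last_clone_kb = g.nodes[ordered[-1]]["n_bands"] * kb_per_band
    return contig


def assembly_partition(g: nx.Graph, contigs: Sequence[Contig]) -> dict[str, list[str]]:
    """Partition of the input clones: contig members, flagged, singletons."""
    in_contig = {c for ctg in contigs for c in ctg.clones}
    flagged = [n for n, d in g.nodes(data=True) if d["q_flag"] and n not in in_contig]
    singletons = [
        n for n in g.nodes if n not in in_contig and not g.nodes[n]["q_flag"]
    ]
    return {
        "contig_clones": sorted(in_contig),
        "flagged": sorted(flagged),
        "singletons": sorted(singletons),
    }
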