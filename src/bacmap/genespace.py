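"""Gene-space statistics: interval clustering test, gene islands, per-bin
density and synteny profiles, restriction-site and band-count profiling.

The clustering test asks whether mapped genes are uniformly spread along the
long contigs of the physical map.  The contigs are subdivided into N
equal-length non-overlapping intervals; under uniformity the expected
numbers of intervals holding zero, one, and two-or-more genes follow the
classical occupancy closed forms, and a chi-square statistic over the three
classes measures the departure.  A gene island is a group of two or more
genes lying within a single clone length of one another — operationally,
genes found on the same clone or on a pair of significantly overlapping
clones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "IntervalTestResult",
    "interval_clustering_test",
    "detect_gene_islands",
    "density_and_synteny_profile",
    "restriction_profile",
    "band_count_profile",
    "ENZYME_MOTIFS",
]

ENZYME_MOTIFS = {
    "HaeIII": "GGCC",
    "HindIII": "AAGCTT",
    "EcoRI": "GAATTC",
    "BamHI": "GGATCC",
    "XbaI": "TCTAGA",
    "XhoI": "CTCGAG",
}


@dataclass
class IntervalTestResult:
    n_intervals: int
    n_genes: int
    interval_length_kb: float
    n0: int
    n1: int
    n2plus: int
    e0: float
    e1: float
    e2plus: float
    chi2: float
    df: int
    p_value: float
    applicable: bool = True


def interval_clustering_test(
    contigs: Mapping[str, tuple[float, Sequence[float]]],
    n_intervals: int = 1000,
    min_contig_kb: float = 1000.0,
) -> IntervalTestResult:
    """Uniformity test of gene placement over long contigs.

    ``contigs`` maps contig id to ``(length_kb, gene_positions_kb)`` with
    positions relative to the contig start.  Contigs shorter than
    ``min_contig_kb`` are excluded.  The N intervals are apportioned to
    contigs by largest remainder so each contig is cut into equal-length
    pieces and the global interval count is exactly N.  Expected class
    counts under uniformity: ``E0 = N (1 - 1/N)^g``,
    ``E1 = g (1 - 1/N)^(g-1)``, ``E2+ = N - E0 - E1``; the chi-square
    statistic over the three classes has 2 degrees of freedom.
    """
    kept = {
        cid: (L, list(pos))
        for cid, (L, pos) in contigs.items()
        if L > min_contig_kb
    }
    if not kept:
        raise ValueError("no contig exceeds the minimum length")
    total_len = sum(L for L, _ in kept.values())
    g = sum(len(pos) for _, pos in kept.values())

    # largest-remainder apportionment of the N intervals across contigs
    quotas = {cid: n_intervals * L / total_len for cid, (L, _) in kept.items()}
    alloc = {cid: int(math.floor(q)) for cid, q in quotas.items()}
    short = n_intervals - sum(alloc.values())
    for cid in sorted(
        kept, key=lambda c: (-(quotas[c] - alloc[c]), c)
    )[:short]:
        alloc[cid] += 1

    counts = []
    for cid, (L, pos) in kept.items():
        k = max(alloc[cid], 0)
        if k == 0:
            continue
        hist = np.histogram(
            np.clip(pos, 0, L - 1e-9), bins=k, range=(0.0, L)
        )[0]
        counts.append(hist)
    hist = np.concatenate(counts) if counts else np.zeros(0, dtype=int)
    n0 = int(np.sum(hist == 0))
    n1 = int(np.sum(hist == 1))
    n2 = int(np.sum(hist >= 2))

    N = n_intervals
    e0 = N * (1 - 1 / N) ** g
    e1 = g * (1 - 1 / N) ** (g - 1)
    e2 = N - e0 - e1
    if g == 0:
        return IntervalTestResult(
            N, 0, total_len / N, n0, n1, n2, e0, e1, e2,
            0.0, 2, 1.0, applicable=False,
        )
    obs = np.array([n0, n1, n2], dtype=float)
    exp = np.array([e0, e1, e2], dtype=float)
    # a vanishing expected class (tiny g) contributes nothing when observed 0
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(exp > 1e-12, (obs - exp) ** 2 / np.maximum(exp, 1e-12), 0.0)
    stat = float(np.sum(terms))
    return IntervalTestResult(
        N, g, total_len / N, n0, n1, n2, e0, e1, e2,
        stat, 2, float(chi2.sf(stat, 2)),
    )


def detect_gene_islands(
    gene_to_clone: Mapping[str, str],
    graph: nx.Graph,
    cutoff: float | None = None,
) -> tuple[list[list[str]], float]:
    """Gene islands from clone co-occurrence.

    Two genes join the same island when they sit on the same clone or on a
    pair of clones overlapping significantly (Sulston score at most
    ``cutoff``; defaults to the assembly network cutoff).  Islands are the
    connected components with at least two genes of the resulting gene
    graph; the returned fraction is members-in-islands over all genes.
    Results do not depend on gene input order.
    """
    if cutoff is None:
        params = graph.graph.get("params")
        cutoff = params.net_cutoff if params is not None else 1e-15
    log_cut = math.log10(cutoff)
    by_clone: dict[str, list[str]] = {}
    for gid in sorted(gene_to_clone):
        by_clone.setdefault(gene_to_clone[gid], []).append(gid)
    gg = nx.Graph()
    gg.add_nodes_from(gene_to_clone)
    clones = sorted(by_clone)
    for c in clones:
        genes = by_clone[c]
        for a, b in zip(genes, genes[1:]):
            gg.add_edge(a, b)
    for i, c1 in enumerate(clones):
        if not graph.has_node(c1):
            continue
        for c2 in graph.neighbors(c1):
            if c2 <= c1 or c2 not in by_clone:
                continue
            if graph.edges[c1, c2]["log10_score"] <= log_cut:
                gg.add_edge(by_clone[c1][0], by_clone[c2][0])
    islands = [
        sorted(comp) for comp in nx.connected_components(gg) if len(comp) >= 2
    ]
    islands.sort()
    n_member = sum(len(i) for i in islands)
    frac = n_member / len(gene_to_clone) if gene_to_clone else 0.0
    return islands, frac


def density_and_synteny_profile(
    marker_table: pd.DataFrame,
    bin_lengths_mb: Mapping[str, float],
    homology: Mapping[str, Mapping[str, str]] | None = None,
    gene_of_marker: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-bin table: anchored Mb, marker count, density and synteny shares.

    ``marker_table`` needs columns ``marker_id`` and ``bin``;
    ``bin_lengths_mb`` gives the anchored physical length per bin.  When
    per-reference homology labels are supplied, percent-syntenic columns per
    reference and a combined percent-non-syntenic column (no syntenic label
    in any reference) are added.  Densities are rounded to 0.1.  A totals
    row is appended.
    """
    rows = []
    tab = marker_table.dropna(subset=["bin"])
    refs = sorted(homology) if homology else []
    for b, length in bin_lengths_mb.items():
        sub = tab[tab["bin"] == b]
        n = len(sub)
        row = {
            "bin": b,
            "anchored_mb": round(length, 1),
            "n_markers": n,
            "markers_per_mb": round(n / length, 1) if length > 0 else math.nan,
        }
        if length <= 0:
            row["flag"] = "zero_anchored_length"
        if refs:
            genes = [
                gene_of_marker.get(m, m) if gene_of_marker else m
                for m in sub["marker_id"]
            ]
            for r in refs:
                syn = sum(1 for g in genes if homology[r].get(g) == "syntenic")
                row[f"pct_syntenic_{r}"] = round(100.0 * syn / n, 1) if n else math.nan
            non = sum(
                1
                for g in genes
                if all(homology[r].get(g) != "syntenic" for r in refs)
            )
            row["pct_non_syntenic"] = round(100.0 * non / n, 1) if n else math.nan
        rows.append(row)
    total_len = sum(bin_lengths_mb.values())
    n_tot = len(tab[tab["bin"].isin(bin_lengths_mb)])
    total = {
        "bin": "total",
        "anchored_mb": round(total_len, 1),
        "n_markers": n_tot,
        "markers_per_mb": round(n_tot / total_len, 1) if total_len else math.nan,
    }
    rows.append(total)
    return pd.DataFrame(rows)


def _count_motif(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def restriction_profile(
    source: Mapping[str, np.ndarray] | str,
    enzymes: Sequence[str],
    regions: Mapping[str, tuple[float, float]],
    window_kb: float = 100.0,
) -> pd.DataFrame:
    """Restriction-site rates (sites per 100 kb) per enzyme per region.

    ``source`` is either a per-enzyme site map (positions in kb) or a DNA
    sequence string (sites are then motif occurrences; all supported
    recognition sites are palindromic, so one strand suffices and region
    bounds are interpreted in kb of sequence).  Regions are (start_kb,
    end_kb) intervals.
    """
    unknown = [e for e in enzymes if isinstance(source, str) and e not in ENZYME_MOTIFS]
    if unknown:
        raise ValueError(
            f"unknown enzyme(s) {unknown}; supported: {sorted(ENZYME_MOTIFS)}"
        )
    rows = []
    for enz in enzymes:
        if isinstance(source, str):
            motif = ENZYME_MOTIFS[enz]
            positions = []
            start = 0
            while True:
                i = source.find(motif, start)
                if i < 0:
                    break
                positions.append(i / 1000.0)
                start = i + 1
            sites = np.asarray(positions)
        else:
            if enz not in source:
                raise ValueError(
                    f"unknown enzyme {enz!r}; site maps available for "
                    f"{sorted(source)}"
                )
            sites = np.asarray(source[enz])
        for name, (lo, hi) in regions.items():
            span = hi - lo
            n = int(np.sum((sites >= lo) & (sites < hi)))
            rows.append(
                {
                    "enzyme": enz,
                    "region": name,
                    "span_kb": span,
                    "n_sites": n,
                    "sites_per_100kb": 100.0 * n / span if span > 0 else math.nan,
                    "window_kb": window_kb,
                }
            )
    return pd.DataFrame(rows)


def band_count_profile(
    fps,
    clone_regions: Mapping[str, str],
) -> pd.DataFrame:
    """Per-region distribution of fingerprint band counts."""
    rows = []
    for cid, region in clone_regions.items():
        if cid in fps:
            rows.append({"region": region, "clone_id": cid, "n_bands": len(fps[cid])})
    df = pd.DataFrame(rows)
    return (
        df.groupby("region")["n_bands"]
        .agg(["count", "mean", "std", "min", "max"])
        .reset_index()
    )
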