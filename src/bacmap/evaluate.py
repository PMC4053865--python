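"""Truth-based scoring of assemblies built from synthetic libraries.

These helpers compare the inferred structures against the generator's
ground truth: whether clones land in the contig covering their true region,
whether any contig fuses physically distant regions (a chimeric join),
how faithfully the within-contig order reproduces true clone positions,
and whether scaffold junctions connect true neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .assembly import Contig
from .scaffolding import Scaffold
from .synthetic import CloneLibrary

__all__ = [
    "PlacementScore",
    "placement_scores",
    "order_spearman",
    "junction_truth",
]


@dataclass
class PlacementScore:
    n_placed: int
    n_correct: int
    fraction_correct: float
    chimeric_joins: int
    contig_details: list[dict]


def _midpoint(clone) -> float:
    return 0.5 * (clone.start_kb + clone.end_kb)


def placement_scores(
    contigs: Sequence[Contig],
    library: CloneLibrary,
    max_gap_inserts: float = 2.0,
) -> PlacementScore:
    """Fraction of clones placed in the contig matching their true region.

    Within each contig the majority source (target chromosome vs decoy)
    defines the contig's region; a clone is correctly placed when it shares
    that source and is not isolated from the rest of the contig by more
    than ``max_gap_inserts`` mean insert lengths.  A contig exhibits a
    chimeric join when a gap larger than that threshold splits it into two
    groups of at least two clones each (one stray clone is a misplacement,
    not a join).
    """
    truth = library.by_id()
    insert = library.insert_mean_kb
    max_gap = max_gap_inserts * insert
    n_placed = n_correct = joins = 0
    details = []
    for ctg in contigs:
        members = [truth[c] for c in ctg.clones if c in truth]
        srcs = [("target" if m.source != "decoy" else "decoy") for m in members]
        majority = max(set(srcs), key=srcs.count)
        same = sorted(
            (m for m, s in zip(members, srcs) if s == majority),
            key=_midpoint,
        )
        mids = np.array([_midpoint(m) for m in same])
        gaps = np.diff(mids)
        # split into physical groups at oversized gaps
        group_sizes = []
        size = 1
        for gp in gaps:
            if gp > max_gap:
                group_sizes.append(size)
                size = 1
            else:
                size += 1
        group_sizes.append(size)
        big_groups = [s for s in group_sizes if s >= 2]
        contig_joins = max(len(big_groups) - 1, 0)
        joins += contig_joins
        main = max(group_sizes)
        # correct = majority source and member of the dominant physical group
        correct = 0
        start = 0
        for s in group_sizes:
            if s == main:
                correct = s
                break
            start += s
        n_placed += len(members)
        n_correct += correct
        details.append(
            {
                "contig_id": ctg.contig_id,
                "n_clones": len(members),
                "majority_source": majority,
                "n_groups": len(group_sizes),
                "chimeric_joins": contig_joins,
            }
        )
    frac = n_correct / n_placed if n_placed else 0.0
    return PlacementScore(n_placed, n_correct, frac, joins, details)


def order_spearman(contig: Contig, library: CloneLibrary) -> float:
    """|Spearman rho| between inferred rank and true start (orientation-free)."""
    truth = library.by_id()
    ranks, starts = [], []
    for r, c in enumerate(contig.clones):
        cl = truth.get(c)
        if cl is None or cl.source == "decoy":
            continue
        ranks.append(r)
        starts.append(cl.start_kb)
    if len(ranks) < 3:
        return 1.0
    rho = spearmanr(ranks, starts).statistic
    return abs(float(rho)) if np.isfinite(rho) else 0.0


def junction_truth(
    scaffolds: Sequence[Scaffold],
    contigs: Sequence[Contig],
    library: CloneLibrary,
    max_gap_inserts: float = 3.0,
) -> dict:
    """Classify realized scaffold junctions as true or false joins.

    A junction is a true join when the two contigs' true spans (target
    clones only) are within ``max_gap_inserts`` mean inserts of each other.
    """
    truth = library.by_id()
    spans: dict[str, tuple[str, float, float]] = {}
    for c in contigs:
        members = [truth[x] for x in c.clones if x in truth]
        srcs = [("target" if m.source != "decoy" else "decoy") for m in members]
        majority = max(set(srcs), key=srcs.count)
        pos = [
            (m.start_kb, m.end_kb)
            for m, s in zip(members, srcs)
            if s == majority
        ]
        spans[c.contig_id] = (
            majority, min(p[0] for p in pos), max(p[1] for p in pos)
        )
    max_gap = max_gap_inserts * library.insert_mean_kb
    n_true = n_false = 0
    for s in scaffolds:
        for j in s.junctions:
            a, b = spans.get(j.contig_a), spans.get(j.contig_b)
            if a is None or b is None or a[0] != b[0]:
                n_false += 1
                continue
            gap = max(a[1], b[1]) - min(a[2], b[2])
            if gap <= max_gap:
                n_true += 1
            else:
                n_false += 1
    total = n_true + n_false
    return {
        "n_junctions": total,
        "n_true": n_true,
        "n_false": n_false,
        "fraction_true": n_true / total if total else 1.0,
    }
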