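"""Synteny-zipper anchoring: virtual gene order, marker assignment, deletion
bins, colinearity breaks and physical scaling.

A "zipper" is a virtual gene order for the unsequenced chromosome arm,
built from the syntenic gene order of a primary sequenced reference, with
genes that moved out of the primary's syntenic region "zipped in" when both
other references place their homologs there, and with known reference-
lineage inversions reversed back.  Scaffolds carrying gene-derived markers
are placed at the median zipper index of their markers, oriented by the
rank correlation between within-scaffold marker order and zipper order, and
assigned to deletion bins — cytogenetic intervals of the arm that serve as
a coarse physical coordinate system.  Comparing the anchored order against
each reference's homolog positions exposes colinearity breaks (inversions
and transpositions), and the anchored lengths per bin yield the expansion
of the arm relative to the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .scaffolding import Scaffold
from .assembly import Contig
from .synthetic import ReferenceSet, SyntheticChromosome

__all__ = [
    "ZipperEntry",
    "Zipper",
    "Marker",
    "DeletionBin",
    "DeletionBinSet",
    "ScalingInput",
    "AnchoredMap",
    "build_zipper",
    "bins_from_truth",
    "markers_from_truth",
    "anchor_map",
    "detect_colinearity_breaks",
    "scale_expansion",
    "per_bin_expansion",
    "scaffolds_from_contigs",
]

ESTABLISHED_BINS = ("I", "II", "III", "IV", "V")


@dataclass
class ZipperEntry:
    zipper_index: int
    gene_id: str
    positions: dict[str, float]  # reference id -> position where present
    zipped_in: bool = False


@dataclass
class Zipper:
    entries: list[ZipperEntry]
    primary: str

    def __len__(self) -> int:
        return len(self.entries)

    def index_of(self) -> dict[str, int]:
        return {e.gene_id: e.zipper_index for e in self.entries}

    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]


@dataclass
class Marker:
    marker_id: str
    marker_class: str  # EST | SSR | ISBP | UniGene | BES
    clone_hits: list[str]
    contig_id: str | None = None
    zipper_gene: str | None = None
    deletion_bin: str | None = None
    mapping_mode: str = "physical"  # physical | in_silico


@dataclass
class DeletionBin:
    name: str
    established: str  # I..V
    frac_lo: float
    frac_hi: float
    zipper_lo: int | None = None
    zipper_hi: int | None = None


@dataclass
class DeletionBinSet:
    bins: list[DeletionBin]
    bin_of_zipper_index: dict[int, str] = field(default_factory=dict)

    def established_names(self) -> list[str]:
        return [b.established for b in self.bins]


@dataclass(frozen=True)
class ScalingInput:
    coverage_fraction: float
    arm_length_kb: float
    reference_length_kb: float
    segment_length_kb: float

    def __post_init__(self) -> None:
        if not (0 < self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.arm_length_kb <= 0 or self.reference_length_kb <= 0:
            raise ValueError("lengths must be positive")
        if self.segment_length_kb < 0:
            raise ValueError("segment length must be non-negative")


@dataclass
class AnchoredMap:
    scaffold_table: pd.DataFrame
    marker_table: pd.DataFrame
    conflicts: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# zipper


def build_zipper(
    refs: ReferenceSet,
    inversion_interval: tuple[str, str] | None = None,
) -> Zipper:
    """Virtual gene order from the primary reference plus zip-ins.

    The backbone is the primary reference's syntenic gene order.  A gene
    that is not syntenic in the primary but syntenic in *both* other
    references is zipped in at the backbone position interpolated from the
    other references.  When ``inversion_interval=(g1, g2)`` names a known
    inversion of the primary lineage, the zipper order between those genes
    (inclusive) is reversed back.
    """
    primary = refs.primary
    others = [r for r in refs.orders if r != primary]
    backbone = [
        (gid, pos)
        for gid, pos in refs.orders[primary]
        if refs.homology[primary].get(gid) == "syntenic"
    ]
    backbone_ids = [g for g, _ in backbone]
    backbone_pos = {g: p for g, p in backbone}

    # candidate zip-ins: syntenic in both other references, not in backbone
    zip_candidates = []
    for r in others:
        for gid, _ in refs.orders[r]:
            if (
                gid not in backbone_pos
                and all(refs.homology[o].get(gid) == "syntenic" for o in others)
                and gid not in zip_candidates
            ):
                zip_candidates.append(gid)

    # interpolate a primary-scale position for each zip-in from the other refs
    def interp_position(gid: str) -> float:
        ests = []
        for r in others:
            order = refs.orders[r]
            pos_r = {g: p for g, p in order if refs.homology[r].get(g) == "syntenic"}
            if gid not in dict(order):
                continue
            p = dict(order)[gid]
            shared = [(g, q) for g, q in pos_r.items() if g in backbone_pos]
            if not shared:
                continue
            shared.sort(key=lambda t: t[1])
            qs = np.array([q for _, q in shared])
            ps = np.array([backbone_pos[g] for g, _ in shared])
            ests.append(float(np.interp(p, qs, ps)))
        return float(np.mean(ests)) if ests else math.inf

    entries = [(gid, backbone_pos[gid], False) for gid in backbone_ids]
    for gid in zip_candidates:
        p = interp_position(gid)
        if math.isfinite(p):
            entries.append((gid, p, True))
    entries.sort(key=lambda t: (t[1], t[0]))

    # record only syntenic homolog positions: a relocated (non-syntenic)
    # copy is not a colinear anchor
    ordered = [
        ZipperEntry(
            i,
            gid,
            {
                r: dict(refs.orders[r])[gid]
                for r in refs.orders
                if refs.homology[r].get(gid) == "syntenic"
            },
            zipped,
        )
        for i, (gid, _p, zipped) in enumerate(entries)
    ]

    if inversion_interval is not None:
        g1, g2 = inversion_interval
        idx = {e.gene_id: i for i, e in enumerate(ordered)}
        if g1 not in idx or g2 not in idx:
            raise ValueError(
                f"inversion endpoints {g1!r}/{g2!r} absent from the zipper"
            )
        lo, hi = sorted((idx[g1], idx[g2]))
        ordered[lo : hi + 1] = ordered[lo : hi + 1][::-1]
        for i, e in enumerate(ordered):
            e.zipper_index = i
    return Zipper(ordered, primary)


# ---------------------------------------------------------------------------
# deletion bins and markers


def bins_from_truth(
    chrom: SyntheticChromosome,
    zipper: Zipper,
) -> DeletionBinSet:
    """Deletion bins from the chromosome's cytological boundaries.

    The six cytological bins are merged into five established bins (the two
    satellite bins collapse into bin IV), and each zipper entry is assigned
    to the bin containing its true locus, defining the bins' zipper
    intervals.  This plays the role of the EST-based bin-to-zipper mapping
    available for a real arm.
    """
    bounds = chrom.bin_bounds
    if len(bounds) != 7:
        # generic fallback: equal mapping of available bins to labels
        edges = list(bounds)
    else:
        edges = [bounds[0], bounds[1], bounds[2], bounds[3], bounds[5], bounds[6]]
    bins = [
        DeletionBin(f"bin_{ESTABLISHED_BINS[i]}", ESTABLISHED_BINS[i],
                    float(edges[i]), float(edges[i + 1]))
        for i in range(len(edges) - 1)
    ]
    pos_of = {g.gene_id: g.position_kb for g in chrom.genes}
    L = chrom.arm_length_kb
    assign: dict[int, str] = {}
    for e in zipper.entries:
        p = pos_of.get(e.gene_id)
        if p is None:
            continue
        f = p / L
        for b in bins:
            if b.frac_lo <= f < b.frac_hi or (b.frac_hi == 1.0 and f == 1.0):
                assign[e.zipper_index] = b.established
                if b.zipper_lo is None or e.zipper_index < b.zipper_lo:
                    b.zipper_lo = e.zipper_index
                if b.zipper_hi is None or e.zipper_index > b.zipper_hi:
                    b.zipper_hi = e.zipper_index
                break
    return DeletionBinSet(bins, assign)


def markers_from_truth(
    gene_to_clones: Mapping[str, Sequence[str]],
    contig_of_clone: Mapping[str, str],
    zipper: Zipper,
    bins: DeletionBinSet | None = None,
    marker_class: str = "UniGene",
) -> list[Marker]:
    """Gene-derived markers from gene->clone assignments.

    Each gene with at least one clone hit becomes a marker; its contig is
    the contig of its hit clones (markers hitting clones of several contigs
    keep ``contig_id=None`` and are later reported as conflicts); its zipper
    hit is its own gene id when present in the zipper; its bin follows its
    zipper interval.
    """
    zidx = zipper.index_of()
    markers = []
    for gid, hits in gene_to_clones.items():
        hits = [h for h in hits]
        ctgs = {contig_of_clone[h] for h in hits if h in contig_of_clone}
        contig = ctgs.pop() if len(ctgs) == 1 else None
        zg = gid if gid in zidx else None
        dbin = None
        if zg is not None and bins is not None:
            dbin = bins.bin_of_zipper_index.get(zidx[zg])
        markers.append(
            Marker(f"m_{gid}", marker_class, hits, contig, zg, dbin)
        )
    return markers


def scaffolds_from_contigs(contigs: Sequence[Contig]) -> list[Scaffold]:
    """Trivial one-contig scaffolds, for anchoring unmerged assemblies."""
    return [
        Scaffold(f"scf_{c.contig_id}", [(c.contig_id, "+")], [], c.length_kb)
        for c in contigs
    ]


# ---------------------------------------------------------------------------
# anchoring


def anchor_map(
    scaffolds: Sequence[Scaffold],
    markers: Sequence[Marker],
    zipper: Zipper,
    bins: DeletionBinSet,
    contigs: Sequence[Contig],
    arm_length_kb: float | None = None,
    min_markers_orient: int = 3,
    min_abs_rho: float = 0.5,
) -> AnchoredMap:
    """Order, orient and bin scaffolds along the chromosome.

    Scaffold position is the median zipper index of its markers (robust to
    isolated non-syntenic markers); orientation is the sign of the Spearman
    correlation between within-scaffold marker coordinates and zipper index
    (recorded as ``?`` below ``min_abs_rho`` or with fewer than
    ``min_markers_orient`` informative markers).  Bin is per-marker via the
    zipper intervals and per-scaffold by majority; a tied majority flags the
    scaffold instead of placing it.  Scaffolds without zipper-informative
    markers fall back to bin-only markers when available.
    """
    contig_by_id = {c.contig_id: c for c in contigs}
    scaffold_of_contig = {
        cid: s.scaffold_id for s in scaffolds for cid, _ in s.contigs
    }
    zidx = zipper.index_of()

    # coordinate of each clone within its scaffold
    clone_coord: dict[str, tuple[str, float]] = {}
    for s in scaffolds:
        offset = 0.0
        for cid, orient in s.contigs:
            ctg = contig_by_id[cid]
            length = ctg.length_kb
            for clone, start in zip(ctg.clones, ctg.est_start_kb):
                x = start if orient == "+" else length - start
                clone_coord[clone] = (s.scaffold_id, offset + x)
            offset += length

    conflicts: list[str] = []
    marker_rows = []
    per_scaffold: dict[str, list[tuple[float, int | None, str | None]]] = {
        s.scaffold_id: [] for s in scaffolds
    }
    for m in markers:
        scfs = {
            clone_coord[h][0] for h in m.clone_hits if h in clone_coord
        }
        if len(scfs) > 1:
            conflicts.append(
                f"marker {m.marker_id} hits clones in {len(scfs)} scaffolds; excluded"
            )
            continue
        scf = scfs.pop() if scfs else None
        coords = [clone_coord[h][1] for h in m.clone_hits if h in clone_coord]
        coord = float(np.median(coords)) if coords else math.nan
        zi = zidx.get(m.zipper_gene) if m.zipper_gene else None
        marker_rows.append(
            {
                "marker_id": m.marker_id,
                "class": m.marker_class,
                "contig_id": m.contig_id,
                "scaffold_id": scf,
                "coord_kb": coord,
                "zipper_index": zi,
                "bin": m.deletion_bin,
                "mapping_mode": m.mapping_mode,
            }
        )
        if scf is not None:
            per_scaffold[scf].append((coord, zi, m.deletion_bin))

    scaffold_rows = []
    for s in scaffolds:
        info = per_scaffold[s.scaffold_id]
        zis = [zi for _, zi, _ in info if zi is not None]
        coords = [c for c, zi, _ in info if zi is not None and not math.isnan(c)]
        bin_votes: dict[str, int] = {}
        for _, _, b in info:
            if b is not None:
                bin_votes[b] = bin_votes.get(b, 0) + 1
        status = "anchored"
        median_z = float(np.median(zis)) if zis else math.nan
        orient = "?"
        if len(zis) >= min_markers_orient and len(set(zis)) > 1 and len(set(coords)) > 1:
            rho = spearmanr(coords, zis).statistic
            if np.isfinite(rho) and abs(rho) >= min_abs_rho:
                orient = "+" if rho > 0 else "-"
        if bin_votes:
            top = sorted(bin_votes.items(), key=lambda t: (-t[1], t[0]))
            if len(top) > 1 and top[0][1] == top[1][1]:
                status = "bin_conflict"
                sbin = None
            else:
                sbin = top[0][0]
        else:
            sbin = None
        if not zis:
            status = "bin_only" if sbin is not None else "unanchored"
        scaffold_rows.append(
            {
                "scaffold_id": s.scaffold_id,
                "length_kb": s.length_kb,
                "n_markers": len(info),
                "median_zipper": median_z,
                "orientation": orient,
                "bin": sbin,
                "status": status,
            }
        )
    stab = pd.DataFrame(scaffold_rows)
    placed = stab[stab["status"] == "anchored"].sort_values(
        ["median_zipper", "scaffold_id"]
    )
    order_index = {sid: i for i, sid in enumerate(placed["scaffold_id"])}
    stab["order_index"] = stab["scaffold_id"].map(order_index).astype("Int64")
    if arm_length_kb:
        stab = stab.sort_values(
            "order_index", na_position="last", kind="stable"
        ).reset_index(drop=True)
        anchored_mask = stab["order_index"].notna()
        cum = stab.loc[anchored_mask, "length_kb"].cumsum()
        stab.loc[anchored_mask, "end_fraction"] = cum / arm_length_kb
        stab.loc[anchored_mask, "start_fraction"] = (
            (cum - stab.loc[anchored_mask, "length_kb"]) / arm_length_kb
        )
    return AnchoredMap(stab, pd.DataFrame(marker_rows), conflicts)


# ---------------------------------------------------------------------------
# colinearity breaks


@dataclass
class ColinearityBreak:
    start_gene: str
    end_gene: str
    genes: list[str]
    refs: list[str]
    n_refs: int


def detect_colinearity_breaks(
    query_order: Sequence[str],
    refs: ReferenceSet,
    min_run: int = 3,
    min_refs: int = 2,
) -> dict[str, list]:
    """Runs of genes whose inferred order contradicts the reference orders.

    For each reference the homolog positions of the query-ordered syntenic
    genes define steps; a step is discordant when its sign opposes the
    reference's global orientation (sign of the Spearman correlation).  Each
    discordant step marks the query-adjacent gene pairs it spans; maximal
    runs of pairs discordant in at least ``min_refs`` references and
    spanning at least ``min_run`` genes are breaks.  Runs discordant in
    exactly one reference are reported separately, and sub-threshold
    discordant spans (single relocated genes) land in the singleton report.
    """
    n = len(query_order)
    qpos = {g: i for i, g in enumerate(query_order)}
    disc = np.zeros((len(refs.orders), max(n - 1, 0)), dtype=bool)
    eval_ok = np.zeros_like(disc)
    ref_ids = sorted(refs.orders)
    for r_i, r in enumerate(ref_ids):
        pos = {
            g: p for g, p in refs.orders[r] if refs.homology[r].get(g) == "syntenic"
        }
        seq = [(qpos[g], pos[g]) for g in query_order if g in pos]
        if len(seq) < 3:
            continue
        idxs = np.array([i for i, _ in seq])
        vals = np.array([v for _, v in seq])
        rho = spearmanr(idxs, vals).statistic
        sign = 1.0 if (not np.isfinite(rho) or rho >= 0) else -1.0
        steps = np.sign(np.diff(vals)) * sign
        for k, s in enumerate(steps):
            lo, hi = idxs[k], idxs[k + 1]
            eval_ok[r_i, lo:hi] = True
            if s < 0:
                disc[r_i, lo:hi] = True

    n_disc = disc.sum(axis=0)
    multi: list[ColinearityBreak] = []
    single: list[ColinearityBreak] = []
    singletons: list[str] = []

    def runs(mask: np.ndarray):
        out = []
        start = None
        for i, v in enumerate(mask):
            if v and start is None:
                start = i
            elif not v and start is not None:
                out.append((start, i - 1))
                start = None
        if start is not None:
            out.append((start, len(mask) - 1))
        return out

    for lo, hi in runs(n_disc >= min_refs):
        genes = list(query_order[lo : hi + 2])
        which = [
            ref_ids[r_i]
            for r_i in range(len(ref_ids))
            if disc[r_i, lo : hi + 1].any()
        ]
        brk = ColinearityBreak(genes[0], genes[-1], genes, which, len(which))
        if len(genes) >= min_run:
            multi.append(brk)
        else:
            singletons.extend(genes)
    for lo, hi in runs(n_disc == 1):
        genes = list(query_order[lo : hi + 2])
        which = [
            ref_ids[r_i]
            for r_i in range(len(ref_ids))
            if disc[r_i, lo : hi + 1].any()
        ]
        brk = ColinearityBreak(genes[0], genes[-1], genes, which, 1)
        if len(genes) >= min_run:
            single.append(brk)
        else:
            singletons.extend(g for g in genes if g not in singletons)
    return {
        "breaks": multi,
        "single_ref": single,
        "singletons": sorted(set(singletons)),
    }


# ---------------------------------------------------------------------------
# scaling


def scale_expansion(s: ScalingInput) -> float:
    """Wheat physical length corresponding to a reference segment.

    ``L_W = (1 / coverage_fraction) x (L_arm / L_ref) x L_segment``.
    """
    if s.reference_length_kb == 0:
        raise ValueError("reference length must be non-zero")
    return (
        (1.0 / s.coverage_fraction)
        * (s.arm_length_kb / s.reference_length_kb)
        * s.segment_length_kb
    )


def per_bin_expansion(
    anchored: AnchoredMap,
    bins: DeletionBinSet,
    zipper: Zipper,
    reference: str,
) -> dict[str, float]:
    """Anchored wheat kb per reference kb, per deletion bin.

    The wheat side sums the lengths of scaffolds assigned to the bin; the
    reference side is the position span of the bin's zipper interval in the
    given reference.  Bins whose reference interval is degenerate are
    skipped.
    """
    stab = anchored.scaffold_table
    out: dict[str, float] = {}
    for b in bins.bins:
        if b.zipper_lo is None or b.zipper_hi is None:
            continue
        entries = [
            e
            for e in zipper.entries
            if b.zipper_lo <= e.zipper_index <= b.zipper_hi
            and reference in e.positions
        ]
        if len(entries) < 2:
            continue
        ref_span = max(e.positions[reference] for e in entries) - min(
            e.positions[reference] for e in entries
        )
        if ref_span <= 0:
            continue
        wheat = float(
            stab.loc[stab["bin"] == b.established, "length_kb"].sum()
        )
        out[b.established] = wheat / ref_span
    return out
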