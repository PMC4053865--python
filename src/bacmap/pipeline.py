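"""Stage-wise pipeline binding simulation, assembly, scaffolding, pooling,
anchoring and gene-space analysis, with serialized artifacts per stage.

Each stage consumes the previous stage's files from the output directory,
so stages can be re-run individually (see :mod:`bacmap.cli`).  A run
serializes its resolved configuration and a summary report next to its
outputs; every random stage derives its generator from the global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .assembly import (
    AssemblyParams,
    assemble_contigs,
    assembly_partition,
    build_overlap_graph,
    detect_questionable,
)
from .anchoring import (
    anchor_map,
    bins_from_truth,
    build_zipper,
    markers_from_truth,
    per_bin_expansion,
)
from .evaluate import junction_truth, order_spearman, placement_scores
from .fingerprints import ScoreParams
from .genespace import (
    band_count_profile,
    detect_gene_islands,
    interval_clustering_test,
    restriction_profile,
)
from .pools import deconvolve_pools
from .scaffolding import assembly_metrics, merge_into_scaffolds, select_mtp
from .synthetic import (
    PoolNoise,
    SimulationConfig,
    genes_to_clones,
    simulate_chromosome,
    simulate_clone_library,
    simulate_decoy_chromosome,
    simulate_fingerprints,
    simulate_pool_signals,
    simulate_references,
)

log = logging.getLogger("bacmap")

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    pool_noise: PoolNoise = field(default_factory=PoolNoise)
    mtp_cutoff: float = 1e-25
    margin_orders: float = 5.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed != self.simulation.seed:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        allowed = {
            "simulation": [f.name for f in dataclasses.fields(SimulationConfig)],
            "assembly": [f.name for f in dataclasses.fields(AssemblyParams)],
            "score": [f.name for f in dataclasses.fields(ScoreParams)],
            "pool_noise": [f.name for f in dataclasses.fields(PoolNoise)],
            "mtp_cutoff": [],
            "margin_orders": [],
            "seed": [],
            "log_level": [],
        }
        data = bio.load_yaml_config(path, allowed)
        kwargs = {}
        for section, klass in (
            ("simulation", SimulationConfig),
            ("assembly", AssemblyParams),
            ("score", ScoreParams),
            ("pool_noise", PoolNoise),
        ):
            if section in data:
                sec = data[section] or {}
                if "island_size_range" in sec:
                    sec["island_size_range"] = tuple(sec["island_size_range"])
                if "insert_range_kb" in sec:
                    sec["insert_range_kb"] = tuple(sec["insert_range_kb"])
                if "syntenic_retention" in sec:
                    sec["syntenic_retention"] = tuple(sec["syntenic_retention"])
                kwargs[section] = klass(**sec)
        for key in ("mtp_cutoff", "margin_orders", "seed", "log_level"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(outdir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage {stage!r} is missing input(s) {missing}; "
            "run the producing stage first"
        )


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim = cfg.simulation
    chrom = simulate_chromosome(sim)
    decoy = simulate_decoy_chromosome(sim)
    library = simulate_clone_library(chrom, sim, decoy)
    fps = simulate_fingerprints(library, chrom, sim, decoy, cfg.score)
    refs = simulate_references(chrom, sim)
    bio.write_genes_bed(chrom, outdir / "genes.bed")
    bio.write_site_maps(chrom, outdir / "site_maps.tsv")
    bio.write_clone_truth(library, outdir / "clone_truth.tsv")
    bio.write_bands(fps, outdir / "bands.txt")
    np.save(outdir / "bin_bounds.npy", chrom.bin_bounds, allow_pickle=False)
    # references and genes, serialized as JSON-friendly structures
    (outdir / "references.json").write_text(
        json.dumps(
            {
                "orders": refs.orders,
                "homology": refs.homology,
                "inversions": refs.inversion_intervals,
                "primary": refs.primary,
            }
        )
    )
    (outdir / "genes.json").write_text(
        json.dumps(
            [
                {"gene_id": g.gene_id, "position_kb": g.position_kb,
                 "island_id": g.island_id}
                for g in chrom.genes
            ]
        )
    )
    log.info("simulate: %d clones, %d genes", len(library), len(chrom.genes))


def _load_chrom(outdir: Path, sim: SimulationConfig):
    from .synthetic import Gene, SyntheticChromosome

    sm = pd.read_csv(outdir / "site_maps.tsv", sep="\t")
    site_maps = {
        enz: np.sort(grp["position_kb"].to_numpy())
        for enz, grp in sm.groupby("enzyme")
    }
    genes = [
        Gene(d["gene_id"], d["position_kb"], d["island_id"])
        for d in json.loads((outdir / "genes.json").read_text())
    ]
    bounds = np.load(outdir / "bin_bounds.npy")
    return SyntheticChromosome(site_maps, genes, bounds, sim.arm_length_kb)


def _load_refs(outdir: Path):
    from .synthetic import ReferenceSet

    d = json.loads((outdir / "references.json").read_text())
    orders = {
        r: [(g, float(p)) for g, p in v] for r, v in d["orders"].items()
    }
    inversions = {
        r: [tuple(pair) for pair in v] for r, v in d["inversions"].items()
    }
    return ReferenceSet(orders, d["homology"], inversions, d["primary"])


def stage_assemble(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "assemble", "bands.txt")
    fps = bio.read_bands(outdir / "bands.txt")
    graph = build_overlap_graph(
        fps, cfg.assembly, cfg.score, cfg.simulation.insert_mean_kb
    )
    graph.graph["insert_mean_kb"] = cfg.simulation.insert_mean_kb
    detect_questionable(graph, cfg.assembly)
    contigs = assemble_contigs(graph, cfg.assembly)
    bio.write_graph(graph, outdir / "graph_edges.tsv", outdir / "graph_nodes.tsv")
    bio.write_contigs(contigs, outdir / "contigs.tsv")
    bio.write_fpc_ctg(contigs, outdir / "contigs.fpc")
    part = assembly_partition(graph, contigs)
    (outdir / "assembly_partition.json").write_text(json.dumps(part))
    log.info("assemble: %d contigs", len(contigs))


def stage_mtp(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "mtp", "contigs.tsv", "graph_edges.tsv")
    graph = bio.read_graph(outdir / "graph_edges.tsv", outdir / "graph_nodes.tsv")
    graph.graph["params"] = cfg.assembly
    contigs = bio.read_contigs(outdir / "contigs.tsv")
    rows = []
    for c in contigs:
        mtp = select_mtp(c, graph, cfg.mtp_cutoff)
        for k, clone in enumerate(mtp.clones):
            rows.append({"contig_id": c.contig_id, "order": k, "clone_id": clone,
                         "auxiliary": False})
        for clone in mtp.auxiliary:
            rows.append({"contig_id": c.contig_id, "order": -1, "clone_id": clone,
                         "auxiliary": True})
    pd.DataFrame(rows).to_csv(outdir / "mtp.tsv", sep="\t", index=False)
    log.info("mtp: %d clones", len(rows))


def stage_scaffold(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "scaffold", "contigs.tsv", "graph_edges.tsv")
    graph = bio.read_graph(outdir / "graph_edges.tsv", outdir / "graph_nodes.tsv")
    graph.graph["params"] = cfg.assembly
    graph.graph["kb_per_band"] = _kb_per_band(cfg, graph)
    graph.graph["insert_mean_kb"] = cfg.simulation.insert_mean_kb
    contigs = _contigs_with_lengths(outdir, graph)
    scaffolds = merge_into_scaffolds(
        contigs, graph, cfg.margin_orders, cfg.assembly.net_cutoff, cfg.mtp_cutoff,
        cfg.assembly.min_parallel,
    )
    rows = []
    for s in scaffolds:
        for k, (cid, orient) in enumerate(s.contigs):
            rows.append({"scaffold_id": s.scaffold_id, "order": k,
                         "contig_id": cid, "orientation": orient,
                         "length_kb": round(s.length_kb, 1)})
    pd.DataFrame(rows).to_csv(outdir / "scaffolds.tsv", sep="\t", index=False)
    jrows = [
        {
            "scaffold_id": s.scaffold_id,
            "contig_a": j.contig_a, "side_a": j.side_a,
            "contig_b": j.contig_b, "side_b": j.side_b,
            "log10_score": round(j.log10_score, 2),
            "bridge_clone": j.bridge_clone or "",
            "clone_a": j.clone_pair[0], "clone_b": j.clone_pair[1],
            "validation": j.validation, "n_connections": j.n_connections,
        }
        for s in scaffolds
        for j in s.junctions
    ]
    pd.DataFrame(
        jrows,
        columns=["scaffold_id", "contig_a", "side_a", "contig_b", "side_b",
                 "log10_score", "bridge_clone", "clone_a", "clone_b",
                 "validation", "n_connections"],
    ).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    bio.write_agp(scaffolds, contigs, outdir / "scaffolds.agp",
                  cfg.simulation.insert_mean_kb)
    log.info("scaffold: %d scaffolds", len(scaffolds))


def _kb_per_band(cfg: PipelineConfig, graph) -> float:
    n_bands = [d["n_bands"] for _, d in graph.nodes(data=True) if d["n_bands"] > 0]
    mean_bands = float(np.mean(n_bands)) if n_bands else 1.0
    return cfg.simulation.insert_mean_kb / max(mean_bands, 1.0)


def _contigs_with_lengths(outdir: Path, graph):
    from .assembly import order_clones

    contigs = bio.read_contigs(outdir / "contigs.tsv")
    out = []
    for c in contigs:
        kb_per_band = graph.graph.get("kb_per_band", 1.0)
        # recompute band-based coordinates so lengths are available
        oc = order_clones(c.clones, graph, kb_per_band)
        oc.contig_id = c.contig_id
        # keep the serialized order (order_clones may flip orientation)
        if oc.clones != c.clones and oc.clones[::-1] == c.clones:
            oc.clones = c.clones
            oc.est_start_kb = [oc.est_start_kb[-1] - s for s in reversed(oc.est_start_kb)]
        out.append(oc)
    return out


def stage_pools(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "pools", "clone_truth.tsv", "mtp.tsv", "genes.json")
    sim = cfg.simulation
    library = bio.read_clone_truth(outdir / "clone_truth.tsv", sim.insert_mean_kb)
    chrom = _load_chrom(outdir, sim)
    mtp = pd.read_csv(outdir / "mtp.tsv", sep="\t")
    mtp_ids = sorted(set(mtp["clone_id"]))
    g2c = genes_to_clones(chrom, library, mtp_ids)
    signals, design = simulate_pool_signals(
        library, mtp_ids, g2c, cfg.pool_noise, sim
    )
    pd.DataFrame(
        signals.intensities, index=signals.pool_ids, columns=signals.probe_ids
    ).to_csv(outdir / "pool_signals.tsv", sep="\t")
    graph = bio.read_graph(outdir / "graph_edges.tsv", outdir / "graph_nodes.tsv")
    calls = deconvolve_pools(signals, design, mtp_ids, graph=graph)
    rows = [
        {
            "probe_id": c.probe_id,
            "status": c.status,
            "n_positive_pools": c.n_positive_pools,
            "clones": ";".join(c.clone_ids),
            "plate": c.addresses[0][0] if c.addresses else "",
            "row": c.addresses[0][1] if c.addresses else "",
            "column": c.addresses[0][2] if c.addresses else "",
            "llr": round(c.llr, 2),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(outdir / "pool_calls.tsv", sep="\t", index=False)
    log.info(
        "pools: %d probes, %d resolved",
        len(calls),
        sum(c.status != "unresolved" for c in calls),
    )


def stage_anchor(cfg: PipelineConfig, outdir: Path) -> None:
    _require(
        outdir, "anchor",
        "contigs.tsv", "scaffolds.tsv", "references.json", "pool_calls.tsv",
    )
    sim = cfg.simulation
    graph = bio.read_graph(outdir / "graph_edges.tsv", outdir / "graph_nodes.tsv")
    graph.graph["params"] = cfg.assembly
    graph.graph["kb_per_band"] = _kb_per_band(cfg, graph)
    contigs = _contigs_with_lengths(outdir, graph)
    refs = _load_refs(outdir)
    chrom = _load_chrom(outdir, sim)
    inv = refs.inversion_intervals.get(refs.primary) or [None]
    zipper = build_zipper(refs, inv[0])
    bins = bins_from_truth(chrom, zipper)
    bio.write_zipper(zipper, outdir / "zipper.tsv")

    calls = pd.read_csv(outdir / "pool_calls.tsv", sep="\t")
    contig_of = {
        clone: c.contig_id for c in contigs for clone in c.clones
    }
    g2c = {}
    for r in calls.itertuples(index=False):
        if r.status == "unresolved" or not isinstance(r.clones, str) or not r.clones:
            continue
        g2c[r.probe_id] = r.clones.split(";")
    markers = markers_from_truth(g2c, contig_of, zipper, bins)

    scaffolds = _load_scaffolds(outdir, contigs)
    amap = anchor_map(
        scaffolds, markers, zipper, bins, contigs, sim.arm_length_kb
    )
    amap.scaffold_table.to_csv(outdir / "anchored_scaffolds.tsv", sep="\t", index=False)
    amap.marker_table.to_csv(outdir / "anchored_markers.tsv", sep="\t", index=False)
    expansion = per_bin_expansion(amap, bins, zipper, refs.primary)
    (outdir / "expansion.json").write_text(json.dumps(expansion))
    log.info("anchor: %d markers, %d scaffolds", len(markers), len(scaffolds))


def _load_scaffolds(outdir: Path, contigs):
    from .scaffolding import Scaffold

    df = pd.read_csv(outdir / "scaffolds.tsv", sep="\t")
    length = {}
    out = []
    for sid, grp in df.groupby("scaffold_id", sort=True):
        grp = grp.sort_values("order")
        out.append(
            Scaffold(
                str(sid),
                list(zip(grp["contig_id"], grp["orientation"])),
                [],
                float(grp["length_kb"].iloc[0]),
            )
        )
    return out


def stage_genespace(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(
        outdir, "genespace",
        "contigs.tsv", "pool_calls.tsv", "anchored_markers.tsv",
        "anchored_scaffolds.tsv", "site_maps.tsv",
    )
    sim = cfg.simulation
    graph = bio.read_graph(outdir / "graph_edges.tsv", outdir / "graph_nodes.tsv")
    graph.graph["params"] = cfg.assembly
    graph.graph["kb_per_band"] = _kb_per_band(cfg, graph)
    contigs = _contigs_with_lengths(outdir, graph)
    calls = pd.read_csv(outdir / "pool_calls.tsv", sep="\t")

    # unique-address genes on contigs: the transcriptional map
    contig_of = {clone: c.contig_id for c in contigs for clone in c.clones}
    start_of = {
        clone: c.est_start_kb[k]
        for c in contigs
        for k, clone in enumerate(c.clones)
    }
    g2clone = {}
    for r in calls.itertuples(index=False):
        if r.status != "unambiguous" or not isinstance(r.clones, str):
            continue
        g2clone[r.probe_id] = r.clones.split(";")[0]

    per_contig: dict[str, tuple[float, list[float]]] = {
        c.contig_id: (c.length_kb, []) for c in contigs
    }
    for gid, clone in g2clone.items():
        cid = contig_of.get(clone)
        if cid is not None:
            per_contig[cid][1].append(start_of[clone])
    try:
        itest = interval_clustering_test(per_contig)
        itest_out = dataclasses.asdict(itest)
    except ValueError as exc:
        itest_out = {"applicable": False, "reason": str(exc)}

    islands, frac = detect_gene_islands(g2clone, graph)

    chrom = _load_chrom(outdir, sim)
    L = sim.arm_length_kb
    regions = {
        "centromeric_fifth": (0.0, 0.2 * L),
        "telomeric_fifth": (0.8 * L, L),
    }
    rprof = restriction_profile(
        chrom.site_maps, sorted(chrom.site_maps), regions
    )
    rprof.to_csv(outdir / "restriction_profile.tsv", sep="\t", index=False)

    fps = bio.read_bands(outdir / "bands.txt")
    library = bio.read_clone_truth(outdir / "clone_truth.tsv", sim.insert_mean_kb)
    clone_regions = {}
    for c in library.clones:
        if c.source == "decoy":
            continue
        mid = 0.5 * (c.start_kb + c.end_kb)
        if mid < 0.2 * L:
            clone_regions[c.clone_id] = "centromeric_fifth"
        elif mid >= 0.8 * L:
            clone_regions[c.clone_id] = "telomeric_fifth"
    bprof = band_count_profile(fps, clone_regions)
    bprof.to_csv(outdir / "band_count_profile.tsv", sep="\t", index=False)

    report = {
        "interval_test": itest_out,
        "n_islands": len(islands),
        "fraction_in_islands": frac,
        "n_unique_address_genes": len(g2clone),
    }
    (outdir / "genespace.json").write_text(json.dumps(report, indent=2))
    return report


def stage_summary(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(outdir, "summary", "contigs.tsv", "scaffolds.tsv", "clone_truth.tsv")
    sim = cfg.simulation
    graph = bio.read_graph(outdir / "graph_edges.tsv", outdir / "graph_nodes.tsv")
    graph.graph["params"] = cfg.assembly
    graph.graph["kb_per_band"] = _kb_per_band(cfg, graph)
    contigs = _contigs_with_lengths(outdir, graph)
    library = bio.read_clone_truth(outdir / "clone_truth.tsv", sim.insert_mean_kb)
    sdf = pd.read_csv(outdir / "scaffolds.tsv", sep="\t")
    scaffold_lengths = sdf.groupby("scaffold_id")["length_kb"].first().tolist()
    cm = assembly_metrics(
        [c.length_kb for c in contigs],
        sim.arm_length_kb,
        [len(c) for c in contigs],
    )
    sm = assembly_metrics(scaffold_lengths, sim.arm_length_kb)
    placement = placement_scores(contigs, library)
    rhos = [order_spearman(c, library) for c in contigs if len(c) >= 10]
    genespace = (
        json.loads((outdir / "genespace.json").read_text())
        if (outdir / "genespace.json").exists()
        else {}
    )
    summary = {
        "seed": cfg.seed,
        "n_clones": len(library),
        "contigs": dataclasses.asdict(cm),
        "scaffolds": dataclasses.asdict(sm),
        "placement_fraction_correct": placement.fraction_correct,
        "chimeric_joins": placement.chimeric_joins,
        "mean_order_spearman": float(np.mean(rhos)) if rhos else None,
        "genespace": genespace,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


STAGES = {
    "simulate": stage_simulate,
    "assemble": stage_assemble,
    "mtp": stage_mtp,
    "scaffold": stage_scaffold,
    "pools": stage_pools,
    "anchor": stage_anchor,
    "genespace": stage_genespace,
}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order and return the summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
    for name, fn in STAGES.items():
        log.info("stage %s", name)
        try:
            fn(cfg, outdir)
        except Exception:
            log.error("stage %s failed", name)
            raise
    return stage_summary(cfg, outdir)
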