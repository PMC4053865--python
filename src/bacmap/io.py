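"""File formats: band files, truth tables, BED/AGP/FASTA exports, configs.

Band files come in two dialects: the native format (one record per clone:
a ``>clone_id n_bands`` header line followed by whitespace-separated
integer bands) and the FPC ``.sizes`` layout (clone name and band count on
one line, one band per line, each record terminated by ``-1``).  Reading
auto-detects the dialect; write-then-read is the identity on band content.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fingerprints import Fingerprint, FingerprintSet
from .synthetic import Clone, CloneLibrary, SyntheticChromosome
from .assembly import Contig
from .scaffolding import Scaffold
from .genespace import ENZYME_MOTIFS

log = logging.getLogger("bacmap")

__all__ = [
    "read_bands",
    "write_bands",
    "write_genes_bed",
    "write_site_maps",
    "write_clone_truth",
    "read_clone_truth",
    "write_contigs",
    "read_contigs",
    "write_fpc_ctg",
    "write_graph",
    "read_graph",
    "write_agp",
    "write_zipper",
    "emit_fasta",
    "load_yaml_config",
]


# ---------------------------------------------------------------------------
# band files


def write_bands(
    fps: FingerprintSet, path: str | Path, dialect: str = "native"
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if dialect == "native":
            for cid in fps:
                bands = fps[cid].bands
                fh.write(f">{cid} {bands.size}\n")
                fh.write(" ".join(str(int(b)) for b in bands) + "\n")
        elif dialect == "sizes":
            for cid in fps:
                bands = fps[cid].bands
                fh.write(f"{cid} {bands.size}\n")
                for b in bands:
                    fh.write(f"{int(b)}\n")
                fh.write("-1\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_bands(path: str | Path) -> FingerprintSet:
    """Read a band file, auto-detecting the dialect.

    Malformed records are reported with their line number; bands that
    arrive unsorted are sorted with a warning.
    """
    path = Path(path)
    text = path.read_text().strip()
    fps = FingerprintSet()
    if not text:
        log.warning("%s: empty band file", path)
        return fps
    lines = text.splitlines()
    if lines[0].lstrip().startswith(">"):
        i = 0
        while i < len(lines):
            header = lines[i].strip()
            if not header:
                i += 1
                continue
            if not header.startswith(">"):
                raise ValueError(f"{path}:{i + 1}: expected '>' header")
            parts = header[1:].split()
            cid = parts[0]
            declared = int(parts[1]) if len(parts) > 1 else None
            i += 1
            vals: list[int] = []
            while i < len(lines) and not lines[i].lstrip().startswith(">"):
                for tok in lines[i].split():
                    try:
                        vals.append(int(tok))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{i + 1}: non-integer band {tok!r}"
                        ) from exc
                i += 1
            if declared is not None and declared != len(vals):
                log.warning(
                    "%s: clone %s declares %d bands, found %d",
                    path, cid, declared, len(vals),
                )
            arr = np.asarray(vals, dtype=np.int64)
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                log.warning("%s: clone %s bands unsorted; sorting", path, cid)
                arr = np.sort(arr)
            fps.add(Fingerprint(cid, arr))
    else:  # FPC .sizes
        i = 0
        while i < len(lines):
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected 'name count'")
            cid, declared = parts[0], int(parts[1])
            i += 1
            vals = []
            while i < len(lines):
                tok = lines[i].strip()
                i += 1
                if tok == "-1":
                    break
                try:
                    vals.append(int(tok))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{i}: non-integer band {tok!r}"
                    ) from exc
            if declared != len(vals):
                log.warning(
                    "%s: clone %s declares %d bands, found %d",
                    path, cid, declared, len(vals),
                )
            arr = np.asarray(vals, dtype=np.int64)
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                log.warning("%s: clone %s bands unsorted; sorting", path, cid)
                arr = np.sort(arr)
            fps.add(Fingerprint(cid, arr))
    return fps


# ---------------------------------------------------------------------------
# truth tables and positional exports


def write_genes_bed(chrom: SyntheticChromosome, path: str | Path, name: str = "arm") -> None:
    with Path(path).open("w") as fh:
        for g in chrom.genes:
            start = int(g.position_kb * 1000)
            fh.write(f"{name}\t{start}\t{start + 1}\t{g.gene_id}\n")


def write_site_maps(chrom: SyntheticChromosome, path: str | Path) -> None:
    rows = []
    for enz, sites in chrom.site_maps.items():
        for s in sites:
            rows.append((enz, float(s)))
    pd.DataFrame(rows, columns=["enzyme", "position_kb"]).to_csv(
        path, sep="\t", index=False
    )


def write_clone_truth(library: CloneLibrary, path: str | Path) -> None:
    rows = [
        {
            "clone_id": c.clone_id,
            "source": c.source,
            "start_kb": c.start_kb,
            "end_kb": c.end_kb,
            "start2_kb": c.start2_kb,
            "end2_kb": c.end2_kb,
            "plate": c.plate,
            "row": c.row,
            "column": c.column,
        }
        for c in library.clones
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clone_truth(path: str | Path, insert_mean_kb: float = 113.0) -> CloneLibrary:
    df = pd.read_csv(path, sep="\t")
    clones = []
    for r in df.itertuples(index=False):
        clones.append(
            Clone(
                r.clone_id,
                r.source,
                float(r.start_kb),
                float(r.end_kb),
                None if pd.isna(r.start2_kb) else float(r.start2_kb),
                None if pd.isna(r.end2_kb) else float(r.end2_kb),
                int(r.plate),
                int(r.row),
                int(r.column),
            )
        )
    return CloneLibrary(clones, insert_mean_kb)


def write_contigs(contigs: Sequence[Contig], path: str | Path) -> None:
    rows = []
    for c in contigs:
        for rank, (clone, start) in enumerate(zip(c.clones, c.est_start_kb)):
            rows.append(
                {
                    "contig_id": c.contig_id,
                    "rank": rank,
                    "clone_id": clone,
                    "est_start_kb": round(start, 2),
                    "linearity": c.linearity_status,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contigs(path: str | Path) -> list[Contig]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, grp in df.groupby("contig_id", sort=True):
        grp = grp.sort_values("rank")
        c = Contig(
            str(cid),
            grp["clone_id"].tolist(),
            est_start_kb=grp["est_start_kb"].tolist(),
            linearity_status=str(grp["linearity"].iloc[0]),
        )
        out.append(c)
    out.sort(key=lambda c: c.contig_id)
    return out


def write_fpc_ctg(contigs: Sequence[Contig], path: str | Path) -> None:
    """FPC-style CTG blocks with approximate clone coordinates (band units)."""
    with Path(path).open("w") as fh:
        for c in contigs:
            fh.write(f"Ctg{c.contig_id}\n")
            starts = c.est_start_bands or c.est_start_kb
            for clone, start in zip(c.clones, starts):
                fh.write(
                    f"BAC : \"{clone}\" Map \"ctg\" Ends Left {start:.0f} "
                    f"Right {start:.0f}\n"
                )
            fh.write("\n")


def write_graph(graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    e_rows = [
        {
            "clone_a": a,
            "clone_b": b,
            "log10_score": d["log10_score"],
            "shared": d["shared"],
            "parallel_support": d["parallel_support"],
            "q_flag": d["q_flag"],
        }
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(
        e_rows,
        columns=[
            "clone_a", "clone_b", "log10_score", "shared",
            "parallel_support", "q_flag",
        ],
    ).to_csv(edges_path, sep="\t", index=False)
    n_rows = [
        {
            "clone_id": n,
            "n_bands": d["n_bands"],
            "q_flag": d["q_flag"],
            "q_reasons": ";".join(d["q_reasons"]),
        }
        for n, d in graph.nodes(data=True)
    ]
    pd.DataFrame(n_rows).to_csv(nodes_path, sep="\t", index=False)


def read_graph(edges_path: str | Path, nodes_path: str | Path):
    import networkx as nx

    g = nx.Graph()
    nodes = pd.read_csv(nodes_path, sep="\t")
    for r in nodes.itertuples(index=False):
        reasons = [] if pd.isna(r.q_reasons) or not r.q_reasons else str(r.q_reasons).split(";")
        g.add_node(r.clone_id, n_bands=int(r.n_bands), q_flag=bool(r.q_flag),
                   q_reasons=reasons)
    edges = pd.read_csv(edges_path, sep="\t")
    for r in edges.itertuples(index=False):
        g.add_edge(
            r.clone_a, r.clone_b,
            log10_score=float(r.log10_score), shared=int(r.shared),
            parallel_support=int(r.parallel_support), q_flag=bool(r.q_flag),
        )
    return g


def write_agp(
    scaffolds: Sequence[Scaffold],
    contigs: Sequence[Contig],
    path: str | Path,
    gap_kb: float = 113.0,
) -> None:
    """AGP v2.1 export: contigs as W components, bridge joins as gaps."""
    length = {c.contig_id: max(c.length_kb, 1.0) for c in contigs}
    with Path(path).open("w") as fh:
        fh.write("##agp-version\t2.1\n")
        for s in scaffolds:
            pos = 0
            part = 0
            for k, (cid, orient) in enumerate(s.contigs):
                if k > 0:
                    j = s.junctions[k - 1] if k - 1 < len(s.junctions) else None
                    if j is not None and j.bridge_clone is not None:
                        part += 1
                        gap = int(gap_kb * 1000)
                        fh.write(
                            f"{s.scaffold_id}\t{pos + 1}\t{pos + gap}\t{part}\t"
                            f"N\t{gap}\tscaffold\tyes\tclone_contig\n"
                        )
                        pos += gap
                part += 1
                span = int(length[cid] * 1000)
                fh.write(
                    f"{s.scaffold_id}\t{pos + 1}\t{pos + span}\t{part}\t"
                    f"W\t{cid}\t1\t{span}\t{orient}\n"
                )
                pos += span


def write_zipper(zipper, path: str | Path) -> None:
    rows = []
    for e in zipper.entries:
        row = {"zipper_index": e.zipper_index, "gene_id": e.gene_id,
               "zipped_in": e.zipped_in}
        for r, p in e.positions.items():
            row[f"pos_{r}"] = round(p, 3)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA realization of a site map


def emit_fasta(
    chrom: SyntheticChromosome,
    path: str | Path,
    bp_per_kb: int = 1000,
    seed: int = 0,
    name: str = "arm",
) -> str:
    """Emit a concrete sequence realizing the chromosome's site maps.

    Recognition motifs are implanted at each mapped site position (scaled
    by ``bp_per_kb``); spurious motif occurrences in the random background
    are destroyed so that motif counts match site counts.  Sites of
    different enzymes closer than one motif length collide and the
    overwritten site is lost from the realization (a few percent at dense
    maps).  Returns the sequence.  Intended for small/scaled chromosomes; a
    full-scale arm would be hundreds of Mb of sequence.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    n = int(chrom.arm_length_kb * bp_per_kb) + 8
    seq = rng.choice(np.array(list("ACGT")), size=n)
    motifs = {e: m for e, m in ENZYME_MOTIFS.items() if e in chrom.site_maps}

    arr = list("".join(seq))
    implant_mask = np.zeros(n, dtype=bool)
    for enz, sites in chrom.site_maps.items():
        if enz not in motifs:
            continue
        m = motifs[enz]
        for s in sites:
            i = int(s * bp_per_kb)
            arr[i : i + len(m)] = m
            implant_mask[i : i + len(m)] = True
    # destroy spurious occurrences by mutating a base outside any implant
    for _ in range(6):
        text = "".join(arr)
        dirty = False
        for m in motifs.values():
            start = 0
            while True:
                i = text.find(m, start)
                if i < 0:
                    break
                if not (
                    implant_mask[i : i + len(m)].all()
                ):  # not an implanted site
                    for k in range(i, i + len(m)):
                        if not implant_mask[k]:
                            arr[k] = "A" if arr[k] != "A" else "C"
                            dirty = True
                            break
                start = i + 1
        if not dirty:
            break
    text = "".join(arr)
    rec = SeqRecord(Seq(text), id=name, description="synthetic realization")
    SeqIO.write([rec], str(path), "fasta")
    return text


# ---------------------------------------------------------------------------
# configuration


def load_yaml_config(path: str | Path, allowed: Mapping[str, Iterable[str]]) -> dict:
    """Load a nested YAML config, rejecting unknown sections or keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    for section, content in data.items():
        if section not in allowed:
            raise ValueError(f"unknown config section {section!r}")
        if isinstance(content, dict):
            bad = set(content) - set(allowed[section])
            if bad:
                raise ValueError(
                    f"unknown keys in section {section!r}: {sorted(bad)}"
                )
    return data
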