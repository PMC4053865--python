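"""Simulate a scaled chromosome arm, fingerprint its BAC library and
assemble linear-topology contigs, then score the result against truth.

Uses a 3 Mb arm (1:100 of a wheat-arm-sized chromosome) so it runs in a
few seconds; the statistical structure (14x coverage, 0.81 purity,
fingerprint noise, chimeras) matches the full-scale defaults.
"""

from bacmap import SimulationConfig, assemble_contigs, build_overlap_graph, detect_questionable
from bacmap.evaluate import order_spearman, placement_scores
from bacmap.synthetic import simulate_chromosome, simulate_clone_library, simulate_fingerprints

cfg = SimulationConfig(arm_length_kb=3000.0, n_genes=40, n_clones=400, seed=1)
chrom = simulate_chromosome(cfg)
library = simulate_clone_library(chrom, cfg)
fps = simulate_fingerprints(library, chrom, cfg)
print(f"{len(library)} clones, mean insert {library.mean_insert_kb:.1f} kb")

graph = build_overlap_graph(fps, insert_mean_kb=cfg.insert_mean_kb)
flags = detect_questionable(graph)
print(f"overlap network: {graph.number_of_edges()} significant overlaps, "
      f"{len(flags['q_clones'])} Q-clones, {len(flags['q_overlaps'])} Q-overlaps")

contigs = assemble_contigs(graph)
print(f"{len(contigs)} contigs; largest holds {len(contigs[0])} clones, "
      f"estimated {contigs[0].length_kb:.0f} kb")

scores = placement_scores(contigs, library)
rho = max(order_spearman(c, library) for c in contigs if len(c) >= 10)
print(f"{100 * scores.fraction_correct:.1f}% of placed clones sit in their "
      f"true region; {scores.chimeric_joins} chimeric joins; "
      f"best per-contig order |rho| = {rho:.3f}")
# Q-clones are parked, never deleted: the scaffolding stage reuses them.
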