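"""Benchmark the edge-scoring method against the classical DE baseline.

In a knockout experiment every pathway containing the KO gene is a true
positive, so both methods can be scored by the TPR/FPR of the pathways their
gene lists flag as enriched (hypergeometric ORA, FDR < 0.1).  The classical
baseline needs two thresholds (|log2 FC| and -log10 p) and is swept over a
grid; the edge-scoring method picks its threshold automatically.
"""

from highedges.diffexpr import moderated_t_test
from highedges.evaluation import classical_sweep, highedges_sweep
from highedges.pathway_io import build_global_graph
from highedges.pipeline import run_highedges
from highedges.simulate import generate_ko_experiment

edges, pathways, truth, data = generate_ko_experiment(seed=7)
stats = moderated_t_test(data)
graph = build_global_graph(edges)
result = run_highedges(stats, graph)

classical, best = classical_sweep(stats, graph, pathways, truth.ko_gene)
he = highedges_sweep(result.scored_edges, graph, pathways, truth.ko_gene,
                     changepoint=result.changepoint)
default = he[he["is_default"]].iloc[0]

print(f"KO gene: {truth.ko_gene}; positive pathways: "
      f"{sorted(truth.positive_pathways)}")
print()
print(f"classical sweep over {len(classical)} threshold pairs; "
      f"best cell (by positive likelihood ratio):")
print(f"  |log2FC| >= {best.fc_cut:.2f}, -log10 p >= {best.p_cut:.2f} -> "
      f"{best.n_genes:.0f} DE genes, TPR {best.tpr:.2f}, FPR {best.fpr:.2f}")
print()
print("edge-score method, automatic threshold (change point + 75% margin):")
print(f"  cutoff {default.score_cutoff:.2f} -> {default.n_genes:.0f} genes, "
      f"TPR {default.tpr:.2f}, FPR {default.fpr:.2f}")
print()
print("The classical numbers show its *best* grid cell, which could not be "
      "known in advance; the edge-score row is the method's default output.")
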