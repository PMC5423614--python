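"""Evaluation harness: classical DE baseline, ORA and knockout benchmarks.

In a knockout (KO) experiment the causal gene is known, so ground truth at
the pathway level is available for free: every pathway containing the KO gene
is a true positive, every other pathway a true negative.  A method that turns
a gene list into significant pathways can then be scored by its true/false
positive rates.

The harness implements:

* the classical differential-expression baseline -- genes selected by
  thresholds on |log2 FC| and -log10 p, restricted to genes annotated to at
  least one pathway (the same restriction is applied to both methods so that
  connectivity comparisons are fair), together with the subgraph induced by
  those genes in the global graph;
* over-representation analysis (ORA): one-sided hypergeometric upper-tail
  test of each pathway's overlap with a gene list, Benjamini-Hochberg FDR
  across pathways, significance at FDR < 0.1;
* KO-based TPR/FPR and the positive likelihood ratio TPR/FPR, which totals
  the two rates into a single number used to pick each method's best
  threshold in sweeps;
* threshold sweeps for both methods: a 2-D grid over (|log2 FC|, -log10 p)
  cuts for the classical approach (default 0.5 ... max|FC| by 0.25 and
  0.5 ... 5 by 0.5) and a 1-D grid of edge-score cutoffs (change point to
  maximum score) for the edge-scoring method.

External pathway-ranking tools (e.g. topology-aware scorers) can be compared
on the same truth via :func:`evaluate_external_table`, which accepts any
pathway/p-value table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mechanism import Mechanism, apply_safety_margin
from .pathway_io import GlobalGraph, PathwayCollection

__all__ = [
    "EvalResult",
    "select_de_genes",
    "induced_subgraph",
    "ora",
    "evaluate_ko",
    "evaluate_external_table",
    "classical_sweep",
    "highedges_sweep",
    "sweep_barplot",
]

ORA_COLUMNS = (
    "pathway_id", "overlap", "pathway_size_in_universe",
    "list_size", "universe_size", "p_value", "fdr", "significant",
)


@dataclass
class EvalResult:
    """TPR/FPR of significant-pathway calls against KO-defined truth."""

    tpr: float
    fpr: float
    positive_lr: float
    n_positive_pathways: int
    n_negative_pathways: int
    gene_list_size: int
    threshold_descriptor: dict

    @staticmethod
    def _lr(tpr: float, fpr: float) -> float:
        if fpr > 0:
            return tpr / fpr
        return math.inf if tpr > 0 else 0.0


def select_de_genes(
    stats: pd.DataFrame,
    fc_cut: float,
    p_cut: float,
    universe: set[str],
) -> list[str]:
    """Classical DE selection: |log2fc| >= fc_cut and -log10(p) >= p_cut.

    The result is intersected with ``universe`` (genes annotated to at least
    one pathway).  ``p_cut`` is on the -log10 scale, ``fc_cut`` on |log2 FC|.
    """
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(stats["p_value"].to_numpy(float))
    keep = (np.abs(stats["log2fc"].to_numpy(float)) >= fc_cut) & (neglogp >= p_cut)
    return [g for g in stats.index[keep] if g in universe]


def induced_subgraph(graph: GlobalGraph, genes) -> Mechanism:
    """Subgraph of the global graph induced by a gene list.

    Edges with both endpoints in ``genes`` are kept; genes with no internal
    interaction remain as singleton components (the classical approach
    typically yields many disconnected genes).
    """
    genes = list(dict.fromkeys(genes))
    gene_set = set(genes)
    rows = []
    for a, b in graph.g.edges:
        if a in gene_set and b in gene_set:
            a2, b2 = (a, b) if a <= b else (b, a)
            rows.append((a2, b2))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b"]).sort_values(
        ["gene_a", "gene_b"]
    ).reset_index(drop=True)
    for col in ("fc_a", "p_a", "fc_b", "p_b", "score"):
        edges[col] = np.nan

    sub = nx.Graph()
    sub.add_nodes_from(genes)
    sub.add_edges_from(rows)
    components = [set(c) for c in nx.connected_components(sub)]
    return Mechanism(
        edges=edges,
        nodes=gene_set,
        components=components,
        cutoff_score=math.nan,
        safety_fraction=math.nan,
        graph=sub,
    )


def ora(
    gene_list,
    pathways: PathwayCollection,
    universe: set[str],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Over-representation analysis of a gene list against every pathway.

    For each pathway with at least one gene in the universe, the one-sided
    hypergeometric upper tail P(X >= overlap) of drawing ``len(gene_list)``
    genes from the universe; BH-FDR across the tested pathways;
    ``significant`` flags FDR < ``alpha``.
    """
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_list) & universe
    n_list = len(gene_set)
    M = len(universe)
    rows = []
    for pid in pathways.ids():
        pw_genes = pathways[pid].genes & universe
        if not pw_genes:
            continue
        k = len(gene_set & pw_genes)
        K = len(pw_genes)
        p = float(sps.hypergeom.sf(k - 1, M, K, n_list))
        rows.append((pid, k, K, n_list, M, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=ORA_COLUMNS[:6])
    if len(out):
        _, fdr, *_ = multipletests(out["p_value"], method="fdr_bh")
        out["fdr"] = fdr
    else:
        out["fdr"] = pd.Series(dtype=float)
    out["significant"] = out["fdr"] < alpha
    return out


def evaluate_ko(
    ora_results: pd.DataFrame,
    ko_gene: str,
    pathways: PathwayCollection,
    alpha: float = 0.1,
    threshold_descriptor: dict | None = None,
) -> EvalResult:
    """Score significant-pathway calls against the KO ground truth.

    Positives are the tested pathways containing the KO gene; negatives all
    other tested pathways.  Significance is re-derived from the FDR column at
    ``alpha`` so the same ORA table can be evaluated at several levels.
    """
    positive_ids = set(pathways.pathways_containing(ko_gene))
    if not positive_ids:
        raise ValueError(f"KO gene {ko_gene!r} belongs to no pathway: no ground-truth positives")
    tested = ora_results["pathway_id"]
    is_pos = tested.isin(positive_ids).to_numpy()
    sig = (ora_results["fdr"] < alpha).to_numpy()
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())
    tpr = float((sig & is_pos).sum() / n_pos) if n_pos else 0.0
    fpr = float((sig & ~is_pos).sum() / n_neg) if n_neg else 0.0
    sizes = ora_results["list_size"].unique()
    return EvalResult(
        tpr=tpr,
        fpr=fpr,
        positive_lr=EvalResult._lr(tpr, fpr),
        n_positive_pathways=n_pos,
        n_negative_pathways=n_neg,
        gene_list_size=int(sizes[0]) if len(sizes) else 0,
        threshold_descriptor=threshold_descriptor or {},
    )


def evaluate_external_table(
    pathway_pvalues: pd.DataFrame,
    ko_gene: str,
    pathways: PathwayCollection,
    alpha: float = 0.1,
    p_column: str = "p_value",
) -> EvalResult:
    """Adapter: evaluate an externally computed pathway p-value table.

    ``pathway_pvalues`` needs columns ``pathway_id`` and ``p_column``; BH-FDR
    is applied here, so raw per-pathway p-values are expected.
    """
    tab = pathway_pvalues[["pathway_id", p_column]].copy()
    _, fdr, *_ = multipletests(tab[p_column], method="fdr_bh")
    tab["fdr"] = fdr
    tab["list_size"] = 0
    return evaluate_ko(tab, ko_gene, pathways, alpha=alpha,
                       threshold_descriptor={"source": "external"})


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def _grid(start: float, stop: float, step: float) -> np.ndarray:
    n = max(1, int(math.floor((stop - start) / step + 1e-9)) + 1)
    return start + step * np.arange(n)


def classical_sweep(
    stats: pd.DataFrame,
    graph: GlobalGraph,
    pathways: PathwayCollection,
    ko_gene: str,
    fc_grid=None,
    p_grid=None,
    alpha: float = 0.1,
    fc_step: float = 0.25,
    p_step: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Evaluate the classical approach over a grid of (FC, p) thresholds.

    Default grid: |log2 FC| cuts from 0.5 to max|log2 FC| in steps of 0.25
    (least to most stringent) and -log10 p cuts from 0.5 to 5 in steps of 0.5.

    Returns the tidy result table (one row per grid cell with tpr, fpr,
    positive_lr and the DE-gene count) and the best row by positive
    likelihood ratio (ties broken by higher tpr, then by more stringent cuts).
    """
    universe = pathways.gene_universe() & set(stats.index)
    if fc_grid is None:
        fc_max = float(np.abs(stats["log2fc"]).max())
        fc_grid = _grid(0.5, max(fc_max, 0.5), fc_step)
    if p_grid is None:
        p_grid = _grid(0.5, 5.0, p_step)
    rows = []
    for fc_cut in fc_grid:
        for p_cut in p_grid:
            genes = select_de_genes(stats, float(fc_cut), float(p_cut), universe)
            if genes:
                res = evaluate_ko(
                    ora(genes, pathways, universe, alpha=alpha),
                    ko_gene, pathways, alpha=alpha,
                )
                tpr, fpr, lr = res.tpr, res.fpr, res.positive_lr
            else:
                tpr = fpr = lr = 0.0
            rows.append((float(fc_cut), float(p_cut), len(genes), tpr, fpr, lr))
    table = pd.DataFrame(
        rows, columns=["fc_cut", "p_cut", "n_genes", "tpr", "fpr", "positive_lr"]
    )
    order = table.sort_values(
        ["positive_lr", "tpr", "fc_cut", "p_cut"],
        ascending=[False, False, False, False],
        kind="mergesort",
    )
    return table, order.iloc[0]


def highedges_sweep(
    scored_edges: pd.DataFrame,
    graph: GlobalGraph,
    pathways: PathwayCollection,
    ko_gene: str,
    threshold_grid=None,
    changepoint=None,
    safety_fraction: float = 0.75,
    alpha: float = 0.1,
    n_points: int = 20,
) -> pd.DataFrame:
    """Evaluate the edge-scoring method over a grid of score cutoffs.

    The default grid spans the change-point threshold to the maximum score;
    for each cutoff the gene list is the endpoint set of edges with
    ``score >= cutoff``.  The row corresponding to the method's default
    selection (change point plus safety margin) is flagged ``is_default``.
    """
    from .mechanism import detect_changepoint

    scores = scored_edges["score"].to_numpy(float)
    if changepoint is None:
        changepoint = detect_changepoint(scores)
    if threshold_grid is None:
        threshold_grid = np.linspace(changepoint.threshold_score, scores.max(), n_points)
    universe = pathways.gene_universe() & (
        set(scored_edges["gene_a"]) | set(scored_edges["gene_b"])
    )

    default_sel = apply_safety_margin(scored_edges, changepoint, safety_fraction)
    default_cutoff = (
        float(default_sel["score"].min()) if len(default_sel) else math.inf
    )

    rows = []
    cutoffs = sorted(set(float(c) for c in threshold_grid) | {default_cutoff})
    for cutoff in cutoffs:
        keep = scored_edges[scored_edges["score"] >= cutoff]
        genes = sorted(set(keep["gene_a"]) | set(keep["gene_b"]))
        genes = [g for g in genes if g in universe]
        if genes:
            res = evaluate_ko(
                ora(genes, pathways, universe, alpha=alpha),
                ko_gene, pathways, alpha=alpha,
            )
            tpr, fpr, lr = res.tpr, res.fpr, res.positive_lr
        else:
            tpr = fpr = lr = 0.0
        rows.append(
            (cutoff, len(keep), len(genes), tpr, fpr, lr, cutoff == default_cutoff)
        )
    return pd.DataFrame(
        rows,
        columns=["score_cutoff", "n_edges", "n_genes", "tpr", "fpr",
                 "positive_lr", "is_default"],
    )


def sweep_barplot(table: pd.DataFrame, x_column: str, path, title: str = "") -> None:
    """TPR/FPR bars over the threshold grid with the gene count on a twin axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(table))
    fig, ax = plt.subplots(figsize=(max(6, len(table) * 0.35), 4))
    ax.bar(x - 0.2, table["tpr"], width=0.4, color="forestgreen", label="TPR")
    ax.bar(x + 0.2, table["fpr"], width=0.4, color="firebrick", label="FPR")
    ax2 = ax.twinx()
    ax2.bar(x, table["n_genes"], width=0.8, color="lightgray", zorder=0, label="genes")
    ax2.set_ylabel("n genes")
    ax.set_zorder(ax2.get_zorder() + 1)
    ax.patch.set_visible(False)
    if "is_default" in table and table["is_default"].any():
        xd = x[table["is_default"].to_numpy()][0]
        ax.axvline(xd, color="steelblue", linestyle="--", label="default selection")
    ax.set_xticks(x)
    ax.set_xticklabels([f"{v:.2g}" for v in table[x_column]], rotation=90, fontsize=7)
    ax.set_xlabel(x_column)
    ax.set_ylabel("rate")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
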