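"""Edge scores: joint evidence of change for each interaction.

Every edge (A, B) of the global graph receives the score

    EdgeScore_AB = FC'_A * (1 - p_A) + FC'_B * (1 - p_B),

where FC'_g is the (by default absolute) log2 fold change of gene g and p_g
its two-sided p-value.  Both endpoints must have been measured; edges with an
unmeasured endpoint are dropped and counted rather than imputed, since an
imputed FC of zero would silently halve the score and bias selection.

The default ``absolute_log2`` transform prevents an up- and a down-regulated
endpoint from cancelling each other; ``signed_log2`` is kept for sensitivity
analysis.
"""

from __future__ import annotations

import csv
from typing import Literal

import pandas as pd

from .pathway_io import GlobalGraph

__all__ = ["score_edge", "score_graph", "write_scored_edges", "read_scored_edges"]

FcTransform = Literal["absolute_log2", "signed_log2"]

SCORE_COLUMNS = (
    "gene_a", "gene_b", "fc_a", "p_a", "fc_b", "p_b",
    "score", "interaction_types", "source_pathways",
)


def _transform(fc: float, mode: FcTransform) -> float:
    if mode == "absolute_log2":
        return abs(fc)
    if mode == "signed_log2":
        return fc
    raise ValueError(f"unknown fc_transform {mode!r}")


def score_edge(
    fc_a: float,
    p_a: float,
    fc_b: float,
    p_b: float,
    fc_transform: FcTransform = "absolute_log2",
) -> float:
    """Score a single interaction from its endpoints' log2 FC and p-value."""
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return _transform(fc_a, fc_transform) * (1.0 - p_a) + _transform(fc_b, fc_transform) * (
        1.0 - p_b
    )


def score_graph(
    graph: GlobalGraph,
    stats: pd.DataFrame,
    fc_transform: FcTransform = "absolute_log2",
) -> tuple[pd.DataFrame, int]:
    """Score every edge of the global graph whose endpoints are both measured.

    Parameters
    ----------
    graph
        The merged interaction graph.
    stats
        Per-gene statistics indexed by gene id with ``log2fc`` and ``p_value``
        columns (see :mod:`highedges.diffexpr`).

    Returns
    -------
    scored, n_dropped
        ``scored``: one row per scorable edge, sorted by descending score and
        then lexicographically by (gene_a, gene_b) so that count-based cuts
        downstream are reproducible.  ``n_dropped``: edges skipped because at
        least one endpoint has no statistics.
    """
    fc = stats["log2fc"]
    pv = stats["p_value"]
    measured = set(stats.index)
    rows = []
    n_dropped = 0
    for a, b, data in graph.g.edges(data=True):
        a, b = (a, b) if a <= b else (b, a)
        if a not in measured or b not in measured:
            n_dropped += 1
            continue
        s = score_edge(float(fc[a]), float(pv[a]), float(fc[b]), float(pv[b]), fc_transform)
        rows.append(
            (
                a, b, float(fc[a]), float(pv[a]), float(fc[b]), float(pv[b]), s,
                ",".join(sorted(data.get("interaction_types", ()))),
                ",".join(sorted(data.get("source_pathways", ()))),
            )
        )
    if not rows:
        raise ValueError("no scorable edges: graph nodes and measured genes do not overlap")
    scored = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    scored = scored.sort_values(
        ["score", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return scored, n_dropped


def write_scored_edges(scored: pd.DataFrame, path) -> None:
    scored.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def read_scored_edges(path) -> pd.DataFrame:
    scored = pd.read_csv(path, sep="\t", keep_default_na=False,
                         dtype={"gene_a": str, "gene_b": str})
    missing = set(SCORE_COLUMNS[:7]) - set(scored.columns)
    if missing:
        raise ValueError(f"scored-edge table missing column(s): {sorted(missing)}")
    return scored
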