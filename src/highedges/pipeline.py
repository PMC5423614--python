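"""End-to-end pipeline: statistics -> edge scores -> change point -> mechanism."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexpr import ExpressionDataset, ModeratedPrior, moderated_t_test
from .mechanism import (
    ChangePointResult,
    Mechanism,
    apply_safety_margin,
    detect_changepoint,
    extract_mechanism,
)
from .pathway_io import GlobalGraph, InteractionEdge, build_global_graph
from .scoring import FcTransform, score_graph

__all__ = ["PipelineResult", "run_highedges"]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, for inspection and export."""

    stats: pd.DataFrame
    graph: GlobalGraph
    scored_edges: pd.DataFrame
    n_dropped_edges: int
    changepoint: ChangePointResult
    mechanism: Mechanism


def run_highedges(
    data_or_stats: ExpressionDataset | pd.DataFrame,
    edges_or_graph: list[InteractionEdge] | GlobalGraph,
    safety_fraction: float = 0.75,
    fc_transform: FcTransform = "absolute_log2",
    prior: ModeratedPrior | None = None,
) -> PipelineResult:
    """Run the full mechanism-inference pipeline.

    Accepts either a two-group expression dataset (per-gene statistics are
    then computed with the moderated t-test) or a precomputed statistics
    table, plus either a flat interaction-edge list or an already merged
    global graph.
    """
    if isinstance(data_or_stats, ExpressionDataset):
        stats = moderated_t_test(data_or_stats, prior=prior)
    else:
        stats = data_or_stats
    graph = (
        edges_or_graph
        if isinstance(edges_or_graph, GlobalGraph)
        else build_global_graph(edges_or_graph)
    )
    scored, n_dropped = score_graph(graph, stats, fc_transform=fc_transform)
    changepoint = detect_changepoint(scored["score"].to_numpy())
    selected = apply_safety_margin(scored, changepoint, safety_fraction)
    mech = extract_mechanism(graph, selected, safety_fraction)
    return PipelineResult(
        stats=stats,
        graph=graph,
        scored_edges=scored,
        n_dropped_edges=n_dropped,
        changepoint=changepoint,
        mechanism=mech,
    )
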