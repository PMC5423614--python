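"""Automatic threshold selection and extraction of the putative mechanism.

The distribution of edge scores in a real comparison is a large low-score
bulk (interactions between unchanged genes) with, when a phenotype has a
coherent mechanism, a sparse high-score tail.  Rather than asking the user
for a score threshold, the critical score is found by a *change-point
analysis*: the sorted (descending) score sequence is split into two segments
by the single change point in mean that minimises the two-segment residual
sum of squares -- equivalently, the optimal 1-D two-means partition of the
scores.  The threshold is the midpoint between the two scores flanking the
split, i.e. the point at which the distribution leaves the high-score regime.

Because the change point may still admit a sizeable set of edges, only the
top ``safety_fraction`` (default 75%) of the above-threshold edges are kept
-- a *safety margin* against false positives.  The cut is count-based
(``ceil(fraction * K)`` of the K above-threshold edges) and is extended to
include any edge tied with the last kept score, so the selection does not
depend on input ordering.

The selected edges form the putative mechanism: a subgraph whose nodes are
exactly the endpoints of the selected edges, reported with its connected
components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .pathway_io import GlobalGraph, write_graphml, write_sif

logger = logging.getLogger(__name__)

__all__ = [
    "ChangePointResult",
    "Mechanism",
    "NoChangePointError",
    "detect_changepoint",
    "apply_safety_margin",
    "extract_mechanism",
    "write_mechanism",
    "write_changepoint_diagnostics",
]

MIN_SCORES = 20
MIN_BINS = 30
MIN_SEPARATION = 4.5


class NoChangePointError(RuntimeError):
    """The score distribution has no detectable change point."""


@dataclass
class ChangePointResult:
    """Detected critical edge score plus the score histogram diagnostics."""

    threshold_score: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    method: str
    n_edges_above: int
    split_index: int  # number of scores in the high-score segment


@dataclass
class Mechanism:
    """The selected high-score subgraph.

    ``edges`` holds one row per selected edge (scored-edge schema);
    ``components`` partitions the node set of the selected subgraph.
    """

    edges: pd.DataFrame
    nodes: set[str]
    components: list[set[str]]
    cutoff_score: float
    safety_fraction: float
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_genes(self) -> int:
        return len(self.nodes)


def _two_segment_split(values: np.ndarray) -> tuple[int, float]:
    """Best single split of ``values`` into two mean segments (min total RSS).

    Returns ``(k, rss)`` where the segments are ``values[:k]`` and
    ``values[k:]``.  Splits between tied neighbours are not considered so a
    threshold between the segments is always well defined.
    """
    v = np.asarray(values, float)
    n = len(v)
    cs = np.cumsum(v)
    cs2 = np.cumsum(v * v)
    k = np.arange(1, n)
    left = cs2[:-1] - cs[:-1] ** 2 / k
    right = (cs2[-1] - cs2[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (n - k)
    rss = left + right
    valid = v[:-1] != v[1:]
    if not valid.any():
        raise NoChangePointError("all scores are identical; no change point exists")
    rss = np.where(valid, rss, np.inf)
    best = int(np.argmin(rss))
    return best + 1, float(rss[best])


def detect_changepoint(
    scores,
    n_bins: int | None = None,
    min_separation: float = MIN_SEPARATION,
) -> ChangePointResult:
    """Find the critical edge-score threshold.

    Parameters
    ----------
    scores
        Edge scores (any order); at least 20 values with at least 2 distinct.
    n_bins
        Histogram bins for the diagnostic output.  Default: Freedman-Diaconis
        bin width with a floor of 30 bins.
    min_separation
        Significance guard: the mean of the high-score segment must exceed
        the mean of the low-score bulk by at least this many bulk standard
        deviations, otherwise the split is indistinguishable from the tail of
        a single noise distribution and no change point is reported.  The
        default keeps the method silent on pure-noise input (an optimal
        two-means split of any unimodal sample still separates its upper tail
        by roughly 4 bulk SDs); pass 0 to disable.

    Returns
    -------
    ChangePointResult
        ``threshold_score`` is the midpoint between the lowest score of the
        high segment and the highest score of the flat low-score regime, so
        selecting ``score >= threshold_score`` keeps exactly the high segment.

    Raises
    ------
    ValueError
        Fewer than 20 scores; select by percentile directly in that case.
    NoChangePointError
        All scores identical, or the best split fails the separation guard.
    """
    s = np.sort(np.asarray(scores, float))[::-1]
    if len(s) < MIN_SCORES:
        raise ValueError(
            f"need >= {MIN_SCORES} scores for change-point detection "
            f"(got {len(s)}); use a direct percentile cut instead"
        )
    k, _ = _two_segment_split(s)
    threshold = 0.5 * (s[k - 1] + s[k])

    if min_separation > 0:
        hi, lo = s[:k], s[k:]
        sd_lo = float(lo.std(ddof=1)) if len(lo) > 1 else 0.0
        gap = (float(hi.mean()) - float(lo.mean())) / max(sd_lo, 1e-12)
        if gap < min_separation:
            raise NoChangePointError(
                f"high-score segment is separated from the bulk by only "
                f"{gap:.2f} bulk SDs (< {min_separation}); the score "
                f"distribution looks like a single population"
            )

    if n_bins is None:
        edges = np.histogram_bin_edges(s, bins="fd")
        if len(edges) - 1 < MIN_BINS:
            edges = np.histogram_bin_edges(s, bins=MIN_BINS)
    else:
        edges = np.histogram_bin_edges(s, bins=n_bins)
    counts, edges = np.histogram(s, bins=edges)

    return ChangePointResult(
        threshold_score=float(threshold),
        bin_edges=edges,
        bin_counts=counts,
        method="least-squares single change point in mean (sorted scores)",
        n_edges_above=int(k),
        split_index=int(k),
    )


def apply_safety_margin(
    scored_edges: pd.DataFrame,
    changepoint: ChangePointResult,
    safety_fraction: float = 0.75,
) -> pd.DataFrame:
    """Keep the top ``ceil(safety_fraction * K)`` of the K above-threshold edges.

    ``scored_edges`` must be sorted by descending score (as produced by
    :func:`highedges.scoring.score_graph`).  Edges tied with the k-th score
    are included, so the result is a prefix of the sorted table and does not
    depend on tie ordering.
    """
    if not 0.0 < safety_fraction <= 1.0:
        raise ValueError("safety_fraction must be in (0, 1]")
    scores = scored_edges["score"].to_numpy(float)
    if np.any(np.diff(scores) > 1e-12):
        raise ValueError("scored_edges must be sorted by descending score")
    K = int((scores >= changepoint.threshold_score).sum())
    if K == 0:
        logger.warning("no edges at or above the change-point threshold; empty selection")
        return scored_edges.iloc[0:0].copy()
    k = math.ceil(safety_fraction * K)
    kth_score = scores[k - 1]
    n_keep = int((scores >= kth_score).sum())  # tie extension
    return scored_edges.iloc[:n_keep].copy()


def extract_mechanism(
    graph: GlobalGraph,
    selected: pd.DataFrame,
    safety_fraction: float = 0.75,
) -> Mechanism:
    """Build the putative-mechanism subgraph from the selected edges.

    Nodes are exactly the endpoints of the selected edges; the original
    interaction-type and direction metadata of the global graph are copied
    onto the subgraph for rendering.  An empty selection yields an empty
    (but valid) mechanism.
    """
    sub = nx.Graph()
    for row in selected.itertuples(index=False):
        attrs = {"score": row.score}
        if graph.g.has_edge(row.gene_a, row.gene_b):
            attrs.update(graph.g.edges[row.gene_a, row.gene_b])
        sub.add_edge(row.gene_a, row.gene_b, **attrs)
        sub.nodes[row.gene_a]["log2fc"] = row.fc_a
        sub.nodes[row.gene_a]["p_value"] = row.p_a
        sub.nodes[row.gene_b]["log2fc"] = row.fc_b
        sub.nodes[row.gene_b]["p_value"] = row.p_b
    components = [set(c) for c in nx.connected_components(sub)]
    cutoff = float(selected["score"].min()) if len(selected) else math.nan
    return Mechanism(
        edges=selected.reset_index(drop=True),
        nodes=set(sub.nodes),
        components=components,
        cutoff_score=cutoff,
        safety_fraction=safety_fraction,
        graph=sub,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_mechanism(mechanism: Mechanism, basename) -> None:
    """Write GraphML, SIF and a flat TSV of the selected edges (``basename.*``)."""
    base = str(basename)
    write_graphml(mechanism.graph, base + ".graphml")
    write_sif(mechanism.graph, base + ".sif")
    mechanism.edges.to_csv(base + ".tsv", sep="\t", index=False)


def write_changepoint_diagnostics(result: ChangePointResult, path) -> None:
    """Histogram of scores (bin edges/counts) plus the chosen threshold, as TSV."""
    diag = pd.DataFrame(
        {
            "bin_low": result.bin_edges[:-1],
            "bin_high": result.bin_edges[1:],
            "count": result.bin_counts,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# threshold_score\t{result.threshold_score}\n")
        fh.write(f"# n_edges_above\t{result.n_edges_above}\n")
        fh.write(f"# method\t{result.method}\n")
        diag.to_csv(fh, sep="\t", index=False)
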