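"""Synthetic knockout experiments with a planted mechanism.

Real validation of a mechanism-inference method needs experiments where the
cause is known; the generators here emulate exactly that setting: a pathway
database of random connected interaction graphs with partially overlapping
gene sets, a knockout (KO) gene that is a member of several pathways (KO
genes studied in practice -- signaling adaptors, transcription factors --
are typically annotated to multiple pathways), and a two-group expression
matrix in which the KO gene drops sharply and the perturbation propagates
with geometric attenuation along a breadth-first cascade of interaction
edges, on top of Gaussian noise on the log2 scale (normalised microarray
intensities).

Defaults (one synthetic study design, used throughout the test-suite and the
acceptance run): 10 pathways of 30 genes, the KO gene a member of 3 pathways,
KO shift -3 log2 units, per-hop decay 0.6, noise SD 0.4, cascade depth 2,
5 case vs 5 control samples.  The KO is modelled as a strong knockdown (a
shift) rather than literal zero expression so variances stay finite and the
moderated test remains well behaved.  Downstream effect signs flip randomly
per edge (activation vs inhibition); edge scoring is sign-insensitive under
its default transform, so this costs the method nothing while keeping the
data realistic.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import ExpressionDataset, write_expression
from .pathway_io import (
    GlobalGraph,
    InteractionEdge,
    Pathway,
    PathwayCollection,
    build_global_graph,
    write_edge_table,
    write_gmt,
)

__all__ = [
    "SyntheticTruth",
    "generate_pathway_db",
    "plant_mechanism",
    "generate_expression",
    "generate_ko_experiment",
    "write_truth",
    "read_truth",
]

# Study-design defaults
N_PATHWAYS = 10
GENES_PER_PATHWAY = 30
EDGE_DENSITY = 0.02
OVERLAP_FRACTION = 0.1
KO_PATHWAY_MEMBERSHIP = 3
KO_LINKS_PER_PATHWAY = 3
KO_EFFECT = -3.0
DECAY = 0.6
NOISE_SD = 0.4
CASCADE_DEPTH = 2
N_CASE = N_CONTROL = 5
N_BACKGROUND_GENES = 50


@dataclass
class SyntheticTruth:
    """Ground truth of a planted knockout mechanism."""

    ko_gene: str
    planted_edges: set[tuple[str, str]]  # sorted gene pairs of the BFS cascade tree
    ko_effect: float
    decay: float
    noise_sd: float
    positive_pathways: set[str]
    cascade_depth: int
    depths: dict[str, int] = field(default_factory=dict)  # gene -> hops from KO
    true_effects: dict[str, float] = field(default_factory=dict)  # gene -> log2 shift

    def __post_init__(self) -> None:
        if not any(self.ko_gene in pair for pair in self.planted_edges):
            raise ValueError("KO gene must be an endpoint of at least one planted edge")
        if not self.positive_pathways:
            raise ValueError("KO gene must belong to at least one pathway")


def _connected_random_graph(genes: list[str], density: float, rng) -> list[tuple[str, str]]:
    """Random spanning tree plus extra edges: connected by construction."""
    edges: set[tuple[str, str]] = set()
    order = list(genes)
    rng.shuffle(order)
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        a, b = sorted((order[i], order[j]))
        edges.add((a, b))
    n = len(order)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((order[i], order[j]))
            if (a, b) not in edges and rng.random() < density:
                edges.add((a, b))
    return sorted(edges)


def _pick_partners(candidates: list[str], degree: dict[str, int], k: int) -> list[str]:
    """The k best-connected candidate genes (ties broken lexicographically).

    The KO hub interacts with each pathway's core machinery: its direct
    targets are the pathway's most connected members, themselves regulators,
    so the knockout's effect propagates beyond one hop (a leaf target would
    truncate the cascade immediately).
    """
    order = sorted(candidates, key=lambda g: (-degree.get(g, 0), g))
    return order[:k]


def generate_pathway_db(
    n_pathways: int = N_PATHWAYS,
    genes_per_pathway: int = GENES_PER_PATHWAY,
    edge_density: float = EDGE_DENSITY,
    overlap_fraction: float = OVERLAP_FRACTION,
    seed: int = 0,
    ko_pathway_membership: int = KO_PATHWAY_MEMBERSHIP,
    ko_links_per_pathway: int = KO_LINKS_PER_PATHWAY,
) -> tuple[list[InteractionEdge], PathwayCollection, str]:
    """Generate a multi-pathway interaction database.

    Each pathway is a connected random graph on its gene set;
    ``overlap_fraction`` of each pathway's genes (after the first) are reused
    from previously generated pathways.  One designated hub gene -- the KO
    candidate -- is made a member of ``ko_pathway_membership`` pathways in
    total, with ``ko_links_per_pathway`` interactions inside each of the
    extra pathways.

    Returns the flat interaction-edge list (the input of
    :func:`highedges.pathway_io.build_global_graph`), the pathway membership
    collection, and the id of the designated KO candidate.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if min(n_pathways, genes_per_pathway) < 1 or edge_density < 0:
        raise ValueError("generator parameters must be positive")
    rng = np.random.default_rng(seed)
    width = len(str(n_pathways * genes_per_pathway))
    counter = 0

    def new_gene() -> str:
        nonlocal counter
        counter += 1
        return f"G{counter:0{width}d}"

    pathway_genes: dict[str, list[str]] = {}
    pathway_edges: dict[str, list[tuple[str, str]]] = {}
    seen: list[str] = []
    hub: str | None = None
    for p in range(n_pathways):
        pid = f"P{p + 1:02d}"
        n_shared = int(round(overlap_fraction * genes_per_pathway)) if p else 0
        n_shared = min(n_shared, len(seen))
        shared = (
            [seen[i] for i in rng.choice(len(seen), size=n_shared, replace=False)]
            if n_shared
            else []
        )
        fresh = [new_gene() for _ in range(genes_per_pathway - len(shared))]
        genes = shared + fresh
        pathway_genes[pid] = genes
        pathway_edges[pid] = _connected_random_graph(genes, edge_density, rng)
        if p == 0:
            # KO candidate: a modest-degree gene of the first pathway, so the
            # depth-limited cascade stays compact (real mechanisms are small).
            # It is kept out of the overlap pool: its extra memberships are
            # planted explicitly below, fixing them at ko_pathway_membership.
            degree: dict[str, int] = {}
            for a, b in pathway_edges[pid]:
                degree[a] = degree.get(a, 0) + 1
                degree[b] = degree.get(b, 0) + 1
            hub = min(sorted(g for g, d in degree.items() if d >= 2), key=degree.get)
            # symmetric hub connectivity: same link count in its home pathway
            # as planted in each extra pathway below
            adjacent = {g for e in pathway_edges[pid] for g in e if hub in e}
            free = [g for g in sorted(genes) if g != hub and g not in adjacent]
            n_more = max(ko_links_per_pathway - degree[hub], 0)
            extra_partners = _pick_partners(free, degree, n_more)
            pathway_edges[pid] = pathway_edges[pid] + [
                tuple(sorted((hub, g))) for g in extra_partners
            ]
            seen.extend(g for g in fresh if g != hub)
        else:
            seen.extend(fresh)

    pids = sorted(pathway_genes)
    n_extra = min(max(ko_pathway_membership - 1, 0), n_pathways - 1)
    extra_pids = [
        pids[1:][i] for i in rng.choice(n_pathways - 1, size=n_extra, replace=False)
    ]
    for pid in extra_pids:
        members = [g for g in pathway_genes[pid] if g != hub]
        local_degree: dict[str, int] = {}
        for a, b in pathway_edges[pid]:
            local_degree[a] = local_degree.get(a, 0) + 1
            local_degree[b] = local_degree.get(b, 0) + 1
        partners = _pick_partners(members, local_degree, ko_links_per_pathway)
        pathway_genes[pid] = pathway_genes[pid] + [hub]
        pathway_edges[pid] = pathway_edges[pid] + [tuple(sorted((hub, g))) for g in partners]

    edges: list[InteractionEdge] = []
    collection = PathwayCollection()
    for pid in pids:
        collection.add(
            Pathway(pathway_id=pid, name=f"synthetic pathway {pid}",
                    genes=set(pathway_genes[pid]))
        )
        for a, b in pathway_edges[pid]:
            sign = "activation" if rng.random() < 0.5 else "inhibition"
            edges.append(
                InteractionEdge(
                    gene_a=a, gene_b=b, directed=True,
                    interaction_type=sign, source_pathways={pid},
                )
            )
    return edges, collection, hub


def plant_mechanism(
    edges: list[InteractionEdge],
    pathways: PathwayCollection,
    seed: int = 0,
    cascade_depth: int = CASCADE_DEPTH,
    ko_gene: str | None = None,
    ko_effect: float = KO_EFFECT,
    decay: float = DECAY,
    noise_sd: float = NOISE_SD,
    random_signs: bool = True,
) -> SyntheticTruth:
    """Choose a KO gene and plant its downstream cascade.

    The KO gene (unless given) is the eligible gene -- degree >= 2 in the
    global graph and a member of >= 1 pathway -- with the most pathway
    memberships, ties broken by degree then lexicographically.  The planted
    mechanism is the breadth-first tree from the KO gene up to
    ``cascade_depth`` hops (neighbours visited in sorted order, so the tree
    is deterministic).  Per-edge interaction signs flip the propagated effect
    randomly when ``random_signs``; the effect magnitude at depth d is
    ``|ko_effect| * decay**d``.
    """
    if cascade_depth < 1:
        raise ValueError("cascade_depth must be >= 1")
    graph: GlobalGraph = build_global_graph(edges)
    g = graph.g
    rng = np.random.default_rng(seed)
    if ko_gene is None:
        eligible = [
            n for n in g.nodes if g.degree[n] >= 2 and pathways.pathways_containing(n)
        ]
        if not eligible:
            raise ValueError("no eligible KO gene (degree >= 2 and in >= 1 pathway)")
        ko_gene = max(
            sorted(eligible),
            key=lambda n: (len(pathways.pathways_containing(n)), g.degree[n]),
        )
    elif ko_gene not in g.nodes:
        raise ValueError(f"requested KO gene {ko_gene!r} is not in the interaction graph")

    depths = {ko_gene: 0}
    effects = {ko_gene: float(ko_effect)}
    planted: set[tuple[str, str]] = set()
    frontier = [ko_gene]
    for d in range(1, cascade_depth + 1):
        nxt = []
        for parent in frontier:
            for child in sorted(g.neighbors(parent)):
                if child in depths:
                    continue
                depths[child] = d
                edge_sign = (-1.0 if rng.random() < 0.5 else 1.0) if random_signs else 1.0
                parent_sign = 1.0 if effects[parent] >= 0 else -1.0
                # sign propagates cumulatively along the path; magnitude decays per hop
                effects[child] = edge_sign * parent_sign * abs(ko_effect) * decay**d
                planted.add(tuple(sorted((parent, child))))
                nxt.append(child)
        frontier = nxt

    positives = set(pathways.pathways_containing(ko_gene))
    return SyntheticTruth(
        ko_gene=ko_gene,
        planted_edges=planted,
        ko_effect=float(ko_effect),
        decay=float(decay),
        noise_sd=float(noise_sd),
        positive_pathways=positives,
        cascade_depth=cascade_depth,
        depths=depths,
        true_effects=effects,
    )


def generate_expression(
    truth: SyntheticTruth,
    genes,
    n_case: int = N_CASE,
    n_control: int = N_CONTROL,
    n_background_genes: int = N_BACKGROUND_GENES,
    seed: int = 0,
    baseline_range: tuple[float, float] = (6.0, 10.0),
) -> ExpressionDataset:
    """Simulate the two-group expression matrix.

    ``genes`` is the measured pathway/graph gene universe;
    ``n_background_genes`` additional measured genes outside every pathway are
    appended (their ids start with ``BG``), mimicking the fact that arrays
    measure far more genes than any pathway database annotates.  Control
    samples are Normal(baseline_g, noise_sd^2) per gene; case samples add the
    planted per-gene effects from ``truth.true_effects``.
    """
    if min(n_case, n_control) < 3:
        raise ValueError("need >= 3 samples per group")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_background_genes, 1)))
    all_genes = list(genes) + [f"BG{i + 1:0{width}d}" for i in range(n_background_genes)]
    baselines = rng.uniform(*baseline_range, size=len(all_genes))
    n = n_case + n_control
    mat = rng.normal(baselines[:, None], truth.noise_sd, size=(len(all_genes), n))
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    for gene, effect in truth.true_effects.items():
        if gene in gene_pos:
            mat[gene_pos[gene], :n_case] += effect
    samples = [f"case_{i + 1}" for i in range(n_case)] + [
        f"control_{i + 1}" for i in range(n_control)
    ]
    values = pd.DataFrame(mat, index=all_genes, columns=samples)
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples
    )
    return ExpressionDataset(values=values, groups=groups)


def generate_ko_experiment(
    seed: int = 0,
    cascade_depth: int = CASCADE_DEPTH,
    ko_effect: float = KO_EFFECT,
    decay: float = DECAY,
    noise_sd: float = NOISE_SD,
    **db_kwargs,
) -> tuple[list[InteractionEdge], PathwayCollection, SyntheticTruth, ExpressionDataset]:
    """One-call default experiment: database, truth and expression matrix.

    Sub-seeds for the three generation stages are derived from ``seed`` so
    that experiments with different seeds are fully independent.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    edges, pathways, ko_candidate = generate_pathway_db(seed=seeds[0], **db_kwargs)
    truth = plant_mechanism(
        edges, pathways, seed=seeds[1], cascade_depth=cascade_depth,
        ko_gene=ko_candidate, ko_effect=ko_effect, decay=decay, noise_sd=noise_sd,
    )
    graph_genes = sorted({g for e in edges for g in (e.gene_a, e.gene_b)})
    data = generate_expression(truth, graph_genes, seed=seeds[2])
    return edges, pathways, truth, data


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "ko_gene": truth.ko_gene,
        "planted_edges": sorted(list(e) for e in truth.planted_edges),
        "ko_effect": truth.ko_effect,
        "decay": truth.decay,
        "noise_sd": truth.noise_sd,
        "positive_pathways": sorted(truth.positive_pathways),
        "cascade_depth": truth.cascade_depth,
        "depths": truth.depths,
        "true_effects": truth.true_effects,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        ko_gene=payload["ko_gene"],
        planted_edges={tuple(e) for e in payload["planted_edges"]},
        ko_effect=payload["ko_effect"],
        decay=payload["decay"],
        noise_sd=payload["noise_sd"],
        positive_pathways=set(payload["positive_pathways"]),
        cascade_depth=payload["cascade_depth"],
        depths=payload["depths"],
        true_effects=payload["true_effects"],
    )


def write_experiment(
    outdir,
    edges: list[InteractionEdge],
    pathways: PathwayCollection,
    truth: SyntheticTruth,
    data: ExpressionDataset,
) -> None:
    """Write the full fixture in the formats the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_table(edges, out / "interactions.tsv")
    write_gmt(pathways, out / "pathways.gmt")
    write_truth(truth, out / "truth.json")
    write_expression(data, out / "expression.tsv", out / "groups.tsv")
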