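"""Readers for pathway interaction sources and construction of the global graph.

The mechanism-inference method operates on a single *global graph*: the union
of all known gene-gene interactions across every pathway in a database (for
instance all KEGG signaling pathways).  This module reads the supported
sources -- KGML (KEGG pathway XML), a generic edge-list TSV, and GMT gene-set
files for pathway membership -- and merges the interaction records into one
deduplicated undirected graph.

Gene identifiers are treated as opaque strings (Entrez ids, symbols, ...);
mapping between identifier spaces is an upstream concern, though
:func:`map_gene_ids` offers a simple two-column hook.

Scoring downstream is symmetric in the two endpoints, so the global graph is
undirected: edges are keyed by the unordered gene pair, while the originally
observed directions and interaction types are kept as edge metadata for
display in the final mechanism.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionEdge",
    "Pathway",
    "PathwayCollection",
    "GlobalGraph",
    "parse_kgml",
    "read_edge_table",
    "read_gmt",
    "build_global_graph",
    "map_gene_ids",
    "write_graphml",
    "write_sif",
]


@dataclass
class InteractionEdge:
    """A single gene-gene interaction record from one pathway source.

    Self-loops are rejected: an edge score of a self-loop degenerates to
    ``2 * FC * (1 - p)`` and carries no interaction information.
    """

    gene_a: str
    gene_b: str
    directed: bool = True
    interaction_type: str = ""
    source_pathways: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("interaction endpoints must be non-empty gene ids")
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on gene {self.gene_a!r} is not allowed")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered gene pair as a sorted tuple (the deduplication key)."""
        a, b = self.gene_a, self.gene_b
        return (a, b) if a <= b else (b, a)


@dataclass
class Pathway:
    pathway_id: str
    name: str
    genes: set[str]


class PathwayCollection:
    """Mapping of pathway id -> (name, gene set), used for ORA and KO truth."""

    def __init__(self, pathways: Iterable[Pathway] = ()) -> None:
        self._pathways: dict[str, Pathway] = {}
        for p in pathways:
            self.add(p)

    def add(self, pathway: Pathway) -> None:
        if pathway.pathway_id in self._pathways:
            raise ValueError(f"duplicate pathway id {pathway.pathway_id!r}")
        if not pathway.genes:
            raise ValueError(f"pathway {pathway.pathway_id!r} has an empty gene set")
        self._pathways[pathway.pathway_id] = pathway

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[str]:
        return iter(self._pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._pathways[pathway_id]

    def ids(self) -> list[str]:
        return list(self._pathways)

    def gene_universe(self) -> set[str]:
        """Union of all pathway gene sets (genes annotated to >=1 pathway)."""
        out: set[str] = set()
        for p in self._pathways.values():
            out |= p.genes
        return out

    def pathways_containing(self, gene: str) -> list[str]:
        return [pid for pid, p in self._pathways.items() if gene in p.genes]


@dataclass
class GlobalGraph:
    """Deduplicated union of all pathway interactions.

    Backed by an undirected :class:`networkx.Graph`; each edge carries the
    union of interaction types, the union of source pathways, and the set of
    originally observed directed pairs as metadata.
    """

    g: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.g.nodes)

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def edge_pairs(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.g.edges]

    def has_edge(self, a: str, b: str) -> bool:
        return self.g.has_edge(a, b)


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------

_GENE_ENTRY_TYPES = {"gene"}


def parse_kgml(
    source,
    *,
    include_reactions: bool = False,
) -> tuple[list[InteractionEdge], Pathway]:
    """Parse one KGML document into interaction edges plus a pathway entry.

    Parameters
    ----------
    source
        Path, file-like object, or XML string/bytes.
    include_reactions
        Also convert KGML ``reaction`` elements (metabolic substrate/product
        links) into edges.  Off by default: the method is built on signaling
        ``relation`` elements.

    Returns
    -------
    edges, pathway
        One :class:`InteractionEdge` per gene-level relation (group and
        multi-gene entries are expanded to all member-gene combinations), and
        a :class:`Pathway` collecting every gene mentioned in the document.

    Relations whose endpoints cannot be resolved to genes (compounds, maps,
    unknown entry ids) are skipped with a logged warning.
    """
    try:
        if isinstance(source, (str, Path)) and not str(source).lstrip().startswith("<"):
            tree = etree.parse(str(source))
            root = tree.getroot()
        elif isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str):
            root = etree.fromstring(source.encode())
        else:  # file-like
            root = etree.parse(source).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValueError(f"malformed KGML document ({source!r}): {exc}") from exc

    pathway_id = root.get("name", "") or root.get("title", "unknown")
    pathway_name = root.get("title", pathway_id)

    # entry id -> list of gene ids (groups expanded below)
    entry_genes: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}  # entry id -> component entry ids
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "")
        if etype in _GENE_ENTRY_TYPES:
            entry_genes[eid] = entry.get("name", "").split()
        elif etype == "group":
            groups[eid] = [c.get("id") for c in entry.findall("component")]

    def resolve(eid: str) -> list[str]:
        if eid in entry_genes:
            return entry_genes[eid]
        if eid in groups:
            out: list[str] = []
            for cid in groups[eid]:
                out.extend(entry_genes.get(cid, []))
            return out
        return []

    edges: list[InteractionEdge] = []
    all_genes: set[str] = set(g for gs in entry_genes.values() for g in gs)

    def add_pairs(genes_1: list[str], genes_2: list[str], itype: str, directed: bool) -> None:
        for ga in genes_1:
            for gb in genes_2:
                if ga == gb:
                    continue
                edges.append(
                    InteractionEdge(
                        gene_a=ga,
                        gene_b=gb,
                        directed=directed,
                        interaction_type=itype,
                        source_pathways={pathway_id},
                    )
                )

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        g1, g2 = resolve(e1), resolve(e2)
        if not g1 or not g2:
            logger.warning(
                "pathway %s: relation %s->%s has no mappable gene endpoint; skipped",
                pathway_id, e1, e2,
            )
            continue
        subtypes = [s.get("name", "") for s in rel.findall("subtype")]
        itype = ",".join(s for s in subtypes if s) or rel.get("type", "")
        add_pairs(g1, g2, itype, directed=True)

    if include_reactions:
        # Metabolic reactions connect compounds; translate them into gene-gene
        # edges by chaining the catalysing genes: producer of a compound ->
        # consumer of the same compound.
        producers: dict[str, list[str]] = {}
        consumers: dict[str, list[str]] = {}
        for rxn in root.findall("reaction"):
            genes = resolve(rxn.get("id"))
            if not genes:
                logger.warning(
                    "pathway %s: reaction %s has no gene entry; skipped",
                    pathway_id, rxn.get("id"),
                )
                continue
            for sub in rxn.findall("substrate"):
                consumers.setdefault(sub.get("name", ""), []).extend(genes)
            for prod in rxn.findall("product"):
                producers.setdefault(prod.get("name", ""), []).extend(genes)
        for compound, prod_genes in producers.items():
            add_pairs(prod_genes, consumers.get(compound, []), "reaction", directed=True)

    if not all_genes:
        raise ValueError(f"KGML pathway {pathway_id!r} contains no gene entries")
    pathway = Pathway(pathway_id=pathway_id, name=pathway_name, genes=all_genes)
    return edges, pathway


# ---------------------------------------------------------------------------
# Edge-list TSV
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("gene_a", "gene_b", "directed", "interaction_type", "pathway_id")

_TRUE_STRINGS = {"1", "true", "yes", "t", "directed"}


def read_edge_table(source) -> list[InteractionEdge]:
    """Read interactions from a TSV with header gene_a/gene_b/directed/interaction_type/pathway_id.

    Rows with ``gene_a == gene_b`` (self-loops) are dropped and counted in a
    logged warning.  Duplicate rows are returned as-is; deduplication is the
    job of :func:`build_global_graph`.
    """
    if isinstance(source, (str, Path)):
        handle = open(source, newline="")
        close = True
    else:
        handle, close = source, False
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in _EDGE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"edge table is missing required column(s): {missing}")
        edges: list[InteractionEdge] = []
        n_self = 0
        for i, row in enumerate(reader, start=2):
            ga, gb = (row["gene_a"] or "").strip(), (row["gene_b"] or "").strip()
            if not ga or not gb:
                raise ValueError(f"edge table line {i}: blank gene identifier")
            if ga == gb:
                n_self += 1
                continue
            edges.append(
                InteractionEdge(
                    gene_a=ga,
                    gene_b=gb,
                    directed=(row["directed"] or "").strip().lower() in _TRUE_STRINGS,
                    interaction_type=(row["interaction_type"] or "").strip(),
                    source_pathways={(row["pathway_id"] or "").strip()},
                )
            )
        if n_self:
            logger.warning("edge table: dropped %d self-loop row(s)", n_self)
        return edges
    finally:
        if close:
            handle.close()


def write_edge_table(edges: Iterable[InteractionEdge], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_EDGE_COLUMNS)
        for e in edges:
            for pid in sorted(e.source_pathways):
                w.writerow([e.gene_a, e.gene_b, int(e.directed), e.interaction_type, pid])


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(source) -> PathwayCollection:
    """Read a GMT file: one pathway per line, ``id<TAB>description<TAB>gene...``."""
    if isinstance(source, str) and ("\n" in source or "\t" in source or not source):
        text = source  # raw GMT content
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:  # file-like
        text = source.read()
    coll = PathwayCollection()
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        pid, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        coll.add(Pathway(pathway_id=pid, name=desc, genes=set(genes)))
    return coll


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in pathways.ids():
            p = pathways[pid]
            fh.write("\t".join([pid, p.name, *sorted(p.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Global graph
# ---------------------------------------------------------------------------


def build_global_graph(edges: Iterable[InteractionEdge]) -> GlobalGraph:
    """Merge interaction records into one undirected graph keyed by gene pair.

    Merged edge metadata: union of ``source_pathways``, union of interaction
    types, and the set of observed directed orderings (for display only).
    The result is independent of input order and idempotent under rebuilds.
    """
    g = nx.Graph()
    for e in edges:
        a, b = e.pair
        if g.has_edge(a, b):
            data = g.edges[a, b]
            data["source_pathways"] |= set(e.source_pathways)
            if e.interaction_type:
                data["interaction_types"] |= {e.interaction_type}
        else:
            g.add_edge(
                a,
                b,
                source_pathways=set(e.source_pathways),
                interaction_types={e.interaction_type} if e.interaction_type else set(),
                directed_pairs=set(),
            )
        if e.directed:
            g.edges[a, b]["directed_pairs"].add((e.gene_a, e.gene_b))
    return GlobalGraph(g=g)


def map_gene_ids(
    edges: Iterable[InteractionEdge], mapping: Mapping[str, str]
) -> list[InteractionEdge]:
    """Apply a two-column id mapping; edges whose endpoints collide become self-loops and are dropped."""
    out: list[InteractionEdge] = []
    n_dropped = 0
    for e in edges:
        a = mapping.get(e.gene_a, e.gene_a)
        b = mapping.get(e.gene_b, e.gene_b)
        if a == b:
            n_dropped += 1
            continue
        out.append(
            InteractionEdge(a, b, e.directed, e.interaction_type, set(e.source_pathways))
        )
    if n_dropped:
        logger.warning("id mapping collapsed %d edge(s) into self-loops; dropped", n_dropped)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _stringify_attrs(g: nx.Graph) -> nx.Graph:
    out = g.copy()
    for *_, data in out.edges(data=True):
        for key, val in list(data.items()):
            if isinstance(val, (set, frozenset)):
                data[key] = ";".join(
                    ",".join(v) if isinstance(v, tuple) else str(v) for v in sorted(val)
                )
    return out


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(_stringify_attrs(g), path)


def write_sif(g: nx.Graph, path, *, default_type: str = "interacts") -> None:
    """Simple interaction format: one ``gene_a<TAB>type<TAB>gene_b`` line per edge."""
    with open(path, "w") as fh:
        for a, b, data in g.edges(data=True):
            types = data.get("interaction_types") or {default_type}
            label = ",".join(sorted(types)) if isinstance(types, (set, frozenset)) else str(types)
            fh.write(f"{a}\t{label or default_type}\t{b}\n")
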