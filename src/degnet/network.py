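"""Pathway XML parsing and the integrated pathway regulatory network.

Pathway files follow the KGML 0.7 subset: ``entry`` elements carrying one or
more gene ids, ``group`` entries referencing component entries, and typed
``relation`` elements between entries. Gene-type entries become network nodes
keyed by their sorted gene-id tuple — a node is a pathway "data object", the
product of one or more genes — and nodes are merged across pathways by that
key. Degrees are computed on the simple undirected graph; hub selection takes
the top decile of degrees, keeping boundary ties, and reports the hub nodes
that contain screened DEGs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = ["PathwayGraph", "parse_pathway", "integrate", "mark_degs", "select_hub_degs",
           "HubSelection", "write_network_tables"]

NodeKey = tuple[str, ...]

# relation subtypes that express pathway cross-references, not gene relations
_DROP_SUBTYPES = {"maplink"}
_GENE_TYPES = {"gene"}


@dataclass
class PathwayGraph:
    """Integrated pathway network on gene-product nodes.

    ``graph`` is a simple undirected :class:`networkx.Graph`; node attributes
    are ``genes`` (frozenset), ``pathways`` (set) and ``is_deg`` (bool); edge
    attributes are ``relations`` and ``pathways`` (sets). Node keys are the
    sorted gene-id tuples.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, key: NodeKey) -> int:
        return int(self.graph.degree[key])

    def genes(self, key: NodeKey) -> frozenset[str]:
        return self.graph.nodes[key]["genes"]

    def deg_nodes(self) -> list[NodeKey]:
        return sorted(k for k, d in self.graph.nodes(data=True) if d.get("is_deg"))

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, d in self.graph.nodes(data=True):
            out |= d["genes"]
        return out

    def add_node(self, key: NodeKey, pathways: set[str]) -> None:
        if key in self.graph:
            self.graph.nodes[key]["pathways"] |= pathways
        else:
            self.graph.add_node(key, genes=frozenset(key), pathways=set(pathways), is_deg=False)

    def add_edge(self, a: NodeKey, b: NodeKey, relations: set[str], pathways: set[str]) -> None:
        if a == b:
            return
        if self.graph.has_edge(a, b):
            self.graph.edges[a, b]["relations"] |= relations
            self.graph.edges[a, b]["pathways"] |= pathways
        else:
            self.graph.add_edge(a, b, relations=set(relations), pathways=set(pathways))


def parse_pathway(path: str | Path, pathway_id: str | None = None) -> PathwayGraph:
    """Parse one pathway XML file into a single-pathway graph.

    Gene-type entries become candidate nodes keyed by their sorted gene-id
    tuple. Group entries are expanded: a relation touching a group is
    replicated to each (recursively resolved) component. Compound/map entries
    and ``maplink`` relations are dropped with a log line. A relation that
    references a missing entry id raises.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    pid = pathway_id or root.get("name") or Path(path).stem

    entry_genes: dict[str, NodeKey] = {}
    group_components: dict[str, list[str]] = {}
    dropped: set[str] = set()
    for entry in root.findall("entry"):
        eid, etype = entry.get("id"), entry.get("type")
        if etype in _GENE_TYPES:
            genes = tuple(sorted(set((entry.get("name") or "").split())))
            if not genes:
                raise ValueError(f"{path}: gene entry {eid} has no gene ids")
            entry_genes[eid] = genes
        elif etype == "group":
            group_components[eid] = [c.get("id") for c in entry.findall("component")]
        else:
            dropped.add(eid)
    if dropped:
        logger.info("%s: dropped %d non-gene entr(ies)", path, len(dropped))

    def resolve(eid: str, seen: frozenset[str] = frozenset()) -> list[NodeKey]:
        """Entry id → list of gene-node keys (groups expanded recursively)."""
        if eid in entry_genes:
            return [entry_genes[eid]]
        if eid in group_components:
            if eid in seen:
                raise ValueError(f"{path}: cyclic group reference at entry {eid}")
            out: list[NodeKey] = []
            for cid in group_components[eid]:
                out.extend(resolve(cid, seen | {eid}))
            return out
        if eid in dropped:
            return []
        raise ValueError(f"{path}: relation references missing entry id {eid!r}")

    g = PathwayGraph()
    for key in entry_genes.values():
        g.add_node(key, {pid})

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        subtypes = {s.get("name") for s in rel.findall("subtype") if s.get("name")}
        if subtypes & _DROP_SUBTYPES:
            logger.info("%s: dropped maplink relation %s-%s", path, e1, e2)
            continue
        keys1, keys2 = resolve(e1), resolve(e2)
        if not keys1 or not keys2:
            logger.info("%s: dropped relation %s-%s touching a non-gene entry", path, e1, e2)
            continue
        for a in keys1:
            for b in keys2:
                g.add_edge(a, b, subtypes or {"unspecified"}, {pid})
    return g


def integrate(graphs: list[PathwayGraph]) -> PathwayGraph:
    """Merge single-pathway graphs into one integrated network.

    Nodes merge by identical gene-id set; edges deduplicate by unordered
    endpoint pair with relation types and pathway provenance unioned.
    Idempotent and invariant to input order.
    """
    if not graphs:
        raise ValueError("no pathway graphs to integrate")
    merged = PathwayGraph()
    for g in graphs:
        for key, d in g.graph.nodes(data=True):
            merged.add_node(key, set(d["pathways"]))
        for a, b, d in g.graph.edges(data=True):
            merged.add_edge(a, b, set(d["relations"]), set(d["pathways"]))
    return merged


def mark_degs(graph: PathwayGraph, degs) -> PathwayGraph:
    """Flag nodes whose gene set intersects the DEG list (in place; returns graph).

    ``degs`` may be a set of gene ids or a dict gene_id → direction; the
    direction map, when given, is stored for the hub report.
    """
    directions = degs if isinstance(degs, dict) else {}
    deg_set = set(degs)
    for key, d in graph.graph.nodes(data=True):
        hit = d["genes"] & deg_set
        d["is_deg"] = bool(hit)
        d["deg_genes"] = frozenset(hit)
        d["deg_directions"] = {g: directions.get(g) for g in hit}
    return graph


@dataclass(frozen=True)
class HubSelection:
    """Top-decile-degree nodes and the DEGs they contain."""

    top_nodes: tuple[NodeKey, ...]
    hub_nodes: tuple[NodeKey, ...]          # top nodes flagged as DEG nodes
    cutoff_degree: int
    hub_genes_up: tuple[str, ...]
    hub_genes_down: tuple[str, ...]

    @property
    def hub_genes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.hub_genes_up) | set(self.hub_genes_down)))


def select_hub_degs(
    graph: PathwayGraph, top_fraction: float = 0.10, include_ties: bool = True
) -> HubSelection:
    """Select nodes whose degree lies in the top ``top_fraction`` of the network.

    The cutoff rank is ``ceil(top_fraction * |V|)``; with ``include_ties``
    every node whose degree equals the cutoff node's degree is kept. The hub
    DEG list is the union of DEG genes over top nodes flagged as DEG nodes,
    split by screen direction when known.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    nodes = sorted(graph.graph.nodes, key=lambda k: (-graph.degree(k), k))
    k = math.ceil(top_fraction * len(nodes))
    cutoff = graph.degree(nodes[k - 1])
    if include_ties:
        top = [n for n in nodes if graph.degree(n) >= cutoff]
    else:
        top = nodes[:k]
    hubs = [n for n in top if graph.graph.nodes[n].get("is_deg")]
    up: set[str] = set()
    down: set[str] = set()
    for n in hubs:
        d = graph.graph.nodes[n]
        for gene in d.get("deg_genes", frozenset()):
            direction = d.get("deg_directions", {}).get(gene)
            (down if direction == "down" else up).add(gene)
    return HubSelection(
        top_nodes=tuple(top), hub_nodes=tuple(hubs), cutoff_degree=int(cutoff),
        hub_genes_up=tuple(sorted(up)), hub_genes_down=tuple(sorted(down)),
    )


def write_network_tables(graph: PathwayGraph, node_path: str | Path, edge_path: str | Path) -> None:
    """Export Cytoscape-importable node and edge TSVs.

    Node columns: node_key, genes, degree, is_deg, pathways.
    Edge columns: a, b, relations, pathways. Rows sorted for determinism.
    """
    with open(node_path, "w") as fh:
        fh.write("node_key\tgenes\tdegree\tis_deg\tpathways\n")
        for key in sorted(graph.graph.nodes):
            d = graph.graph.nodes[key]
            fh.write("\t".join([
                "|".join(key), ",".join(sorted(d["genes"])), str(graph.degree(key)),
                str(int(bool(d.get("is_deg")))), ",".join(sorted(d["pathways"])),
            ]) + "\n")
    with open(edge_path, "w") as fh:
        fh.write("a\tb\trelations\tpathways\n")
        rows = []
        for a, b, d in graph.graph.edges(data=True):
            a, b = sorted((a, b))
            rows.append(("|".join(a), "|".join(b),
                         ",".join(sorted(d["relations"])), ",".join(sorted(d["pathways"]))))
        for row in sorted(rows):
            fh.write("\t".join(row) + "\n")
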