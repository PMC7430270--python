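"""Directed signaling-pathway graphs and effector-gene topology.

A signaling pathway is modelled as a directed graph over gene IDs. An
*effector gene* is a node that receives signals but outputs none: in-degree
>= 1 and out-degree 0, with self-edges ignored for both degrees (a
self-loop is not a signal to another gene). For each effector, the
*upstream set* is every node with a directed path to it, at its shortest
directed-path length in edges — the network distance used as the
signal-attenuation penalty downstream.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "EffectorSet",
    "find_effectors",
    "upstream_distances",
    "effector_set",
    "effector_census",
    "read_kgml",
    "read_edgelist",
    "read_registry",
]


@dataclass(frozen=True)
class PathwayGraph:
    """A directed gene-interaction graph.

    Parameters
    ----------
    pathway_id : str
        Stable identifier (e.g. a KEGG accession like ``hsa04310``).
    name : str
        Human-readable pathway title.
    nodes : frozenset of str
        Gene IDs. Every edge endpoint must be a member.
    edges : frozenset of (str, str)
        Ordered (source, target) pairs. Self-edges are stored but carry no
        upstream relationship.
    edge_types : mapping (source, target) -> str, optional
        Interaction-type tags (activation/inhibition...). Stored for
        reporting only; scoring uses topology alone.
    """

    pathway_id: str
    name: str
    nodes: frozenset
    edges: frozenset
    edge_types: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        for s, t in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(
                    f"pathway {self.pathway_id!r}: edge ({s!r}, {t!r}) has an "
                    f"endpoint outside the node set"
                )

    def to_networkx(self, drop_self_edges: bool = True) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t in self.edges:
            if drop_self_edges and s == t:
                continue
            g.add_edge(s, t)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class EffectorSet:
    """Effectors of one pathway with their upstream distance maps.

    ``upstream[e]`` maps each gene with a directed path to effector ``e``
    onto its shortest-path length in edges (>= 1); ``e`` itself never
    appears in its own map.
    """

    pathway_id: str
    effectors: tuple
    upstream: dict

    def __post_init__(self):
        for e in self.effectors:
            dmap = self.upstream[e]
            if e in dmap:
                raise ValueError(f"effector {e!r} appears in its own upstream map")
            if any(d < 1 for d in dmap.values()):
                raise ValueError(f"effector {e!r} has an upstream distance < 1")

    def links(self):
        """Yield (upstream gene, effector, distance) triples, sorted."""
        for e in self.effectors:
            for g, d in sorted(self.upstream[e].items()):
                yield g, e, d


def find_effectors(graph: PathwayGraph) -> list:
    """Return the effector genes of ``graph``, sorted by gene ID.

    Effectors are nodes with in-degree >= 1 and out-degree 0 once
    self-edges are discarded. An isolated node has no signal inputs and is
    not an effector.
    """
    g = graph.to_networkx(drop_self_edges=True)
    return sorted(
        n for n in g.nodes if g.out_degree(n) == 0 and g.in_degree(n) >= 1
    )


def upstream_distances(graph: PathwayGraph, effector: str) -> dict:
    """Shortest directed-path length (in edges) from each upstream gene.

    Returns every node with a directed path to ``effector``, mapped to its
    network distance; the effector itself is excluded. Nodes inside cycles
    upstream of the effector enter at their shortest-path distance.

    Raises
    ------
    ValueError
        If ``effector`` is not an effector of this graph.
    """
    if effector not in find_effectors(graph):
        raise ValueError(
            f"gene {effector!r} is not an effector of pathway {graph.pathway_id!r}"
        )
    g = graph.to_networkx(drop_self_edges=True).reverse(copy=False)
    dist = nx.single_source_shortest_path_length(g, effector)
    return {n: d for n, d in dist.items() if n != effector}


def effector_set(graph: PathwayGraph) -> EffectorSet:
    effs = find_effectors(graph)
    return EffectorSet(
        pathway_id=graph.pathway_id,
        effectors=tuple(effs),
        upstream={e: upstream_distances(graph, e) for e in effs},
    )


def effector_census(pathways: list) -> tuple:
    """Count effectors per pathway.

    Returns ``(table, n_with_effectors)`` where ``table`` has one row per
    pathway (pathway_id, name, effector_count) and ``n_with_effectors`` is
    the number of pathways containing at least one effector.
    """
    if not pathways:
        raise ValueError("effector_census requires at least one pathway")
    rows = [
        (p.pathway_id, p.name, len(find_effectors(p))) for p in pathways
    ]
    table = pd.DataFrame(rows, columns=["pathway_id", "name", "effector_count"])
    return table, int((table["effector_count"] > 0).sum())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

#: KGML entry types that contribute gene nodes.
_GENE_TYPES = {"gene"}


def read_kgml(path) -> PathwayGraph:
    """Parse a KEGG KGML pathway file into a :class:`PathwayGraph`.

    A KGML entry of type ``gene`` listing several gene IDs (``name="hsa:1
    hsa:2"``) is expanded into one node per gene, each sharing the entry's
    edges. ``group`` entries are expanded to the union of their components'
    genes. Each ``relation`` becomes directed edges entry1 -> entry2 over
    the expanded gene sets; the first subtype name is kept as the edge
    type. Non-gene entries (compounds, maps) are ignored.
    """
    tree = etree.parse(os.fspath(path))
    root = tree.getroot()
    pathway_id = root.get("name", "") or os.path.basename(os.fspath(path))
    if pathway_id.startswith("path:"):
        pathway_id = pathway_id[len("path:"):]
    name = root.get("title", pathway_id)

    entry_genes: dict = {}
    groups: dict = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype in _GENE_TYPES:
            entry_genes[eid] = entry.get("name", "").split()
        elif etype == "group":
            groups[eid] = [c.get("id") for c in entry.findall("component")]

    # expand groups to their component genes
    for gid, comps in groups.items():
        genes: list = []
        for cid in comps:
            genes.extend(entry_genes.get(cid, []))
        entry_genes[gid] = genes

    nodes: set = set()
    for genes in entry_genes.values():
        nodes.update(genes)

    edges: set = set()
    edge_types: dict = {}
    for rel in root.findall("relation"):
        src = entry_genes.get(rel.get("entry1"), [])
        tgt = entry_genes.get(rel.get("entry2"), [])
        subtype = rel.find("subtype")
        tag = subtype.get("name") if subtype is not None else None
        for s in src:
            for t in tgt:
                edges.add((s, t))
                if tag is not None:
                    edge_types[(s, t)] = tag
    return PathwayGraph(pathway_id, name, frozenset(nodes), frozenset(edges), edge_types)


def read_edgelist(path, pathway_id: str, name: str = "") -> PathwayGraph:
    """Read a TSV edge list (header ``source<TAB>target[<TAB>type]``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:2] != ["source", "target"]:
        raise ValueError(
            f"edge list {path!s}: expected header 'source<TAB>target[<TAB>type]', "
            f"got {list(df.columns)!r}"
        )
    edges = set()
    edge_types = {}
    has_type = len(df.columns) >= 3
    for row in df.itertuples(index=False):
        s, t = str(row[0]), str(row[1])
        edges.add((s, t))
        if has_type and not pd.isna(row[2]):
            edge_types[(s, t)] = str(row[2])
    nodes = {g for e in edges for g in e}
    return PathwayGraph(pathway_id, name or pathway_id, frozenset(nodes), frozenset(edges), edge_types)


def read_registry(path) -> list:
    """Read a pathway registry TSV ``pathway_id<TAB>name<TAB>edgelist_path``.

    Edge-list paths are resolved relative to the registry file. Files
    ending in ``.xml`` or ``.kgml`` are parsed as KGML, anything else as a
    TSV edge list.
    """
    reg = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "name", "edgelist_path"}
    if not required.issubset(set(reg.columns)):
        raise ValueError(
            f"registry {path!s}: expected columns {sorted(required)}, got {list(reg.columns)!r}"
        )
    base = os.path.dirname(os.path.abspath(os.fspath(path)))
    pathways = []
    for row in reg.itertuples(index=False):
        p = row.edgelist_path
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        if p.lower().endswith((".xml", ".kgml")):
            g = read_kgml(p)
            g = PathwayGraph(row.pathway_id, row.name, g.nodes, g.edges, g.edge_types)
        else:
            g = read_edgelist(p, row.pathway_id, row.name)
        pathways.append(g)
    logger.info("loaded %d pathways from %s", len(pathways), path)
    return pathways
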