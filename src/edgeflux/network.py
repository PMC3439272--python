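"""Interaction-network and annotation data model with text-format readers/writers.

The network is a mixed graph: undirected edges (stored once under an
unordered key) and directed arcs.  Undirected edges are treated as
bidirectional only inside the walk engine; here they are single records.
Annotations are term -> gene-set maps (GMT dialect) optionally backed by a
parent-child ontology from which term depths ("levels") are computed.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("edgeflux")

__all__ = [
    "Edge",
    "InteractionNetwork",
    "AnnotationMap",
    "read_edge_list",
    "read_gmt",
    "read_ontology_edges",
    "write_network",
]


@dataclass(frozen=True)
class Edge:
    """A single interaction.

    ``directed`` arcs go source -> target; undirected edges are unordered
    pairs.  ``etype`` is a free-form interaction-type label (e.g. ``pp``,
    ``tf-target``); it is carried through to result tables but does not
    affect the walk.
    """

    source: str
    target: str
    directed: bool = False
    etype: str = ""

    @property
    def key(self) -> tuple:
        """Canonical identity: ordered pair if directed, sorted pair if not."""
        if self.directed:
            return (self.source, self.target, True)
        a, b = sorted((self.source, self.target))
        return (a, b, False)

    @property
    def pair_key(self) -> tuple[str, str]:
        """Unordered endpoint pair (used for the walk's arc set)."""
        a, b = sorted((self.source, self.target))
        return (a, b)

    @property
    def label(self) -> str:
        """Human-readable row identifier, stable across runs."""
        if self.directed:
            return f"{self.source}->{self.target}"
        a, b = sorted((self.source, self.target))
        return f"{a}--{b}"


class InteractionNetwork:
    """A deduplicated mixed graph of molecular interactions.

    Invariants enforced at construction: every endpoint is a node, no
    self-loops (dropped with a logged warning), no duplicates under the
    canonical key within an interaction type, node weights (when attached)
    are strictly positive and finite.
    """

    def __init__(
        self,
        edges: Iterable[Edge] = (),
        nodes: Iterable[str] = (),
        node_weights: Mapping[str, float] | None = None,
    ):
        self.nodes: set[str] = set(nodes)
        self._edges: dict[tuple, Edge] = {}
        self.n_self_loops_dropped = 0
        self.n_duplicates_dropped = 0
        self.n_mixed_resolved = 0
        for e in edges:
            self._add(e)
        self.node_weights: dict[str, float] = {}
        if node_weights is not None:
            self.set_node_weights(node_weights)

    def _add(self, e: Edge) -> None:
        if e.source == e.target:
            self.n_self_loops_dropped += 1
            logger.warning("dropping self-loop on %r", e.source)
            return
        self.nodes.add(e.source)
        self.nodes.add(e.target)
        # dedup within a type: undirected swallows either arc direction;
        # a directed arc arriving where the undirected pair exists (or vice
        # versa) resolves to undirected, maximizing connectivity.
        und_key = (*e.pair_key, False, e.etype)
        if not e.directed:
            removed = False
            for d_key in ((e.pair_key[0], e.pair_key[1], True, e.etype),
                          (e.pair_key[1], e.pair_key[0], True, e.etype)):
                if d_key in self._edges:
                    del self._edges[d_key]
                    removed = True
            if removed:
                self.n_mixed_resolved += 1
                logger.warning(
                    "pair (%s, %s) seen both directed and undirected; "
                    "keeping undirected", *e.pair_key)
            if und_key in self._edges and not removed:
                self.n_duplicates_dropped += 1
                return
            self._edges[und_key] = Edge(*e.pair_key, False, e.etype)
        else:
            if und_key in self._edges:
                self.n_mixed_resolved += 1
                logger.warning(
                    "pair (%s, %s) seen both directed and undirected; "
                    "keeping undirected", *e.pair_key)
                return
            d_key = (e.source, e.target, True, e.etype)
            if d_key in self._edges:
                self.n_duplicates_dropped += 1
                return
            self._edges[d_key] = e

    @property
    def edges(self) -> list[Edge]:
        """Edges in a deterministic (sorted-key) order."""
        return [self._edges[k] for k in sorted(self._edges)]

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, edge_key: tuple) -> bool:
        s, t, directed = edge_key
        if directed:
            return any(k[:3] == (s, t, True) for k in self._edges)
        a, b = sorted((s, t))
        return any(k[:3] == (a, b, False) for k in self._edges)

    def arc_set(self) -> set[tuple[str, str]]:
        """Unique directed arcs after expanding undirected edges; this is
        what the walk engine sees (parallel typed edges collapse)."""
        arcs: set[tuple[str, str]] = set()
        for e in self._edges.values():
            arcs.add((e.source, e.target))
            if not e.directed:
                arcs.add((e.target, e.source))
        return arcs

    def canonical_edge_keys(self) -> list[tuple]:
        """Sorted unique (a, b, directed) keys ignoring the type label."""
        return sorted({k[:3] for k in self._edges})

    def set_node_weights(self, weights: Mapping[str, float]) -> None:
        for gene, w in weights.items():
            if not (math.isfinite(w) and w > 0):
                raise ValueError(
                    f"node weight for {gene!r} must be strictly positive "
                    f"and finite, got {w!r}")
        self.node_weights = dict(weights)

    def induced(self, edges: Iterable[Edge]) -> "InteractionNetwork":
        """Subnetwork with exactly the given edges (no neighbor expansion)."""
        return InteractionNetwork(edges)


@dataclass
class AnnotationMap:
    """term -> gene-set annotations with optional ontology structure.

    ``ontology_parents`` maps a term to its parent set; term levels are
    shortest parent-chain distances from a root (a term with no parents).
    """

    term_to_genes: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    ontology_parents: dict[str, set[str]] | None = None
    levels: dict[str, float] | None = None

    def genes(self) -> set[str]:
        out: set[str] = set()
        for g in self.term_to_genes.values():
            out |= g
        return out

    def gene_to_terms(self) -> dict[str, frozenset[str]]:
        """Inverted index F_i: gene -> set of terms annotating it."""
        idx: dict[str, set[str]] = {}
        for term, genes in self.term_to_genes.items():
            for g in genes:
                idx.setdefault(g, set()).add(term)
        return {g: frozenset(t) for g, t in idx.items()}

    def level_of(self, term: str) -> float:
        if self.levels is None:
            return math.inf
        return self.levels.get(term, math.inf)

    def ancestors_of(self, term: str) -> set[str]:
        if not self.ontology_parents:
            return set()
        out: set[str] = set()
        stack = list(self.ontology_parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.ontology_parents.get(p, ()))
        return out

    def propagate_to_ancestors(self) -> "AnnotationMap":
        """Return a copy where each gene is also annotated to every ancestor
        of its terms (standard ontology true-path semantics)."""
        if not self.ontology_parents:
            return self
        new: dict[str, set[str]] = {t: set(g) for t, g in self.term_to_genes.items()}
        for term, genes in self.term_to_genes.items():
            for anc in self.ancestors_of(term):
                new.setdefault(anc, set()).update(genes)
        return AnnotationMap(
            term_to_genes={t: frozenset(g) for t, g in new.items() if g},
            term_names=dict(self.term_names),
            ontology_parents=self.ontology_parents,
            levels=self.levels,
        )


def read_edge_list(path, default_directed: bool = False) -> InteractionNetwork:
    """Read a tab-separated edge list.

    Columns: source, target, optional flag in {directed, undirected},
    optional interaction-type label.  Lines starting with ``#`` are
    comments.  Raises ``ValueError`` naming the line number on malformed
    input and on an empty file.
    """
    edges: list[Edge] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: malformed edge at line {lineno}: {line!r}")
            source, target = fields[0].strip(), fields[1].strip()
            directed = default_directed
            etype = ""
            if len(fields) >= 3 and fields[2].strip():
                flag = fields[2].strip().lower()
                if flag not in ("directed", "undirected"):
                    raise ValueError(
                        f"{path}: line {lineno}: directedness flag must be "
                        f"'directed' or 'undirected', got {fields[2]!r}")
                directed = flag == "directed"
            if len(fields) >= 4:
                etype = fields[3].strip()
            edges.append(Edge(source, target, directed, etype))
            n_lines += 1
    if n_lines == 0:
        raise ValueError(f"{path}: no edges found (empty edge list)")
    net = InteractionNetwork(edges)
    if net.n_self_loops_dropped:
        logger.info("%s: dropped %d self-loop(s)", path, net.n_self_loops_dropped)
    return net


def read_gmt(path) -> AnnotationMap:
    """Read GMT annotations: term TAB description TAB gene TAB gene ...

    Terms with no genes are dropped with a warning; a line with fewer than
    two fields is malformed.  Gene symbols are case-preserving.
    """
    term_to_genes: dict[str, frozenset[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip():
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: {line!r}")
            term = fields[0].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                logger.warning(
                    "%s: line %d: term %r has no genes; dropped",
                    path, lineno, term)
                continue
            term_to_genes[term] = genes
            term_names[term] = fields[1].strip()
    return AnnotationMap(term_to_genes=term_to_genes, term_names=term_names)


def read_ontology_edges(path) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Read child TAB parent lines; return (parent map, term levels).

    level(term) = shortest parent-chain length from a root (a term with no
    parents); roots are level 0.  Raises on a cycle, listing one.
    """
    parents: dict[str, set[str]] = {}
    terms: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: malformed ontology line {lineno}: {line!r}")
            child, parent = fields[0].strip(), fields[1].strip()
            parents.setdefault(child, set()).add(parent)
            terms.add(child)
            terms.add(parent)
    dg = nx.DiGraph()
    dg.add_nodes_from(terms)
    for child, ps in parents.items():
        for p in ps:
            dg.add_edge(p, child)  # parent -> child, so BFS flows downward
    try:
        cycle = nx.find_cycle(dg)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise ValueError(f"{path}: ontology contains a cycle: {cycle}")
    levels = compute_levels(parents, terms)
    return parents, levels


def compute_levels(parents: Mapping[str, set[str]],
                   terms: Iterable[str] | None = None) -> dict[str, float]:
    """Breadth-first levels from every root (no-parent term); unreachable
    terms get ``math.inf``."""
    all_terms = set(terms) if terms is not None else set(parents)
    for ps in parents.values():
        all_terms |= set(ps)
    children: dict[str, set[str]] = {t: set() for t in all_terms}
    for child, ps in parents.items():
        for p in ps:
            children.setdefault(p, set()).add(child)
    roots = [t for t in sorted(all_terms) if not parents.get(t)]
    levels: dict[str, float] = {t: math.inf for t in all_terms}
    queue: deque[str] = deque()
    for r in roots:
        levels[r] = 0
        queue.append(r)
    while queue:
        t = queue.popleft()
        for c in children.get(t, ()):
            if levels[c] > levels[t] + 1:
                levels[c] = levels[t] + 1
                queue.append(c)
    return levels


def write_network(network: InteractionNetwork,
                  node_attributes: Mapping[str, Mapping[str, object]] | None,
                  path,
                  fmt: str = "edge-list") -> None:
    """Write the network as an edge-list TSV or GraphML.

    ``node_attributes`` maps node -> {attribute name: value}; referencing a
    node absent from the network is an error.  Edge-list output round-trips
    through :func:`read_edge_list`.
    """
    node_attributes = dict(node_attributes or {})
    for node in node_attributes:
        if node not in network.nodes:
            raise ValueError(f"attributes given for unknown node {node!r}")
    if fmt == "edge-list":
        with open(path, "w") as fh:
            fh.write("# source\ttarget\tdirectedness\ttype\n")
            for e in network.edges:
                flag = "directed" if e.directed else "undirected"
                fh.write(f"{e.source}\t{e.target}\t{flag}\t{e.etype}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        for n in sorted(network.nodes):
            g.add_node(n, **{k: v for k, v in node_attributes.get(n, {}).items()})
        for e in network.edges:
            g.add_edge(e.source, e.target,
                       directed=e.directed, etype=e.etype)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}; "
                         "use 'edge-list' or 'graphml'")
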