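"""Gene-annotated ontology handling for visible neural networks.

A visible neural network (VNN) mirrors a biological ontology: every term of
the ontology becomes a block of ``k`` neurons, and a neuron block may only
receive input from the blocks of its child terms (or from the genes annotated
to it).  This module provides the graph plumbing that makes such a network
compilable:

* :func:`load_ontology` parses parent-child edges plus term->gene annotations
  (tab-delimited dialect or OBO) into a validated :class:`OntologyGraph`;
* :func:`prune_ontology` removes terms that are too small or too redundant,
  reassigning their genes and children upward;
* :func:`layerize` assigns every term to a layer and inserts *virtual nodes*
  so that every edge connects adjacent layers only;
* :func:`build_connectivity` emits the binary sparse masks that define where
  trainable weights may exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "OntologyGraph",
    "PruneConfig",
    "LayeredHierarchy",
    "SparseConnectivity",
    "load_ontology",
    "load_obo_ontology",
    "prune_ontology",
    "layerize",
    "build_connectivity",
]

#: Relation labels treated as parent-child by default.  The tab-delimited
#: dialect uses "default"; OBO files use "is_a"/"part_of".
DEFAULT_RELATIONS = ("default", "is_a", "part_of")


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, multiple roots, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OntologyGraph:
    """A rooted, gene-annotated directed acyclic graph of ontology terms.

    Edges are stored parent -> child.  Exactly one term (the root) has no
    parent; every annotated gene is attached to at least one term.
    """

    terms: set[str]
    edges: list[tuple[str, str, str]]  # (parent, child, relation)
    annotations: dict[str, set[str]]  # term -> genes
    root: str = field(init=False)

    def __post_init__(self) -> None:
        self._validate()

    # -- graph views --------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with parent -> child edges over the term set."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for parent, child, rel in self.edges:
            g.add_edge(parent, child, relation=rel)
        return g

    def genes(self) -> list[str]:
        """Sorted list of all annotated genes."""
        out: set[str] = set()
        for gs in self.annotations.values():
            out |= gs
        return sorted(out)

    def children(self, term: str) -> set[str]:
        return {c for p, c, _ in self.edges if p == term}

    def parents(self, term: str) -> set[str]:
        return {p for p, c, _ in self.edges if c == term}

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(
                f"ontology contains a cycle through term {cycle[0][0]!r}"
            )
        roots = [t for t in self.terms if g.in_degree(t) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"ontology must have exactly one root, found {sorted(roots)!r}"
            )
        self.root = roots[0]
        unknown = set(self.annotations) - self.terms
        if unknown:
            raise OntologyError(f"annotations reference unknown terms: {sorted(unknown)}")
        if not any(self.annotations.values()):
            raise OntologyError("ontology has an empty annotation set")


@dataclass(frozen=True)
class PruneConfig:
    """Retention criteria for ontology terms.

    ``min_genes``
        minimum number of genes annotated to a term (after reassignments);
    ``min_distinct_from_children``
        minimum number of a term's genes not annotated to any of its
        children (checked only for terms that have children);
    ``max_depth``
        maximum number of term levels above the bottom layer.
    """

    min_genes: int = 5
    min_distinct_from_children: int = 10
    max_depth: int = 8

    def __post_init__(self) -> None:
        for name in ("min_genes", "min_distinct_from_children", "max_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class LayeredHierarchy:
    """A pruned ontology flattened into strictly adjacent layers.

    Layer 0 is the gene input layer; layer 1 holds the most specific terms;
    the top layer holds the root.  Edges only connect layer ``s`` to layer
    ``s+1``.  Virtual nodes are synthetic pass-through nodes inserted where an
    original edge (or a gene annotated to a high-layer term) would otherwise
    span more than one layer.
    """

    layer_of: dict[str, int]  # node -> layer (terms + virtual nodes)
    virtual_nodes: dict[str, tuple[str, int]]  # node -> (source node, layer)
    edges: list[tuple[str, str]]  # (parent, child), adjacency-only
    genes: list[str]  # ordered gene list = input positions
    gene_links: dict[str, set[str]]  # layer-1 node -> genes feeding it
    terms: set[str]  # real (non-virtual) terms

    @property
    def n_layers(self) -> int:
        return max(self.layer_of.values())

    def nodes_at(self, layer: int) -> list[str]:
        """Deterministic node order: lexicographic, virtual nodes last."""
        nodes = [n for n, s in self.layer_of.items() if s == layer]
        return sorted(nodes, key=lambda n: (n in self.virtual_nodes, n))

    # -- (de)serialization for checkpoints and the CLI ----------------------

    def to_dict(self) -> dict:
        return {
            "layer_of": dict(self.layer_of),
            "virtual_nodes": {k: list(v) for k, v in self.virtual_nodes.items()},
            "edges": [list(e) for e in self.edges],
            "genes": list(self.genes),
            "gene_links": {k: sorted(v) for k, v in self.gene_links.items()},
            "terms": sorted(self.terms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayeredHierarchy":
        return cls(
            layer_of=dict(d["layer_of"]),
            virtual_nodes={k: (v[0], int(v[1])) for k, v in d["virtual_nodes"].items()},
            edges=[tuple(e) for e in d["edges"]],
            genes=list(d["genes"]),
            gene_links={k: set(v) for k, v in d["gene_links"].items()},
            terms=set(d["terms"]),
        )


@dataclass
class SparseConnectivity:
    """Binary masks defining where trainable VNN weights may exist.

    ``masks[0]`` has shape ``(k*p1, g)`` (layer-1 nodes vs genes); ``masks[s-1]``
    for ``s >= 2`` has shape ``(k*p_s, k*p_{s-1})``.  Entries are 0/1.
    """

    masks: list[sp.csr_matrix]
    node_order: list[list[str]]  # node order per layer, index 0 = layer 1
    genes: list[str]
    k: int


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _iter_lines(source) -> list[str]:
    """Accept a path, an open file, or an iterable of lines."""
    if hasattr(source, "read"):
        return list(source)
    if isinstance(source, (str, bytes)):
        with open(source) as fh:
            return list(fh)
    return list(source)


def load_ontology(edge_source, annotation_source, relations=DEFAULT_RELATIONS) -> OntologyGraph:
    """Parse a tab-delimited ontology into a validated :class:`OntologyGraph`.

    Edge records are ``parent<TAB>child[<TAB>relation]`` (relation defaults to
    ``"default"``); annotation records are ``term<TAB>gene[<TAB>"gene"]``.
    Annotation records naming a term absent from the edge set are rejected
    with a warning reporting the rejected count.
    """
    edges: list[tuple[str, str, str]] = []
    terms: set[str] = set()
    for line in _iter_lines(edge_source):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise OntologyError(f"malformed edge record: {line!r}")
        parent, child = parts[0], parts[1]
        relation = parts[2] if len(parts) > 2 else "default"
        if relation not in relations:
            continue
        edges.append((parent, child, relation))
        terms |= {parent, child}

    annotations: dict[str, set[str]] = {}
    rejected = 0
    for line in _iter_lines(annotation_source):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise OntologyError(f"malformed annotation record: {line!r}")
        term, gene = parts[0], parts[1]
        if term not in terms:
            rejected += 1
            continue
        annotations.setdefault(term, set()).add(gene)
    if rejected:
        warnings.warn(
            f"rejected {rejected} annotation record(s) referencing unknown terms",
            stacklevel=2,
        )
    return OntologyGraph(terms=terms, edges=edges, annotations=annotations)


def load_obo_ontology(obo_source, annotation_source, relations=("is_a", "part_of")) -> OntologyGraph:
    """Load an OBO ontology plus a two-column term->gene annotation table."""
    import obonet

    graph = obonet.read_obo(obo_source)
    # obonet edges run child -> parent with the relation as the edge key
    edge_lines = [
        f"{parent}\t{child}\t{key}"
        for child, parent, key in graph.edges(keys=True)
        if key in relations
    ]
    return load_ontology(edge_lines, annotation_source, relations=relations)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def _delete_term(g: nx.DiGraph, annotations: dict[str, set[str]], term: str) -> None:
    """Remove ``term``, attaching its children and genes to all its parents."""
    parents = list(g.predecessors(term))
    children = list(g.successors(term))
    genes = annotations.pop(term, set())
    for p in parents:
        if genes:
            annotations.setdefault(p, set()).update(genes)
        for c in children:
            if not g.has_edge(p, c):
                g.add_edge(p, c, relation="default")
    g.remove_node(term)


def _depths_from_root(g: nx.DiGraph, root: str) -> dict[str, int]:
    """Longest-path distance from the root (root = 0)."""
    depth = {n: 0 for n in g.nodes}
    for n in nx.topological_sort(g):
        for c in g.successors(n):
            depth[c] = max(depth[c], depth[n] + 1)
    return depth


def prune_ontology(graph: OntologyGraph, config: PruneConfig = PruneConfig()) -> OntologyGraph:
    """Delete terms failing the retention criteria, merging them upward.

    Terms are evaluated bottom-up (children before parents) and the procedure
    iterates to a fixpoint, because a deletion pushes genes to the parents and
    can change their distinct-gene counts.  A deleted term's genes and
    children are assigned to *all* of its parents.  The depth limit is then
    enforced by deleting (with the same rule) any term sitting more than
    ``max_depth`` levels below the root, deepest first.  The root is never
    deleted.
    """
    g = graph.to_networkx()
    annotations = {t: set(gs) for t, gs in graph.annotations.items()}
    root = graph.root

    outer_changed = True
    while outer_changed:
        outer_changed = False
        # criteria fixpoint, bottom-up
        changed = True
        while changed:
            changed = False
            for term in reversed(list(nx.topological_sort(g))):
                if term == root or term not in g:
                    continue
                genes = annotations.get(term, set())
                if len(genes) < config.min_genes:
                    _delete_term(g, annotations, term)
                    changed = outer_changed = True
                    continue
                children = list(g.successors(term))
                if children:
                    child_genes: set[str] = set()
                    for c in children:
                        child_genes |= annotations.get(c, set())
                    if len(genes - child_genes) < config.min_distinct_from_children:
                        _delete_term(g, annotations, term)
                        changed = outer_changed = True
        # depth enforcement
        depth = _depths_from_root(g, root)
        if depth and max(depth.values()) > config.max_depth:
            too_deep = [t for t, d in depth.items() if d > config.max_depth]
            for term in sorted(too_deep, key=lambda t: -depth[t]):
                if term in g and term != root:
                    _delete_term(g, annotations, term)
                    outer_changed = True

    if root not in g or (g.out_degree(root) == 0 and not annotations.get(root)):
        raise OntologyError("pruning deleted every term below the root")
    surviving = set(g.nodes)
    if not any(annotations.get(t) for t in surviving):
        raise OntologyError("pruning produced an ontology with no annotated genes")
    return OntologyGraph(
        terms=surviving,
        edges=[(p, c, d.get("relation", "default")) for p, c, d in g.edges(data=True)],
        annotations={t: gs for t, gs in annotations.items() if gs},
    )


# ---------------------------------------------------------------------------
# Layerization
# ---------------------------------------------------------------------------


def layerize(graph: OntologyGraph) -> LayeredHierarchy:
    """Assign layers and insert virtual nodes so edges span exactly one layer.

    A term's layer is 1 + the length of the longest term-path to a bottom
    term below it (bottom terms sit at layer 1; genes conceptually at layer
    0).  For an edge spanning ``d > 1`` layers, ``d - 1`` pass-through virtual
    nodes are inserted; chains are shared between parents consuming the same
    child.  A gene annotated to a term at layer ``L > 1`` is routed through
    ``L - 1`` gene-carrying virtual nodes so that genes feed layer-1 nodes
    only.
    """
    g = graph.to_networkx()
    # layer = longest path down to a bottom term
    layer: dict[str, int] = {}
    for term in reversed(list(nx.topological_sort(g))):
        succ = list(g.successors(term))
        layer[term] = 1 if not succ else 1 + max(layer[c] for c in succ)

    layer_of = dict(layer)
    virtual_nodes: dict[str, tuple[str, int]] = {}
    edges: list[tuple[str, str]] = []
    gene_links: dict[str, set[str]] = {}

    def _virtual(source: str, at_layer: int, tag: str) -> str:
        name = f"{source}::{tag}::{at_layer}"
        if name not in virtual_nodes:
            virtual_nodes[name] = (source, at_layer)
            layer_of[name] = at_layer
        return name

    # term-term edges, routed through shared virtual chains
    seen: set[tuple[str, str]] = set()
    for parent, child in g.edges():
        lo, hi = layer[child], layer[parent]
        prev = child
        for s in range(lo + 1, hi):
            node = _virtual(child, s, "virt")
            if (node, prev) not in seen:
                edges.append((node, prev))
                seen.add((node, prev))
            prev = node
        if (parent, prev) not in seen:
            edges.append((parent, prev))
            seen.add((parent, prev))

    # gene annotations, routed through gene-carrying virtual chains
    for term in sorted(graph.terms):
        genes = graph.annotations.get(term, set())
        if not genes:
            continue
        if layer[term] == 1:
            gene_links.setdefault(term, set()).update(genes)
            continue
        carrier = _virtual(term, 1, "genecarrier")
        gene_links.setdefault(carrier, set()).update(genes)
        prev = carrier
        for s in range(2, layer[term]):
            node = _virtual(term, s, "genecarrier")
            if (node, prev) not in seen:
                edges.append((node, prev))
                seen.add((node, prev))
            prev = node
        if (term, prev) not in seen:
            edges.append((term, prev))
            seen.add((term, prev))

    return LayeredHierarchy(
        layer_of=layer_of,
        virtual_nodes=virtual_nodes,
        edges=edges,
        genes=graph.genes(),
        gene_links=gene_links,
        terms=set(graph.terms),
    )


# ---------------------------------------------------------------------------
# Connectivity masks
# ---------------------------------------------------------------------------


def build_connectivity(hierarchy: LayeredHierarchy, k: int) -> SparseConnectivity:
    """Compile a :class:`LayeredHierarchy` into binary sparse weight masks.

    Every node owns ``k`` neurons.  The first mask links layer-1 neurons to
    the genes feeding their node (``k`` nonzeros per gene link); each later
    mask holds a dense ``k x k`` block per hierarchy edge (``k**2`` nonzeros
    per edge).  Node ordering is deterministic: lexicographic within a layer,
    virtual nodes after real nodes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_layers = hierarchy.n_layers
    node_order = [hierarchy.nodes_at(s) for s in range(1, n_layers + 1)]
    gene_index = {g: i for i, g in enumerate(hierarchy.genes)}

    masks: list[sp.csr_matrix] = []
    # layer 1: (k*p1) x g
    layer1 = node_order[0]
    rows, cols = [], []
    for ni, node in enumerate(layer1):
        for gene in sorted(hierarchy.gene_links.get(node, ())):
            gi = gene_index[gene]
            for j in range(k):
                rows.append(ni * k + j)
                cols.append(gi)
    masks.append(
        sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(k * len(layer1), len(hierarchy.genes)),
        )
    )

    # layers 2..top: (k*p) x (k*c)
    for s in range(2, n_layers + 1):
        parents = node_order[s - 1]
        children = node_order[s - 2]
        pidx = {n: i for i, n in enumerate(parents)}
        cidx = {n: i for i, n in enumerate(children)}
        rows, cols = [], []
        for parent, child in hierarchy.edges:
            if hierarchy.layer_of[parent] != s:
                continue
            pi, ci = pidx[parent], cidx[child]
            for a in range(k):
                for b in range(k):
                    rows.append(pi * k + a)
                    cols.append(ci * k + b)
        masks.append(
            sp.csr_matrix(
                (np.ones(len(rows), dtype=np.int8), (rows, cols)),
                shape=(k * len(parents), k * len(children)),
            )
        )

    return SparseConnectivity(masks=masks, node_order=node_order, genes=list(hierarchy.genes), k=k)
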