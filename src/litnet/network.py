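"""Co-occurrence and hierarchy networks: construction, set algebra,
properties, common-node similarity, and Gephi-compatible I/O.

Every edge carries the set of supporting pmids so set operations recompute
weights exactly instead of summing (summing would double-count documents
matched by both queries).  Co-occurrence scope is the whole title+abstract;
self-loops are excluded.  GEXF round-trips preserve nodes, labels,
attributes, edges and weights — pmid provenance is deliberately not written
to GEXF (documented lossy); imported edges carry ``pmids=None``.
"""

from __future__ import annotations

import io
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx

from .corpus import Corpus, EntityId, document_entities, mention_counts
from .errors import FormatError, UsageError
from .ontology import HierTree, MeshTree, Taxonomy, induced_subtree, mesh_forest


@dataclass
class NodeData:
    """Node payload.  ``pmids`` (supporting documents) enables exact
    doc_count recomputation under set operations; it is ``None`` for nodes
    without document provenance (hierarchy nodes, GEXF imports)."""

    label: str
    entity_class: str | None = None
    doc_count: int = 0
    attrs: dict = field(default_factory=dict)
    pmids: frozenset[str] | None = None


@dataclass
class EdgeData:
    """Edge payload.  ``pmids is None`` means provenance unknown (e.g. a
    network re-imported from GEXF); the stored weight is then authoritative."""

    pmids: frozenset[str] | None
    weight: int

    @classmethod
    def from_pmids(cls, pmids: Iterable[str]) -> "EdgeData":
        fs = frozenset(pmids)
        return cls(pmids=fs, weight=len(fs))


def _ekey(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class CoocNetwork:
    nodes: dict[str, NodeData] = field(default_factory=dict)
    edges: dict[tuple[str, str], EdgeData] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add_node(self, node_id: str, data: NodeData) -> None:
        self.nodes[node_id] = data

    def add_edge(self, u: str, v: str, data: EdgeData) -> None:
        if u == v:
            raise UsageError(f"self-loop on {u!r} not allowed")
        if u not in self.nodes or v not in self.nodes:
            raise UsageError(f"edge endpoints {u!r}, {v!r} must be nodes")
        self.edges[_ekey(u, v)] = data

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self) -> set[str]:
        return set(self.nodes)

    def copy(self) -> "CoocNetwork":
        return CoocNetwork(
            nodes={
                nid: NodeData(d.label, d.entity_class, d.doc_count, dict(d.attrs), d.pmids)
                for nid, d in self.nodes.items()
            },
            edges={k: EdgeData(e.pmids, e.weight) for k, e in self.edges.items()},
            provenance=dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# construction


def build_cooc_network(
    corpus: Corpus,
    pmids: Iterable[str] | None = None,
    classes: Iterable[str] | None = None,
    query_text: str = "",
    corpus_id: str = "",
) -> CoocNetwork:
    """Document-level co-occurrence network over the selected documents.

    Nodes are normalized entities of the selected classes; ``doc_count`` is
    the number of distinct supporting documents.  Two entities are linked iff
    at least one selected document mentions both; the edge stores exactly
    those pmids and ``weight = |pmids|``.
    """
    selected = sorted(set(corpus.documents) if pmids is None else
                      set(pmids) & set(corpus.documents))
    net = CoocNetwork(provenance={"query_text": query_text, "corpus_id": corpus_id})

    node_pmids: dict[EntityId, set[str]] = {}
    edge_pmids: dict[tuple[str, str], set[str]] = {}
    for pmid in selected:
        ents = document_entities(corpus[pmid], classes)
        for e in ents:
            node_pmids.setdefault(e, set()).add(pmid)
        for a, b in itertools.combinations(ents, 2):
            edge_pmids.setdefault(_ekey(a.node_id, b.node_id), set()).add(pmid)

    labels = _display_labels(corpus, selected, classes, node_pmids)
    for eid in sorted(node_pmids):
        net.add_node(
            eid.node_id,
            NodeData(
                label=labels[eid],
                entity_class=eid.entity_class or None,
                doc_count=len(node_pmids[eid]),
                pmids=frozenset(node_pmids[eid]),
            ),
        )
    for key in sorted(edge_pmids):
        net.edges[key] = EdgeData.from_pmids(edge_pmids[key])
    return net


def _display_labels(corpus, selected, classes, node_pmids) -> dict[EntityId, str]:
    # most frequent surface form, lexicographic tie-break
    counts = mention_counts(corpus, selected, classes)
    out = {}
    for eid in node_pmids:
        forms = counts.get(eid, {})
        if forms:
            out[eid] = min(forms, key=lambda m: (-forms[m], m))
        else:
            out[eid] = eid.node_id
    return out


def build_hierarchy_network(
    hits: Mapping[EntityId, int],
    ontology: Taxonomy | MeshTree,
    root: int | None = None,
    categories: Iterable[str] = ("C", "D"),
) -> CoocNetwork:
    """Tree-shaped network rendering of the hierarchy over ``hits``.

    ``hits`` maps entity ids (all taxid-namespace or all mesh-namespace) to
    document counts.  Taxa render via :func:`induced_subtree`, MeSH UIs via
    :func:`mesh_forest`; mixed namespaces are a usage error.
    """
    namespaces = {e.namespace for e in hits}
    if len(namespaces) > 1:
        raise UsageError(f"mixed hit namespaces {sorted(namespaces)}")
    ns = namespaces.pop() if namespaces else None

    if ns == "taxid":
        if not isinstance(ontology, Taxonomy):
            raise UsageError("taxid hits require a Taxonomy")
        doc_counts = {int(e.accession): c for e, c in hits.items()}
        tree = induced_subtree(ontology, set(doc_counts), root, doc_counts)
    elif ns == "mesh":
        if not isinstance(ontology, MeshTree):
            raise UsageError("mesh hits require a MeshTree")
        doc_counts = {e.accession: c for e, c in hits.items()}
        tree = mesh_forest(ontology, set(doc_counts), categories, doc_counts)
    elif ns is None:
        return CoocNetwork()
    else:
        raise UsageError(f"hits in namespace {ns!r} have no hierarchy")
    return hierarchy_to_network(tree)


def hierarchy_to_network(tree: HierTree) -> CoocNetwork:
    """Graph form of a :class:`HierTree`: parent-child edges, category and
    doc_count carried as node attributes.  Hierarchy edges have no document
    provenance, hence weight 0."""
    net = CoocNetwork(provenance={"kind": "hierarchy"})
    for node in tree.root.walk():
        net.add_node(
            node.node_id,
            NodeData(
                label=node.label,
                doc_count=int(node.payload.get("doc_count", 0)),
                attrs={"category": node.category},
            ),
        )
    for node in tree.root.walk():
        for child in node.children:
            net.add_edge(node.node_id, child.node_id, EdgeData.from_pmids(()))
    return net


# ---------------------------------------------------------------------------
# set algebra


def _merge_pmids(a: EdgeData, b: EdgeData, op: str) -> EdgeData:
    if a.pmids is not None and b.pmids is not None:
        return EdgeData.from_pmids(a.pmids | b.pmids)
    # provenance unknown on at least one side: fall back on stored weights
    weight = max(a.weight, b.weight) if op == "union" else min(a.weight, b.weight)
    return EdgeData(pmids=None, weight=weight)


def _merge_node(a: NodeData | None, b: NodeData | None) -> NodeData:
    if a is None:
        assert b is not None
        return NodeData(b.label, b.entity_class, b.doc_count, dict(b.attrs), b.pmids)
    if b is None:
        return NodeData(a.label, a.entity_class, a.doc_count, dict(a.attrs), a.pmids)
    attrs = dict(b.attrs)
    attrs.update(a.attrs)
    if a.pmids is not None and b.pmids is not None:
        pmids: frozenset[str] | None = a.pmids | b.pmids
        doc_count = len(pmids)
    else:
        pmids, doc_count = None, max(a.doc_count, b.doc_count)
    return NodeData(a.label, a.entity_class or b.entity_class, doc_count, attrs, pmids)


def union_networks(a: CoocNetwork, b: CoocNetwork) -> CoocNetwork:
    out = CoocNetwork(provenance={"op": "union"})
    for nid in sorted(a.node_ids() | b.node_ids()):
        out.add_node(nid, _merge_node(a.nodes.get(nid), b.nodes.get(nid)))
    for key in sorted(set(a.edges) | set(b.edges)):
        if key in a.edges and key in b.edges:
            out.edges[key] = _merge_pmids(a.edges[key], b.edges[key], "union")
        else:
            src = a.edges.get(key) or b.edges[key]
            out.edges[key] = EdgeData(src.pmids, src.weight)
    return out


def intersect_networks(a: CoocNetwork, b: CoocNetwork) -> CoocNetwork:
    """Nodes in both, edges in both; edge pmids are united so the weight
    reflects every supporting document from either side."""
    out = CoocNetwork(provenance={"op": "intersect"})
    for nid in sorted(a.node_ids() & b.node_ids()):
        out.add_node(nid, _merge_node(a.nodes.get(nid), b.nodes.get(nid)))
    for key in sorted(set(a.edges) & set(b.edges)):
        out.edges[key] = _merge_pmids(a.edges[key], b.edges[key], "union")
    return out


def difference_networks(a: CoocNetwork, b: CoocNetwork) -> CoocNetwork:
    """Nodes of ``a`` absent from ``b``; edges of ``a`` whose endpoints both
    survive."""
    out = CoocNetwork(provenance={"op": "difference"})
    surviving = a.node_ids() - b.node_ids()
    for nid in sorted(surviving):
        d = a.nodes[nid]
        out.add_node(nid, NodeData(d.label, d.entity_class, d.doc_count, dict(d.attrs), d.pmids))
    for (u, v), e in sorted(a.edges.items()):
        if u in surviving and v in surviving:
            out.edges[(u, v)] = EdgeData(e.pmids, e.weight)
    return out


def highlight_common(a: CoocNetwork, b: CoocNetwork) -> CoocNetwork:
    """Union of the two networks with a boolean node attribute ``common``
    marking nodes present in both — the display-style counterpart of strict
    intersection."""
    out = union_networks(a, b)
    both = a.node_ids() & b.node_ids()
    for nid, data in out.nodes.items():
        data.attrs["common"] = nid in both
    out.provenance = {"op": "highlight_common"}
    return out


# ---------------------------------------------------------------------------
# properties and similarity


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    density: float
    mean_degree: float
    n_components: int
    max_component_size: int

    def as_tsv(self) -> str:
        head = "n_nodes\tn_edges\tdensity\tmean_degree\tn_components\tmax_component_size"
        row = (
            f"{self.n_nodes}\t{self.n_edges}\t{self.density:.6g}\t"
            f"{self.mean_degree:.6g}\t{self.n_components}\t{self.max_component_size}"
        )
        return head + "\n" + row + "\n"


def network_properties(net: CoocNetwork) -> NetworkStats:
    n, m = net.n_nodes, net.n_edges
    if n == 0:
        return NetworkStats(0, 0, 0.0, 0.0, 0, 0)
    g = to_networkx(net)
    comps = list(nx.connected_components(g))
    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        density=(2.0 * m / (n * (n - 1))) if n >= 2 else 0.0,
        mean_degree=2.0 * m / n,
        n_components=len(comps),
        max_component_size=max(len(c) for c in comps),
    )


@dataclass(frozen=True)
class SimilarityReport:
    """Common-node comparison of a query network against a reference.

    True positives are the nodes present in both networks; precision, recall,
    F1 and Jaccard derive from the node-set counts.  ``defined`` is False
    when both networks are empty (all metrics meaningless)."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    jaccard: float
    defined: bool = True

    def as_tsv(self) -> str:
        head = "tp\tfp\tfn\tprecision\trecall\tf1\tjaccard\tdefined"
        if not self.defined:
            row = f"{self.tp}\t{self.fp}\t{self.fn}\tNA\tNA\tNA\tNA\tfalse"
        else:
            row = (
                f"{self.tp}\t{self.fp}\t{self.fn}\t{self.precision:.6g}\t"
                f"{self.recall:.6g}\t{self.f1:.6g}\t{self.jaccard:.6g}\ttrue"
            )
        return head + "\n" + row + "\n"


def compare_networks(query: CoocNetwork, reference: CoocNetwork) -> SimilarityReport:
    qn, rn = query.node_ids(), reference.node_ids()
    tp = len(qn & rn)
    fp = len(qn - rn)
    fn = len(rn - qn)
    if not qn and not rn:
        return SimilarityReport(0, 0, 0, math.nan, math.nan, math.nan, math.nan,
                                defined=False)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return SimilarityReport(tp, fp, fn, precision, recall, f1, jaccard)


# ---------------------------------------------------------------------------
# Gephi-compatible I/O


def to_networkx(net: CoocNetwork) -> nx.Graph:
    g = nx.Graph()
    for nid, d in net.nodes.items():
        attrs = {"label": d.label, "doc_count": d.doc_count}
        if d.entity_class is not None:
            attrs["entity_class"] = d.entity_class
        for k, v in d.attrs.items():
            attrs[k] = v
        g.add_node(nid, **attrs)
    for (u, v), e in net.edges.items():
        g.add_edge(u, v, weight=e.weight)
    return g


def from_networkx(g: nx.Graph) -> CoocNetwork:
    if g.is_directed():
        raise FormatError("directed graphs are not supported")
    net = CoocNetwork()
    for nid, data in g.nodes(data=True):
        data = dict(data)
        label = data.pop("label", str(nid))
        entity_class = data.pop("entity_class", None)
        doc_count = int(data.pop("doc_count", 0))
        for drop in ("id", "pid"):  # gexf bookkeeping keys
            data.pop(drop, None)
        net.add_node(str(nid), NodeData(label, entity_class, doc_count, data))
    for u, v, data in g.edges(data=True):
        if u == v:
            raise FormatError(f"self-loop on {u!r} in imported graph")
        net.edges[_ekey(str(u), str(v))] = EdgeData(
            pmids=None, weight=int(data.get("weight", 1))
        )
    return net


def export_gexf(net: CoocNetwork, stream: TextIO) -> None:
    """Write GEXF 1.2draft (undirected, typed attvalues) for Gephi."""
    for line in nx.generate_gexf(to_networkx(net), version="1.2draft"):
        stream.write(line + "\n")


def export_graphml(net: CoocNetwork, stream: TextIO) -> None:
    for line in nx.generate_graphml(to_networkx(net)):
        stream.write(line + "\n")


def import_gexf(stream: TextIO | str) -> CoocNetwork:
    """Read a GEXF file back into a :class:`CoocNetwork`.

    Node ids, labels, attributes, edges and weights are preserved; pmid
    provenance is not representable in GEXF, so edges come back with
    ``pmids=None``.  Directed or malformed files raise :class:`FormatError`.
    """
    text = stream if isinstance(stream, str) else stream.read()
    try:
        g = nx.read_gexf(io.BytesIO(text.encode("utf-8")), relabel=False)
    except Exception as exc:  # networkx raises various xml errors
        raise FormatError(f"not a readable GEXF file: {exc}") from exc
    return from_networkx(g)


# ---------------------------------------------------------------------------
# tree serialization


def tree_to_nested(tree: HierTree, fmt: str = "indented") -> str:
    """Serialize a :class:`HierTree` deterministically.

    ``indented``: two spaces per depth, ``label [category]`` per line with a
    trailing ``(doc_count)`` when present.  ``json``: nested objects with
    node_id/label/category/payload/children.
    """
    if fmt == "indented":
        lines: list[str] = []

        def walk(node, depth):
            suffix = ""
            if "doc_count" in node.payload:
                suffix = f" ({node.payload['doc_count']})"
            lines.append(f"{'  ' * depth}{node.label} [{node.category}]{suffix}")
            for child in node.children:
                walk(child, depth + 1)

        walk(tree.root, 0)
        return "\n".join(lines) + "\n"
    if fmt == "json":

        def shape(node):
            return {
                "node_id": node.node_id,
                "label": node.label,
                "category": node.category,
                "payload": node.payload,
                "children": [shape(c) for c in node.children],
            }

        return json.dumps(shape(tree.root), indent=2, sort_keys=True) + "\n"
    raise ValueError(f"unknown tree format {fmt!r}")


def network_summary(net: CoocNetwork) -> str:
    """Node table as TSV: node_id, label, entity_class, doc_count, category, common."""
    lines = ["node_id\tlabel\tentity_class\tdoc_count\tcategory\tcommon"]
    for nid in sorted(net.nodes):
        d = net.nodes[nid]
        lines.append(
            f"{nid}\t{d.label}\t{d.entity_class or ''}\t{d.doc_count}\t"
            f"{d.attrs.get('category', '')}\t{d.attrs.get('common', '')}"
        )
    return "\n".join(lines) + "\n"
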