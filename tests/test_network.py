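import io
import itertools
import math
import random

import pytest

from litnet.corpus import EntityId, parse_pubtator
from litnet.errors import FormatError, UsageError
from litnet.network import (
    CoocNetwork,
    EdgeData,
    NodeData,
    build_cooc_network,
    build_hierarchy_network,
    compare_networks,
    difference_networks,
    export_gexf,
    export_graphml,
    hierarchy_to_network,
    highlight_common,
    import_gexf,
    intersect_networks,
    network_properties,
    network_summary,
    tree_to_nested,
    union_networks,
)
from litnet.ontology import induced_subtree, load_mesh
from litnet.query import run_query


def mknet(nodes, edges=()):
    net = CoocNetwork()
    for nid in nodes:
        net.add_node(nid, NodeData(label=nid))
    for u, v, pmids in edges:
        net.add_edge(u, v, EdgeData.from_pmids(pmids))
    return net


# --- construction ----------------------------------------------------------


def test_single_doc_two_entities():
    text = (
        "1|t|T\n1|a|X and Y\n"
        "1\t2\t3\tX\tSpecies\t11\n"
        "1\t8\t9\tY\tSpecies\t22\n\n"
    )
    net = build_cooc_network(parse_pubtator(text))
    assert net.n_nodes == 2 and net.n_edges == 1
    edge = net.edges[("taxid:11", "taxid:22")]
    assert edge.weight == 1 and edge.pmids == {"1"}


def test_single_entity_no_edges():
    text = "1|t|T\n1|a|X here\n1\t2\t3\tX\tSpecies\t11\n\n"
    net = build_cooc_network(parse_pubtator(text))
    assert net.n_nodes == 1 and net.n_edges == 0


def test_empty_selection_gives_empty_network(corpus):
    net = build_cooc_network(corpus, pmids=set())
    assert net.n_nodes == 0 and net.n_edges == 0


def brute_force_cooc(corpus, pmids, classes=None):
    """Oracle: double loop over documents x unordered entity pairs."""
    from litnet.corpus import normalize_identifier

    node_pmids, edge_pmids = {}, {}
    for doc in corpus:
        if doc.pmid not in pmids:
            continue
        ents = set()
        for ann in doc.annotations:
            if classes is not None and ann.entity_class not in classes:
                continue
            ents.update(normalize_identifier(ann.raw_id, ann.entity_class))
        ids = sorted(e.node_id for e in ents)
        for nid in ids:
            node_pmids.setdefault(nid, set()).add(doc.pmid)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                edge_pmids.setdefault((ids[i], ids[j]), set()).add(doc.pmid)
    return node_pmids, edge_pmids


def test_cooc_matches_brute_force(big_corpus):
    pmids = set(big_corpus.documents)
    net = build_cooc_network(big_corpus, pmids)
    node_pmids, edge_pmids = brute_force_cooc(big_corpus, pmids)
    assert set(net.nodes) == set(node_pmids)
    assert {nid: d.doc_count for nid, d in net.nodes.items()} == {
        nid: len(ps) for nid, ps in node_pmids.items()
    }
    assert set(net.edges) == set(edge_pmids)
    for key, e in net.edges.items():
        assert e.pmids == edge_pmids[key]
        assert e.weight == len(edge_pmids[key])


def test_cooc_weight_invariants(big_corpus):
    net = build_cooc_network(big_corpus)
    for (u, v), e in net.edges.items():
        assert e.weight == len(e.pmids)
        assert net.nodes[u].doc_count >= e.weight
        assert net.nodes[v].doc_count >= e.weight


def test_ground_truth_pairs(corpus, groundtruth):
    net = build_cooc_network(corpus)
    gt_pairs = {
        tuple(k.split("|")): set(v)
        for k, v in groundtruth["corpus"]["pair_pmids"].items()
    }
    assert {k: e.pmids for k, e in net.edges.items()} == {
        k: frozenset(v) for k, v in gt_pairs.items()
    }


# --- hierarchy networks ----------------------------------------------------


def test_hierarchy_network_taxonomy_labels(taxonomy, groundtruth):
    species = [int(t) for t, r in groundtruth["taxonomy"]["rank"].items()
               if r == "species"][:3]
    hits = {EntityId("taxid", str(t), "Species"): 2 for t in species}
    net = build_hierarchy_network(hits, taxonomy)
    for t in species:
        data = net.nodes[str(t)]
        assert data.label == f"{t}: {groundtruth['taxonomy']['name'][str(t)]}"
        assert data.attrs["category"] == "hit"
        assert data.doc_count == 2


def test_hierarchy_network_mesh_labels(mesh, groundtruth):
    ui = sorted(mesh.descriptors)[0]
    net = build_hierarchy_network({EntityId("mesh", ui, "Chemical"): 1}, mesh)
    tn = groundtruth["mesh"]["per_ui"][ui][0]
    assert net.nodes[tn].label == f"{tn}: {groundtruth['mesh']['heading'][ui]}"


def test_hierarchy_network_single_root_hit(taxonomy):
    root = taxonomy.root_taxid
    net = build_hierarchy_network({EntityId("taxid", str(root), "Species"): 1}, taxonomy)
    assert net.n_nodes == 1 and net.n_edges == 0


def test_hierarchy_network_mixed_namespaces_rejected(taxonomy):
    hits = {
        EntityId("taxid", "9001101", "Species"): 1,
        EntityId("mesh", "D9000001", "Chemical"): 1,
    }
    with pytest.raises(UsageError, match="mixed"):
        build_hierarchy_network(hits, taxonomy)


# --- set algebra -----------------------------------------------------------


def random_networks(seed, n_pairs):
    """Pairs of networks built from random pmid selections of one corpus."""
    from litnet.fixtures import FixtureSpec, make_all

    arts = make_all(FixtureSpec(seed=17, n_docs=60))
    corpus = parse_pubtator(arts["corpus.pubtator"])
    rng = random.Random(seed)
    pmids = sorted(corpus.documents)
    for _ in range(n_pairs):
        sa = set(rng.sample(pmids, rng.randint(5, 30)))
        sb = set(rng.sample(pmids, rng.randint(5, 30)))
        yield (build_cooc_network(corpus, sa), build_cooc_network(corpus, sb),
               corpus, sa, sb)


class TestSetOps:
    def test_idempotence(self, corpus):
        a = build_cooc_network(corpus)
        assert union_networks(a, a).node_ids() == a.node_ids()
        assert set(union_networks(a, a).edges) == set(a.edges)
        assert intersect_networks(a, a).node_ids() == a.node_ids()
        d = difference_networks(a, a)
        assert d.n_nodes == 0 and d.n_edges == 0

    def test_inclusion_exclusion_and_partition(self):
        for a, b, *_ in random_networks(17, 10):
            u = union_networks(a, b)
            i = intersect_networks(a, b)
            d = difference_networks(a, b)
            assert len(u.nodes) == a.n_nodes + b.n_nodes - i.n_nodes
            assert d.node_ids() | i.node_ids() == a.node_ids()
            assert d.node_ids() & i.node_ids() == set()

    def test_node_edge_sets_match_set_algebra_oracle(self):
        for a, b, *_ in random_networks(18, 10):
            u = union_networks(a, b)
            i = intersect_networks(a, b)
            d = difference_networks(a, b)
            assert u.node_ids() == a.node_ids() | b.node_ids()
            assert i.node_ids() == a.node_ids() & b.node_ids()
            assert d.node_ids() == a.node_ids() - b.node_ids()
            assert set(u.edges) == set(a.edges) | set(b.edges)
            assert set(i.edges) == set(a.edges) & set(b.edges)
            assert set(d.edges) == {
                (x, y) for (x, y) in a.edges
                if x in d.node_ids() and y in d.node_ids()
            }

    def test_commutativity(self):
        for a, b, *_ in random_networks(19, 5):
            assert union_networks(a, b).node_ids() == union_networks(b, a).node_ids()
            assert set(union_networks(a, b).edges) == set(union_networks(b, a).edges)
            assert intersect_networks(a, b).node_ids() == intersect_networks(b, a).node_ids()

    def test_union_weights_recomputed_from_pmids(self):
        for a, b, corpus, sa, sb in random_networks(20, 5):
            u = union_networks(a, b)
            rebuilt = build_cooc_network(corpus, sa | sb)
            assert set(u.edges) == set(rebuilt.edges)
            for k in u.edges:
                assert u.edges[k].pmids == rebuilt.edges[k].pmids
                assert u.edges[k].weight == rebuilt.edges[k].weight
            assert {n: d.doc_count for n, d in u.nodes.items()} == {
                n: d.doc_count for n, d in rebuilt.nodes.items()
            }

    def test_weight_invariant_after_any_op(self):
        for a, b, *_ in random_networks(21, 5):
            for net in (union_networks(a, b), intersect_networks(a, b),
                        difference_networks(a, b), highlight_common(a, b)):
                for e in net.edges.values():
                    assert e.pmids is not None and e.weight == len(e.pmids)


class TestHighlightCommon:
    def test_disjoint(self):
        a = mknet(["x", "y"], [("x", "y", {"1"})])
        b = mknet(["p", "q"], [("p", "q", {"2"})])
        h = highlight_common(a, b)
        assert h.n_nodes == 4
        assert not any(d.attrs["common"] for d in h.nodes.values())

    def test_identical(self):
        a = mknet(["x", "y"], [("x", "y", {"1"})])
        h = highlight_common(a, a)
        assert all(d.attrs["common"] for d in h.nodes.values())

    def test_exactly_four_shared(self):
        a = mknet([f"s{i}" for i in range(4)] + ["a1", "a2"])
        b = mknet([f"s{i}" for i in range(4)] + ["b1", "b2", "b3"])
        h = highlight_common(a, b)
        assert sum(d.attrs["common"] for d in h.nodes.values()) == 4


# --- properties ------------------------------------------------------------


class TestNetworkProperties:
    def test_empty(self):
        stats = network_properties(CoocNetwork())
        assert (stats.n_nodes, stats.n_edges, stats.density,
                stats.mean_degree, stats.n_components,
                stats.max_component_size) == (0, 0, 0.0, 0.0, 0, 0)

    def test_triangle(self):
        net = mknet(["a", "b", "c"],
                    [("a", "b", {"1"}), ("b", "c", {"1"}), ("a", "c", {"1"})])
        stats = network_properties(net)
        assert stats.density == 1.0
        assert stats.n_components == 1
        assert stats.mean_degree == 2.0

    def test_components_match_flood_fill(self, big_corpus):
        net = build_cooc_network(big_corpus)
        stats = network_properties(net)
        # flood fill oracle
        adj = {n: set() for n in net.nodes}
        for u, v in net.edges:
            adj[u].add(v)
            adj[v].add(u)
        seen, comps = set(), []
        for start in net.nodes:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                n = stack.pop()
                if n in comp:
                    continue
                comp.add(n)
                stack.extend(adj[n] - comp)
            seen |= comp
            comps.append(comp)
        assert stats.n_components == len(comps)
        assert stats.max_component_size == max(len(c) for c in comps)

    def test_singleton_density_zero(self):
        assert network_properties(mknet(["only"])).density == 0.0


# --- similarity ------------------------------------------------------------


class TestCompareNetworks:
    def test_identity(self, corpus):
        a = build_cooc_network(corpus)
        rep = compare_networks(a, a)
        assert (rep.precision, rep.recall, rep.f1, rep.jaccard) == (1.0, 1.0, 1.0, 1.0)
        assert rep.defined

    def test_disjoint(self):
        rep = compare_networks(mknet(["a", "b"]), mknet(["c"]))
        assert rep.tp == 0
        assert (rep.precision, rep.recall, rep.f1, rep.jaccard) == (0.0, 0.0, 0.0, 0.0)

    def test_overlap_4_fixture(self):
        a = mknet([f"s{i}" for i in range(4)] + [f"a{i}" for i in range(6)])
        b = mknet([f"s{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        rep = compare_networks(a, b)
        assert (rep.tp, rep.fp, rep.fn) == (4, 6, 4)
        assert rep.precision == 0.4
        assert rep.recall == 0.5
        assert rep.jaccard == 4 / 14
        assert rep.tp + rep.fp == a.n_nodes
        assert rep.tp + rep.fn == b.n_nodes

    def test_both_empty_flagged_undefined(self):
        rep = compare_networks(CoocNetwork(), CoocNetwork())
        assert not rep.defined
        assert math.isnan(rep.precision)

    def test_symmetry(self):
        for a, b, *_ in random_networks(22, 5):
            fwd, rev = compare_networks(a, b), compare_networks(b, a)
            assert fwd.tp == rev.tp
            assert fwd.precision == rev.recall and fwd.recall == rev.precision
            assert fwd.f1 == pytest.approx(rev.f1)


# --- I/O -------------------------------------------------------------------


def roundtrip_gexf(net):
    buf = io.StringIO()
    export_gexf(net, buf)
    return import_gexf(buf.getvalue())


class TestGexf:
    def test_empty_roundtrip(self):
        back = roundtrip_gexf(CoocNetwork())
        assert back.n_nodes == 0 and back.n_edges == 0

    def test_two_node_roundtrip(self):
        net = mknet(["x", "y"], [("x", "y", {"1", "2"})])
        net.nodes["x"].attrs["common"] = True
        back = roundtrip_gexf(net)
        assert back.node_ids() == {"x", "y"}
        assert back.edges[("x", "y")].weight == 2
        assert back.edges[("x", "y")].pmids is None  # provenance documented lossy
        assert back.nodes["x"].attrs["common"] is True

    def test_fixture_roundtrip_preserves_everything(self, corpus):
        net = build_cooc_network(corpus)
        back = roundtrip_gexf(net)
        assert back.node_ids() == net.node_ids()
        assert set(back.edges) == set(net.edges)
        for k in net.edges:
            assert back.edges[k].weight == net.edges[k].weight
        for nid, d in net.nodes.items():
            assert back.nodes[nid].label == d.label
            assert back.nodes[nid].doc_count == d.doc_count
            assert back.nodes[nid].entity_class == d.entity_class

    def test_hierarchy_attrs_roundtrip(self, taxonomy):
        species = 9001101
        tree = induced_subtree(taxonomy, {species})
        net = hierarchy_to_network(tree)
        back = roundtrip_gexf(net)
        assert back.nodes[str(species)].attrs["category"] == "hit"

    def test_directed_file_rejected(self):
        directed = (
            '<?xml version="1.0" encoding="utf-8"?>'
            '<gexf xmlns="http://www.gexf.net/1.2draft" version="1.2">'
            '<graph defaultedgetype="directed"><nodes>'
            '<node id="a" label="a"/><node id="b" label="b"/></nodes>'
            '<edges><edge id="0" source="a" target="b"/></edges>'
            "</graph></gexf>"
        )
        with pytest.raises(FormatError):
            import_gexf(directed)

    def test_malformed_file_rejected(self):
        with pytest.raises(FormatError):
            import_gexf("this is not xml at all")

    def test_graphml_export_is_wellformed(self, corpus):
        import xml.etree.ElementTree as ET

        net = build_cooc_network(corpus)
        buf = io.StringIO()
        export_graphml(net, buf)
        root = ET.fromstring(buf.getvalue())
        assert root.tag.endswith("graphml")


# --- tree serialization ----------------------------------------------------


class TestTreeToNested:
    def test_single_node(self, taxonomy):
        t = induced_subtree(taxonomy, {taxonomy.root_taxid})
        assert len(tree_to_nested(t).strip().split("\n")) == 1

    def test_chain_depths(self, taxonomy):
        t = induced_subtree(taxonomy, {9000003})  # phylum node: depth-2 chain
        lines = tree_to_nested(t).rstrip("\n").split("\n")
        assert len(lines) == 3
        assert [len(l) - len(l.lstrip()) for l in lines] == [0, 2, 4]

    def test_line_count_equals_node_count(self, taxonomy):
        rng = random.Random(3)
        hits = set(rng.sample(sorted(taxonomy.nodes), 8))
        t = induced_subtree(taxonomy, hits)
        assert len(tree_to_nested(t).rstrip("\n").split("\n")) == t.n_nodes()

    def test_json_shape(self, taxonomy):
        import json

        t = induced_subtree(taxonomy, {9001101})
        data = json.loads(tree_to_nested(t, "json"))
        assert set(data) == {"node_id", "label", "category", "payload", "children"}

    def test_doc_count_rendered(self, taxonomy):
        t = induced_subtree(taxonomy, {9001101}, doc_counts={9001101: 4})
        assert "(4)" in tree_to_nested(t)


def test_network_summary_header(corpus):
    net = build_cooc_network(corpus)
    head = network_summary(net).split("\n", 1)[0]
    assert head.split("\t") == ["node_id", "label", "entity_class",
                               "doc_count", "category", "common"]


def test_rebuild_from_union_equals_union_of_networks(corpus, groundtruth):
    planted = groundtruth["corpus"]["planted"]
    sa = set(planted["zetaflavone"])
    sb = set(planted["glowmoss extract"])
    na = build_cooc_network(corpus, sa)
    nb = build_cooc_network(corpus, sb)
    u = union_networks(na, nb)
    rebuilt = build_cooc_network(corpus, sa | sb)
    assert u.node_ids() == rebuilt.node_ids()
    assert set(u.edges) == set(rebuilt.edges)
    for k in u.edges:
        assert u.edges[k].pmids == rebuilt.edges[k].pmids
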