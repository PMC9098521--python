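"""NCBI-taxonomy and MeSH tree loading, plus induced hierarchies over hits.

The taxonomy loader consumes the NCBI dump dialect (fields separated by
``\\t|\\t``, records terminated by ``\\t|``).  MeSH descriptors come either in
the ASCII ``*NEWRECORD`` dialect or a 3-column TSV fallback
(``ui<TAB>heading<TAB>comma-joined tree numbers``).

Hierarchies over a hit set are returned as :class:`HierTree`: a rooted tree
whose nodes carry a category (``hit`` / ``ancestor`` / ``recommended``), a
label, and an optional payload such as ``doc_count``.  Children are ordered
lexicographically by node id so serialization is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .errors import FormatError, StructuralError, UnknownIdError

# ---------------------------------------------------------------------------
# taxonomy


@dataclass(frozen=True)
class TaxonNode:
    parent: int
    rank: str
    name: str


@dataclass
class Taxonomy:
    nodes: dict[int, TaxonNode]
    root_taxid: int
    qc: list[str] = field(default_factory=list, compare=False)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def name_of(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank_of(self, taxid: int) -> str:
        return self.nodes[taxid].rank


def _split_dump_row(line: str) -> list[str]:
    row = line.rstrip("\r\n")
    if row.endswith("\t|"):
        row = row[: -len("\t|")]
    return row.split("\t|\t")


def load_taxonomy_dump(nodes_stream: str | TextIO, names_stream: str | TextIO) -> Taxonomy:
    """Load ``nodes.dmp``/``names.dmp``-dialect streams into a :class:`Taxonomy`.

    Only rows whose name class is ``scientific name`` define labels; nodes
    without one get the placeholder ``taxid:<id>`` plus a QC warning.  A
    parent-pointer cycle raises :class:`StructuralError` listing the cycle.
    """
    nodes_text = nodes_stream if isinstance(nodes_stream, str) else nodes_stream.read()
    names_text = names_stream if isinstance(names_stream, str) else names_stream.read()

    parents: dict[int, tuple[int, str]] = {}
    for lineno, line in enumerate(nodes_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dump_row(line)
        if len(fields) < 3:
            raise FormatError(f"nodes line {lineno}: expected >=3 fields, got {len(fields)}")
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise FormatError(f"nodes line {lineno}: non-integer taxid") from exc
        parents[taxid] = (parent, fields[2])

    names: dict[int, str] = {}
    qc: list[str] = []
    for lineno, line in enumerate(names_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dump_row(line)
        if len(fields) < 4:
            raise FormatError(f"names line {lineno}: expected >=4 fields, got {len(fields)}")
        taxid = int(fields[0])
        if fields[3] != "scientific name":
            continue
        if taxid not in parents:
            qc.append(f"names line {lineno}: taxid {taxid} not in nodes")
            continue
        names[taxid] = fields[1]

    root = next((t for t, (p, _) in parents.items() if p == t or p not in parents), None)
    if root is None:
        raise StructuralError("no root node (every node has a distinct known parent)")

    nodes: dict[int, TaxonNode] = {}
    for taxid, (parent, rank) in parents.items():
        if taxid not in names:
            qc.append(f"taxid {taxid} has no scientific name")
        nodes[taxid] = TaxonNode(parent, rank, names.get(taxid, f"taxid:{taxid}"))

    tax = Taxonomy(nodes=nodes, root_taxid=root, qc=qc)
    _check_acyclic(tax)
    return tax


def _check_acyclic(tax: Taxonomy) -> None:
    state: dict[int, int] = {}  # 0 in-progress, 1 done
    for start in tax.nodes:
        path: list[int] = []
        cur = start
        while True:
            if state.get(cur) == 1:
                break
            if state.get(cur) == 0:
                cycle = path[path.index(cur):] if cur in path else [cur]
                raise StructuralError(
                    "cycle in taxonomy parent pointers: "
                    + " -> ".join(str(t) for t in cycle + [cur])
                )
            state[cur] = 0
            path.append(cur)
            parent = tax.nodes[cur].parent
            if cur == tax.root_taxid or parent == cur or parent not in tax.nodes:
                break
            cur = parent
        for t in path:
            state[t] = 1


def ancestors(tax: Taxonomy, taxid: int) -> list[int]:
    """Ancestor taxids nearest-first, self excluded, ending at the root."""
    if taxid not in tax.nodes:
        raise UnknownIdError(f"unknown taxid {taxid}")
    out: list[int] = []
    cur = taxid
    while cur != tax.root_taxid:
        cur = tax.nodes[cur].parent
        out.append(cur)
    return out


def filter_clade(tax: Taxonomy, hits: Iterable[int], clade: int) -> set[int]:
    """Subset of ``hits`` lying inside ``clade`` (clade itself included)."""
    if clade not in tax.nodes:
        raise UnknownIdError(f"unknown clade taxid {clade}")
    kept: set[int] = set()
    for h in hits:
        if h not in tax.nodes:
            continue
        if h == clade or clade in ancestors(tax, h):
            kept.add(h)
    return kept


# ---------------------------------------------------------------------------
# MeSH


@dataclass(frozen=True)
class MeshDescriptor:
    ui: str
    heading: str
    tree_numbers: tuple[str, ...]


@dataclass
class MeshTree:
    descriptors: dict[str, MeshDescriptor]
    positions: dict[str, str]  # tree number -> owning ui
    qc: list[str] = field(default_factory=list, compare=False)


#: Canonical labels of the MeSH category roots this pipeline works with.
CATEGORY_LABELS = {"C": "Diseases [C]", "D": "Chemicals and Drugs [D]"}


def load_mesh(stream: str | TextIO, dialect: str = "tsv") -> MeshTree:
    """Load MeSH descriptor records from the ASCII or TSV dialect.

    Duplicate UIs and tree numbers claimed by two descriptors are format
    errors.  Descriptors with zero tree numbers are retained but flagged as
    unplaceable.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if dialect == "ascii":
        records = _parse_mesh_ascii(text)
    elif dialect == "tsv":
        records = _parse_mesh_tsv(text)
    else:
        raise ValueError(f"unknown MeSH dialect {dialect!r}")

    descriptors: dict[str, MeshDescriptor] = {}
    positions: dict[str, str] = {}
    qc: list[str] = []
    for desc in records:
        if desc.ui in descriptors:
            raise FormatError(f"duplicate MeSH ui {desc.ui}")
        descriptors[desc.ui] = desc
        if not desc.tree_numbers:
            qc.append(f"descriptor {desc.ui} has no tree numbers (unplaceable)")
        for tn in desc.tree_numbers:
            if tn in positions:
                raise FormatError(
                    f"tree number {tn} claimed by both {positions[tn]} and {desc.ui}"
                )
            positions[tn] = desc.ui
    return MeshTree(descriptors=descriptors, positions=positions, qc=qc)


def _parse_mesh_ascii(text: str) -> list[MeshDescriptor]:
    records: list[MeshDescriptor] = []
    ui: str | None = None
    heading = ""
    tns: list[str] = []
    in_record = False

    def flush():
        nonlocal ui, heading, tns, in_record
        if in_record:
            if ui is None:
                raise FormatError("MeSH record without UI line")
            records.append(MeshDescriptor(ui, heading, tuple(tns)))
        ui, heading, tns, in_record = None, "", [], False

    for line in text.splitlines():
        line = line.rstrip()
        if line == "*NEWRECORD":
            flush()
            in_record = True
        elif line.startswith("MH = "):
            heading = line[5:]
        elif line.startswith("MN = "):
            tns.append(line[5:])
        elif line.startswith("UI = "):
            ui = line[5:]
    flush()
    return records


def _parse_mesh_tsv(text: str) -> list[MeshDescriptor]:
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"MeSH TSV line {lineno}: expected 3 fields, got {len(fields)}")
        ui, heading, joined = fields
        tns = tuple(t for t in joined.split(",") if t)
        records.append(MeshDescriptor(ui, heading, tns))
    return records


def tree_number_parent(tn: str) -> str | None:
    """Parent position of a dotted tree number; None for top-level codes."""
    if "." in tn:
        return tn.rsplit(".", 1)[0]
    return None


# ---------------------------------------------------------------------------
# hierarchy trees


@dataclass
class HierNode:
    node_id: str
    label: str
    category: str  # hit | ancestor | recommended
    payload: dict = field(default_factory=dict)
    children: list["HierNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class HierTree:
    root: HierNode
    skipped: list[str] = field(default_factory=list, compare=False)

    def node_ids(self) -> set[str]:
        return {n.node_id for n in self.root.walk()}

    def n_nodes(self) -> int:
        return sum(1 for _ in self.root.walk())

    def n_edges(self) -> int:
        return sum(len(n.children) for n in self.root.walk())


def _assemble_tree(
    node_ids: set[str],
    parent_of: Mapping[str, str | None],
    make_node,
) -> HierNode:
    children: dict[str, list[str]] = {nid: [] for nid in node_ids}
    root_id = None
    for nid in node_ids:
        parent = parent_of[nid]
        if parent is None:
            root_id = nid
        else:
            children[parent].append(nid)

    def build(nid: str) -> HierNode:
        node = make_node(nid)
        node.children = [build(c) for c in sorted(children[nid])]
        return node

    assert root_id is not None
    return build(root_id)


def induced_subtree(
    tax: Taxonomy,
    hits: Iterable[int],
    root: int | None = None,
    doc_counts: Mapping[int, int] | None = None,
) -> HierTree:
    """Minimal tree over ``hits`` plus every ancestor on a hit-to-root path.

    Hits absent from the taxonomy, or not descending from ``root``, are
    reported in ``skipped`` and excluded — never fatal.  Hit nodes get
    category ``hit`` (internal hits allowed), others ``ancestor``.  Labels
    are ``<taxid>: <scientific name>``.
    """
    if root is None:
        root = tax.root_taxid
    if root not in tax.nodes:
        raise UnknownIdError(f"unknown root taxid {root}")

    hitset = set(hits)
    keep: set[int] = {root}
    skipped: list[str] = []
    for h in sorted(hitset):
        if h not in tax.nodes:
            skipped.append(f"taxid {h}: not in taxonomy")
            continue
        if h == root:
            continue
        anc = ancestors(tax, h)
        if root not in anc:
            skipped.append(f"taxid {h}: outside clade {root}")
            continue
        keep.add(h)
        keep.update(anc[: anc.index(root)])

    parent_of: dict[str, str | None] = {}
    for t in keep:
        parent_of[str(t)] = None if t == root else str(tax.nodes[t].parent)

    def make_node(nid: str) -> HierNode:
        t = int(nid)
        payload = {}
        if doc_counts is not None and t in doc_counts:
            payload["doc_count"] = doc_counts[t]
        return HierNode(
            node_id=nid,
            label=f"{t}: {tax.nodes[t].name}",
            category="hit" if t in hitset else "ancestor",
            payload=payload,
        )

    tree = HierTree(root=_assemble_tree({str(t) for t in keep}, parent_of, make_node))
    tree.skipped = skipped
    return tree


MESH_FOREST_ROOT_ID = "MeSH"


def mesh_forest(
    mesh: MeshTree,
    hits: Iterable[str],
    categories: Iterable[str] = ("C", "D"),
    doc_counts: Mapping[str, int] | None = None,
) -> HierTree:
    """Forest of hit tree-number positions united under a synthetic root.

    Each hit UI contributes one node per owned tree number whose top-level
    letter is in ``categories``; ancestors materialize by truncating dotted
    codes.  Node identity is the tree number, so a descriptor with positions
    in both C and D appears as two hit nodes.  Labels are
    ``<tree number>: <heading>``; category roots use their canonical labels.
    """
    cats = set(categories)
    skipped: list[str] = []
    hit_positions: set[str] = set()
    hit_ui_of: dict[str, str] = {}
    closure: set[str] = set()

    for ui in sorted(set(hits)):
        desc = mesh.descriptors.get(ui)
        if desc is None:
            skipped.append(f"mesh ui {ui}: not in MeSH tree")
            continue
        for tn in desc.tree_numbers:
            if tn[0] not in cats:
                continue
            hit_positions.add(tn)
            hit_ui_of[tn] = ui
            cur: str | None = tn
            while cur is not None:
                closure.add(cur)
                cur = tree_number_parent(cur)

    letters = sorted({tn[0] for tn in closure})
    node_ids = {MESH_FOREST_ROOT_ID} | set(letters) | closure
    parent_of: dict[str, str | None] = {MESH_FOREST_ROOT_ID: None}
    for letter in letters:
        parent_of[letter] = MESH_FOREST_ROOT_ID
    for tn in closure:
        parent_of[tn] = tree_number_parent(tn) or tn[0]

    def make_node(nid: str) -> HierNode:
        if nid == MESH_FOREST_ROOT_ID:
            return HierNode(nid, "MeSH Tree Structures", "ancestor")
        if nid in CATEGORY_LABELS or (len(nid) == 1 and nid.isalpha()):
            return HierNode(nid, CATEGORY_LABELS.get(nid, f"[{nid}]"), "ancestor")
        ui = mesh.positions.get(nid)
        heading = mesh.descriptors[ui].heading if ui else nid
        payload = {}
        if doc_counts is not None and nid in hit_positions:
            ui_hit = hit_ui_of[nid]
            if ui_hit in doc_counts:
                payload["doc_count"] = doc_counts[ui_hit]
        return HierNode(
            node_id=nid,
            label=f"{nid}: {heading}",
            category="hit" if nid in hit_positions else "ancestor",
            payload=payload,
        )

    tree = HierTree(root=_assemble_tree(node_ids, parent_of, make_node))
    tree.skipped = skipped
    return tree
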