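"""Allied-species recommendation from a reference species list.

A reference list (one scientific name per line, ``#`` comments) is resolved
against the loaded taxonomy by exact case-insensitive scientific-name match.
For every anchor node of the requested rank (genus by default) that covers at
least one literature-hit species, the reference species under that anchor
that are not themselves hits are recommended, and can be drawn into a
hierarchy network as extra nodes with category ``recommended``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .errors import UnknownIdError
from .network import CoocNetwork, EdgeData, NodeData
from .ontology import Taxonomy, ancestors

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RefEntry:
    raw_name: str
    taxid: int | None
    issue: str | None = None


@dataclass
class ReferenceList:
    entries: list[RefEntry]
    source_name: str = ""

    def resolved(self) -> list[int]:
        return [e.taxid for e in self.entries if e.taxid is not None]

    def report(self) -> list[str]:
        return [f"{e.raw_name}\t{e.issue}" for e in self.entries if e.issue]


def parse_reference_lines(text: str) -> list[str]:
    """Names from a reference-list file: one per line, ``#`` comments, blank
    lines skipped."""
    names = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(line)
    return names


def match_names(names: Iterable[str], tax: Taxonomy, source_name: str = "") -> ReferenceList:
    """Resolve raw names by exact case-insensitive scientific-name match.

    Unmatched names stay in the list with ``taxid=None``; names shared by two
    taxids are reported ambiguous and left unresolved.  Total function.
    """
    by_name: dict[str, list[int]] = {}
    for taxid, node in tax.nodes.items():
        by_name.setdefault(node.name.casefold(), []).append(taxid)

    entries: list[RefEntry] = []
    for raw in names:
        cands = by_name.get(raw.casefold(), [])
        if len(cands) == 1:
            entries.append(RefEntry(raw, cands[0]))
        elif not cands:
            entries.append(RefEntry(raw, None, "no taxonomy match"))
        else:
            entries.append(
                RefEntry(raw, None, f"ambiguous: taxids {sorted(cands)}")
            )
    return ReferenceList(entries=entries, source_name=source_name)


@dataclass(frozen=True)
class Recommendation:
    anchor: int
    hit_species: frozenset[int]
    recommended: frozenset[int]

    def __post_init__(self):
        assert not (self.recommended & self.hit_species)


def _rank_anchor(tax: Taxonomy, taxid: int, rank: str) -> int | None:
    """Nearest strict ancestor whose rank string equals ``rank`` exactly."""
    for anc in ancestors(tax, taxid):
        if tax.rank_of(anc) == rank:
            return anc
    return None


def recommend_allied(
    hits: Iterable[int],
    ref: ReferenceList,
    tax: Taxonomy,
    rank: str = "genus",
) -> list[Recommendation]:
    """Recommend reference species sharing a rank-level ancestor with a hit.

    One :class:`Recommendation` per anchor node of rank ``rank`` covering at
    least one hit, holding the resolved reference species under that anchor
    minus the hits themselves; empty recommendations are dropped.  Output is
    sorted by anchor taxid and invariant to input ordering.
    """
    hitset = {h for h in hits if h in tax.nodes}
    anchor_hits: dict[int, set[int]] = {}
    for h in sorted(hitset):
        anchor = _rank_anchor(tax, h, rank)
        if anchor is None:
            log.warning("hit taxid %d has no ancestor of rank %r; skipped", h, rank)
            continue
        anchor_hits.setdefault(anchor, set()).add(h)

    if not anchor_hits:
        log.warning("no hit has an ancestor of rank %r; nothing to recommend", rank)
        return []

    anchor_refs: dict[int, set[int]] = {a: set() for a in anchor_hits}
    for r in ref.resolved():
        if r not in tax.nodes:
            continue
        anchor = _rank_anchor(tax, r, rank)
        if anchor in anchor_refs:
            anchor_refs[anchor].add(r)

    out: list[Recommendation] = []
    for anchor in sorted(anchor_hits):
        recommended = anchor_refs[anchor] - hitset
        if recommended:
            out.append(
                Recommendation(anchor, frozenset(anchor_hits[anchor]), frozenset(recommended))
            )
    return out


def annotate_recommendations(
    tree_net: CoocNetwork,
    recs: Iterable[Recommendation],
    tax: Taxonomy,
) -> CoocNetwork:
    """Add recommended species to a hierarchy network, each linked to its
    anchor-rank node.  The input network is not mutated."""
    out = tree_net.copy()
    for rec in recs:
        anchor_id = str(rec.anchor)
        if anchor_id not in out.nodes:
            raise UnknownIdError(
                f"anchor node {anchor_id} ({tax.nodes[rec.anchor].name if rec.anchor in tax.nodes else '?'}) "
                f"missing from network"
            )
        for taxid in sorted(rec.recommended):
            nid = str(taxid)
            if nid not in out.nodes:
                out.add_node(
                    nid,
                    NodeData(
                        label=f"{taxid}: {tax.nodes[taxid].name}",
                        doc_count=0,
                        attrs={"category": "recommended"},
                    ),
                )
            out.add_edge(anchor_id, nid, EdgeData.from_pmids(()))
    return out


def recommendations_tsv(recs: Iterable[Recommendation], tax: Taxonomy) -> str:
    """Report: anchor taxid, anchor name, hit count, recommended taxid, name."""
    lines = ["anchor_taxid\tanchor_name\thit_count\trecommended_taxid\trecommended_name"]
    for rec in recs:
        for taxid in sorted(rec.recommended):
            lines.append(
                f"{rec.anchor}\t{tax.nodes[rec.anchor].name}\t{len(rec.hit_species)}\t"
                f"{taxid}\t{tax.nodes[taxid].name}"
            )
    return "\n".join(lines) + "\n"
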