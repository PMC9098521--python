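"""PubTator-format corpus I/O and identifier normalization.

The PubTator dialect is plain text: per document a ``PMID|t|<title>`` line,
an optional ``PMID|a|<abstract>`` line, zero or more tab-separated annotation
lines (``pmid  start  end  mention  class  identifier``), and a blank line
between documents.  Character offsets address the concatenation
``title + " " + abstract``.  Offset validation is opt-in (``strict``):
real exports contain drifted offsets, so the lenient default only records a
QC issue.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .errors import FormatError, ValidationError

#: The six annotation classes the pipeline understands.  Unknown class
#: strings are preserved verbatim on the annotation and flagged in QC.
KNOWN_CLASSES = frozenset(
    {"Species", "Chemical", "Disease", "Gene", "Mutation", "CellLine"}
)

_MESH_CODE = re.compile(r"^[CD]\d{6,9}$")
_MESH_PREFIX = re.compile(r"^mesh:", re.IGNORECASE)


@dataclass(frozen=True)
class Annotation:
    """A single entity mention inside one document."""

    pmid: str
    start: int
    end: int
    mention: str
    entity_class: str
    raw_id: str


@dataclass
class Document:
    pmid: str
    title: str
    abstract: str = ""
    annotations: list[Annotation] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Offset text: title, a single joining space, then the abstract."""
        return self.title + " " + self.abstract

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Document):
            return NotImplemented
        return (
            self.pmid == other.pmid
            and self.title == other.title
            and self.abstract == other.abstract
            and self.annotations == other.annotations
        )


@dataclass(frozen=True)
class QCIssue:
    """One quality-control finding: where it happened and what it is."""

    pmid: str
    line: int
    issue: str

    def as_tsv(self) -> str:
        return f"{self.pmid}\t{self.line}\t{self.issue}"


@dataclass
class Corpus:
    """An ordered mapping of pmid -> Document plus collected QC issues.

    Equality ignores QC issues so round-trip identity is about content.
    """

    documents: dict[str, Document] = field(default_factory=dict)
    qc: list[QCIssue] = field(default_factory=list, compare=False)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents.values())

    def __contains__(self, pmid: str) -> bool:
        return pmid in self.documents

    def __getitem__(self, pmid: str) -> Document:
        return self.documents[pmid]


@dataclass(frozen=True, order=True)
class EntityId:
    """Normalized entity identifier, totally ordered for stable output.

    ``namespace`` is one of ``taxid``/``mesh``/``gene``/``other``; ordering is
    by (namespace, accession) as required for deterministic serialization.
    """

    namespace: str
    accession: str
    entity_class: str = field(compare=False, default="")

    @property
    def node_id(self) -> str:
        return f"{self.namespace}:{self.accession}"

    def __str__(self) -> str:
        return self.node_id


def normalize_identifier(raw_id: str, entity_class: str) -> list[EntityId]:
    """Split a verbatim identifier field into typed :class:`EntityId` values.

    Composite identifiers are split on ``;`` and ``|``; ``MESH:`` prefixes are
    stripped case-insensitively; a bare integer with class Species becomes a
    ``taxid``; a ``C``/``D`` MeSH code with class Chemical or Disease becomes
    ``mesh``; ``-`` or empty yields nothing; anything else is kept under the
    ``other`` namespace.  Total function — never raises.
    """
    out: list[EntityId] = []
    for part in re.split(r"[;|]", raw_id or ""):
        part = part.strip()
        if not part or part == "-":
            continue
        bare = _MESH_PREFIX.sub("", part)
        if entity_class == "Species" and bare.isdigit():
            out.append(EntityId("taxid", bare, entity_class))
        elif entity_class in ("Chemical", "Disease") and _MESH_CODE.match(bare):
            out.append(EntityId("mesh", bare, entity_class))
        else:
            out.append(EntityId("other", part, entity_class))
    return out


_TITLE_RE = re.compile(r"^([^|\t]+)\|t\|(.*)$")
_ABSTRACT_RE = re.compile(r"^([^|\t]+)\|a\|(.*)$")


def parse_pubtator(stream: str | TextIO, strict_offsets: bool = False) -> Corpus:
    """Parse PubTator-format text into a :class:`Corpus`.

    Unparseable annotation lines become QC issues, not silent drops.  A
    malformed title line or duplicate pmid raises :class:`FormatError` naming
    the line number.  With ``strict_offsets`` an annotation whose text slice
    does not equal its mention raises :class:`ValidationError`; otherwise it
    is recorded as a QC issue.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    corpus = Corpus()
    current: Document | None = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            current = None
            continue
        m = _TITLE_RE.match(line)
        if m:
            pmid, title = m.group(1), m.group(2)
            if pmid in corpus.documents:
                raise FormatError(f"line {lineno}: duplicate pmid {pmid!r}")
            current = Document(pmid=pmid, title=title)
            corpus.documents[pmid] = current
            continue
        m = _ABSTRACT_RE.match(line)
        if m:
            pmid, abstract = m.group(1), m.group(2)
            if current is None or current.pmid != pmid:
                raise FormatError(
                    f"line {lineno}: abstract line for {pmid!r} without "
                    f"matching title line"
                )
            current.abstract = abstract
            continue
        if "\t" in line:
            _parse_annotation_line(corpus, current, line, lineno, strict_offsets)
            continue
        raise FormatError(f"line {lineno}: unrecognized line {line[:60]!r}")

    return corpus


def _parse_annotation_line(
    corpus: Corpus,
    current: Document | None,
    line: str,
    lineno: int,
    strict: bool,
) -> None:
    fields = line.split("\t")
    pmid = fields[0]
    if len(fields) != 6:
        corpus.qc.append(
            QCIssue(pmid, lineno, f"annotation line has {len(fields)} fields, expected 6")
        )
        return
    if current is None or pmid != current.pmid:
        corpus.qc.append(QCIssue(pmid, lineno, "annotation outside its document block"))
        return
    _, start_s, end_s, mention, entity_class, raw_id = fields
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        corpus.qc.append(QCIssue(pmid, lineno, f"non-integer offsets {start_s!r}/{end_s!r}"))
        return
    if not (0 <= start < end) or not mention:
        corpus.qc.append(QCIssue(pmid, lineno, "invalid span or empty mention"))
        return
    if entity_class not in KNOWN_CLASSES:
        corpus.qc.append(QCIssue(pmid, lineno, f"unknown entity class {entity_class!r}"))
    text = current.text
    if text[start:end] != mention:
        msg = (
            f"offset mismatch: [{start},{end}) reads "
            f"{text[start:end]!r}, annotation says {mention!r}"
        )
        if strict:
            raise ValidationError(f"line {lineno}: {msg}")
        corpus.qc.append(QCIssue(pmid, lineno, msg))
    if raw_id.strip() in ("", "-"):
        corpus.qc.append(QCIssue(pmid, lineno, "unidentified mention (no identifier)"))
    current.annotations.append(
        Annotation(pmid, start, end, mention, entity_class, raw_id)
    )


def write_pubtator(corpus: Corpus) -> str:
    """Canonical serialization; ``parse_pubtator`` of the result reproduces
    the corpus exactly (pmids, texts, annotations, order).  Lines end ``\\n``.
    """
    chunks: list[str] = []
    for doc in corpus:
        chunks.append(f"{doc.pmid}|t|{doc.title}\n")
        if doc.abstract:
            chunks.append(f"{doc.pmid}|a|{doc.abstract}\n")
        for a in doc.annotations:
            chunks.append(
                f"{a.pmid}\t{a.start}\t{a.end}\t{a.mention}\t"
                f"{a.entity_class}\t{a.raw_id}\n"
            )
        chunks.append("\n")
    return "".join(chunks)


def entity_document_index(
    corpus: Corpus, classes: Iterable[str] | None = None
) -> dict[EntityId, set[str]]:
    """Map each normalized entity to the set of pmids that mention it.

    Multiple mentions within one document contribute the pmid once (sets
    deduplicate).  ``classes`` restricts to the given entity classes;
    ``None`` means all.  Unidentified mentions are excluded by
    :func:`normalize_identifier` returning nothing for them.
    """
    wanted = None if classes is None else set(classes)
    index: dict[EntityId, set[str]] = {}
    for doc in corpus:
        for ann in doc.annotations:
            if wanted is not None and ann.entity_class not in wanted:
                continue
            for eid in normalize_identifier(ann.raw_id, ann.entity_class):
                index.setdefault(eid, set()).add(doc.pmid)
    return index


def qc_report(corpus: Corpus) -> str:
    """QC findings as tab-separated text: pmid, line, issue."""
    lines = ["pmid\tline\tissue"]
    lines += [issue.as_tsv() for issue in corpus.qc]
    return "\n".join(lines) + "\n"


def document_entities(
    doc: Document, classes: Iterable[str] | None = None
) -> list[EntityId]:
    """Distinct normalized entities of a document, sorted."""
    wanted = None if classes is None else set(classes)
    seen: set[EntityId] = set()
    for ann in doc.annotations:
        if wanted is not None and ann.entity_class not in wanted:
            continue
        seen.update(normalize_identifier(ann.raw_id, ann.entity_class))
    return sorted(seen)


def mention_counts(
    corpus: Corpus, pmids: Iterable[str] | None = None,
    classes: Iterable[str] | None = None,
) -> Mapping[EntityId, dict[str, int]]:
    """Per-entity surface-form counts, used to pick display labels."""
    wanted = None if classes is None else set(classes)
    selected = set(corpus.documents) if pmids is None else set(pmids)
    counts: dict[EntityId, dict[str, int]] = {}
    for doc in corpus:
        if doc.pmid not in selected:
            continue
        for ann in doc.annotations:
            if wanted is not None and ann.entity_class not in wanted:
                continue
            for eid in normalize_identifier(ann.raw_id, ann.entity_class):
                bucket = counts.setdefault(eid, {})
                bucket[ann.mention] = bucket.get(ann.mention, 0) + 1
    return counts
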