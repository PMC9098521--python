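"""Seeded generators for synthetic taxonomy dumps, MeSH tables, annotated
corpora and reference species lists, with recorded ground truth.

Every generator takes a :class:`FixtureSpec` and is deterministic: the same
spec produces byte-identical artifacts.  Identifiers are drawn from a
reserved synthetic range (taxids >= 9,000,000; MeSH UIs ``D9xxxxxx``) so
examples never collide with real database identifiers.  The ground truth
records exactly what each emitted file implies (entity→pmid sets, pairwise
co-occurrence sets, node depths, per-genus species assignments, planted
keyword documents) so independent brute-force re-derivation can check it.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

TAXID_BASE = 9_000_000
PMID_BASE = 80_000_000

_SPINE = [
    ("no rank", "Radix cellularis"),
    ("kingdom", "Regnum synthetica"),
    ("phylum", "Phylumia ficta"),
    ("order", "Ordinales exempli"),
    ("family", "Familiaceae"),
]

_FILLERS = [
    "routine screening of botanical samples",
    "metabolite profiles were recorded",
    "voucher specimens were deposited",
    "field collections spanned two seasons",
    "assay conditions followed standard practice",
]


@dataclass
class FixtureSpec:
    seed: int = 7
    n_genera: int = 5
    species_per_genus: int = 4
    n_mesh_descriptors: int = 20
    n_docs: int = 50
    entities_per_doc: tuple[int, int] = (2, 5)
    keyword_terms: tuple[str, ...] = ("zetaflavone", "glowmoss extract")
    n_reference: int = 12
    n_misspelled: int = 3

    def __post_init__(self):
        for name in ("n_genera", "species_per_genus", "n_mesh_descriptors", "n_docs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.entities_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("entities_per_doc must be a range with 1 <= lo <= hi")

    def _rng(self, role: str) -> random.Random:
        return random.Random(f"{self.seed}:{role}")


# ---------------------------------------------------------------------------
# taxonomy


def make_taxonomy(spec: FixtureSpec) -> tuple[str, str, dict]:
    """Emit nodes.dmp / names.dmp text for a linear spine with genera and
    species hanging off the family node, plus ground truth (depths, names,
    genus→species map)."""
    rows: list[tuple[int, int, str, str]] = []  # taxid, parent, rank, name
    root = TAXID_BASE + 1
    prev = root
    depth: dict[int, int] = {}
    for i, (rank, name) in enumerate(_SPINE):
        taxid = TAXID_BASE + 1 + i
        parent = taxid - 1 if i else taxid
        rows.append((taxid, parent, rank, name))
        depth[taxid] = i
        prev = taxid
    family = prev

    genus_species: dict[int, list[int]] = {}
    for g in range(1, spec.n_genera + 1):
        genus_id = TAXID_BASE + 100 + g
        rows.append((genus_id, family, "genus", f"Genus{g}"))
        depth[genus_id] = depth[family] + 1
        genus_species[genus_id] = []
        for s in range(1, spec.species_per_genus + 1):
            sp_id = TAXID_BASE + 1000 + g * 100 + s
            rows.append((sp_id, genus_id, "species", f"Genus{g} species{s}"))
            depth[sp_id] = depth[genus_id] + 1
            genus_species[genus_id].append(sp_id)

    nodes_text = "".join(f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r, _ in rows)
    names_text = "".join(
        f"{t}\t|\t{n}\t|\t\t|\tscientific name\t|\n" for t, _, _, n in rows
    )
    gt = {
        "root": root,
        "family": family,
        "depth": {str(t): d for t, d in depth.items()},
        "name": {str(t): n for t, _, _, n in rows},
        "rank": {str(t): r for t, _, r, _ in rows},
        "genus_species": {str(g): sp for g, sp in genus_species.items()},
    }
    return nodes_text, names_text, gt


# ---------------------------------------------------------------------------
# MeSH


def make_mesh(spec: FixtureSpec) -> tuple[str, dict]:
    """Emit a MeSH TSV over the C (disease) and D (chemical) branches.

    Tree positions nest under C04 / D02 by attaching each new descriptor
    below a randomly chosen existing position.  Every fifth descriptor owns a
    second tree number in the opposite branch, exercising multi-position
    hits.
    """
    rng = spec._rng("mesh")
    branch_positions = {"C": ["C04"], "D": ["D02"]}
    rows: list[tuple[str, str, list[str]]] = []
    per_ui: dict[str, list[str]] = {}
    for k in range(1, spec.n_mesh_descriptors + 1):
        ui = f"D{9_000_000 + k}"
        letter = "C" if k % 2 else "D"
        tns = [_new_position(rng, branch_positions, letter, k)]
        if k % 5 == 0:
            other = "D" if letter == "C" else "C"
            tns.append(_new_position(rng, branch_positions, other, k))
        heading = f"Heading{k:03d}"
        rows.append((ui, heading, tns))
        per_ui[ui] = tns

    tsv = "".join(f"{ui}\t{heading}\t{','.join(tns)}\n" for ui, heading, tns in rows)
    gt = {
        "per_ui": per_ui,
        "heading": {ui: heading for ui, heading, _ in rows},
        "n_positions": sum(len(t) for t in per_ui.values()),
        "branch_of": {ui: [tn[0] for tn in tns] for ui, tns in per_ui.items()},
    }
    return tsv, gt


def _new_position(rng: random.Random, branch_positions: dict, letter: str, k: int) -> str:
    parent = rng.choice(branch_positions[letter])
    tn = f"{parent}.{100 + k}"
    branch_positions[letter].append(tn)
    return tn


# ---------------------------------------------------------------------------
# corpus


def make_corpus(spec: FixtureSpec, tax_gt: dict, mesh_gt: dict) -> tuple[str, dict]:
    """Emit a PubTator corpus whose annotations point at synthetic species
    and MeSH descriptors with exact offsets into title + " " + abstract.

    Keyword terms are planted verbatim into a recorded subset of titles so
    Boolean queries have known answers.  Per-document entity draws allow
    duplicates to exercise index-level deduplication.  Ground truth records
    entity→pmid sets and unordered-pair→pmid sets.
    """
    rng = spec._rng("corpus")
    species = [
        (int(t), tax_gt["name"][t])
        for t in sorted(tax_gt["name"])
        if tax_gt["rank"][t] == "species"
    ]
    pool: list[tuple[str, str, str, str]] = []  # (node_id, mention, class, raw_id)
    for taxid, name in species:
        pool.append((f"taxid:{taxid}", name, "Species", str(taxid)))
    for ui in sorted(mesh_gt["per_ui"]):
        cls = "Disease" if mesh_gt["branch_of"][ui][0] == "C" else "Chemical"
        pool.append((f"mesh:{ui}", mesh_gt["heading"][ui], cls, f"MESH:{ui}"))

    entity_pmids: dict[str, list[str]] = {}
    pair_pmids: dict[str, list[str]] = {}
    planted: dict[str, list[str]] = {kw: [] for kw in spec.keyword_terms}

    chunks: list[str] = []
    for i in range(spec.n_docs):
        pmid = str(PMID_BASE + i)
        kws = [kw for kw in spec.keyword_terms if rng.random() < 0.35]
        for kw in kws:
            planted[kw].append(pmid)
        title = f"Survey {i:03d}" + ("".join(f" regarding {kw}" for kw in kws))

        n_ent = rng.randint(*spec.entities_per_doc)
        picks = [rng.choice(pool) for _ in range(n_ent)]

        abstract_parts: list[str] = []
        anns: list[tuple[int, int, str, str, str]] = []
        pos = 0
        for node_id, mention, cls, raw_id in picks:
            lead = "We examined "
            abstract_parts.append(lead)
            pos += len(lead)
            abstract_parts.append(mention)
            anns.append((pos, pos + len(mention), mention, cls, raw_id))
            pos += len(mention)
            tail = f" during {rng.choice(_FILLERS)}. "
            abstract_parts.append(tail)
            pos += len(tail)
        abstract = "".join(abstract_parts).rstrip()

        chunks.append(f"{pmid}|t|{title}\n")
        if abstract:
            chunks.append(f"{pmid}|a|{abstract}\n")
        offset0 = len(title) + 1
        for start, end, mention, cls, raw_id in anns:
            chunks.append(
                f"{pmid}\t{offset0 + start}\t{offset0 + end}\t{mention}\t{cls}\t{raw_id}\n"
            )
        chunks.append("\n")

        distinct = sorted({p[0] for p in picks})
        for nid in distinct:
            entity_pmids.setdefault(nid, []).append(pmid)
        for x in range(len(distinct)):
            for y in range(x + 1, len(distinct)):
                pair_pmids.setdefault(f"{distinct[x]}|{distinct[y]}", []).append(pmid)

    gt = {"entity_pmids": entity_pmids, "pair_pmids": pair_pmids, "planted": planted}
    return "".join(chunks), gt


# ---------------------------------------------------------------------------
# reference list


def make_reference_list(spec: FixtureSpec, tax_gt: dict) -> tuple[str, dict]:
    """Emit a reference species list sampled across genera, with a configured
    number of deliberately misspelled names for name-matching tests."""
    rng = spec._rng("reference")
    all_species = sorted(
        int(t) for t in tax_gt["rank"] if tax_gt["rank"][t] == "species"
    )
    n_ref = min(spec.n_reference, len(all_species))
    chosen = sorted(rng.sample(all_species, n_ref))
    names = [tax_gt["name"][str(t)] for t in chosen]

    n_bad = min(spec.n_misspelled, len(names))
    bad_idx = sorted(rng.sample(range(len(names)), n_bad)) if n_bad else []
    out_names: list[str] = []
    misspelled: list[str] = []
    resolved: dict[str, int] = {}
    for idx, (taxid, name) in enumerate(zip(chosen, names)):
        if idx in bad_idx:
            bad = name + "xx"
            out_names.append(bad)
            misspelled.append(bad)
        else:
            out_names.append(name)
            resolved[name] = taxid

    text = "# synthetic reference species list\n" + "".join(n + "\n" for n in out_names)
    gt = {
        "emitted": out_names,
        "misspelled": misspelled,
        "resolved": resolved,
        "chosen_taxids": chosen,
    }
    return text, gt


# ---------------------------------------------------------------------------
# bundle


def make_all(spec: FixtureSpec) -> dict[str, str]:
    """All artifacts plus a groundtruth.json, keyed by file name."""
    nodes, names, tax_gt = make_taxonomy(spec)
    mesh_tsv, mesh_gt = make_mesh(spec)
    corpus_text, corpus_gt = make_corpus(spec, tax_gt, mesh_gt)
    ref_text, ref_gt = make_reference_list(spec, tax_gt)
    gt = {
        "spec": asdict(spec),
        "taxonomy": tax_gt,
        "mesh": mesh_gt,
        "corpus": corpus_gt,
        "reference": ref_gt,
    }
    return {
        "nodes.dmp": nodes,
        "names.dmp": names,
        "mesh.tsv": mesh_tsv,
        "corpus.pubtator": corpus_text,
        "reference.txt": ref_text,
        "groundtruth.json": json.dumps(gt, indent=2, sort_keys=True) + "\n",
    }


def write_all(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in make_all(spec).items():
        path = out / name
        path.write_text(text, encoding="utf-8")
        written.append(path)
    return written
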