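# litnet

Offline toolkit for turning bioentity annotations of biomedical literature
into networks and hierarchies:

- **PubTator-format I/O** — parse/write annotated title+abstract corpora,
  normalize raw identifier fields into typed entity ids (`taxid:…` for
  species, `mesh:…` for chemicals/diseases), with a QC report for malformed
  lines, drifted offsets and unidentified mentions.
- **Boolean queries** — `AND` / `OR` / `NOT` (binary, PubMed-style),
  `"quoted phrases"`, `trunc*` wildcards and implicit AND, evaluated locally
  over title+abstract tokens.
- **Co-occurrence networks** — entities linked when they appear in the same
  document; every node and edge carries its supporting pmid set, so
  union/intersection/difference recompute weights exactly. A
  `highlight` variant marks nodes common to two networks for display.
- **Hierarchies** — induced subtrees of the NCBI taxonomy
  (`nodes.dmp`/`names.dmp` dialect) over species hits, and MeSH
  tree-structure forests (ASCII `*NEWRECORD` or TSV dialect) over
  chemical/disease hits, serialized as indented lists, JSON or graphs.
- **Similarity** — common-node comparison between networks (tp/fp/fn,
  precision, recall, F1, Jaccard) plus basic network properties.
- **Recommendation** — resolve a reference species list against the
  taxonomy and propose allied species that share a rank-level ancestor
  (genus by default) with literature-hit species.
- **Gephi interop** — GEXF (1.2draft, undirected, typed attributes) and
  GraphML export, GEXF import. Edge pmid provenance is not representable in
  GEXF and is documented as lossy on round-trip.
- **Seeded fixtures** — deterministic generators for synthetic taxonomy
  dumps, MeSH tables, annotated corpora and reference lists with recorded
  ground truth, so everything is testable with no downloads.

Live PubMed/PubTator fetching is deliberately out of scope; the
`FetchAdapter` protocol in `litnet.cli` documents where a networked client
would plug in, and local files emulate it.

## CLI

```sh
# generate a synthetic workspace
litnet fixtures make --seed 7 --out fx/

# query: matching pmids, one per line, sorted
litnet query --corpus fx/corpus.pubtator --query '"glowmoss extract" OR zetaflavone' --out pmids.txt

# co-occurrence network of entities in matching documents
litnet network --corpus fx/corpus.pubtator --query zetaflavone \
    --classes Species,Chemical,Disease --out net.gexf --summary nodes.tsv

# taxonomic hierarchy of species hits (indented text, JSON, or GEXF)
litnet tree --corpus fx/corpus.pubtator --nodes fx/nodes.dmp --names fx/names.dmp \
    --query zetaflavone --out tree.txt

# MeSH tree-structure hierarchy of chemical/disease hits
litnet meshnet --corpus fx/corpus.pubtator --mesh fx/mesh.tsv --out mesh.txt

# combine and compare networks
litnet setop --op union --a a.gexf --b b.gexf --out u.gexf
litnet compare --a a.gexf --b b.gexf --out report.tsv

# allied-species recommendation from a reference list
litnet recommend --corpus fx/corpus.pubtator --nodes fx/nodes.dmp \
    --names fx/names.dmp --reference fx/reference.txt \
    --query zetaflavone --out recs.tsv --tree-out tree.gexf

# corpus QC report
litnet qc --corpus fx/corpus.pubtator --out qc.tsv
```

A YAML config file can supply default option values (`--config cfg.yaml`);
explicit flags win. Exit codes: 0 success, 1 data error, 2 usage error.
All outputs are deterministically ordered.

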