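# phare

Ontology-driven normalization and integration of heterogeneous text-mined
pharmacogenomic relationships.

Fine-grained relationships mined from biomedical text are highly
heterogeneous: the same fact appears with different verbs ("inhibit",
"repress", "antagonize"), in different voices ("A is inhibited by B" vs.
"B inhibited A"), and with composite noun phrases ("coumadin requirements
differences") whose meaning depends on what modifies what.  `phare` maps
such raw relationships onto a relationship ontology — entity-type and role
hierarchies with synonyms, inverse roles, symmetry, and modifier
restrictions — and integrates them into an RDF knowledge base with
sentence-level provenance that can be queried and exported as a network.

## What is in the box

| Module | Purpose |
| --- | --- |
| `phare.ontology` | Ontology model (entity types, roles, key-entity lexicon), Turtle/N-Triples serialization, validation, label lookup services |
| `phare.normalize` | The four-step normalization: composite subject, composite object, relationship type, assembly with inverse/symmetric expansion; batch integration with provenance merging; refinement report for curators |
| `phare.kb` | Knowledge-base construction, inference materialization (supertype typing, inverse/symmetric closure), triple-pattern query, RDF round-trip, GML subnetwork export |
| `phare.induce` | Fully automatic ontology induction from a corpus plus a synonym (synset) resource |
| `phare.evaluate` | Coverage, expression reduction, label statistics, duplicate-identification histogram |
| `phare.fixtures` | A small, complete fixture ontology and a seeded paraphrase generator with retained ground truth |
| `phare.cli` | The `phare` command-line tool |

## CLI quick tour

```sh
# write the built-in fixture ontology and some raw relationships, then:
phare validate-ontology onto.ttl
phare lexicon-check lexicon.tsv
phare normalize --ontology onto.ttl --lexicon lexicon.tsv \
    --raw raws.jsonl --out kb.ttl --report failures.tsv
phare query --kb kb.ttl -s warfarin -p inhibits
phare subnetwork --kb kb.ttl --ontology onto.ttl --focus warfarin \
    --min-sentences 5 --top-labels 2 --gml net.gml
phare induce --raw raws.jsonl --synsets synsets.txt --mode all --out auto.ttl
phare evaluate --raw raws.jsonl --ontology onto.ttl --report metrics.json
phare gen-fixture --seed 7 --out gen.jsonl --truth truth.json
```

Raw relationships are JSON-lines (`raw_type`, `subject_tokens`,
`object_tokens`, `pmid`, `sentence`) or a TSV dialect; the lexicon is a TSV
with pipe-delimited synonyms and Entrez/DrugBank/MeSH columns; ontologies
and knowledge bases are Turtle (N-Triples also supported); synsets are one
whitespace-separated set per line.

## Key conventions

- Label matching is case-insensitive with a light pluralization fallback
  (`requirements` → `requirement`).
- The `$$` marker inside role labels separates passive-voice forms
  (`is$$inhibited`) from the simple past (`inhibited`); it is kept opaque.
- Individual identifiers replace spaces with `=` (`parkinson=disease`,
  `vkorc1=expression`).
- Provenance is serialized as `"[PMID, sentence]"` comment strings attached
  to each triple via axiom annotation nodes.
- A relationship and its inverse-derived twin are both kept in the KB but
  count as one *expression* for reduction/duplicate statistics.

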