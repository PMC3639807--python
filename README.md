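# mhbi — semantic annotation of monogenean haptoral-bar images

Monogeneans are parasitic flatworms of fish identified largely by the shape
of their sclerotised hard parts — above all the haptoral bar, the stiff
element of the posterior attachment organ.  Collections of digitised
haptoral-bar drawings extracted from the taxonomic literature are typically
stored as loose image files whose meaning lives in filenames and folder
structure.  `mhbi` turns such collections into a structured knowledge graph:
each image becomes a named individual in an OWL-style ontology, linked to its
taxon, its diagnostic part, the publication it was extracted from, and the
fish host the parasite was found on.

The package is aimed at biodiversity informaticians and parasite taxonomists
who want their image annotations queryable and mergeable with other
ontologies, and at anyone who needs a small, fully-tested reference
implementation of structural ontology quality tests.

## What it implements

* **Vocabulary** — the MHBI (Monogenean Haptoral Bar Image) schema: 7 concept
  classes (`Specimen`, `TaxonName`, `PublicationCitation`, and four
  controlled-term classes, of which `DiagnosticPartTerms` is newly coined;
  the rest reuse the TDWG LSID vocabulary) and 27 core properties, split
  4 + 3 (Specimen object + datatype), 8 + 4 (TaxonName), 2 + 5
  (PublicationCitation) and 1 shared `definedTerm`.  Evidenced OWL
  characteristics only: `typeForName` is functional with inverse-functional
  inverse `part`; `isBelong` is transitive with transitive inverse
  `hasSpecies`; the extension `hasSynonym` is symmetric (its own inverse).
* **Instance naming** — deterministic labels:
  `Bifurcohaptor baungi` → **BifBaungi** (3-letter genus prefix + epithet),
  `Lim + Furtado, 1983` → **LimFurtado1983**, and specimen images like
  **bif-baungi-vb-i1** (genus prefix – epithet – part abbreviation – 1-based
  sequence number).
* **Ingestion** — CSV tables (specimens, taxa, publications, hosts) to
  instance triples over the schema, strict-mode checked.
* **Entailment materialization** — transitive closure, symmetric completion
  and inverse materialization with per-triple provenance, kept apart from
  asserted triples until explicitly folded in.
* **Validation** — 8 clarity + 12 coherence structural tests (the
  Gruber-style battery as run by Protégé-era ontology test suites), with a
  registered minimal mutant per test as a negative control.
* **Merging** — joins the parasite graph to a simple fish ontology by
  promoting `isHostedIn` from a literal-valued property to an object property
  targeting fish taxon individuals, without touching either source schema.

## Worked example

```python
from mhbi import DEFAULT_NAMESPACES as ns, ingest, validate
from mhbi.fixtures import worked_example_fixture
from mhbi.inference import transitive_closure

fx = worked_example_fixture()
graph = ingest(fx.specimens, fx.taxa, fx.publications, schema=fx.schema)
print(len(graph))                                  # 206 triples
print(validate(graph).overall_pass)                # True
closure = transitive_closure(graph, ns.schema_iri("isBelong"))
for t in sorted(closure.inferred, key=lambda t: (t.subject.full, t.object.full)):
    print(t.subject.local_name, "isBelong", t.object.local_name)
```

prints

```
206
True
BifBaungi isBelong Ancylodiscoididae
BifBaungi isBelong Dactylogyridea
Bifurcohaptor isBelong Dactylogyridea
```

— the species record asserts only one `isBelong` step per rank; the
transitive characteristic carries *BifBaungi* up to its family and order.
The `examples/` directory holds one short script per capability (schema
build + validation, annotation, inference, host merge, synthetic data); each
prints what it computes and what the numbers mean.  The same operations are
available from the shell via the `mhbi` command
(`build | ingest | infer | validate | merge | query | fixtures`).

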