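# Methods

## The annotation model

A monogenean haptoral-bar image collection is modelled as an RDF-style triple
graph.  Nodes are fully named IRIs (no blank nodes — every entity the scheme
talks about has a stable printed label) or literals (plain text, or integers
for years).  Each IRI carries exactly one *node kind*: concept class, object
property, datatype property, annotation property, or individual.  Kind
exclusivity is enforced at assertion time and is what makes the "no
meta-class" style checks meaningful.

The schema comprises 7 concept classes and 27 core properties.  `Specimen`
describes one digitised image of a haptoral bar; `TaxonName` one scientific
name at any rank; `PublicationCitation` the source publication; and four
controlled-term classes (`DiagnosticPartTerms`, `KindOfSpecimenTerms`,
`TaxonRankTerms`, `PublicationTypeTerms`) enumerate the closed value lists,
each bound by the shared `definedTerm` datatype property.  Most terms reuse
the TDWG LSID vocabulary; `DiagnosticPartTerms` is newly coined for the
sclerotised hard parts.

Only evidenced OWL characteristics are asserted: `typeForName`
(Specimen → TaxonName) is functional and inverse to the inverse-functional
`part`; `isBelong` (TaxonName → TaxonName, one step up the classification)
is transitive and inverse to the transitive `hasSpecies`.  `hasGenus`,
`hasFamily` and `hasOrder` stay plain rank-specific object properties without
inverse axioms: declaring three further inverses of `isBelong` would break
the uniqueness that the "inverse must have matching range and domain" test
presumes.  The symmetric `hasSynonym` and the `part` sub-property family
(`fullImage`, `isBar`, `isHaptor`) ship as *extension* properties: the
extension registry adds declarations monotonically and never mutates a core
axiom, and sub-properties inherit domain and range from their super-property
when not given.

Two modelling points were genuinely open and resolved as follows:

* **`isHostedIn`.**  The vocabulary classifies it as an object property of
  `TaxonName` (it names a host organism), but as long as the host ontology is
  absent there is nothing for it to point at, so the standalone schema
  declares it literal-valued and the merge step performs the promotion.  The
  published census (8 object + 4 datatype under `TaxonName`) is reported from
  the vocabulary-level classification.
* **`isHaptorBar`.**  The tabular usage (Specimen → DiagnosticPartTerms) and
  the sub-property reading (under `part`) conflict; the data-level usage wins
  for the core property, and the sub-property semantics is exercised by the
  dedicated `fullImage`/`isBar`/`isHaptor` extension family.
* **Two `year` properties.**  `TaxonName` and `PublicationCitation` both
  carry a `year`; they are distinct IRIs in per-concept sub-namespaces so
  their domains stay unambiguous.
* The asserted instance graph carries `typeForName` but not its inverse
  `part` triple: the `part` link is the model's showcase inverse entailment
  and is produced by the materializer (an `assert_inverse_part` flag restores
  eager assertion for consumers that want fully asserted graphs).

## Naming conventions

Species instances concatenate the title-cased first three genus letters with
the title-cased epithet (`BifBaungi`); genus/family/order instances keep the
full name; publications concatenate title-cased author surnames plus the
4-digit year (`LimFurtado1983`); specimen images use the lower-cased
genus-prefix/epithet/part-abbreviation/sequence pattern (`bif-baungi-vb-i1`).
Inputs are ASCII-folded (diacritics stripped) so labels are IRI-safe.  The
part-abbreviation table ships with `ventral bar → vb`, `dorsal bar → db`,
`anchor → an`, `full image → fi` and is configurable.  The collection
identifier (`specimenId`) uses a second scheme — source tag plus 3-letter
genus/epithet codes plus three letters per part word (`j1-bif-bau-ven-bar`);
the source tag defaults to `j1` and is configurable, as the scheme's leading
token is not otherwise constrained.  Homonym collisions (two genera sharing a
3-letter prefix and an epithet) are disambiguated by appending the family
initial, with a warning — the convention itself does not address them.

## Entailment materialization

Transitive closure is computed per property over its object edges
(networkx reachability); the test suite checks it against an independent
boolean-matrix-power oracle on graphs of up to 50 nodes.  Cyclic input —
taxonomically impossible but input-possible — still terminates: nodes on a
cycle entail their own self-link, and each strongly connected component is
reported as a diagnostic rather than an error, since validation is a
separate concern.  Symmetric completion and inverse materialization add only
the missing converse triples.  Inferred triples are disjoint from asserted
ones and carry rule provenance (`transitive`/`symmetric`/`inverse`); the
fixpoint driver re-runs all rules until no new triple appears, so inverse
links are derived from closure-derived triples too.  Folding entailments
into the asserted graph is an explicit step (`--materialize` on the CLI).

## Validation battery

Twenty structural checks — 8 clarity, 12 coherence — operationalise the
classic clarity/coherence reading of ontology quality.  They run over
asserted axioms only: "redundant classes" means ancestor–descendant
co-occurrence within one property's domain or range set under the asserted
subclass closure; "narrowing" is checked against the asserted closure (no
reasoner); a "top-level property" is one with no asserted super-property;
the sub-property condition of the inverse-hierarchy test accepts axioms
derivable through the asserted sub-property closure; "system ontologies"
are exactly the RDF, RDFS, OWL and XSD namespaces.  All 20 tests are hard
failures by default; a lenient list downgrades named tests for third-party
files.  Validation never mutates the graph and always returns exactly 8 + 12
results.

Each test has a registered minimal mutant as a negative control.  Nineteen
mutants fail exactly their target test; the one exception is principled:
marking the transitive `isBelong` functional violates both the
"transitive cannot be functional" clarity test and the "inverse of
functional must be inverse-functional" coherence test, because `isBelong`
has the declared inverse `hasSpecies`.  The mutant registry records the full
entailed failure set per mutant and the selectivity matrix asserts exact
equality.

## Host-ontology merge

The fish ontology is deliberately minimal: one `TaxonName` concept with
naming/rank datatype properties, in its own namespace pair.  Merging unions
both graphs, retracts `isHostedIn`'s datatype declaration and literal range,
redeclares it as an object property with range fish `TaxonName`, and
resolves each host-label literal to a fish taxon individual by exact label,
normalized label (case-folded, separator-stripped) or an explicit map.
Ambiguous matches abort with the candidate list.  Unresolved labels follow a
policy: keep the literal (default — lossless), drop the triple, or abort.
Fish IRIs are never rewritten.  The merged reference fixture must pass all
20 structural tests.

## Synthetic data

The generator emits a consistent taxonomy tree (orders > families > genera >
species, every child under exactly one parent), specimen rows with cycling
diagnostic parts and per-part 1-based sequence numbers, publications, and a
host table, all from a seeded pseudo-Latin syllable sampler whose draws are
collision-checked (a collision-injection flag deliberately provokes homonym
labels to exercise the disambiguation path).  Default shape is 2 orders × 2
families × 2 genera × 2 species with one or two specimens per species —
desk-scale sizes chosen so every test runs in seconds while exercising every
code path; the real collections this emulates are two orders of magnitude
larger (hundreds of species, dozens of genera), and a configuration bound of
10⁴ individuals keeps accidental blow-ups out.  Host assignment and
unresolvable-host injection are Bernoulli draws at configurable fractions;
the manifest records the *realised* counts, which ingestion must reproduce
exactly.  What the generator does not emulate: real nomenclatural strings
(authorship with diacritics and punctuation), shared epithets across genera
(unless injected), multi-publication synonymies, or images themselves — so
passing tests show structural correctness of the pipeline, not robustness to
the full messiness of literature-derived names.

## Numerical and serialization choices

Serialization goes through rdflib; the round-trip contract is triple-set
identity (not byte identity) in both Turtle and RDF/XML.  Plain-text
literals round-trip as plain literals, integers as `xsd:integer`.  Graph
equality is set equality of triples; declarations are carried as `rdf:type`
triples so they survive round-trips.  Strict mode (default) rejects triples
whose predicate is neither a declared property nor an RDF/RDFS/OWL built-in;
lax mode exists for third-party files.  Ties in reports and violation lists
are broken by lexicographic IRI order, making every output deterministic.

## Known limitations

No OWL-DL reasoning, class subsumption inference, SPARQL, named graphs or
network import resolution; blank nodes are unsupported (restriction-style
axioms used in negative controls are expressed with named nodes); the
controlled lists for publication types beyond journal article and book are
placeholders flagged non-authoritative; `lists`
(PublicationCitation → TaxonName) follows the most plausible reading of an
under-documented property and is flagged as such in the vocabulary manifest.
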