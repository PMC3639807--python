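"""Ingest the worked-example tables (the Bifurcohaptor baungi ventral-bar
image, its taxon chain, and the Lim & Furtado 1983 citation) and show the
naming conventions plus a few of the emitted triples.

A species instance is named from the 3-letter genus prefix plus the epithet
(BifBaungi); a specimen image gets the lower-case genus/epithet prefix, part
abbreviation, and 1-based sequence number (bif-baungi-vb-i1).
"""

from mhbi import (
    DEFAULT_NAMESPACES as ns,
    ingest,
    publication_instance_name,
    species_instance_name,
    specimen_instance_name,
)
from mhbi.fixtures import worked_example_fixture
from mhbi.graph import IRI

print("species name:    ", species_instance_name("Bifurcohaptor", "baungi"))
print("publication name:", publication_instance_name(["Lim", "Furtado"], 1983))
print("specimen name:   ", specimen_instance_name("Bifurcohaptor", "baungi", "ventral bar", 1))
print()

fx = worked_example_fixture()
graph = ingest(fx.specimens, fx.taxa, fx.publications, schema=fx.schema)
print(f"ingested graph: {len(graph)} triples "
      f"(matches hand-written expectation: {graph.same_triples(fx.expected_graph)})")
for t in sorted(graph.match(ns.instance_iri("BifBaungi"), None, None),
                key=lambda t: t.predicate.full):
    obj = t.object.full.split("#")[-1] if isinstance(t.object, IRI) else repr(t.object.value)
    print(f"  BifBaungi {t.predicate.local_name} {obj}")
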