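"""Merge the parasite instance graph with the fish (host) ontology.

Before merging, isHostedIn holds the host name as a bare label; the merge
promotes it to an object property whose range is the fish TaxonName concept
and links each resolvable label to the matching fish taxon individual.  The
merged graph must still pass all 20 structural tests.
"""

from mhbi import DEFAULT_NAMESPACES as ns, build_fish_graph, ingest, validate
from mhbi.fixtures import worked_example_fixture
from mhbi.graph import IRI
from mhbi.merge import MergePlan, merge_ontologies

fx = worked_example_fixture()
graph = ingest(fx.specimens, fx.taxa, fx.publications, schema=fx.schema)
fish = build_fish_graph(fx.hosts)

result = merge_ontologies(graph, fish, MergePlan())
print(f"host labels linked to fish taxa: {result.linked}")
print(f"isHostedIn is now: {result.graph.kind_of(ns.schema_iri('isHostedIn')).value}")
for t in result.graph.match(None, ns.schema_iri("isHostedIn"), None):
    obj = t.object.full if isinstance(t.object, IRI) else repr(t.object.value)
    print(f"  {t.subject.local_name} isHostedIn {obj}")
rep = validate(result.graph)
print(f"merged graph passes all 20 structural tests: {rep.overall_pass}")
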