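"""Materialize the entailments the property characteristics license on the
worked example.

isBelong is transitive, so the species reaches its family and order through
the closure; isBelong/hasSpecies and typeForName/part are inverse pairs, so
each asserted link licenses the reverse one; hasSynonym is symmetric, so a
one-directional synonym assertion completes itself.
"""

from mhbi import DEFAULT_NAMESPACES as ns, ingest
from mhbi.fixtures import worked_example_fixture
from mhbi.inference import (
    fold,
    materialize_inverse,
    materialize_symmetric,
    transitive_closure,
)

fx = worked_example_fixture()
graph = ingest(fx.specimens, fx.taxa, fx.publications, schema=fx.schema)

is_belong = ns.schema_iri("isBelong")
closure = transitive_closure(graph, is_belong)
print(f"transitive closure of isBelong adds {len(closure.inferred)} triples:")
for t in sorted(closure.inferred, key=lambda t: (t.subject.full, t.object.full)):
    print(f"  {t.subject.local_name} isBelong {t.object.local_name}")

closed = fold(graph, closure)
inverse = materialize_inverse(closed, (is_belong, ns.schema_iri("hasSpecies")))
print(f"\ninverse hasSpecies adds {len(inverse.inferred)} triples, including:")
for t in sorted(inverse.inferred, key=lambda t: (t.subject.full, t.object.full)):
    print(f"  {t.subject.local_name} hasSpecies {t.object.local_name}")

part = materialize_inverse(graph, (ns.schema_iri("typeForName"), ns.schema_iri("part")))
for t in part.inferred:
    print(f"\ninverse of typeForName: {t.subject.local_name} part {t.object.local_name}")

synonym = materialize_symmetric(graph, ns.schema_iri("hasSynonym"))
for t in synonym.inferred:
    print(f"symmetric hasSynonym: {t.subject.local_name} hasSynonym {t.object.local_name}")
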