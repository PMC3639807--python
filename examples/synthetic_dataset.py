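"""Generate a seeded synthetic haptoral-bar annotation dataset and check the
bookkeeping manifest against the ingested graph.

The generator emits a consistent taxonomy tree (orders > families > genera >
species), specimen image rows, publications, and a host table; the manifest
records the exact per-concept individual counts the ingested graph must show.
"""

from mhbi import DEFAULT_NAMESPACES as ns, ingest
from mhbi.fixtures import GeneratorConfig, generate
from mhbi.graph import RDF_TYPE

config = GeneratorConfig(seed=7, n_specimens_per_species=2, host_fraction=0.5)
dataset = generate(config)
print(f"generated {len(dataset.specimens)} specimen rows, "
      f"{len(dataset.taxa)} taxon rows, {len(dataset.publications)} publications")

graph = ingest(dataset.specimens, dataset.taxa, dataset.publications)
for concept in ("Specimen", "TaxonName", "PublicationCitation"):
    actual = len(graph.match(None, RDF_TYPE, ns.schema_iri(concept)))
    expected = dataset.manifest["counts"][concept]
    print(f"  {concept}: ingested {actual}, manifest {expected}, match={actual == expected}")
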