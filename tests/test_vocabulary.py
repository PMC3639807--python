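"""Vocabulary registry and schema builders: census, characteristics,
extension mechanics, fish schema."""

import pytest

from mhbi.graph import (
    IRI,
    NodeKind,
    OWL_INVERSE_OF,
    OWL_FUNCTIONAL,
    OWL_INVERSE_FUNCTIONAL,
    OWL_SYMMETRIC,
    OWL_TRANSITIVE,
    RDF_TYPE,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBPROPERTYOF,
    Triple,
)
from mhbi.vocabulary import (
    CORE_CONCEPTS,
    CORE_PROPERTIES,
    EXT_HAS_SYNONYM,
    EXT_PART_SUBPROPERTIES,
    VocabularyError,
    build_fish_schema,
    build_mhbi_schema,
    build_reference_schema,
    census,
    core_property_breakdown,
    register_extension_property,
    vocabulary_manifest,
    _obj,
)


class TestRegistry:
    def test_seven_concepts_with_one_new(self):
        assert len(CORE_CONCEPTS) == 7
        new = [c for c in CORE_CONCEPTS if c.source == "mhbi-new"]
        assert [c.name for c in new] == ["DiagnosticPartTerms"]

    def test_core_property_census_is_27(self):
        assert len(CORE_PROPERTIES) == 27
        assert all(p.core for p in CORE_PROPERTIES)

    def test_per_concept_breakdown(self):
        breakdown = core_property_breakdown()
        assert breakdown["Specimen"] == {"object": 4, "datatype": 3}
        assert breakdown["TaxonName"] == {"object": 8, "datatype": 4}
        assert breakdown["PublicationCitation"] == {"object": 2, "datatype": 5}
        assert breakdown["shared"] == {"object": 0, "datatype": 1}

    def test_datatype_properties_never_carry_relational_characteristics(self):
        for p in CORE_PROPERTIES:
            if p.kind == "datatype":
                assert not p.characteristics & {"transitive", "symmetric", "inverse-functional"}

    def test_transitive_properties_not_functional(self):
        for p in CORE_PROPERTIES + (EXT_HAS_SYNONYM,) + EXT_PART_SUBPROPERTIES:
            if "transitive" in p.characteristics:
                assert "functional" not in p.characteristics
                assert "inverse-functional" not in p.characteristics


class TestBuild:
    def test_graph_census(self, reference_schema, ns):
        c = census(reference_schema, ns)
        assert c.concept_classes == 7
        assert c.core_properties == 27
        assert c.extension_properties == 4  # hasSynonym + the part sub-family

    def test_build_is_deterministic(self):
        assert build_reference_schema().serialize("turtle") == build_reference_schema().serialize("turtle")

    def test_characteristic_axioms(self, reference_schema, ns):
        g = reference_schema
        assert g.has(ns.schema_iri("typeForName"), RDF_TYPE, OWL_FUNCTIONAL)
        assert g.has(ns.schema_iri("part"), RDF_TYPE, OWL_INVERSE_FUNCTIONAL)
        assert g.has(ns.schema_iri("isBelong"), RDF_TYPE, OWL_TRANSITIVE)
        assert g.has(ns.schema_iri("hasSpecies"), RDF_TYPE, OWL_TRANSITIVE)
        assert g.has(ns.schema_iri("hasSynonym"), RDF_TYPE, OWL_SYMMETRIC)
        # the symmetric property is its own inverse
        assert g.has(ns.schema_iri("hasSynonym"), OWL_INVERSE_OF, ns.schema_iri("hasSynonym"))

    def test_inverse_pairs_have_swapped_domain_range(self, reference_schema, ns):
        g = reference_schema
        pairs = [("typeForName", "part"), ("isBelong", "hasSpecies")]
        for a, b in pairs:
            pa, pb = ns.schema_iri(a), ns.schema_iri(b)
            assert g.has(pa, OWL_INVERSE_OF, pb) or g.has(pb, OWL_INVERSE_OF, pa)
            assert g.objects(pa, RDFS_DOMAIN) == g.objects(pb, RDFS_RANGE)
            assert g.objects(pa, RDFS_RANGE) == g.objects(pb, RDFS_DOMAIN)

    def test_host_property_is_literal_valued_before_merge(self, reference_schema, ns):
        assert reference_schema.kind_of(ns.schema_iri("isHostedIn")) is NodeKind.DATATYPE_PROPERTY

    def test_term_individuals(self, reference_schema, ns):
        g = reference_schema
        for label, concept in [
            ("HaptorSclerotisedpartBar", "DiagnosticPartTerms"),
            ("Illustration", "KindOfSpecimenTerms"),
            ("Species", "TaxonRankTerms"),
            ("JournalArticle", "PublicationTypeTerms"),
        ]:
            ind = ns.instance_iri(label)
            assert g.kind_of(ind) is NodeKind.INDIVIDUAL
            assert g.has(ind, RDF_TYPE, ns.schema_iri(concept))
        ranks = g.subjects(RDF_TYPE, ns.schema_iri("TaxonRankTerms"))
        assert {i.local_name for i in ranks} == {"Species", "Genus", "Family", "Order"}

    def test_year_properties_are_distinct_iris(self, ns):
        taxon_year = IRI(ns.taxon_schema, "year")
        pub_year = IRI(ns.pub_schema, "year")
        assert taxon_year != pub_year


class TestFishSchema:
    def test_single_concept_class(self, ns):
        fish = build_fish_schema(ns)
        assert len(fish.iris_of_kind(NodeKind.CONCEPT_CLASS)) == 1

    def test_disjoint_from_mhbi_schema(self, reference_schema, ns):
        fish = build_fish_schema(ns)
        assert not set(fish.declarations) & set(reference_schema.declarations)


class TestExtensions:
    def test_extension_preserves_core(self, ns):
        core = build_mhbi_schema(ns)
        extended = build_mhbi_schema(ns)
        register_extension_property(extended, EXT_HAS_SYNONYM, ns)
        assert core.triples <= extended.triples  # monotone
        assert census(extended, ns).core_properties == 27
        assert census(extended, ns).extension_properties == 1

    def test_part_subproperties_inherit_domain_and_range(self, reference_schema, ns):
        part = ns.schema_iri("part")
        for name in ("fullImage", "isBar", "isHaptor"):
            p = ns.schema_iri(name)
            assert reference_schema.has(p, RDFS_SUBPROPERTYOF, part)
            assert reference_schema.objects(p, RDFS_DOMAIN) == reference_schema.objects(part, RDFS_DOMAIN)
            assert reference_schema.objects(p, RDFS_RANGE) == reference_schema.objects(part, RDFS_RANGE)

    def test_name_collision_with_core_rejected(self, schema_copy, ns):
        clash = _obj("rank", "TaxonName", ["TaxonName"], ["TaxonRankTerms"], core=False)
        with pytest.raises(VocabularyError):
            register_extension_property(schema_copy, clash, ns)

    def test_core_flag_rejected(self, schema_copy, ns):
        with pytest.raises(VocabularyError):
            register_extension_property(
                schema_copy, _obj("novel", "TaxonName", ["TaxonName"], ["TaxonName"]), ns
            )

    def test_extension_survives_roundtrip(self, reference_schema, ns):
        from mhbi.graph import OntologyGraph

        back = OntologyGraph.parse(reference_schema.serialize("turtle"), "turtle")
        assert back.has(ns.schema_iri("isBar"), RDFS_SUBPROPERTYOF, ns.schema_iri("part"))


def test_manifest_lists_every_entry():
    rows = vocabulary_manifest()
    concepts = [r for r in rows if r["entry"] == "concept"]
    props = [r for r in rows if r["entry"] == "property"]
    assert len(concepts) == 7
    assert len(props) == 27 + 4
    assert all(r["source"] in ("tdwg", "mhbi-new") for r in rows)
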