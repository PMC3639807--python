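"""Instance naming conventions and record-to-triple conversion."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mhbi.annotation import (
    Annotator,
    NamingError,
    RecordError,
    SpecimenRecord,
    higher_taxon_instance_name,
    ingest,
    publication_instance_name,
    specimen_id,
    specimen_instance_name,
    species_instance_name,
)
from mhbi.graph import IRI, Literal, NodeKind, RDF_TYPE, Triple


class TestNamingRules:
    @pytest.mark.parametrize(
        "genus,epithet,expected",
        [
            ("Bifurcohaptor", "baungi", "BifBaungi"),
            ("Bycanistes", "gharui", "BycGharui"),
            ("Aaa", "x", "AaaX"),
            ("bifurcohaptor", "BAUNGI", "BifBaungi"),  # case-normalised
        ],
    )
    def test_species_names(self, genus, epithet, expected):
        assert species_instance_name(genus, epithet) == expected

    def test_short_genus_rejected(self):
        with pytest.raises(NamingError):
            species_instance_name("Ab", "x")

    @pytest.mark.parametrize(
        "rank,name,expected",
        [
            ("Genus", "Bifurcohaptor", "Bifurcohaptor"),
            ("Family", "Ancylodiscoididae", "Ancylodiscoididae"),
            ("Order", "Dactylogyridea", "Dactylogyridea"),
        ],
    )
    def test_higher_taxa_keep_full_name(self, rank, name, expected):
        assert higher_taxon_instance_name(rank, name) == expected

    def test_species_rank_must_use_species_rule(self):
        with pytest.raises(NamingError):
            higher_taxon_instance_name("Species", "Bifurcohaptor baungi")

    @pytest.mark.parametrize(
        "authors,year,expected",
        [
            (["Lim", "Furtado"], 1983, "LimFurtado1983"),
            (["Jain"], 1958, "Jain1958"),
        ],
    )
    def test_publication_names(self, authors, year, expected):
        assert publication_instance_name(authors, year) == expected

    def test_publication_needs_authors(self):
        with pytest.raises(NamingError):
            publication_instance_name([], 1983)

    @pytest.mark.parametrize(
        "seq,expected",
        [(1, "bif-baungi-vb-i1"), (2, "bif-baungi-vb-i2")],
    )
    def test_specimen_names(self, seq, expected):
        assert specimen_instance_name("Bifurcohaptor", "baungi", "ventral bar", seq) == expected

    def test_specimen_sequence_is_one_based(self):
        with pytest.raises(NamingError):
            specimen_instance_name("Bifurcohaptor", "baungi", "ventral bar", 0)

    def test_unregistered_part_rejected(self):
        with pytest.raises(NamingError):
            specimen_instance_name("Bifurcohaptor", "baungi", "copulatory organ", 1)

    def test_specimen_id_scheme(self):
        assert specimen_id("Bifurcohaptor", "baungi", "ventral bar") == "j1-bif-bau-ven-bar"

    def test_diacritics_folded(self):
        assert species_instance_name("Bïfurcohaptor", "baúngi") == "BifBaungi"

    @given(
        st.text(alphabet="abcdefghij", min_size=3, max_size=10),
        st.text(alphabet="abcdefghij", min_size=1, max_size=10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_species_naming_is_deterministic_and_clean(self, genus, epithet):
        a = species_instance_name(genus, epithet)
        assert a == species_instance_name(genus, epithet)
        assert " " not in a and a[0].isupper()


def _record(**kw):
    base = dict(
        genus="Bifurcohaptor",
        species_epithet="baungi",
        family="Ancylodiscoididae",
        order="Dactylogyridea",
        diagnostic_part="ventral bar",
        kind_of_specimen="Illustration",
        image_path="/images/x.jpg",
        image_description="",
        sequence_number=1,
        citation_key="LimFurtado1983",
        host_name=None,
    )
    base.update(kw)
    return SpecimenRecord(**base)


class TestAnnotateSpecimen:
    def _annotator(self, schema, ns):
        a = Annotator(schema, ns)
        a.citations.add("LimFurtado1983")
        return a

    def test_emits_expected_object_triples(self, reference_schema, ns):
        triples = self._annotator(reference_schema, ns).annotate_specimen(_record())
        spec = ns.instance_iri("bif-baungi-vb-i1")
        assert Triple(spec, ns.schema_iri("typeForName"), ns.instance_iri("BifBaungi")) in triples
        assert Triple(spec, ns.schema_iri("isCitedIn"), ns.instance_iri("LimFurtado1983")) in triples
        assert (
            Triple(ns.instance_iri("BifBaungi"), ns.schema_iri("isBelong"), ns.instance_iri("Bifurcohaptor"))
            in triples
        )

    def test_dangling_citation_rejected(self, reference_schema, ns):
        annotator = Annotator(reference_schema, ns)
        with pytest.raises(RecordError, match="dangling"):
            annotator.annotate_specimen(_record())

    def test_host_is_optional(self, reference_schema, ns):
        annotator = self._annotator(reference_schema, ns)
        without = annotator.annotate_specimen(_record())
        with_host = annotator.annotate_specimen(_record(host_name="SilBagMysHemurus"))
        host_triples = {t for t in with_host if t.predicate == ns.schema_iri("isHostedIn")}
        assert len(host_triples) == 1
        assert with_host - host_triples == without

    def test_every_predicate_declared_in_schema(self, reference_schema, ns):
        """Strict-mode completeness: ingest never emits an undeclared predicate."""
        triples = self._annotator(reference_schema, ns).annotate_specimen(
            _record(host_name="SilBagMysHemurus", image_description="single bar")
        )
        for t in triples:
            assert reference_schema.is_declared_property(t.predicate) or t.predicate == RDF_TYPE

    def test_functional_typeForName_single_valued(self, reference_schema, ns):
        annotator = self._annotator(reference_schema, ns)
        triples = set()
        for seq in (1, 2):
            triples |= annotator.annotate_specimen(_record(sequence_number=seq))
        by_spec = {}
        for t in triples:
            if t.predicate == ns.schema_iri("typeForName"):
                by_spec.setdefault(t.subject, set()).add(t.object)
        assert by_spec and all(len(v) == 1 for v in by_spec.values())

    def test_homonym_collision_disambiguated_with_warning(self, reference_schema, ns):
        annotator = self._annotator(reference_schema, ns)
        annotator.species_label("Bifurcohaptor", "baungi")
        with pytest.warns(UserWarning, match="homonym"):
            other = annotator.species_label("Bifurcoides", "baungi", family="Dactylogyridae")
        assert other == "BifBaungiD"


class TestIngest:
    def test_batch_counts_one_specimen_individual_per_row(self, reference_schema, ns):
        rows = []
        for i, (genus, epithet) in enumerate(
            [("Bifurcohaptor", "baungi"), ("Bifurcohaptor", "indicus"), ("Dactylogyrus", "vastator")]
        ):
            rows.append(
                {
                    "genus": genus, "species_epithet": epithet, "family": "Ancylodiscoididae",
                    "order": "Dactylogyridea", "diagnostic_part": "ventral bar",
                    "kind_of_specimen": "Illustration", "image_path": f"/images/{i}.jpg",
                    "image_description": "", "sequence_number": 1,
                    "citation_key": "Jain1958", "host_name": "",
                }
            )
        pubs = pd.DataFrame(
            [{"authors": "Jain", "year": 1958, "title": "", "parent_publication": "",
              "number": "", "pub_type": "JournalArticle", "lists": ""}]
        )
        graph = ingest(pd.DataFrame(rows), pd.DataFrame(columns=["rank", "name_complete"]), pubs)
        specimens = graph.match(None, RDF_TYPE, ns.schema_iri("Specimen"))
        assert len(specimens) == 3

    def test_bad_row_reports_row_number(self, reference_schema):
        bad = pd.DataFrame(
            [{"genus": "Bifurcohaptor", "species_epithet": "", "sequence_number": 1,
              "diagnostic_part": "ventral bar", "kind_of_specimen": "Illustration",
              "citation_key": "X1900"}]
        )
        pubs = pd.DataFrame(
            [{"authors": "X", "year": 1900, "title": "", "parent_publication": "",
              "number": "", "pub_type": "JournalArticle", "lists": ""}]
        )
        with pytest.raises(RecordError, match="row 1"):
            ingest(bad, pd.DataFrame(columns=["rank", "name_complete"]), pubs)

    def test_worked_example_reproduces_expected_graph(self, worked_example, worked_graph):
        assert worked_graph.same_triples(worked_example.expected_graph)
        assert worked_graph.declarations == worked_example.expected_graph.declarations

    def test_worked_example_key_literals(self, worked_graph, ns):
        species = ns.instance_iri("BifBaungi")
        assert worked_graph.has(species, ns.schema_iri("authorship"), Literal("Lim & Furtado"))
        assert worked_graph.has(species, IRI(ns.taxon_schema, "year"), Literal(1983))
        assert worked_graph.has(
            species,
            ns.schema_iri("locality"),
            Literal("Tasek Bera, Pahang; Bukit Merah Reservoir, Perak"),
        )
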