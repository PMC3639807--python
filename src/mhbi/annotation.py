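"""Deterministic instance naming and conversion of tabular records to triples.

Naming conventions for individuals:

* species — first three letters of the genus, title-cased, followed by the
  title-cased epithet (``Bifurcohaptor baungi`` → ``BifBaungi``);
* genus/family/order — the full name, first letter capitalised;
* publication — concatenated title-cased author surnames plus the 4-digit
  year (``Lim`` + ``Furtado`` + 1983 → ``LimFurtado1983``);
* specimen image — lower-cased 3-letter genus prefix, epithet, a registered
  abbreviation of the diagnostic part, and a 1-based sequence number, joined
  with hyphens (``bif-baungi-vb-i1``).

Input tables are comma-separated UTF-8 files with a header row, one file per
record kind (specimens, taxa, publications, hosts).  Ingestion emits, for a
specimen, the type/``kindOfSpecimen``/``isHaptorBar``/``typeForName``/
``isCitedIn`` object triples and the id/path/description literals, plus the
taxon chain (rank, one ``isBelong`` step per level, genus-level
``hasSpecies``) and any host-label literal.  The inverse ``part`` triple on
the taxon is *not* asserted by default: it is the showcase entailment of the
``typeForName``/``part`` inverse pair and is left to the materializer (set
``assert_inverse_part=True`` to assert it instead).
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .graph import IRI, Literal, NodeKind, OntologyGraph, RDF_TYPE, Triple
from .vocabulary import (
    DEFAULT_NAMESPACES,
    Namespaces,
    build_fish_schema,
    build_reference_schema,
)


class NamingError(ValueError):
    """Inputs that the naming conventions cannot be applied to."""


class RecordError(ValueError):
    """An input row violates the record contract (reported with row context)."""


#: diagnostic-part label → (specimen-label abbreviation, controlled term label)
DEFAULT_PART_TABLE: dict[str, tuple[str, str]] = {
    "ventral bar": ("vb", "HaptorSclerotisedpartBar"),
    "dorsal bar": ("db", "HaptorSclerotisedpartBar"),
    "anchor": ("an", "HaptorSclerotisedpartAnchor"),
    "full image": ("fi", "FullImage"),
}

RANKS = ("Species", "Genus", "Family", "Order")
#: rank of the parent one step up the classification
PARENT_RANK = {"Species": "Genus", "Genus": "Family", "Family": "Order"}


def ascii_fold(text: str) -> str:
    """Strip diacritics and whitespace so labels are IRI-safe."""
    folded = unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")
    return "".join(folded.split())


def _title(word: str) -> str:
    word = ascii_fold(word)
    return word[:1].upper() + word[1:].lower() if word else ""


def species_instance_name(genus: str, epithet: str) -> str:
    """``("Bifurcohaptor", "baungi")`` → ``"BifBaungi"``."""
    genus = ascii_fold(genus)
    epithet = ascii_fold(epithet)
    if not genus or not epithet:
        raise NamingError("genus and species epithet must be non-empty")
    if len(genus) < 3:
        raise NamingError(f"genus {genus!r} is shorter than the 3-letter prefix")
    return _title(genus[:3]) + _title(epithet)


def higher_taxon_instance_name(rank: str, name: str) -> str:
    """Genus/family/order instances keep the full name, capitalised."""
    if rank == "Species":
        raise NamingError("species instances are named with species_instance_name")
    if rank not in RANKS:
        raise NamingError(f"unknown rank {rank!r}")
    name = ascii_fold(name)
    if not name:
        raise NamingError("taxon name must be non-empty")
    return name[:1].upper() + name[1:]


def publication_instance_name(authors: Sequence[str], year: int) -> str:
    """``(["Lim", "Furtado"], 1983)`` → ``"LimFurtado1983"``."""
    authors = [a for a in (ascii_fold(a) for a in authors) if a]
    if not authors:
        raise NamingError("a publication needs at least one author surname")
    if not (1000 <= int(year) <= 9999):
        raise NamingError(f"year must be a 4-digit integer, got {year!r}")
    return "".join(_title(a) for a in authors) + str(int(year))


def specimen_instance_name(
    genus: str,
    epithet: str,
    part_label: str,
    seq: int,
    part_table: Mapping[str, tuple[str, str]] = DEFAULT_PART_TABLE,
) -> str:
    """``("Bifurcohaptor", "baungi", "ventral bar", 1)`` → ``"bif-baungi-vb-i1"``."""
    genus = ascii_fold(genus)
    epithet = ascii_fold(epithet)
    if len(genus) < 3 or not epithet:
        raise NamingError("genus must have >= 3 letters and epithet must be non-empty")
    key = part_label.strip().lower()
    if key not in part_table:
        raise NamingError(f"no registered abbreviation for diagnostic part {part_label!r}")
    if int(seq) < 1:
        raise NamingError(f"sequence number must be >= 1, got {seq}")
    abbrev = part_table[key][0]
    return f"{genus[:3].lower()}-{epithet.lower()}-{abbrev}-i{int(seq)}"


def specimen_id(
    genus: str, epithet: str, part_label: str, source_tag: str = "j1"
) -> str:
    """Collection identifier: source tag, 3-letter genus and epithet codes,
    and three letters of each word of the part label, hyphen-joined
    (``j1-bif-bau-ven-bar``)."""
    genus = ascii_fold(genus).lower()
    epithet = ascii_fold(epithet).lower()
    part_words = [w[:3].lower() for w in part_label.split() if w]
    if len(genus) < 3 or len(epithet) < 3 or not part_words:
        raise NamingError("specimen id needs >=3-letter genus and epithet and a part label")
    return "-".join([source_tag, genus[:3], epithet[:3]] + part_words)


# -- records -------------------------------------------------------------


@dataclass(frozen=True)
class SpecimenRecord:
    genus: str
    species_epithet: str
    family: str
    order: str
    diagnostic_part: str
    kind_of_specimen: str
    image_path: str
    image_description: str
    sequence_number: int
    citation_key: str
    host_name: Optional[str] = None

    def __post_init__(self) -> None:
        if int(self.sequence_number) < 1:
            raise RecordError("sequence_number must be >= 1")
        for f in ("genus", "species_epithet", "diagnostic_part", "kind_of_specimen", "citation_key"):
            if not getattr(self, f):
                raise RecordError(f"specimen record field {f!r} must be non-empty")


@dataclass(frozen=True)
class TaxonRecord:
    rank: str
    name_complete: str
    authorship: str = ""
    year: Optional[int] = None
    locality: str = ""
    parent_name: str = ""
    synonyms: tuple[str, ...] = ()
    label: str = ""  # verbatim instance-label override

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise RecordError(f"rank must be one of {RANKS}, got {self.rank!r}")
        if not self.name_complete and not self.label:
            raise RecordError("taxon record needs name_complete or a verbatim label")


@dataclass(frozen=True)
class PublicationRecord:
    authors: tuple[str, ...]
    year: int
    title: str = ""
    parent_publication: str = ""
    number: str = ""
    pub_type: str = "JournalArticle"
    lists: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.authors:
            raise RecordError("publication record needs at least one author")
        if not (1000 <= int(self.year) <= 9999):
            raise RecordError(f"publication year must be a 4-digit integer, got {self.year!r}")

    @property
    def instance_name(self) -> str:
        return publication_instance_name(list(self.authors), self.year)


SPECIMEN_COLUMNS = [
    "genus", "species_epithet", "family", "order", "diagnostic_part", "kind_of_specimen",
    "image_path", "image_description", "sequence_number", "citation_key", "host_name",
]
TAXON_COLUMNS = ["rank", "name_complete", "authorship", "year", "locality", "parent_name", "synonyms", "label"]
PUBLICATION_COLUMNS = ["authors", "year", "title", "parent_publication", "number", "pub_type", "lists"]
HOST_COLUMNS = ["label", "name_complete"]


def _cell(row, col) -> str:
    v = row.get(col, "")
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return ""
    return str(v).strip()


def _split(value: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in value.split(";") if s.strip())


def specimen_records(df: pd.DataFrame) -> list[SpecimenRecord]:
    records = []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            records.append(
                SpecimenRecord(
                    genus=_cell(row, "genus"),
                    species_epithet=_cell(row, "species_epithet"),
                    family=_cell(row, "family"),
                    order=_cell(row, "order"),
                    diagnostic_part=_cell(row, "diagnostic_part"),
                    kind_of_specimen=_cell(row, "kind_of_specimen"),
                    image_path=_cell(row, "image_path"),
                    image_description=_cell(row, "image_description"),
                    sequence_number=int(float(row.get("sequence_number", 0) or 0)),
                    citation_key=_cell(row, "citation_key"),
                    host_name=_cell(row, "host_name") or None,
                )
            )
        except (RecordError, ValueError) as exc:
            raise RecordError(f"specimens row {idx + 1}: {exc}") from exc
    return records


def taxon_records(df: pd.DataFrame) -> list[TaxonRecord]:
    records = []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            year_raw = _cell(row, "year")
            records.append(
                TaxonRecord(
                    rank=_cell(row, "rank"),
                    name_complete=_cell(row, "name_complete"),
                    authorship=_cell(row, "authorship"),
                    year=int(float(year_raw)) if year_raw else None,
                    locality=_cell(row, "locality"),
                    parent_name=_cell(row, "parent_name"),
                    synonyms=_split(_cell(row, "synonyms")),
                    label=_cell(row, "label"),
                )
            )
        except (RecordError, ValueError) as exc:
            raise RecordError(f"taxa row {idx + 1}: {exc}") from exc
    return records


def publication_records(df: pd.DataFrame) -> list[PublicationRecord]:
    records = []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            records.append(
                PublicationRecord(
                    authors=_split(_cell(row, "authors")),
                    year=int(float(_cell(row, "year"))),
                    title=_cell(row, "title"),
                    parent_publication=_cell(row, "parent_publication"),
                    number=_cell(row, "number"),
                    pub_type=_cell(row, "pub_type") or "JournalArticle",
                    lists=_split(_cell(row, "lists")),
                )
            )
        except (RecordError, ValueError) as exc:
            raise RecordError(f"publications row {idx + 1}: {exc}") from exc
    return records


# -- annotation ----------------------------------------------------------


class Annotator:
    """Stateful converter from records to instance triples.

    Tracks known citation labels (``isCitedIn`` must resolve), species-label
    provenance for homonym detection (two genera sharing a 3-letter prefix and
    an epithet get disambiguated with the family initial plus a warning), and
    the controlled-term individuals of the schema.
    """

    def __init__(
        self,
        schema: OntologyGraph,
        ns: Namespaces = DEFAULT_NAMESPACES,
        part_table: Mapping[str, tuple[str, str]] = DEFAULT_PART_TABLE,
        source_tag: str = "j1",
        assert_inverse_part: bool = False,
    ) -> None:
        self.schema = schema
        self.ns = ns
        self.part_table = dict(part_table)
        self.source_tag = source_tag
        self.assert_inverse_part = assert_inverse_part
        self.citations: set[str] = set()
        self._species_labels: dict[str, tuple[str, str]] = {}

    def _p(self, name: str, ns_key: str = "schema") -> IRI:
        namespace = {
            "schema": self.ns.schema,
            "taxon": self.ns.taxon_schema,
            "pub": self.ns.pub_schema,
        }[ns_key]
        return IRI(namespace, name)

    def _term(self, label: str) -> IRI:
        ind = self.ns.instance_iri(label)
        if self.schema.kind_of(ind) is not NodeKind.INDIVIDUAL:
            raise RecordError(f"controlled term {label!r} is not a registered term individual")
        return ind

    def species_label(self, genus: str, epithet: str, family: str = "") -> str:
        label = species_instance_name(genus, epithet)
        key = (ascii_fold(genus).lower(), ascii_fold(epithet).lower())
        seen = self._species_labels.get(label)
        if seen is not None and seen != key:
            disambiguated = label + (_title(family)[:1] if family else "X")
            warnings.warn(
                f"homonym collision on species label {label!r}; using {disambiguated!r}",
                stacklevel=2,
            )
            label = disambiguated
        self._species_labels.setdefault(label, key)
        return label

    def _type_individual(self, triples: set[Triple], ind: IRI, concept: str) -> None:
        triples.add(Triple(ind, RDF_TYPE, self.ns.schema_iri(concept)))

    def annotate_publication(self, record: PublicationRecord) -> set[Triple]:
        pub = self.ns.instance_iri(record.instance_name)
        self.citations.add(record.instance_name)
        triples: set[Triple] = set()
        self._type_individual(triples, pub, "PublicationCitation")
        triples.add(Triple(pub, self._p("pubType"), self._term(record.pub_type)))
        triples.add(Triple(pub, self._p("author"), Literal(" & ".join(record.authors))))
        triples.add(Triple(pub, self._p("year", "pub"), Literal(int(record.year))))
        if record.title:
            triples.add(Triple(pub, self._p("title"), Literal(record.title)))
        if record.parent_publication:
            triples.add(Triple(pub, self._p("parentPublicationString"), Literal(record.parent_publication)))
        if record.number:
            triples.add(Triple(pub, self._p("number"), Literal(record.number)))
        for taxon_label in record.lists:
            triples.add(Triple(pub, self._p("lists"), self.ns.instance_iri(taxon_label)))
        return triples

    def taxon_label(self, record: TaxonRecord) -> str:
        if record.label:
            return ascii_fold(record.label)
        if record.rank == "Species":
            parts = record.name_complete.split()
            if len(parts) != 2:
                raise RecordError(
                    f"species name_complete must be 'Genus epithet', got {record.name_complete!r}"
                )
            return self.species_label(parts[0], parts[1])
        return higher_taxon_instance_name(record.rank, record.name_complete)

    def annotate_taxon(self, record: TaxonRecord) -> set[Triple]:
        ind = self.ns.instance_iri(self.taxon_label(record))
        triples: set[Triple] = set()
        self._type_individual(triples, ind, "TaxonName")
        triples.add(Triple(ind, self._p("rank"), self._term(record.rank)))
        if record.name_complete:
            triples.add(Triple(ind, self._p("nameComplete"), Literal(record.name_complete)))
        if record.authorship:
            triples.add(Triple(ind, self._p("authorship"), Literal(record.authorship)))
        if record.year is not None:
            triples.add(Triple(ind, self._p("year", "taxon"), Literal(int(record.year))))
        if record.locality:
            triples.add(Triple(ind, self._p("locality"), Literal(record.locality)))
        if record.parent_name:
            parent_rank = PARENT_RANK.get(record.rank)
            if parent_rank is None:
                raise RecordError(f"rank {record.rank} cannot have a parent taxon")
            parent = self.ns.instance_iri(higher_taxon_instance_name(parent_rank, record.parent_name))
            triples.add(Triple(ind, self._p("isBelong"), parent))
            if record.rank == "Species":
                triples.add(Triple(parent, self._p("hasSpecies"), ind))
        for syn in record.synonyms:
            if not self.schema.is_declared_property(self._p("hasSynonym")):
                raise RecordError(
                    "taxon record carries synonyms but hasSynonym is not in the schema; "
                    "build the schema with the standard extensions"
                )
            triples.add(Triple(ind, self._p("hasSynonym"), self.ns.instance_iri(ascii_fold(syn))))
        return triples

    def annotate_specimen(self, record: SpecimenRecord) -> set[Triple]:
        if record.citation_key not in self.citations:
            raise RecordError(
                f"dangling reference: citation key {record.citation_key!r} matches no publication"
            )
        spec = self.ns.instance_iri(
            specimen_instance_name(
                record.genus, record.species_epithet, record.diagnostic_part,
                record.sequence_number, self.part_table,
            )
        )
        part_term = self.part_table[record.diagnostic_part.strip().lower()][1]
        species = self.ns.instance_iri(
            self.species_label(record.genus, record.species_epithet, record.family)
        )
        triples: set[Triple] = set()
        self._type_individual(triples, spec, "Specimen")
        triples.add(Triple(spec, self._p("kindOfSpecimen"), self._term(record.kind_of_specimen)))
        triples.add(Triple(spec, self._p("isHaptorBar"), self._term(part_term)))
        triples.add(Triple(spec, self._p("typeForName"), species))
        triples.add(Triple(spec, self._p("isCitedIn"), self.ns.instance_iri(record.citation_key)))
        triples.add(
            Triple(
                spec,
                self._p("specimenId"),
                Literal(specimen_id(record.genus, record.species_epithet, record.diagnostic_part, self.source_tag)),
            )
        )
        if record.image_path:
            triples.add(Triple(spec, self._p("imgDir"), Literal(record.image_path)))
        if record.image_description:
            triples.add(Triple(spec, self._p("imgDescription"), Literal(record.image_description)))
        if self.assert_inverse_part:
            triples.add(Triple(species, self._p("part"), spec))
        # taxon chain: species -> genus -> family -> order
        self._type_individual(triples, species, "TaxonName")
        triples.add(Triple(species, self._p("rank"), self._term("Species")))
        genus = self.ns.instance_iri(higher_taxon_instance_name("Genus", record.genus))
        triples.add(Triple(species, self._p("isBelong"), genus))
        triples.add(Triple(genus, self._p("hasSpecies"), species))
        self._type_individual(triples, genus, "TaxonName")
        triples.add(Triple(genus, self._p("rank"), self._term("Genus")))
        if record.family:
            family = self.ns.instance_iri(higher_taxon_instance_name("Family", record.family))
            triples.add(Triple(genus, self._p("isBelong"), family))
            self._type_individual(triples, family, "TaxonName")
            triples.add(Triple(family, self._p("rank"), self._term("Family")))
            if record.order:
                order = self.ns.instance_iri(higher_taxon_instance_name("Order", record.order))
                triples.add(Triple(family, self._p("isBelong"), order))
                self._type_individual(triples, order, "TaxonName")
                triples.add(Triple(order, self._p("rank"), self._term("Order")))
        if record.host_name:
            triples.add(Triple(species, self._p("isHostedIn"), Literal(record.host_name)))
        return triples


def annotate_specimen(
    record: SpecimenRecord,
    schema: OntologyGraph,
    ns: Namespaces = DEFAULT_NAMESPACES,
    citations: Iterable[str] = (),
    **kw,
) -> set[Triple]:
    """One-shot wrapper around :class:`Annotator` for a single record."""
    annotator = Annotator(schema, ns, **kw)
    annotator.citations.update(citations)
    return annotator.annotate_specimen(record)


def ingest(
    specimens: pd.DataFrame,
    taxa: pd.DataFrame,
    publications: pd.DataFrame,
    schema: Optional[OntologyGraph] = None,
    ns: Namespaces = DEFAULT_NAMESPACES,
    **annotator_kw,
) -> OntologyGraph:
    """Convert the three record tables into an instance graph layered on the
    schema.  The returned graph contains the schema triples plus all emitted
    instance triples; every subject typed under a declared concept class is
    declared as an individual."""
    if schema is None:
        schema = build_reference_schema(ns)
    graph = schema.copy()
    annotator = Annotator(schema, ns, **annotator_kw)
    emitted: set[Triple] = set()
    for record in publication_records(publications):
        emitted |= annotator.annotate_publication(record)
    tax_records = taxon_records(taxa)
    for record in tax_records:  # labels first so synonym targets resolve
        annotator.taxon_label(record)
    for record in tax_records:
        emitted |= annotator.annotate_taxon(record)
    for record in specimen_records(specimens):
        emitted |= annotator.annotate_specimen(record)
    classes = graph.iris_of_kind(NodeKind.CONCEPT_CLASS)
    for t in emitted:
        if t.predicate == RDF_TYPE and isinstance(t.object, IRI) and t.object in classes:
            if graph.kind_of(t.subject) is None:
                graph.declare(t.subject, NodeKind.INDIVIDUAL)
    graph.add_all(emitted)
    return graph


def build_fish_graph(
    hosts: pd.DataFrame, ns: Namespaces = DEFAULT_NAMESPACES
) -> OntologyGraph:
    """Fish (host) schema plus one taxon individual per host row."""
    graph = build_fish_schema(ns)
    taxon = ns.fish_schema_iri("TaxonName")
    for idx, row in enumerate(hosts.to_dict("records")):
        label = ascii_fold(_cell(row, "label"))
        if not label:
            raise RecordError(f"hosts row {idx + 1}: empty host label")
        ind = ns.fish_instance_iri(label)
        graph.declare(ind, NodeKind.INDIVIDUAL)
        graph.add(Triple(ind, RDF_TYPE, taxon))
        name = _cell(row, "name_complete")
        if name:
            graph.add(Triple(ind, ns.fish_schema_iri("nameComplete"), Literal(name)))
    return graph
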