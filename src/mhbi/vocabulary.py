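"""The MHBI controlled vocabulary as a declarative registry plus schema builders.

The Monogenean Haptoral Bar Image (MHBI) scheme annotates digitised images of
the haptoral bar — a sclerotised diagnostic hard part of monogenean flatworms —
with their taxonomy and publication provenance.  The vocabulary reuses the
TDWG LSID vocabulary wherever it fits and adds one genuinely new concept,
``DiagnosticPartTerms``, for the hard-part terms.

Seven concepts and twenty-seven core properties make up the schema:

========================  ===================  ====================
concept                   object properties    datatype properties
========================  ===================  ====================
Specimen                  4                    3
TaxonName                 8                    4
PublicationCitation       2                    5
four ``*Terms`` concepts  —                    1 (shared definedTerm)
========================  ===================  ====================

Only the evidenced OWL characteristics are asserted: ``typeForName`` is
functional with inverse-functional inverse ``part``; ``isBelong`` is
transitive with transitive inverse ``hasSpecies``.  ``hasSynonym`` (symmetric,
its own inverse) and the ``part`` sub-property family (``fullImage``,
``isBar``, ``isHaptor``) are shipped as extension properties: registering an
extension never touches a core axiom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .graph import (
    IRI,
    Literal,
    NodeKind,
    OntologyGraph,
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
    XSD_INTEGER,
    XSD_STRING,
    GraphError,
)


class VocabularyError(GraphError):
    """Ill-formed concept/property definition or extension registration."""


DEFAULT_BASE = "http://example.org/mhbi"
DEFAULT_FISH_BASE = "http://example.org/fish"


@dataclass(frozen=True)
class Namespaces:
    """Prefix layout: schema terms, two single-purpose namespaces keeping the
    taxon-level and publication-level ``year`` properties distinct, an
    instance namespace for all printed individual labels, and a disjoint pair
    for the fish (host) ontology."""

    schema: str
    taxon_schema: str
    pub_schema: str
    instance: str
    fish_schema: str
    fish_instance: str

    @classmethod
    def from_bases(cls, base: str = DEFAULT_BASE, fish_base: str = DEFAULT_FISH_BASE) -> "Namespaces":
        base = base.rstrip("/#")
        fish_base = fish_base.rstrip("/#")
        return cls(
            schema=base + "/schema#",
            taxon_schema=base + "/schema/taxon#",
            pub_schema=base + "/schema/publication#",
            instance=base + "/ind#",
            fish_schema=fish_base + "/schema#",
            fish_instance=fish_base + "/ind#",
        )

    @property
    def prefixes(self) -> dict[str, str]:
        return {
            "mhbi": self.schema,
            "mhbit": self.taxon_schema,
            "mhbip": self.pub_schema,
            "ind": self.instance,
            "fish": self.fish_schema,
            "fishind": self.fish_instance,
        }

    def schema_iri(self, name: str) -> IRI:
        return IRI(self.schema, name)

    def instance_iri(self, name: str) -> IRI:
        return IRI(self.instance, name)

    def fish_schema_iri(self, name: str) -> IRI:
        return IRI(self.fish_schema, name)

    def fish_instance_iri(self, name: str) -> IRI:
        return IRI(self.fish_instance, name)


DEFAULT_NAMESPACES = Namespaces.from_bases()

_NS_KEYS = {"schema", "taxon", "pub"}


@dataclass(frozen=True)
class ConceptDef:
    name: str
    source: str  # "tdwg" | "mhbi-new"
    description: str


CORE_CONCEPTS: tuple[ConceptDef, ...] = (
    ConceptDef("Specimen", "tdwg", "An illustrated image of a monogenean haptoral bar."),
    ConceptDef("TaxonName", "tdwg", "A single scientific name at any rank."),
    ConceptDef("PublicationCitation", "tdwg", "A reference to the publication describing the species."),
    ConceptDef("DiagnosticPartTerms", "mhbi-new", "Controlled terms for monogenean sclerotised hard parts."),
    ConceptDef("KindOfSpecimenTerms", "tdwg", "Controlled terms for the kind of specimen record."),
    ConceptDef("TaxonRankTerms", "tdwg", "Controlled terms for taxonomic rank."),
    ConceptDef("PublicationTypeTerms", "tdwg", "Controlled terms for the type of publication."),
)

CONCEPT_BY_NAME = {c.name: c for c in CORE_CONCEPTS}

TERMS_CONCEPTS = (
    "DiagnosticPartTerms",
    "KindOfSpecimenTerms",
    "TaxonRankTerms",
    "PublicationTypeTerms",
)


@dataclass(frozen=True)
class PropertyDef:
    """One vocabulary property.

    ``range`` is a tuple of concept names for object properties or a literal
    datatype tag (``"string"`` / ``"integer"``) for datatype properties.
    ``ns_key`` selects the namespace ("schema" for almost everything; the two
    ``year`` properties live in taxon/publication sub-namespaces so their
    domains stay unambiguous).  ``host_link`` marks ``isHostedIn``, which is
    classified as an object property but declared literal-valued until the
    host ontology is merged in.
    """

    name: str
    kind: str  # "object" | "datatype"
    concept: str  # owning concept for the census ("shared" for definedTerm)
    domain: tuple[str, ...]
    range: Union[tuple[str, ...], str]
    characteristics: frozenset = frozenset()
    inverse: Optional[str] = None
    super: Optional[str] = None
    core: bool = True
    source: str = "tdwg"
    ns_key: str = "schema"
    host_link: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("object", "datatype"):
            raise VocabularyError(f"unknown property kind {self.kind!r}")
        if self.ns_key not in _NS_KEYS:
            raise VocabularyError(f"unknown namespace key {self.ns_key!r}")
        if self.kind == "datatype":
            if not isinstance(self.range, str):
                raise VocabularyError(f"datatype property {self.name} must have a literal range")
            bad = self.characteristics & {"transitive", "symmetric", "inverse-functional"}
            if bad:
                raise VocabularyError(
                    f"datatype property {self.name} cannot carry {sorted(bad)} characteristics"
                )


def _obj(name, concept, domain, range_, **kw) -> PropertyDef:
    return PropertyDef(name, "object", concept, tuple(domain), tuple(range_), **kw)


def _dat(name, concept, domain, range_, **kw) -> PropertyDef:
    return PropertyDef(name, "datatype", concept, tuple(domain), range_, **kw)


CORE_PROPERTIES: tuple[PropertyDef, ...] = (
    # Specimen: 4 object + 3 datatype
    _obj("kindOfSpecimen", "Specimen", ["Specimen"], ["KindOfSpecimenTerms"]),
    _obj("isHaptorBar", "Specimen", ["Specimen"], ["DiagnosticPartTerms"], source="mhbi-new"),
    _obj("isCitedIn", "Specimen", ["Specimen"], ["PublicationCitation"]),
    _obj(
        "typeForName",
        "Specimen",
        ["Specimen"],
        ["TaxonName"],
        characteristics=frozenset({"functional"}),
        inverse="part",
    ),
    _dat("specimenId", "Specimen", ["Specimen"], "string"),
    _dat("imgDir", "Specimen", ["Specimen"], "string"),
    _dat("imgDescription", "Specimen", ["Specimen"], "string"),
    # TaxonName: 8 object + 4 datatype
    _obj("rank", "TaxonName", ["TaxonName"], ["TaxonRankTerms"]),
    _obj(
        "isBelong",
        "TaxonName",
        ["TaxonName"],
        ["TaxonName"],
        characteristics=frozenset({"transitive"}),
        inverse="hasSpecies",
    ),
    _obj(
        "part",
        "TaxonName",
        ["TaxonName"],
        ["Specimen"],
        characteristics=frozenset({"inverse-functional"}),
        inverse="typeForName",
    ),
    _obj(
        "hasSpecies",
        "TaxonName",
        ["TaxonName"],
        ["TaxonName"],
        characteristics=frozenset({"transitive"}),
        inverse="isBelong",
    ),
    _obj("hasGenus", "TaxonName", ["TaxonName"], ["TaxonName"]),
    _obj("hasFamily", "TaxonName", ["TaxonName"], ["TaxonName"]),
    _obj("hasOrder", "TaxonName", ["TaxonName"], ["TaxonName"]),
    _obj("isHostedIn", "TaxonName", ["TaxonName"], ["fish:TaxonName"], host_link=True),
    _dat("nameComplete", "TaxonName", ["TaxonName"], "string"),
    _dat("authorship", "TaxonName", ["TaxonName"], "string"),
    _dat("year", "TaxonName", ["TaxonName"], "integer", ns_key="taxon"),
    _dat("locality", "TaxonName", ["TaxonName"], "string"),
    # PublicationCitation: 2 object + 5 datatype
    _obj("pubType", "PublicationCitation", ["PublicationCitation"], ["PublicationTypeTerms"]),
    _obj("lists", "PublicationCitation", ["PublicationCitation"], ["TaxonName"]),
    _dat("author", "PublicationCitation", ["PublicationCitation"], "string"),
    _dat("year", "PublicationCitation", ["PublicationCitation"], "integer", ns_key="pub"),
    _dat("title", "PublicationCitation", ["PublicationCitation"], "string"),
    _dat("parentPublicationString", "PublicationCitation", ["PublicationCitation"], "string"),
    _dat("number", "PublicationCitation", ["PublicationCitation"], "string"),
    # shared across the four *Terms concepts: 1 datatype
    _dat("definedTerm", "shared", list(TERMS_CONCEPTS), "string"),
)

#: inverse axioms asserted once per pair (the registry lists both directions)
INVERSE_PAIRS: tuple[tuple[str, str], ...] = (("typeForName", "part"), ("isBelong", "hasSpecies"))


@dataclass(frozen=True)
class TermInstance:
    concept: str
    label: str
    authoritative: bool = True


TERM_INSTANCES: tuple[TermInstance, ...] = (
    TermInstance("DiagnosticPartTerms", "HaptorSclerotisedpartBar"),
    TermInstance("DiagnosticPartTerms", "HaptorSclerotisedpartAnchor"),
    TermInstance("DiagnosticPartTerms", "FullImage"),
    TermInstance("KindOfSpecimenTerms", "Illustration"),
    TermInstance("KindOfSpecimenTerms", "DigitalObject"),
    TermInstance("KindOfSpecimenTerms", "StillImage"),
    TermInstance("TaxonRankTerms", "Species"),
    TermInstance("TaxonRankTerms", "Genus"),
    TermInstance("TaxonRankTerms", "Family"),
    TermInstance("TaxonRankTerms", "Order"),
    TermInstance("PublicationTypeTerms", "JournalArticle"),
    TermInstance("PublicationTypeTerms", "Book"),
    # The controlled list has four members but only two are named; these two
    # placeholders are non-authoritative.
    TermInstance("PublicationTypeTerms", "BookSection", authoritative=False),
    TermInstance("PublicationTypeTerms", "Thesis", authoritative=False),
)

# -- standard extension properties --------------------------------------

EXT_HAS_SYNONYM = _obj(
    "hasSynonym",
    "TaxonName",
    ["TaxonName"],
    ["TaxonName"],
    characteristics=frozenset({"symmetric"}),
    inverse="hasSynonym",  # a symmetric property is its own inverse
    core=False,
    source="mhbi-new",
)

#: sub-properties of ``part`` — domain and range inherited from the super.
EXT_PART_SUBPROPERTIES: tuple[PropertyDef, ...] = (
    _obj("fullImage", "TaxonName", [], [], super="part", core=False, source="mhbi-new"),
    _obj("isBar", "TaxonName", [], [], super="part", core=False, source="mhbi-new"),
    _obj("isHaptor", "TaxonName", [], [], super="part", core=False, source="mhbi-new"),
)

STANDARD_EXTENSIONS: tuple[PropertyDef, ...] = (EXT_HAS_SYNONYM,) + EXT_PART_SUBPROPERTIES

_CHARACTERISTIC_TERMS = {
    "functional": OWL_FUNCTIONAL,
    "inverse-functional": OWL_INVERSE_FUNCTIONAL,
    "transitive": OWL_TRANSITIVE,
    "symmetric": OWL_SYMMETRIC,
}

_LITERAL_RANGES = {"string": XSD_STRING, "integer": XSD_INTEGER}


def property_iri(pdef: PropertyDef, ns: Namespaces = DEFAULT_NAMESPACES) -> IRI:
    namespace = {"schema": ns.schema, "taxon": ns.taxon_schema, "pub": ns.pub_schema}[pdef.ns_key]
    return IRI(namespace, pdef.name)


def core_property_iris(ns: Namespaces = DEFAULT_NAMESPACES) -> dict[IRI, PropertyDef]:
    return {property_iri(p, ns): p for p in CORE_PROPERTIES}


def _range_iris(pdef: PropertyDef, ns: Namespaces) -> list[IRI]:
    assert pdef.kind == "object"
    out = []
    for name in pdef.range:
        if name.startswith("fish:"):
            out.append(ns.fish_schema_iri(name.split(":", 1)[1]))
        else:
            out.append(ns.schema_iri(name))
    return out


def _declare_property(graph: OntologyGraph, pdef: PropertyDef, ns: Namespaces, host_as_literal: bool) -> None:
    p = property_iri(pdef, ns)
    as_datatype = pdef.kind == "datatype" or (pdef.host_link and host_as_literal)
    graph.declare(p, NodeKind.DATATYPE_PROPERTY if as_datatype else NodeKind.OBJECT_PROPERTY)
    for dom in pdef.domain:
        graph.add(Triple(p, RDFS_DOMAIN, ns.schema_iri(dom)))
    if as_datatype:
        tag = pdef.range if isinstance(pdef.range, str) else "string"
        graph.add(Triple(p, RDFS_RANGE, _LITERAL_RANGES[tag]))
    else:
        for r in _range_iris(pdef, ns):
            graph.add(Triple(p, RDFS_RANGE, r))
    for ch in sorted(pdef.characteristics):
        graph.add(Triple(p, RDF_TYPE, _CHARACTERISTIC_TERMS[ch]))


def build_mhbi_schema(
    ns: Namespaces = DEFAULT_NAMESPACES,
    extensions: Sequence[PropertyDef] = (),
    host_as_literal: bool = True,
    base_iri: str = DEFAULT_BASE,
) -> OntologyGraph:
    """Build the reference MHBI schema graph: 7 concept classes, 27 core
    properties with domains/ranges/characteristics/inverses, and the
    controlled-term individuals.  Deterministic: two builds serialize
    identically."""
    graph = OntologyGraph(base_iri=base_iri, strict=True, prefixes=ns.prefixes)
    for concept in CORE_CONCEPTS:
        graph.declare(ns.schema_iri(concept.name), NodeKind.CONCEPT_CLASS)
    for pdef in CORE_PROPERTIES:
        _declare_property(graph, pdef, ns, host_as_literal)
    for a, b in INVERSE_PAIRS:
        pa = property_iri(next(p for p in CORE_PROPERTIES if p.name == a), ns)
        pb = property_iri(next(p for p in CORE_PROPERTIES if p.name == b), ns)
        graph.add(Triple(pa, OWL_INVERSE_OF, pb))
    defined_term = ns.schema_iri("definedTerm")
    for term in TERM_INSTANCES:
        ind = ns.instance_iri(term.label)
        graph.declare(ind, NodeKind.INDIVIDUAL)
        graph.add(Triple(ind, RDF_TYPE, ns.schema_iri(term.concept)))
        graph.add(Triple(ind, defined_term, Literal(term.label)))
    for pdef in extensions:
        register_extension_property(graph, pdef, ns)
    return graph


def build_reference_schema(ns: Namespaces = DEFAULT_NAMESPACES, **kw) -> OntologyGraph:
    """Core schema plus the standard extensions (``hasSynonym`` and the
    ``part`` sub-property family) — the graph the evaluation battery and the
    mutant fixtures run against."""
    return build_mhbi_schema(ns=ns, extensions=STANDARD_EXTENSIONS, **kw)


def register_extension_property(
    graph: OntologyGraph, pdef: PropertyDef, ns: Namespaces = DEFAULT_NAMESPACES
) -> OntologyGraph:
    """Add a non-core property without touching existing axioms.

    When the definition names a super-property and leaves domain/range empty,
    both are inherited from the super-property's asserted axioms.
    """
    if pdef.core:
        raise VocabularyError(f"{pdef.name} is marked core; extensions must have core=False")
    p = property_iri(pdef, ns)
    if graph.kind_of(p) is not None:
        raise VocabularyError(f"extension property {pdef.name} collides with an existing declaration")
    graph.declare(
        p,
        NodeKind.DATATYPE_PROPERTY if pdef.kind == "datatype" else NodeKind.OBJECT_PROPERTY,
    )
    super_iri = ns.schema_iri(pdef.super) if pdef.super else None
    if super_iri is not None and not graph.is_declared_property(super_iri):
        raise VocabularyError(f"super-property {pdef.super} of {pdef.name} is not declared")
    if pdef.domain:
        for dom in pdef.domain:
            graph.add(Triple(p, RDFS_DOMAIN, ns.schema_iri(dom)))
    elif super_iri is not None:
        for t in graph.match(super_iri, RDFS_DOMAIN, None):
            graph.add(Triple(p, RDFS_DOMAIN, t.object))
    if pdef.kind == "datatype":
        graph.add(Triple(p, RDFS_RANGE, _LITERAL_RANGES[pdef.range]))
    elif pdef.range:
        for r in _range_iris(pdef, ns):
            graph.add(Triple(p, RDFS_RANGE, r))
    elif super_iri is not None:
        for t in graph.match(super_iri, RDFS_RANGE, None):
            graph.add(Triple(p, RDFS_RANGE, t.object))
    for ch in sorted(pdef.characteristics):
        graph.add(Triple(p, RDF_TYPE, _CHARACTERISTIC_TERMS[ch]))
    if super_iri is not None:
        graph.add(Triple(p, RDFS_SUBPROPERTYOF, super_iri))
    if pdef.inverse:
        inv = ns.schema_iri(pdef.inverse) if pdef.inverse != pdef.name else p
        graph.add(Triple(p, OWL_INVERSE_OF, inv))
    return graph


def build_fish_schema(
    ns: Namespaces = DEFAULT_NAMESPACES, base_iri: str = DEFAULT_FISH_BASE
) -> OntologyGraph:
    """A deliberately simple host ontology: a single fish ``TaxonName``
    concept with the naming/rank datatype properties its instances need."""
    graph = OntologyGraph(base_iri=base_iri, strict=True, prefixes=ns.prefixes)
    taxon = ns.fish_schema_iri("TaxonName")
    graph.declare(taxon, NodeKind.CONCEPT_CLASS)
    for name in ("nameComplete", "rank"):
        p = ns.fish_schema_iri(name)
        graph.declare(p, NodeKind.DATATYPE_PROPERTY)
        graph.add(Triple(p, RDFS_DOMAIN, taxon))
        graph.add(Triple(p, RDFS_RANGE, XSD_STRING))
    return graph


# -- census & manifest ---------------------------------------------------


def core_property_breakdown() -> dict[str, dict[str, int]]:
    """Vocabulary-level census by owning concept, e.g. Specimen → 4 object +
    3 datatype.  ``isHostedIn`` counts as object here (its vocabulary-level
    classification) even though it is literal-valued until merge."""
    out: dict[str, dict[str, int]] = {}
    for p in CORE_PROPERTIES:
        bucket = out.setdefault(p.concept, {"object": 0, "datatype": 0})
        bucket[p.kind] += 1
    return out


@dataclass(frozen=True)
class SchemaCensus:
    concept_classes: int
    core_properties: int
    extension_properties: int
    term_individuals: int


def census(graph: OntologyGraph, ns: Namespaces = DEFAULT_NAMESPACES) -> SchemaCensus:
    """Count declarations actually present in a schema graph."""
    schema_nss = {ns.schema, ns.taxon_schema, ns.pub_schema}
    concepts = sum(
        1 for i in graph.iris_of_kind(NodeKind.CONCEPT_CLASS) if i.namespace == ns.schema
    )
    core = set(core_property_iris(ns))
    n_core = sum(1 for i in core if graph.is_declared_property(i))
    n_ext = sum(
        1
        for i, k in graph.declarations.items()
        if k.value.endswith("property") and i.namespace in schema_nss and i not in core
    )
    inds = sum(1 for i in graph.iris_of_kind(NodeKind.INDIVIDUAL) if i.namespace == ns.instance)
    return SchemaCensus(concepts, n_core, n_ext, inds)


def vocabulary_manifest(extensions: Sequence[PropertyDef] = STANDARD_EXTENSIONS) -> list[dict]:
    """Machine-readable vocabulary listing: one entry per concept/property
    with its source (TDWG reuse vs newly coined)."""
    rows: list[dict] = []
    for c in CORE_CONCEPTS:
        rows.append(
            {"entry": "concept", "name": c.name, "concept": c.name, "source": c.source,
             "kind": "", "description": c.description}
        )
    for p in tuple(CORE_PROPERTIES) + tuple(extensions):
        rows.append(
            {
                "entry": "property",
                "name": p.name,
                "concept": p.concept,
                "source": p.source,
                "kind": p.kind,
                "description": ("core" if p.core else "extension")
                + (f"; sub-property of {p.super}" if p.super else ""),
            }
        )
    return rows


def write_manifest(path, extensions: Sequence[PropertyDef] = STANDARD_EXTENSIONS) -> None:
    import csv

    rows = vocabulary_manifest(extensions)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["entry", "name", "concept", "kind", "source", "description"],
            delimiter="\t",
        )
        writer.writeheader()
        writer.writerows(rows)
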