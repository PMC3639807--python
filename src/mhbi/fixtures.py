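"""Packaged worked-example dataset, parametric synthetic datasets, and the
20-mutant negative-control suite for the validation battery.

``worked_example_fixture`` reproduces the *Bifurcohaptor baungi* worked example — one
ventral-bar specimen image, its four-rank taxon chain, the Lim & Furtado 1983
citation, a fish host, and a synonym pair — both as input tables and as the
hand-written triple graph ingestion must reproduce exactly.

``generate`` emits taxonomically consistent synthetic tables (every species
under exactly one genus, and so on up the classification) from a seeded
pseudo-Latin name sampler, together with a bookkeeping manifest of the exact
per-concept counts the ingested graph must show.  The generator's shape
parameters mirror the cardinality structure of a real haptoral-bar image
collection, scaled to desk size.

``mutate`` applies one of 20 registered minimal axiom edits to the reference
schema, each constructed so that exactly one validation test (plus any
logically entailed co-failures, recorded per mutant) goes red.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .annotation import (
    HOST_COLUMNS,
    PUBLICATION_COLUMNS,
    SPECIMEN_COLUMNS,
    TAXON_COLUMNS,
)
from .graph import (
    IRI,
    Literal,
    NodeKind,
    OntologyGraph,
    OWL_CARDINALITY,
    OWL_FUNCTIONAL,
    OWL_INVERSE_FUNCTIONAL,
    OWL_INVERSE_OF,
    OWL_ON_PROPERTY,
    OWL_ONE_OF,
    OWL_RESTRICTION,
    OWL_TRANSITIVE,
    RDF_TYPE,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDFS_SUBPROPERTYOF,
    Triple,
    iri_from_string,
)
from .vocabulary import (
    DEFAULT_NAMESPACES,
    Namespaces,
    PropertyDef,
    build_reference_schema,
    register_extension_property,
    _obj,
)


class FixtureError(ValueError):
    pass


# -- worked example ------------------------------------------------------


@dataclass
class WorkedExampleFixture:
    specimens: pd.DataFrame
    taxa: pd.DataFrame
    publications: pd.DataFrame
    hosts: pd.DataFrame
    schema: OntologyGraph
    expected_graph: OntologyGraph
    ns: Namespaces


_LOCALITY = "Tasek Bera, Pahang; Bukit Merah Reservoir, Perak"
_TITLE = (
    "Ancylodiscoidins (Monogenea: Dactylogyridae) from two freshwater fish "
    "species of Peninsular Malaysia"
)


def worked_example_fixture(ns: Namespaces = DEFAULT_NAMESPACES) -> WorkedExampleFixture:
    """The worked-example record set and its expected instance graph."""
    specimens = pd.DataFrame(
        [
            {
                "genus": "Bifurcohaptor",
                "species_epithet": "baungi",
                "family": "Ancylodiscoididae",
                "order": "Dactylogyridea",
                "diagnostic_part": "ventral bar",
                "kind_of_specimen": "Illustration",
                "image_path": "/images/BIF-BAUNGI-ventral-bar-single.jpg",
                "image_description": "",
                "sequence_number": 1,
                "citation_key": "LimFurtado1983",
                "host_name": "SilBagMysHemurus",
            }
        ],
        columns=SPECIMEN_COLUMNS,
    )
    taxa = pd.DataFrame(
        [
            {
                "rank": "Species",
                "name_complete": "Bifurcohaptor baungi",
                "authorship": "Lim & Furtado",
                "year": 1983,
                "locality": _LOCALITY,
                "parent_name": "Bifurcohaptor",
                "synonyms": "",
                "label": "",
            },
            {
                "rank": "Genus",
                "name_complete": "Bifurcohaptor",
                "authorship": "Jain",
                "year": 1958,
                "locality": "",
                "parent_name": "Ancylodiscoididae",
                "synonyms": "",
                "label": "",
            },
            {
                "rank": "Family",
                "name_complete": "Ancylodiscoididae",
                "authorship": "",
                "year": "",
                "locality": "",
                "parent_name": "Dactylogyridea",
                "synonyms": "",
                "label": "",
            },
            {
                "rank": "Order",
                "name_complete": "Dactylogyridea",
                "authorship": "",
                "year": "",
                "locality": "",
                "parent_name": "",
                "synonyms": "",
                "label": "",
            },
            # the synonym pair is attested only by its instance labels, so the
            # labels are used verbatim rather than derived from a binomial
            {
                "rank": "Species",
                "name_complete": "",
                "authorship": "",
                "year": "",
                "locality": "",
                "parent_name": "",
                "synonyms": "SiloGharui",
                "label": "BycGharui",
            },
            {
                "rank": "Species",
                "name_complete": "",
                "authorship": "",
                "year": "",
                "locality": "",
                "parent_name": "",
                "synonyms": "",
                "label": "SiloGharui",
            },
        ],
        columns=TAXON_COLUMNS,
    )
    publications = pd.DataFrame(
        [
            {
                "authors": "Lim;Furtado",
                "year": 1983,
                "title": _TITLE,
                "parent_publication": "Folia Parasitologica",
                "number": "30, 377-380",
                "pub_type": "JournalArticle",
                "lists": "BifBaungi",
            }
        ],
        columns=PUBLICATION_COLUMNS,
    )
    hosts = pd.DataFrame(
        [{"label": "SilBagMysHemurus", "name_complete": "Mystus nemurus"}],
        columns=HOST_COLUMNS,
    )
    schema = build_reference_schema(ns)
    expected = schema.copy()
    _add_expected_instances(expected, ns)
    return WorkedExampleFixture(specimens, taxa, publications, hosts, schema, expected, ns)


def _add_expected_instances(g: OntologyGraph, ns: Namespaces) -> None:
    """Hand-written expected triples for the worked example (independent of
    the annotation code paths)."""
    ind = ns.instance_iri
    p = ns.schema_iri
    tyear = IRI(ns.taxon_schema, "year")
    pyear = IRI(ns.pub_schema, "year")
    spec = ind("bif-baungi-vb-i1")
    species, genus = ind("BifBaungi"), ind("Bifurcohaptor")
    family, order = ind("Ancylodiscoididae"), ind("Dactylogyridea")
    pub = ind("LimFurtado1983")
    byc, silo = ind("BycGharui"), ind("SiloGharui")
    for individual in (spec, species, genus, family, order, pub, byc, silo):
        g.declare(individual, NodeKind.INDIVIDUAL)
    triples = [
        (spec, RDF_TYPE, p("Specimen")),
        (spec, p("kindOfSpecimen"), ind("Illustration")),
        (spec, p("isHaptorBar"), ind("HaptorSclerotisedpartBar")),
        (spec, p("typeForName"), species),
        (spec, p("isCitedIn"), pub),
        (spec, p("specimenId"), Literal("j1-bif-bau-ven-bar")),
        (spec, p("imgDir"), Literal("/images/BIF-BAUNGI-ventral-bar-single.jpg")),
        (species, RDF_TYPE, p("TaxonName")),
        (species, p("rank"), ind("Species")),
        (species, p("isBelong"), genus),
        (species, p("isHostedIn"), Literal("SilBagMysHemurus")),
        (species, p("nameComplete"), Literal("Bifurcohaptor baungi")),
        (species, p("authorship"), Literal("Lim & Furtado")),
        (species, tyear, Literal(1983)),
        (species, p("locality"), Literal(_LOCALITY)),
        (genus, RDF_TYPE, p("TaxonName")),
        (genus, p("rank"), ind("Genus")),
        (genus, p("isBelong"), family),
        (genus, p("hasSpecies"), species),
        (genus, p("nameComplete"), Literal("Bifurcohaptor")),
        (genus, p("authorship"), Literal("Jain")),
        (genus, tyear, Literal(1958)),
        (family, RDF_TYPE, p("TaxonName")),
        (family, p("rank"), ind("Family")),
        (family, p("isBelong"), order),
        (family, p("nameComplete"), Literal("Ancylodiscoididae")),
        (order, RDF_TYPE, p("TaxonName")),
        (order, p("rank"), ind("Order")),
        (order, p("nameComplete"), Literal("Dactylogyridea")),
        (pub, RDF_TYPE, p("PublicationCitation")),
        (pub, p("pubType"), ind("JournalArticle")),
        (pub, p("lists"), species),
        (pub, p("author"), Literal("Lim & Furtado")),
        (pub, pyear, Literal(1983)),
        (pub, p("title"), Literal(_TITLE)),
        (pub, p("parentPublicationString"), Literal("Folia Parasitologica")),
        (pub, p("number"), Literal("30, 377-380")),
        (byc, RDF_TYPE, p("TaxonName")),
        (byc, p("rank"), ind("Species")),
        (byc, p("hasSynonym"), silo),
        (silo, RDF_TYPE, p("TaxonName")),
        (silo, p("rank"), ind("Species")),
    ]
    for s, pred, o in triples:
        g.add(Triple(s, pred, o))


# -- synthetic generator -------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    n_orders: int = 2
    n_families_per_order: int = 2
    n_genera_per_family: int = 2
    n_species_per_genus: int = 2
    n_specimens_per_species: int = 1
    n_publications: int = 3
    host_fraction: float = 0.5
    unresolvable_host_fraction: float = 0.0
    collision_injection: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_orders,
            self.n_families_per_order,
            self.n_genera_per_family,
            self.n_species_per_genus,
            self.n_publications,
        )
        if any(c < 1 for c in counts) or self.n_specimens_per_species < 0:
            raise FixtureError("generator counts must be positive (specimens may be zero)")
        for frac in (self.host_fraction, self.unresolvable_host_fraction):
            if not 0.0 <= frac <= 1.0:
                raise FixtureError("fractions must lie in [0, 1]")
        if self.total_individuals > 10_000:
            raise FixtureError(
                f"configuration would generate {self.total_individuals} individuals (bound 10000)"
            )

    @property
    def n_species(self) -> int:
        return (
            self.n_orders
            * self.n_families_per_order
            * self.n_genera_per_family
            * self.n_species_per_genus
        )

    @property
    def total_individuals(self) -> int:
        n_genera = self.n_orders * self.n_families_per_order * self.n_genera_per_family
        n_families = self.n_orders * self.n_families_per_order
        taxa = self.n_species + n_genera + n_families + self.n_orders
        return taxa + self.n_species * self.n_specimens_per_species + self.n_publications


@dataclass
class GeneratedDataset:
    specimens: pd.DataFrame
    taxa: pd.DataFrame
    publications: pd.DataFrame
    hosts: pd.DataFrame
    manifest: dict


_SYLLABLES = (
    "ba", "bi", "bo", "ca", "ce", "co", "da", "do", "fa", "ga", "gi", "ha", "lo",
    "ma", "mi", "na", "ne", "pa", "pe", "ra", "ro", "sa", "si", "ta", "ti", "tu",
    "va", "vi", "xa", "zo",
)


class _NameSampler:
    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, n_syllables: int, suffix: str = "") -> str:
        for _ in range(1000):
            w = "".join(self.rng.choice(_SYLLABLES) for _ in range(n_syllables)) + suffix
            if w not in self.used:
                self.used.add(w)
                return w
        raise FixtureError("name sampler exhausted; reduce the requested counts")


_PARTS = ("ventral bar", "dorsal bar", "anchor")


def generate(config: GeneratorConfig) -> GeneratedDataset:
    """Seeded synthetic tables plus a manifest of exact expected counts."""
    rng = random.Random(config.seed)
    sampler = _NameSampler(rng)

    orders = [sampler.word(3, "idea").capitalize() for _ in range(config.n_orders)]
    taxa_rows: list[dict] = []
    species_info: list[dict] = []
    species_labels: set[str] = set()
    n_families = 0
    n_genera = 0
    for order in orders:
        taxa_rows.append(_taxon_row("Order", order))
        for _ in range(config.n_families_per_order):
            family = sampler.word(3, "idae").capitalize()
            n_families += 1
            taxa_rows.append(_taxon_row("Family", family, parent=order))
            for _ in range(config.n_genera_per_family):
                genus = sampler.word(3).capitalize()
                n_genera += 1
                taxa_rows.append(_taxon_row("Genus", genus, parent=family))
                for _ in range(config.n_species_per_genus):
                    epithet = sampler.word(3)
                    label = genus[:3] + epithet.capitalize()
                    if not config.collision_injection:
                        # resample on 3-letter-prefix homonyms so default
                        # datasets never need disambiguation
                        tries = 0
                        while label in species_labels and tries < 100:
                            epithet = sampler.word(3)
                            label = genus[:3] + epithet.capitalize()
                            tries += 1
                    species_labels.add(label)
                    taxa_rows.append(
                        _taxon_row(
                            "Species",
                            f"{genus} {epithet}",
                            parent=genus,
                            year=rng.randint(1900, 2010),
                            authorship=sampler.word(2).capitalize(),
                        )
                    )
                    species_info.append(
                        {"genus": genus, "epithet": epithet, "family": family, "order": order}
                    )

    pub_rows = []
    pub_keys = []
    for _ in range(config.n_publications):
        authors = [sampler.word(2).capitalize() for _ in range(rng.randint(1, 3))]
        year = rng.randint(1900, 2010)
        key = "".join(authors) + str(year)
        pub_rows.append(
            {
                "authors": ";".join(authors),
                "year": year,
                "title": " ".join(sampler.word(3) for _ in range(4)),
                "parent_publication": sampler.word(4).capitalize(),
                "number": str(rng.randint(1, 60)),
                "pub_type": rng.choice(("JournalArticle", "Book")),
                "lists": "",
            }
        )
        pub_keys.append(key)

    n_hosts = max(1, config.n_species // 2)
    host_rows = [
        {"label": sampler.word(4).capitalize(), "name_complete": f"{sampler.word(3).capitalize()} {sampler.word(3)}"}
        for _ in range(n_hosts)
    ]
    resolvable_labels = [h["label"] for h in host_rows]

    specimen_rows = []
    n_hosted = 0
    n_unresolvable = 0
    hosted_species: set[str] = set()
    for info in species_info:
        host = ""
        if rng.random() < config.host_fraction:
            if rng.random() < config.unresolvable_host_fraction:
                host = sampler.word(5).capitalize()  # never added to the host table
                n_unresolvable += 1
            else:
                host = rng.choice(resolvable_labels)
                n_hosted += 1
            hosted_species.add(info["genus"][:3] + info["epithet"].capitalize())
        seq_counter: dict[str, int] = {}
        for _ in range(config.n_specimens_per_species):
            part = rng.choice(_PARTS)
            seq = seq_counter.get(part, 0) + 1
            seq_counter[part] = seq
            specimen_rows.append(
                {
                    "genus": info["genus"],
                    "species_epithet": info["epithet"],
                    "family": info["family"],
                    "order": info["order"],
                    "diagnostic_part": part,
                    "kind_of_specimen": "Illustration",
                    "image_path": f"/images/{info['genus'].upper()}-{info['epithet'].upper()}-{part.replace(' ', '-')}-{seq}.jpg",
                    "image_description": "",
                    "sequence_number": seq,
                    "citation_key": rng.choice(pub_keys),
                    "host_name": host,
                }
            )

    manifest = {
        "seed": config.seed,
        "counts": {
            "Specimen": len(specimen_rows),
            "TaxonName": config.n_species + n_genera + n_families + config.n_orders,
            "PublicationCitation": config.n_publications,
            "Species": config.n_species,
            "Genus": n_genera,
            "Family": n_families,
            "Order": config.n_orders,
        },
        "hosts": {
            "resolvable_assignments": n_hosted,
            "unresolvable_assignments": n_unresolvable,
            "species_with_host": len(hosted_species),
            "fish_individuals": n_hosts,
        },
    }
    return GeneratedDataset(
        specimens=pd.DataFrame(specimen_rows, columns=SPECIMEN_COLUMNS),
        taxa=pd.DataFrame(taxa_rows, columns=TAXON_COLUMNS),
        publications=pd.DataFrame(pub_rows, columns=PUBLICATION_COLUMNS),
        hosts=pd.DataFrame(host_rows, columns=HOST_COLUMNS),
        manifest=manifest,
    )


def _taxon_row(rank, name, parent="", year="", authorship="") -> dict:
    return {
        "rank": rank,
        "name_complete": name,
        "authorship": authorship,
        "year": year,
        "locality": "",
        "parent_name": parent,
        "synonyms": "",
        "label": "",
    }


def write_tables(dataset, out_dir) -> dict[str, str]:
    """Write the four record tables (and manifest) as CSV/JSON text files."""
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in ("specimens", "taxa", "publications", "hosts"):
        path = os.path.join(out_dir, f"{name}.csv")
        getattr(dataset, name).to_csv(path, index=False)
        paths[name] = path
    if getattr(dataset, "manifest", None) is not None:
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataset.manifest, fh, indent=2, sort_keys=True)
        paths["manifest"] = path
    return paths


def random_graph(
    rng: random.Random,
    n_triples: int = 30,
    base: str = "http://example.org/random",
) -> OntologyGraph:
    """A seeded random but well-formed graph: a few classes, object and
    datatype properties, individuals, and literal values.  Used for
    serialization round-trip and query property checks."""
    ns_schema = base.rstrip("/#") + "/schema#"
    ns_inst = base.rstrip("/#") + "/ind#"
    g = OntologyGraph(base_iri=base, prefixes={"rs": ns_schema, "ri": ns_inst})
    classes = [IRI(ns_schema, f"Class{i}") for i in range(rng.randint(1, 4))]
    obj_props = [IRI(ns_schema, f"rel{i}") for i in range(rng.randint(1, 4))]
    dat_props = [IRI(ns_schema, f"attr{i}") for i in range(rng.randint(1, 3))]
    individuals = [IRI(ns_inst, f"item{i}") for i in range(rng.randint(2, 12))]
    for c in classes:
        g.declare(c, NodeKind.CONCEPT_CLASS)
    for p in obj_props:
        g.declare(p, NodeKind.OBJECT_PROPERTY)
        g.add(Triple(p, RDFS_DOMAIN, rng.choice(classes)))
        g.add(Triple(p, RDFS_RANGE, rng.choice(classes)))
    for p in dat_props:
        g.declare(p, NodeKind.DATATYPE_PROPERTY)
        g.add(Triple(p, RDFS_DOMAIN, rng.choice(classes)))
    for i in individuals:
        g.declare(i, NodeKind.INDIVIDUAL)
        g.add(Triple(i, RDF_TYPE, rng.choice(classes)))
    for _ in range(n_triples):
        if rng.random() < 0.6:
            g.add(Triple(rng.choice(individuals), rng.choice(obj_props), rng.choice(individuals)))
        elif rng.random() < 0.5:
            g.add(Triple(rng.choice(individuals), rng.choice(dat_props), Literal(rng.randint(0, 5000))))
        else:
            word = "".join(rng.choice("abcdefgh ") for _ in range(rng.randint(1, 12))).strip() or "x"
            g.add(Triple(rng.choice(individuals), rng.choice(dat_props), Literal(word)))
    return g


# -- mutants -------------------------------------------------------------


@dataclass(frozen=True)
class MutantSpec:
    target_test: str
    description: str
    expected_failures: frozenset


def _ext(name, domain, range_, **kw) -> PropertyDef:
    return _obj(name, "TaxonName", domain, range_, core=False, source="mhbi-new", **kw)


def _m_c1(g: OntologyGraph, ns: Namespaces) -> None:
    r = ns.schema_iri("IsBelongCardinalityOne")
    g.add(Triple(r, RDF_TYPE, OWL_RESTRICTION))
    g.add(Triple(r, OWL_ON_PROPERTY, ns.schema_iri("isBelong")))
    g.add(Triple(r, OWL_CARDINALITY, Literal(1)))


def _m_c2(g: OntologyGraph, ns: Namespaces) -> None:
    enum = ns.schema_iri("SpecimenKindEnumeration")
    g.declare(enum, NodeKind.CONCEPT_CLASS)
    g.add(Triple(enum, OWL_ONE_OF, ns.schema_iri("Specimen")))


def _m_c3(g: OntologyGraph, ns: Namespaces) -> None:
    g.add_import(iri_from_string("http://www.w3.org/2002/07/owl"))


def _m_c4(g: OntologyGraph, ns: Namespaces) -> None:
    g.add(Triple(ns.schema_iri("TaxonName"), RDF_TYPE, ns.schema_iri("Specimen")))


def _m_c5(g: OntologyGraph, ns: Namespaces) -> None:
    from .graph import OWL_CLASS

    g.add(Triple(ns.schema_iri("rank"), RDFS_RANGE, OWL_CLASS))


def _m_c6(g: OntologyGraph, ns: Namespaces) -> None:
    from .graph import RDFS_RESOURCE

    g.add(Triple(ns.schema_iri("Specimen"), RDFS_SUBCLASSOF, RDFS_RESOURCE))


def _m_c7(g: OntologyGraph, ns: Namespaces) -> None:
    note = ns.schema_iri("note")
    g.declare(note, NodeKind.ANNOTATION_PROPERTY)
    g.add(Triple(note, RDFS_SUBPROPERTYOF, ns.schema_iri("imgDescription")))


def _m_c8(g: OntologyGraph, ns: Namespaces) -> None:
    g.add(Triple(ns.schema_iri("isBelong"), RDF_TYPE, OWL_FUNCTIONAL))


def _m_k1(g: OntologyGraph, ns: Namespaces) -> None:
    p = ns.schema_iri("hasHook")
    g.declare(p, NodeKind.OBJECT_PROPERTY)
    g.add(Triple(p, RDFS_RANGE, ns.schema_iri("Specimen")))


def _subclass_and(g: OntologyGraph, ns: Namespaces, prop: str, predicate: IRI) -> None:
    sub = ns.schema_iri("BarTerms")
    g.declare(sub, NodeKind.CONCEPT_CLASS)
    g.add(Triple(sub, RDFS_SUBCLASSOF, ns.schema_iri("DiagnosticPartTerms")))
    g.add(Triple(ns.schema_iri(prop), predicate, sub))


def _m_k2(g: OntologyGraph, ns: Namespaces) -> None:
    _subclass_and(g, ns, "definedTerm", RDFS_DOMAIN)


def _m_k3(g: OntologyGraph, ns: Namespaces) -> None:
    _subclass_and(g, ns, "isHaptorBar", RDFS_RANGE)


def _m_k4(g: OntologyGraph, ns: Namespaces) -> None:
    g.add(Triple(ns.schema_iri("isBar"), RDFS_DOMAIN, ns.schema_iri("PublicationCitation")))


def _m_k5(g: OntologyGraph, ns: Namespaces) -> None:
    g.add(Triple(ns.schema_iri("isBar"), RDFS_RANGE, ns.schema_iri("PublicationCitation")))


def _m_k6(g: OntologyGraph, ns: Namespaces) -> None:
    g.discard(Triple(ns.schema_iri("part"), RDF_TYPE, OWL_INVERSE_FUNCTIONAL))


def _m_k7(g: OntologyGraph, ns: Namespaces) -> None:
    g.discard(Triple(ns.schema_iri("typeForName"), RDF_TYPE, OWL_FUNCTIONAL))


def _m_k8(g: OntologyGraph, ns: Namespaces) -> None:
    register_extension_property(
        g, _ext("specimenTaxonLink", ["Specimen"], ["TaxonName"]), ns
    )
    register_extension_property(
        g,
        _ext("barTypeForName", ["Specimen"], ["TaxonName"], super="specimenTaxonLink"),
        ns,
    )
    g.add(Triple(ns.schema_iri("barTypeForName"), OWL_INVERSE_OF, ns.schema_iri("isBar")))


def _m_k9(g: OntologyGraph, ns: Namespaces) -> None:
    has_syn = ns.schema_iri("hasSynonym")
    g.discard(Triple(has_syn, OWL_INVERSE_OF, has_syn))
    register_extension_property(g, _ext("synonymOf", ["TaxonName"], ["TaxonName"]), ns)
    g.add(Triple(has_syn, OWL_INVERSE_OF, ns.schema_iri("synonymOf")))


def _m_k10(g: OntologyGraph, ns: Namespaces) -> None:
    register_extension_property(g, _ext("taxonLink", ["TaxonName"], ["TaxonName"]), ns)
    g.add(Triple(ns.schema_iri("hasSpecies"), RDFS_SUBPROPERTYOF, ns.schema_iri("taxonLink")))


def _m_k11(g: OntologyGraph, ns: Namespaces) -> None:
    g.discard(Triple(ns.schema_iri("hasSpecies"), RDF_TYPE, OWL_TRANSITIVE))


def _m_k12(g: OntologyGraph, ns: Namespaces) -> None:
    # an inverse whose domain/range are NOT swapped relative to isCitedIn
    p = ns.schema_iri("cites")
    g.declare(p, NodeKind.OBJECT_PROPERTY)
    g.add(Triple(p, RDFS_DOMAIN, ns.schema_iri("Specimen")))
    g.add(Triple(p, RDFS_RANGE, ns.schema_iri("PublicationCitation")))
    g.add(Triple(ns.schema_iri("isCitedIn"), OWL_INVERSE_OF, p))


_MUTANT_FNS: dict[str, tuple[str, Callable, frozenset]] = {
    "C1": ("cardinality restriction placed on transitive isBelong", _m_c1, frozenset({"C1"})),
    "C2": ("enumeration class listing the Specimen concept", _m_c2, frozenset({"C2"})),
    "C3": ("import of the OWL system ontology", _m_c3, frozenset({"C3"})),
    "C4": ("TaxonName concept asserted as an instance of Specimen", _m_c4, frozenset({"C4"})),
    "C5": ("rank given owl:Class as range", _m_c5, frozenset({"C5"})),
    "C6": ("Specimen subclassed under rdfs:Resource", _m_c6, frozenset({"C6"})),
    "C7": ("annotation property in a sub-property axiom", _m_c7, frozenset({"C7"})),
    # marking transitive isBelong functional also breaks K6, because its
    # declared inverse hasSpecies is then not inverse-functional
    "C8": ("transitive isBelong additionally marked functional", _m_c8, frozenset({"C8", "K6"})),
    "K1": ("object property declared without a domain", _m_k1, frozenset({"K1"})),
    "K2": ("definedTerm domain holding a class and its subclass", _m_k2, frozenset({"K2"})),
    "K3": ("isHaptorBar range holding a class and its subclass", _m_k3, frozenset({"K3"})),
    "K4": ("isBar domain widened beyond its super-property part", _m_k4, frozenset({"K4"})),
    "K5": ("isBar range widened beyond its super-property part", _m_k5, frozenset({"K5"})),
    "K6": ("inverse-functional characteristic removed from part", _m_k6, frozenset({"K6"})),
    "K7": ("functional characteristic removed from typeForName", _m_k7, frozenset({"K7"})),
    "K8": ("inverse of sub-property isBar not under inverse of part", _m_k8, frozenset({"K8"})),
    "K9": ("symmetric hasSynonym given a non-symmetric inverse", _m_k9, frozenset({"K9"})),
    "K10": ("hasSpecies demoted below a new top-level property", _m_k10, frozenset({"K10"})),
    "K11": ("transitive characteristic removed from hasSpecies", _m_k11, frozenset({"K11"})),
    "K12": ("inverse of isCitedIn declared with unswapped domain/range", _m_k12, frozenset({"K12"})),
}

MUTANTS: dict[str, MutantSpec] = {
    tid: MutantSpec(tid, desc, failures) for tid, (desc, _, failures) in _MUTANT_FNS.items()
}


def mutate(
    schema: OntologyGraph, spec: MutantSpec | str, ns: Namespaces = DEFAULT_NAMESPACES
) -> OntologyGraph:
    """Apply a registered minimal axiom edit; the input graph is untouched."""
    target = spec.target_test if isinstance(spec, MutantSpec) else spec
    if target not in _MUTANT_FNS:
        raise FixtureError(f"unknown mutant target {target!r}")
    mutated = schema.copy()
    _MUTANT_FNS[target][1](mutated, ns)
    return mutated


def reference_schema(ns: Namespaces = DEFAULT_NAMESPACES) -> OntologyGraph:
    """The graph the battery and all mutants are defined against."""
    return build_reference_schema(ns)
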