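"""Minimal triple-graph data model with OWL-vocabulary tagging.

The graph is a plain set of ``(subject, predicate, object)`` triples over
fully named IRIs — blank nodes are deliberately unsupported, because every
entity in the annotation scheme (concept classes, properties, specimen and
taxon individuals) carries a stable name.  Each IRI additionally carries a
*node kind* tag (concept class, object/datatype/annotation property, or
individual); kinds are mutually exclusive for one IRI, which underpins the
"no meta-class" style structural checks in :mod:`mhbi.validator`.

Serialization to Turtle and RDF/XML is delegated to :mod:`rdflib`; the
round-trip contract is triple-set identity, not byte identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Union

import rdflib
from rdflib.namespace import XSD as _RDFLIB_XSD


class GraphError(ValueError):
    """Structural problem in a triple or graph."""


class DeclarationError(GraphError):
    """Missing, conflicting, or duplicate node-kind declaration."""


class ParseError(GraphError):
    """A document could not be parsed into a well-formed graph."""


_ABSOLUTE_IRI = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:")


@dataclass(frozen=True, eq=False)
class IRI:
    """An absolute IRI split into a namespace base and a local name.

    Equality and hashing are defined on the concatenation, so two IRIs that
    split the same absolute IRI differently compare equal.
    """

    namespace: str
    local_name: str

    def __post_init__(self) -> None:
        if not _ABSOLUTE_IRI.match(self.namespace):
            raise GraphError(f"namespace is not an absolute IRI base: {self.namespace!r}")
        if not self.local_name or any(c.isspace() for c in self.local_name):
            raise GraphError(f"invalid local name: {self.local_name!r}")

    @property
    def full(self) -> str:
        return self.namespace + self.local_name

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IRI) and self.full == other.full

    def __hash__(self) -> int:
        return hash(self.full)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.full}>"


def iri_from_string(s: str) -> IRI:
    """Split an absolute IRI at the last ``#`` or ``/`` into an :class:`IRI`."""
    for sep in ("#", "/"):
        idx = s.rfind(sep)
        if 0 < idx < len(s) - 1:
            return IRI(s[: idx + 1], s[idx + 1 :])
    raise GraphError(f"cannot split IRI into namespace and local name: {s!r}")


@dataclass(frozen=True)
class Literal:
    """A literal value: plain text or an integer (bare values, as printed
    in the tabular annotation records)."""

    value: Union[str, int]

    def __post_init__(self) -> None:
        if isinstance(self.value, bool) or not isinstance(self.value, (str, int)):
            raise GraphError(f"unsupported literal value: {self.value!r}")

    @property
    def datatype(self) -> str:
        return "integer" if isinstance(self.value, int) else "string"


Node = Union[IRI, Literal]


@dataclass(frozen=True)
class Triple:
    subject: IRI
    predicate: IRI
    object: Node

    def __post_init__(self) -> None:
        if not isinstance(self.subject, IRI):
            raise GraphError(f"triple subject must be an IRI, got {self.subject!r}")
        if not isinstance(self.predicate, IRI):
            raise GraphError(f"triple predicate must be an IRI, got {self.predicate!r}")
        if not isinstance(self.object, (IRI, Literal)):
            raise GraphError(f"triple object must be an IRI or Literal, got {self.object!r}")


class NodeKind(Enum):
    CONCEPT_CLASS = "concept-class"
    OBJECT_PROPERTY = "object-property"
    DATATYPE_PROPERTY = "datatype-property"
    ANNOTATION_PROPERTY = "annotation-property"
    INDIVIDUAL = "individual"


PROPERTY_KINDS = frozenset(
    {NodeKind.OBJECT_PROPERTY, NodeKind.DATATYPE_PROPERTY, NodeKind.ANNOTATION_PROPERTY}
)

# Well-known vocabulary namespaces.
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

SYSTEM_NAMESPACES = (RDF_NS, RDFS_NS, OWL_NS, XSD_NS)


def _rdf(name: str) -> IRI:
    return IRI(RDF_NS, name)


def _rdfs(name: str) -> IRI:
    return IRI(RDFS_NS, name)


def _owl(name: str) -> IRI:
    return IRI(OWL_NS, name)


def _xsd(name: str) -> IRI:
    return IRI(XSD_NS, name)


RDF_TYPE = _rdf("type")
RDFS_DOMAIN = _rdfs("domain")
RDFS_RANGE = _rdfs("range")
RDFS_SUBCLASSOF = _rdfs("subClassOf")
RDFS_SUBPROPERTYOF = _rdfs("subPropertyOf")
RDFS_LABEL = _rdfs("label")
RDFS_CLASS = _rdfs("Class")
RDFS_RESOURCE = _rdfs("Resource")
OWL_CLASS = _owl("Class")
OWL_OBJECT_PROPERTY = _owl("ObjectProperty")
OWL_DATATYPE_PROPERTY = _owl("DatatypeProperty")
OWL_ANNOTATION_PROPERTY = _owl("AnnotationProperty")
OWL_NAMED_INDIVIDUAL = _owl("NamedIndividual")
OWL_INVERSE_OF = _owl("inverseOf")
OWL_FUNCTIONAL = _owl("FunctionalProperty")
OWL_INVERSE_FUNCTIONAL = _owl("InverseFunctionalProperty")
OWL_TRANSITIVE = _owl("TransitiveProperty")
OWL_SYMMETRIC = _owl("SymmetricProperty")
OWL_RESTRICTION = _owl("Restriction")
OWL_ON_PROPERTY = _owl("onProperty")
OWL_CARDINALITY = _owl("cardinality")
OWL_MIN_CARDINALITY = _owl("minCardinality")
OWL_MAX_CARDINALITY = _owl("maxCardinality")
OWL_ONE_OF = _owl("oneOf")
OWL_IMPORTS = _owl("imports")
OWL_ONTOLOGY = _owl("Ontology")
XSD_STRING = _xsd("string")
XSD_INTEGER = _xsd("integer")

CARDINALITY_PREDICATES = frozenset({OWL_CARDINALITY, OWL_MIN_CARDINALITY, OWL_MAX_CARDINALITY})

#: rdf:type objects that double as node-kind declarations.
KIND_FOR_TERM = {
    OWL_CLASS: NodeKind.CONCEPT_CLASS,
    OWL_OBJECT_PROPERTY: NodeKind.OBJECT_PROPERTY,
    OWL_DATATYPE_PROPERTY: NodeKind.DATATYPE_PROPERTY,
    OWL_ANNOTATION_PROPERTY: NodeKind.ANNOTATION_PROPERTY,
    OWL_NAMED_INDIVIDUAL: NodeKind.INDIVIDUAL,
}
TERM_FOR_KIND = {v: k for k, v in KIND_FOR_TERM.items()}


def is_builtin(iri: IRI) -> bool:
    return any(iri.full.startswith(ns) for ns in SYSTEM_NAMESPACES)


class OntologyGraph:
    """A set of triples plus node-kind declarations and import links.

    ``strict`` mode (the default) requires every predicate to be either a
    declared property or an RDF/RDFS/OWL built-in before a triple using it
    is accepted; lax mode is meant for third-party files.
    """

    def __init__(
        self,
        base_iri: str = "http://example.org/mhbi",
        strict: bool = True,
        prefixes: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.base_iri = base_iri
        self.strict = strict
        self.prefixes: dict[str, str] = dict(prefixes or {})
        self.triples: set[Triple] = set()
        self.declarations: dict[IRI, NodeKind] = {}
        self.imports: list[IRI] = []

    # -- declarations ---------------------------------------------------

    def declare(self, iri: IRI, kind: NodeKind) -> "OntologyGraph":
        existing = self.declarations.get(iri)
        if existing is not None and existing is not kind:
            raise DeclarationError(
                f"{iri.full} already declared as {existing.value}, cannot redeclare as {kind.value}"
            )
        self.declarations[iri] = kind
        self.triples.add(Triple(iri, RDF_TYPE, TERM_FOR_KIND[kind]))
        return self

    def retract_declaration(self, iri: IRI) -> None:
        kind = self.declarations.pop(iri, None)
        if kind is not None:
            self.triples.discard(Triple(iri, RDF_TYPE, TERM_FOR_KIND[kind]))

    def kind_of(self, iri: IRI) -> Optional[NodeKind]:
        return self.declarations.get(iri)

    def iris_of_kind(self, kind: NodeKind) -> set[IRI]:
        return {i for i, k in self.declarations.items() if k is kind}

    def is_declared_property(self, iri: IRI) -> bool:
        return self.declarations.get(iri) in PROPERTY_KINDS

    # -- triples --------------------------------------------------------

    def add(self, t: Triple) -> "OntologyGraph":
        if not isinstance(t, Triple):
            raise GraphError(f"expected a Triple, got {t!r}")
        if self.strict and not self.is_declared_property(t.predicate) and not is_builtin(t.predicate):
            raise DeclarationError(
                f"predicate {t.predicate.full} is not declared as a property (strict mode)"
            )
        if isinstance(t.object, Literal):
            pred_kind = self.declarations.get(t.predicate)
            if pred_kind is NodeKind.OBJECT_PROPERTY:
                raise GraphError(
                    f"literal object on object property {t.predicate.full}: {t.object.value!r}"
                )
        if t.predicate == RDF_TYPE and isinstance(t.object, IRI) and t.object in KIND_FOR_TERM:
            self.declare(t.subject, KIND_FOR_TERM[t.object])
            return self
        self.triples.add(t)
        return self

    def add_all(self, triples: Iterable[Triple]) -> "OntologyGraph":
        for t in triples:
            self.add(t)
        return self

    def discard(self, t: Triple) -> None:
        if t.predicate == RDF_TYPE and isinstance(t.object, IRI) and t.object in KIND_FOR_TERM:
            if self.declarations.get(t.subject) is KIND_FOR_TERM[t.object]:
                del self.declarations[t.subject]
        self.triples.discard(t)

    def has(self, s: IRI, p: IRI, o: Node) -> bool:
        return Triple(s, p, o) in self.triples

    def match(
        self,
        subject: Optional[IRI] = None,
        predicate: Optional[IRI] = None,
        object: Optional[Node] = None,
    ) -> set[Triple]:
        """Return the triples unifying with a pattern; ``None`` is a wildcard."""
        return {
            t
            for t in self.triples
            if (subject is None or t.subject == subject)
            and (predicate is None or t.predicate == predicate)
            and (object is None or t.object == object)
        }

    def objects(self, subject: IRI, predicate: IRI) -> set[Node]:
        return {t.object for t in self.triples if t.subject == subject and t.predicate == predicate}

    def subjects(self, predicate: IRI, object: Node) -> set[IRI]:
        return {t.subject for t in self.triples if t.predicate == predicate and t.object == object}

    # -- imports --------------------------------------------------------

    def ontology_node(self) -> IRI:
        return iri_from_string(self.base_iri)

    def add_import(self, target: IRI) -> "OntologyGraph":
        if target not in self.imports:
            self.imports.append(target)
        self.triples.add(Triple(self.ontology_node(), OWL_IMPORTS, target))
        return self

    # -- misc -----------------------------------------------------------

    def copy(self) -> "OntologyGraph":
        g = OntologyGraph(self.base_iri, self.strict, self.prefixes)
        g.triples = set(self.triples)
        g.declarations = dict(self.declarations)
        g.imports = list(self.imports)
        return g

    def same_triples(self, other: "OntologyGraph") -> bool:
        return self.triples == other.triples

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def __contains__(self, t: Triple) -> bool:
        return t in self.triples

    # -- serialization --------------------------------------------------

    _FORMATS = {"turtle": "turtle", "rdfxml": "xml"}

    def serialize(self, format: str = "turtle") -> str:
        if format not in self._FORMATS:
            raise GraphError(f"unsupported format {format!r}; expected one of {sorted(self._FORMATS)}")
        rg = rdflib.Graph()
        for prefix, ns in self.prefixes.items():
            rg.bind(prefix, rdflib.Namespace(ns))
        for t in sorted(self.triples, key=_triple_sort_key):
            rg.add((_to_rdflib(t.subject), _to_rdflib(t.predicate), _to_rdflib(t.object)))
        return rg.serialize(format=self._FORMATS[format])

    @classmethod
    def parse(
        cls,
        text: str,
        format: str = "turtle",
        base_iri: str = "http://example.org/mhbi",
        strict: bool = False,
        prefixes: Optional[Mapping[str, str]] = None,
    ) -> "OntologyGraph":
        if format not in cls._FORMATS:
            raise GraphError(f"unsupported format {format!r}; expected one of {sorted(cls._FORMATS)}")
        rg = rdflib.Graph()
        try:
            rg.parse(data=text, format=cls._FORMATS[format])
        except Exception as exc:  # rdflib raises format-specific subclasses
            raise ParseError(f"malformed {format} document: {exc}") from exc
        g = cls(base_iri=base_iri, strict=False, prefixes=prefixes)
        pending: list[Triple] = []
        for s, p, o in rg:
            if isinstance(s, rdflib.BNode) or isinstance(o, rdflib.BNode):
                raise ParseError("blank nodes are not supported in this graph model")
            pending.append(Triple(_from_rdflib(s), _from_rdflib(p), _from_rdflib(o)))
        # First pass: declarations, so strict re-checking has them available.
        for t in pending:
            if t.predicate == RDF_TYPE and isinstance(t.object, IRI) and t.object in KIND_FOR_TERM:
                g.declare(t.subject, KIND_FOR_TERM[t.object])
        for t in pending:
            g.add(t)
            if t.predicate == OWL_IMPORTS and isinstance(t.object, IRI) and t.object not in g.imports:
                g.imports.append(t.object)
        g.strict = strict
        if strict:
            for t in g.triples:
                if not g.is_declared_property(t.predicate) and not is_builtin(t.predicate):
                    raise DeclarationError(
                        f"predicate {t.predicate.full} is not declared as a property (strict mode)"
                    )
        return g


def _triple_sort_key(t: Triple) -> tuple:
    o = t.object
    okey = o.full if isinstance(o, IRI) else f"\x00{o.value}"
    return (t.subject.full, t.predicate.full, okey)


def _to_rdflib(node: Node) -> Union[rdflib.URIRef, rdflib.Literal]:
    if isinstance(node, IRI):
        return rdflib.URIRef(node.full)
    if node.datatype == "integer":
        return rdflib.Literal(node.value, datatype=_RDFLIB_XSD.integer)
    return rdflib.Literal(node.value)


def _from_rdflib(node) -> Node:
    if isinstance(node, rdflib.URIRef):
        return iri_from_string(str(node))
    if isinstance(node, rdflib.Literal):
        if node.datatype in (_RDFLIB_XSD.integer, _RDFLIB_XSD.int, _RDFLIB_XSD.long):
            return Literal(int(node))
        return Literal(str(node))
    raise ParseError(f"unsupported RDF node: {node!r}")


def add_triple(graph: OntologyGraph, t: Triple) -> OntologyGraph:
    """Functional-style alias for :meth:`OntologyGraph.add`."""
    return graph.add(t)


def match(graph: OntologyGraph, pattern: tuple) -> set[Triple]:
    """Triple-pattern query; pattern entries of ``None`` are wildcards."""
    s, p, o = pattern
    return graph.match(s, p, o)
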