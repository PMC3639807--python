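"""Structural quality battery: 8 clarity tests and 12 coherence tests.

The battery follows the Gruber-style clarity/coherence evaluation as run in
Protégé-era ontology test suites: clarity tests guard against constructs that
blur the interpretation of a term (meta-classes, enumerations over schema
terms, system-ontology imports, functional transitive properties, ...);
coherence tests check that the property axioms are mutually consistent
(non-empty and non-redundant domains, sub-properties narrowing their super,
inverse pairs agreeing on functionality, symmetry, transitivity, hierarchy
level, and swapped domain/range).

All checks are over asserted axioms only — the asserted subclass and
sub-property transitive closures, no reasoner — and validation never mutates
the graph.  Every run yields exactly 8 + 12 results; a test passes iff its
violation list is empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .graph import (
    IRI,
    NodeKind,
    OntologyGraph,
    PROPERTY_KINDS,
    CARDINALITY_PREDICATES,
    OWL_CLASS,
    OWL_INVERSE_OF,
    OWL_FUNCTIONAL,
    OWL_INVERSE_FUNCTIONAL,
    OWL_ON_PROPERTY,
    OWL_ONE_OF,
    OWL_SYMMETRIC,
    OWL_TRANSITIVE,
    OWL_IMPORTS,
    RDF_NS,
    RDFS_NS,
    OWL_NS,
    XSD_NS,
    RDF_TYPE,
    RDFS_CLASS,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDFS_SUBPROPERTYOF,
)

CLARITY_NAMES = (
    "No Cardinality Restriction on Transitive Properties",
    "No Classes or Properties in Enumerations",
    "No Import of System Ontologies",
    "No Meta-Class",
    "No Properties with Class as Range",
    "No Sub Classes of RDF Classes",
    "No Super or Sub Properties of Annotation Properties",
    "Transitive Properties cannot be Functional",
)

COHERENCE_NAMES = (
    "Domain of a Property should not be empty",
    "Domain of a Property should not contain redundant Classes",
    "Range of a Property should not contain redundant Classes",
    "Domain of a Sub Property can only narrow Super Property",
    "Range of a Sub Property can only narrow Super Property",
    "Inverse of Functional must be Inverse Functional",
    "Inverse of Inverse Functional must be Functional",
    "Inverse of Sub Property must be Subproperty of Inverse of Super Property",
    "Inverse of Symmetric Property must be Symmetric Property",
    "Inverse of Top Level Property must be Top Level Property",
    "Inverse of Transitive Property must be Transitive Property",
    "Inverse Property must have matching Range and Domain",
)

CLARITY_IDS = tuple(f"C{i}" for i in range(1, 9))
COHERENCE_IDS = tuple(f"K{i}" for i in range(1, 13))
ALL_TEST_IDS = CLARITY_IDS + COHERENCE_IDS

_SYSTEM_NS_BASES = (RDF_NS, RDFS_NS, OWL_NS, XSD_NS)
_META_CLASS_TERMS = (RDFS_CLASS, OWL_CLASS)


@dataclass(frozen=True)
class Violation:
    subject: str
    explanation: str

    def as_tuple(self) -> tuple[str, str]:
        return (self.subject, self.explanation)


@dataclass(frozen=True)
class TestResult:
    test_id: str
    name: str
    violations: tuple[Violation, ...]

    @property
    def passed(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class ValidationReport:
    clarity: tuple[TestResult, ...]
    coherence: tuple[TestResult, ...]
    lenient: tuple[str, ...] = ()

    @property
    def results(self) -> tuple[TestResult, ...]:
        return self.clarity + self.coherence

    @property
    def failed_ids(self) -> tuple[str, ...]:
        return tuple(r.test_id for r in self.results if not r.passed)

    @property
    def overall_pass(self) -> bool:
        return all(r.passed or r.test_id in self.lenient for r in self.results)

    def result(self, test_id: str) -> TestResult:
        for r in self.results:
            if r.test_id == test_id:
                return r
        raise KeyError(test_id)


# -- axiom views ---------------------------------------------------------


class _Axioms:
    """Read-only views of the axioms the tests consult."""

    def __init__(self, graph: OntologyGraph):
        self.graph = graph
        self.classes = graph.iris_of_kind(NodeKind.CONCEPT_CLASS)
        self.properties = {
            i: k for i, k in graph.declarations.items() if k in PROPERTY_KINDS
        }
        self.annotation_props = {
            i for i, k in self.properties.items() if k is NodeKind.ANNOTATION_PROPERTY
        }
        self.regular_props = sorted(
            (i for i, k in self.properties.items() if k is not NodeKind.ANNOTATION_PROPERTY),
            key=lambda i: i.full,
        )
        self.subclass_ancestors = _transitive(
            (t.subject, t.object)
            for t in graph.match(None, RDFS_SUBCLASSOF, None)
            if isinstance(t.object, IRI)
        )
        self.subprop_pairs = [
            (t.subject, t.object)
            for t in graph.match(None, RDFS_SUBPROPERTYOF, None)
            if isinstance(t.object, IRI)
        ]
        self.subprop_ancestors = _transitive(self.subprop_pairs)
        self.inverses: dict[IRI, set[IRI]] = {}
        for t in graph.match(None, OWL_INVERSE_OF, None):
            if isinstance(t.object, IRI):
                self.inverses.setdefault(t.subject, set()).add(t.object)
                self.inverses.setdefault(t.object, set()).add(t.subject)

    def characteristics(self, p: IRI) -> set[IRI]:
        return {
            t.object
            for t in self.graph.match(p, RDF_TYPE, None)
            if isinstance(t.object, IRI)
        }

    def domains(self, p: IRI) -> set[IRI]:
        return {o for o in self.graph.objects(p, RDFS_DOMAIN) if isinstance(o, IRI)}

    def ranges(self, p: IRI) -> set[IRI]:
        return {o for o in self.graph.objects(p, RDFS_RANGE) if isinstance(o, IRI)}

    def is_subclass_of(self, sub: IRI, sup: IRI) -> bool:
        return sub == sup or sup in self.subclass_ancestors.get(sub, ())

    def is_subprop_of(self, sub: IRI, sup: IRI) -> bool:
        return sub == sup or sup in self.subprop_ancestors.get(sub, ())

    def top_level(self, p: IRI) -> bool:
        return not any(s == p for s, _ in self.subprop_pairs)


def _transitive(pairs: Iterable[tuple[IRI, IRI]]) -> dict[IRI, set[IRI]]:
    direct: dict[IRI, set[IRI]] = {}
    for a, b in pairs:
        direct.setdefault(a, set()).add(b)
    closure: dict[IRI, set[IRI]] = {}

    def ancestors(node: IRI, seen: set[IRI]) -> set[IRI]:
        if node in closure:
            return closure[node]
        out: set[IRI] = set()
        for parent in direct.get(node, ()):
            if parent in seen:
                continue
            out.add(parent)
            out |= ancestors(parent, seen | {parent})
        closure[node] = out
        return out

    for node in list(direct):
        ancestors(node, {node})
    return closure


# -- clarity tests -------------------------------------------------------


def _c1(ax: _Axioms) -> list[Violation]:
    out = []
    for t in sorted(ax.graph.match(None, OWL_ON_PROPERTY, None), key=lambda t: t.subject.full):
        if not isinstance(t.object, IRI) or OWL_TRANSITIVE not in ax.characteristics(t.object):
            continue
        if any(ax.graph.match(t.subject, pred, None) for pred in CARDINALITY_PREDICATES):
            out.append(
                Violation(t.object.full, "cardinality restriction constrains a transitive property")
            )
    return out


def _c2(ax: _Axioms) -> list[Violation]:
    out = []
    for t in sorted(ax.graph.match(None, OWL_ONE_OF, None), key=lambda t: t.subject.full):
        if isinstance(t.object, IRI) and (t.object in ax.classes or t.object in ax.properties):
            out.append(Violation(t.object.full, "enumeration contains a class or property term"))
    return out


def _c3(ax: _Axioms) -> list[Violation]:
    targets = list(ax.graph.imports)
    for t in ax.graph.match(None, OWL_IMPORTS, None):
        if isinstance(t.object, IRI) and t.object not in targets:
            targets.append(t.object)
    out = []
    for target in targets:
        if any(target.full.startswith(ns.rstrip("#/")) for ns in _SYSTEM_NS_BASES):
            out.append(Violation(target.full, "imports a system (RDF/RDFS/OWL/XSD) ontology"))
    return out


def _c4(ax: _Axioms) -> list[Violation]:
    out = []
    for t in sorted(ax.graph.match(None, RDF_TYPE, None), key=lambda t: t.subject.full):
        if t.subject in ax.classes and isinstance(t.object, IRI) and t.object in ax.classes:
            out.append(
                Violation(t.subject.full, f"declared class is an instance of class {t.object.full}")
            )
    return out


def _c5(ax: _Axioms) -> list[Violation]:
    out = []
    for p in ax.regular_props:
        for r in sorted(ax.ranges(p), key=lambda i: i.full):
            if r in _META_CLASS_TERMS:
                out.append(Violation(p.full, f"range is the meta-level class term {r.full}"))
    return out


def _c6(ax: _Axioms) -> list[Violation]:
    out = []
    for t in sorted(ax.graph.match(None, RDFS_SUBCLASSOF, None), key=lambda t: t.subject.full):
        if (
            t.subject in ax.classes
            and isinstance(t.object, IRI)
            and (t.object.full.startswith(RDF_NS) or t.object.full.startswith(RDFS_NS))
        ):
            out.append(Violation(t.subject.full, f"subclass of built-in class {t.object.full}"))
    return out


def _c7(ax: _Axioms) -> list[Violation]:
    out = []
    for sub, sup in sorted(ax.subprop_pairs, key=lambda p: (p[0].full, p[1].full)):
        for side in (sub, sup):
            if side in ax.annotation_props:
                out.append(
                    Violation(side.full, "annotation property occurs in a sub/super-property axiom")
                )
    return out


def _c8(ax: _Axioms) -> list[Violation]:
    out = []
    for p in ax.regular_props:
        ch = ax.characteristics(p)
        if OWL_TRANSITIVE in ch and OWL_FUNCTIONAL in ch:
            out.append(Violation(p.full, "property is both transitive and functional"))
    return out


# -- coherence tests -----------------------------------------------------


def _k1(ax: _Axioms) -> list[Violation]:
    return [
        Violation(p.full, "property has no declared domain")
        for p in ax.regular_props
        if not ax.domains(p)
    ]


def _redundant(ax: _Axioms, getter, what: str) -> list[Violation]:
    out = []
    for p in ax.regular_props:
        values = sorted(getter(p), key=lambda i: i.full)
        for a in values:
            for b in values:
                if a != b and a in ax.classes and b in ax.classes and ax.is_subclass_of(a, b):
                    out.append(
                        Violation(p.full, f"{what} contains {b.full} and its subclass {a.full}")
                    )
    return out


def _k2(ax: _Axioms) -> list[Violation]:
    return _redundant(ax, ax.domains, "domain")


def _k3(ax: _Axioms) -> list[Violation]:
    return _redundant(ax, ax.ranges, "range")


def _narrowing(ax: _Axioms, getter, what: str) -> list[Violation]:
    out = []
    for sub, sup in sorted(ax.subprop_pairs, key=lambda p: (p[0].full, p[1].full)):
        if sub in ax.annotation_props or sup in ax.annotation_props:
            continue
        sup_values = getter(sup)
        if not sup_values:
            continue
        for v in sorted(getter(sub), key=lambda i: i.full):
            if not any(ax.is_subclass_of(v, sv) for sv in sup_values):
                out.append(
                    Violation(
                        sub.full,
                        f"{what} {v.full} does not narrow super-property {sup.full}",
                    )
                )
    return out


def _k4(ax: _Axioms) -> list[Violation]:
    return _narrowing(ax, ax.domains, "domain")


def _k5(ax: _Axioms) -> list[Violation]:
    return _narrowing(ax, ax.ranges, "range")


def _k6(ax: _Axioms) -> list[Violation]:
    out = []
    for p in ax.regular_props:
        if OWL_FUNCTIONAL not in ax.characteristics(p):
            continue
        for q in sorted(ax.inverses.get(p, ()), key=lambda i: i.full):
            if OWL_INVERSE_FUNCTIONAL not in ax.characteristics(q):
                out.append(
                    Violation(q.full, f"inverse of functional {p.full} is not inverse-functional")
                )
    return out


def _k7(ax: _Axioms) -> list[Violation]:
    out = []
    for p in ax.regular_props:
        if OWL_INVERSE_FUNCTIONAL not in ax.characteristics(p):
            continue
        for q in sorted(ax.inverses.get(p, ()), key=lambda i: i.full):
            if OWL_FUNCTIONAL not in ax.characteristics(q):
                out.append(
                    Violation(q.full, f"inverse of inverse-functional {p.full} is not functional")
                )
    return out


def _k8(ax: _Axioms) -> list[Violation]:
    out = []
    for sub, sup in sorted(ax.subprop_pairs, key=lambda p: (p[0].full, p[1].full)):
        if sub in ax.annotation_props or sup in ax.annotation_props:
            continue
        for q in sorted(ax.inverses.get(sub, ()), key=lambda i: i.full):
            sup_inverses = ax.inverses.get(sup, set())
            if not sup_inverses:
                continue
            if not any(ax.is_subprop_of(q, qs) for qs in sup_inverses):
                out.append(
                    Violation(
                        q.full,
                        f"inverse of sub-property {sub.full} is not a sub-property of the "
                        f"inverse of {sup.full}",
                    )
                )
    return out


def _k9(ax: _Axioms) -> list[Violation]:
    out = []
    for p in ax.regular_props:
        if OWL_SYMMETRIC not in ax.characteristics(p):
            continue
        for q in sorted(ax.inverses.get(p, ()), key=lambda i: i.full):
            if OWL_SYMMETRIC not in ax.characteristics(q):
                out.append(Violation(q.full, f"inverse of symmetric {p.full} is not symmetric"))
    return out


def _k10(ax: _Axioms) -> list[Violation]:
    out = []
    for p in ax.regular_props:
        if not ax.top_level(p):
            continue
        for q in sorted(ax.inverses.get(p, ()), key=lambda i: i.full):
            if not ax.top_level(q):
                out.append(
                    Violation(q.full, f"inverse of top-level {p.full} has a super-property")
                )
    return out


def _k11(ax: _Axioms) -> list[Violation]:
    out = []
    for p in ax.regular_props:
        if OWL_TRANSITIVE not in ax.characteristics(p):
            continue
        for q in sorted(ax.inverses.get(p, ()), key=lambda i: i.full):
            if OWL_TRANSITIVE not in ax.characteristics(q):
                out.append(Violation(q.full, f"inverse of transitive {p.full} is not transitive"))
    return out


def _k12(ax: _Axioms) -> list[Violation]:
    out = []
    seen: set[frozenset] = set()
    for p in ax.regular_props:
        for q in sorted(ax.inverses.get(p, ()), key=lambda i: i.full):
            pair = frozenset((p, q))
            if pair in seen:
                continue
            seen.add(pair)
            if ax.domains(p) != ax.ranges(q) or ax.ranges(p) != ax.domains(q):
                out.append(
                    Violation(
                        p.full,
                        f"inverse pair {p.full} / {q.full} does not have swapped domain and range",
                    )
                )
    return out


_CLARITY_FNS = (_c1, _c2, _c3, _c4, _c5, _c6, _c7, _c8)
_COHERENCE_FNS = (_k1, _k2, _k3, _k4, _k5, _k6, _k7, _k8, _k9, _k10, _k11, _k12)


def run_clarity(graph: OntologyGraph) -> tuple[TestResult, ...]:
    ax = _Axioms(graph)
    return tuple(
        TestResult(tid, name, tuple(fn(ax)))
        for tid, name, fn in zip(CLARITY_IDS, CLARITY_NAMES, _CLARITY_FNS)
    )


def run_coherence(graph: OntologyGraph) -> tuple[TestResult, ...]:
    ax = _Axioms(graph)
    return tuple(
        TestResult(tid, name, tuple(fn(ax)))
        for tid, name, fn in zip(COHERENCE_IDS, COHERENCE_NAMES, _COHERENCE_FNS)
    )


def validate(graph: OntologyGraph, lenient: Sequence[str] = ()) -> ValidationReport:
    """Run the full 20-test battery.  ``lenient`` names tests whose failures
    are reported but do not affect ``overall_pass`` (for third-party files)."""
    unknown = set(lenient) - set(ALL_TEST_IDS)
    if unknown:
        raise ValueError(f"unknown test ids in lenient list: {sorted(unknown)}")
    return ValidationReport(run_clarity(graph), run_coherence(graph), tuple(lenient))


def report(results: ValidationReport, format: str = "json") -> str:
    """Render a report with stable field order; json or text."""
    if format == "json":
        payload = {
            "overall_pass": results.overall_pass,
            "lenient": list(results.lenient),
            "tests": [
                {
                    "id": r.test_id,
                    "name": r.name,
                    "passed": r.passed,
                    "violations": [list(v.as_tuple()) for v in r.violations],
                }
                for r in results.results
            ],
        }
        return json.dumps(payload, indent=2)
    if format == "text":
        lines = []
        for section, rs in (("Clarity", results.clarity), ("Coherence", results.coherence)):
            lines.append(f"{section}:")
            for r in rs:
                status = "PASS" if r.passed else "FAIL"
                if not r.passed and r.test_id in results.lenient:
                    status = "FAIL (lenient)"
                lines.append(f"  [{status}] {r.test_id}: {r.name}")
                for v in r.violations:
                    lines.append(f"      - {v.subject}: {v.explanation}")
        lines.append(f"Overall: {'PASS' if results.overall_pass else 'FAIL'}")
        return "\n".join(lines)
    raise ValueError(f"unknown report format {format!r}")
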