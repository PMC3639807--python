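"""Materialization of entailments licensed by OWL property characteristics.

Three rules are supported, matching the characteristics the vocabulary
actually asserts:

* transitive — ``(a P b), (b P c) ⊢ (a P c)`` (e.g. ``isBelong`` up the
  taxonomic classification);
* symmetric — ``(a P b) ⊢ (b P a)`` (e.g. ``hasSynonym``);
* inverse — ``(a P b) ⊢ (b Q a)`` for a declared inverse pair (e.g.
  ``typeForName``/``part``, ``isBelong``/``hasSpecies``).

Inferred triples are kept separate from asserted ones, each tagged with the
rule that produced it; :func:`fold` merges them in explicitly.  Closure
terminates on cyclic input (taxonomically impossible but input-possible);
cycles are reported as diagnostics rather than errors, since validation is a
separate concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .graph import (
    IRI,
    OntologyGraph,
    OWL_INVERSE_OF,
    OWL_FUNCTIONAL,
    OWL_INVERSE_FUNCTIONAL,
    OWL_SYMMETRIC,
    OWL_TRANSITIVE,
    RDF_TYPE,
    Triple,
)


class InferenceUsageError(ValueError):
    """A rule was requested for a property lacking the licensing characteristic."""


@dataclass
class EntailmentSet:
    """Inferred triples with per-triple rule provenance; disjoint from the
    asserted triples of the graph they were computed over."""

    inferred: set[Triple] = field(default_factory=set)
    provenance: dict[Triple, str] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    def _absorb(self, other: "EntailmentSet") -> None:
        for t in other.inferred:
            if t not in self.inferred:
                self.inferred.add(t)
                self.provenance[t] = other.provenance[t]
        self.diagnostics.extend(other.diagnostics)

    def __len__(self) -> int:
        return len(self.inferred)


def _has_characteristic(graph: OntologyGraph, prop: IRI, term: IRI) -> bool:
    return graph.has(prop, RDF_TYPE, term)


def _object_edges(graph: OntologyGraph, prop: IRI) -> list[tuple[IRI, IRI]]:
    return [
        (t.subject, t.object)
        for t in graph.match(None, prop, None)
        if isinstance(t.object, IRI)
    ]


def transitive_closure(graph: OntologyGraph, prop: IRI) -> EntailmentSet:
    """Triples in the transitive closure of ``prop`` that are not asserted."""
    if not _has_characteristic(graph, prop, OWL_TRANSITIVE):
        raise InferenceUsageError(f"{prop.full} does not carry the transitive characteristic")
    edges = _object_edges(graph, prop)
    ent = EntailmentSet()
    if not edges:
        return ent
    dg = nx.DiGraph(edges)
    cyclic_nodes: set[IRI] = set()
    for scc in nx.strongly_connected_components(dg):
        if len(scc) > 1 or any(dg.has_edge(n, n) for n in scc):
            cyclic_nodes |= scc
            names = sorted(n.full for n in scc)
            ent.diagnostics.append(f"cycle under {prop.full}: {', '.join(names)}")
    asserted = set(edges)
    for node in dg.nodes:
        reachable = set(nx.descendants(dg, node))
        if node in cyclic_nodes:  # self-reachable via a path of length >= 1
            reachable.add(node)
        for target in reachable:
            if (node, target) not in asserted:
                t = Triple(node, prop, target)
                ent.inferred.add(t)
                ent.provenance[t] = "transitive"
    return ent


def materialize_symmetric(graph: OntologyGraph, prop: IRI) -> EntailmentSet:
    if not _has_characteristic(graph, prop, OWL_SYMMETRIC):
        raise InferenceUsageError(f"{prop.full} does not carry the symmetric characteristic")
    ent = EntailmentSet()
    asserted = set(_object_edges(graph, prop))
    for a, b in asserted:
        if a != b and (b, a) not in asserted:
            t = Triple(b, prop, a)
            ent.inferred.add(t)
            ent.provenance[t] = "symmetric"
    return ent


def declared_inverse(graph: OntologyGraph, prop: IRI) -> Optional[IRI]:
    for t in graph.match(prop, OWL_INVERSE_OF, None):
        if isinstance(t.object, IRI):
            return t.object
    for s in graph.subjects(OWL_INVERSE_OF, prop):
        return s
    return None


def materialize_inverse(graph: OntologyGraph, property_pair: tuple[IRI, IRI]) -> EntailmentSet:
    p, q = property_pair
    if not (graph.has(p, OWL_INVERSE_OF, q) or graph.has(q, OWL_INVERSE_OF, p)):
        raise InferenceUsageError(f"{p.full} and {q.full} are not a declared inverse pair")
    ent = EntailmentSet()
    p_edges = set(_object_edges(graph, p))
    q_edges = set(_object_edges(graph, q))
    for forward, backward, fwd_edges, bwd_edges in ((p, q, p_edges, q_edges), (q, p, q_edges, p_edges)):
        for a, b in fwd_edges:
            if (b, a) not in bwd_edges:
                t = Triple(b, backward, a)
                if t not in ent.inferred:
                    ent.inferred.add(t)
                    ent.provenance[t] = "inverse"
    return ent


def check_functional_violations(graph: OntologyGraph, prop: IRI) -> list[tuple[IRI, list]]:
    """Subjects with >= 2 objects under a functional property, and objects
    with >= 2 subjects under an inverse-functional one."""
    functional = _has_characteristic(graph, prop, OWL_FUNCTIONAL)
    inverse_functional = _has_characteristic(graph, prop, OWL_INVERSE_FUNCTIONAL)
    if not (functional or inverse_functional):
        raise InferenceUsageError(
            f"{prop.full} is neither functional nor inverse-functional"
        )
    violations: list[tuple[IRI, list]] = []
    triples = graph.match(None, prop, None)
    if functional:
        by_subject: dict[IRI, set] = {}
        for t in triples:
            by_subject.setdefault(t.subject, set()).add(t.object)
        for s, values in sorted(by_subject.items(), key=lambda kv: kv[0].full):
            if len(values) > 1:
                violations.append((s, sorted(values, key=_node_key)))
    if inverse_functional:
        by_object: dict = {}
        for t in triples:
            if isinstance(t.object, IRI):
                by_object.setdefault(t.object, set()).add(t.subject)
        for o, subjects in sorted(by_object.items(), key=lambda kv: kv[0].full):
            if len(subjects) > 1:
                violations.append((o, sorted(subjects, key=_node_key)))
    return violations


def _node_key(n) -> str:
    return n.full if isinstance(n, IRI) else str(n.value)


def materialize_all(graph: OntologyGraph, properties: Sequence[IRI]) -> EntailmentSet:
    """Apply every applicable rule for the given properties to fixpoint.

    The working graph grows with each round's inferences so that, e.g., the
    inverse rule fires on closure-derived triples; the returned set is
    relative to the original asserted triples.
    """
    work = graph.copy()
    total = EntailmentSet()
    props = list(properties)
    while True:
        round_new = EntailmentSet()
        for p in props:
            if _has_characteristic(work, p, OWL_TRANSITIVE):
                round_new._absorb(transitive_closure(work, p))
            if _has_characteristic(work, p, OWL_SYMMETRIC):
                round_new._absorb(materialize_symmetric(work, p))
            q = declared_inverse(work, p)
            if q is not None:
                round_new._absorb(materialize_inverse(work, (p, q)))
        fresh = round_new.inferred - work.triples
        if not fresh:
            total.diagnostics.extend(d for d in round_new.diagnostics if d not in total.diagnostics)
            break
        for t in fresh:
            work.triples.add(t)
            if t not in total.inferred:
                total.inferred.add(t)
                total.provenance[t] = round_new.provenance[t]
        total.diagnostics.extend(d for d in round_new.diagnostics if d not in total.diagnostics)
    return total


def fold(graph: OntologyGraph, entailments: EntailmentSet) -> OntologyGraph:
    """Return a copy of the graph with the inferred triples asserted."""
    out = graph.copy()
    out.add_all(entailments.inferred)
    return out
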