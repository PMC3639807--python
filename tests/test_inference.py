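"""Entailment materialization vs independent brute-force oracles."""

import itertools
import random

import numpy as np
import pytest

from mhbi.graph import (
    IRI,
    NodeKind,
    OntologyGraph,
    OWL_INVERSE_OF,
    OWL_SYMMETRIC,
    OWL_TRANSITIVE,
    RDF_TYPE,
    Triple,
)
from mhbi.inference import (
    EntailmentSet,
    InferenceUsageError,
    check_functional_violations,
    fold,
    materialize_all,
    materialize_inverse,
    materialize_symmetric,
    transitive_closure,
)

NS = "http://example.org/i#"


def _prop_graph(characteristic=None, name="rel"):
    g = OntologyGraph(base_iri="http://example.org/i")
    p = IRI(NS, name)
    g.declare(p, NodeKind.OBJECT_PROPERTY)
    if characteristic is not None:
        g.add(Triple(p, RDF_TYPE, characteristic))
    return g, p


def _edges(n_nodes, density, rng, acyclic=True):
    nodes = [IRI(NS, f"n{i}") for i in range(n_nodes)]
    edges = []
    for i, j in itertools.permutations(range(n_nodes), 2):
        if acyclic and i >= j:
            continue
        if rng.random() < density:
            edges.append((nodes[i], nodes[j]))
    return nodes, edges


def _warshall_oracle(nodes, edges):
    """Reachability with path length >= 1 via boolean matrix powers."""
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[index[a], index[b]] = True
    reach = adj.copy()
    power = adj.copy()
    for _ in range(n):
        power = power @ adj
        reach |= power
    return {
        (nodes[i], nodes[j]) for i in range(n) for j in range(n) if reach[i, j]
    }


class TestTransitiveClosure:
    def test_worked_chain(self, worked_graph, ns):
        is_belong = ns.schema_iri("isBelong")
        ent = transitive_closure(worked_graph, is_belong)
        ind = ns.instance_iri
        assert Triple(ind("BifBaungi"), is_belong, ind("Ancylodiscoididae")) in ent.inferred
        assert ent.inferred == {
            Triple(ind("BifBaungi"), is_belong, ind("Ancylodiscoididae")),
            Triple(ind("BifBaungi"), is_belong, ind("Dactylogyridea")),
            Triple(ind("Bifurcohaptor"), is_belong, ind("Dactylogyridea")),
        }
        assert all(tag == "transitive" for tag in ent.provenance.values())

    def test_single_triple_infers_nothing(self):
        g, p = _prop_graph(OWL_TRANSITIVE)
        g.add(Triple(IRI(NS, "a"), p, IRI(NS, "b")))
        assert transitive_closure(g, p).inferred == set()

    def test_requires_transitive_characteristic(self):
        g, p = _prop_graph()
        with pytest.raises(InferenceUsageError):
            transitive_closure(g, p)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_dag_matches_matrix_oracle(self, seed):
        rng = random.Random(seed)
        g, p = _prop_graph(OWL_TRANSITIVE)
        nodes, edges = _edges(25, 0.12, rng)
        for a, b in edges:
            g.add(Triple(a, p, b))
        ent = transitive_closure(g, p)
        expected = _warshall_oracle(nodes, edges) - set(edges)
        assert {(t.subject, t.object) for t in ent.inferred} == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_cyclic_graph_matches_oracle_and_is_flagged(self, seed):
        rng = random.Random(100 + seed)
        g, p = _prop_graph(OWL_TRANSITIVE)
        nodes, edges = _edges(10, 0.25, rng, acyclic=False)
        if not edges:
            pytest.skip("degenerate draw")
        for a, b in edges:
            g.add(Triple(a, p, b))
        ent = transitive_closure(g, p)
        expected = _warshall_oracle(nodes, edges) - set(edges)
        assert {(t.subject, t.object) for t in ent.inferred} == expected

    def test_explicit_cycle_is_diagnosed(self):
        g, p = _prop_graph(OWL_TRANSITIVE)
        a, b = IRI(NS, "a"), IRI(NS, "b")
        g.add(Triple(a, p, b))
        g.add(Triple(b, p, a))
        ent = transitive_closure(g, p)
        assert any("cycle" in d for d in ent.diagnostics)
        assert Triple(a, p, a) in ent.inferred


class TestSymmetric:
    def test_worked_synonym_pair(self, worked_graph, ns):
        has_syn = ns.schema_iri("hasSynonym")
        ent = materialize_symmetric(worked_graph, has_syn)
        assert ent.inferred == {
            Triple(ns.instance_iri("SiloGharui"), has_syn, ns.instance_iri("BycGharui"))
        }

    def test_self_loop_infers_nothing(self):
        g, p = _prop_graph(OWL_SYMMETRIC)
        a = IRI(NS, "a")
        g.add(Triple(a, p, a))
        assert materialize_symmetric(g, p).inferred == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_completion_matches_unordered_pair_oracle(self, seed):
        rng = random.Random(seed)
        g, p = _prop_graph(OWL_SYMMETRIC)
        nodes, edges = _edges(12, 0.2, rng, acyclic=False)
        for a, b in edges:
            g.add(Triple(a, p, b))
        ent = materialize_symmetric(g, p)
        asserted = set(edges)
        expected = {(b, a) for a, b in asserted if a != b and (b, a) not in asserted}
        assert {(t.subject, t.object) for t in ent.inferred} == expected

    def test_requires_symmetric_characteristic(self):
        g, p = _prop_graph(OWL_TRANSITIVE)
        with pytest.raises(InferenceUsageError):
            materialize_symmetric(g, p)


class TestInverse:
    def test_worked_part_inference(self, worked_graph, ns):
        pair = (ns.schema_iri("typeForName"), ns.schema_iri("part"))
        ent = materialize_inverse(worked_graph, pair)
        assert ent.inferred == {
            Triple(
                ns.instance_iri("BifBaungi"),
                ns.schema_iri("part"),
                ns.instance_iri("bif-baungi-vb-i1"),
            )
        }

    def test_closure_then_inverse_reaches_family(self, worked_graph, ns):
        is_belong, has_species = ns.schema_iri("isBelong"), ns.schema_iri("hasSpecies")
        closed = fold(worked_graph, transitive_closure(worked_graph, is_belong))
        ent = materialize_inverse(closed, (is_belong, has_species))
        assert (
            Triple(ns.instance_iri("Ancylodiscoididae"), has_species, ns.instance_iri("BifBaungi"))
            in ent.inferred
        )

    def test_fixpoint_on_materialized_graph(self, worked_graph, ns):
        pair = (ns.schema_iri("typeForName"), ns.schema_iri("part"))
        once = fold(worked_graph, materialize_inverse(worked_graph, pair))
        assert materialize_inverse(once, pair).inferred == set()

    def test_undeclared_pair_rejected(self, worked_graph, ns):
        with pytest.raises(InferenceUsageError):
            materialize_inverse(worked_graph, (ns.schema_iri("rank"), ns.schema_iri("part")))


class TestFunctionalViolations:
    def test_double_typeForName_detected(self, worked_graph, ns):
        mutant = worked_graph.copy()
        spec = ns.instance_iri("bif-baungi-vb-i1")
        mutant.add(Triple(spec, ns.schema_iri("typeForName"), ns.instance_iri("BifIndicus")))
        violations = check_functional_violations(mutant, ns.schema_iri("typeForName"))
        assert len(violations) == 1 and violations[0][0] == spec

    def test_clean_worked_example(self, worked_graph, ns):
        assert check_functional_violations(worked_graph, ns.schema_iri("typeForName")) == []
        assert check_functional_violations(worked_graph, ns.schema_iri("part")) == []

    def test_empty_graph(self):
        g, p = _prop_graph()
        from mhbi.graph import OWL_FUNCTIONAL

        g.add(Triple(p, RDF_TYPE, OWL_FUNCTIONAL))
        assert check_functional_violations(g, p) == []

    def test_plain_property_rejected(self):
        g, p = _prop_graph()
        with pytest.raises(InferenceUsageError):
            check_functional_violations(g, p)


class TestMaterializeAll:
    def test_monotone_and_disjoint(self, worked_graph, ns):
        props = [ns.schema_iri(n) for n in ("isBelong", "hasSpecies", "typeForName", "part", "hasSynonym")]
        ent = materialize_all(worked_graph, props)
        assert ent.inferred.isdisjoint(worked_graph.triples)
        folded = fold(worked_graph, ent)
        assert worked_graph.triples <= folded.triples

    def test_applying_twice_equals_once(self, worked_graph, ns):
        props = [ns.schema_iri(n) for n in ("isBelong", "hasSpecies", "typeForName", "part", "hasSynonym")]
        once = fold(worked_graph, materialize_all(worked_graph, props))
        assert materialize_all(once, props).inferred == set()
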