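"""Join the parasite (MHBI) ontology to a host (fish) ontology.

Monogeneans are fish parasites, so each parasite taxon records the host it
was found on.  Standalone, ``isHostedIn`` holds a bare host label; merging
*promotes* it to an object property whose range is the fish ``TaxonName``
concept and rewrites each resolvable host-label literal into a link to the
corresponding fish taxon individual.  Neither source schema is otherwise
altered, and fish IRIs keep their own namespace — no IRI rewriting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .graph import (
    IRI,
    Literal,
    NodeKind,
    OntologyGraph,
    RDF_TYPE,
    RDFS_RANGE,
    Triple,
)
from .vocabulary import DEFAULT_NAMESPACES, Namespaces


class MergeError(ValueError):
    """Unresolvable hosts under the ``error`` policy, or bad plan input."""


class AmbiguousHostError(MergeError):
    """A host label matches two or more fish taxon individuals."""


MATCH_MODES = ("exact-label", "normalized-label", "explicit-map")
UNRESOLVED_POLICIES = ("keep-literal", "drop", "error")


@dataclass(frozen=True)
class MergePlan:
    match_mode: str = "exact-label"
    explicit_map: Optional[dict[str, IRI]] = None
    unresolved_policy: str = "keep-literal"

    def __post_init__(self) -> None:
        if self.match_mode not in MATCH_MODES:
            raise MergeError(f"unknown match mode {self.match_mode!r}")
        if self.unresolved_policy not in UNRESOLVED_POLICIES:
            raise MergeError(f"unknown unresolved policy {self.unresolved_policy!r}")


@dataclass
class MergeResult:
    graph: OntologyGraph
    linked: int = 0
    kept_literals: int = 0
    dropped: int = 0
    unresolved_labels: list[str] = field(default_factory=list)
    replaced_literal_triples: int = 0
    promotion_axioms: int = 0


def _normalize(label: str) -> str:
    return "".join(c for c in label.casefold() if c not in "- _")


def fish_individuals(fish: OntologyGraph, ns: Namespaces = DEFAULT_NAMESPACES) -> list[IRI]:
    taxon = ns.fish_schema_iri("TaxonName")
    return sorted(
        (
            i
            for i in fish.iris_of_kind(NodeKind.INDIVIDUAL)
            if fish.has(i, RDF_TYPE, taxon)
        ),
        key=lambda i: i.full,
    )


def resolve_host(
    label: str,
    fish: OntologyGraph,
    plan: MergePlan,
    ns: Namespaces = DEFAULT_NAMESPACES,
) -> Optional[IRI]:
    """Resolve a host label to a fish taxon individual, or ``None``.

    ``explicit-map`` consults the plan's map first and falls back to exact
    label matching; ``normalized-label`` compares after case-folding and
    stripping hyphens, underscores and spaces.
    """
    if plan.match_mode == "explicit-map" and plan.explicit_map and label in plan.explicit_map:
        return plan.explicit_map[label]
    candidates = fish_individuals(fish, ns)
    if plan.match_mode == "normalized-label":
        target = _normalize(label)
        hits = [c for c in candidates if _normalize(c.local_name) == target]
    else:
        hits = [c for c in candidates if c.local_name == label]
    if len(hits) > 1:
        raise AmbiguousHostError(
            f"host label {label!r} matches several fish taxa: {[h.full for h in hits]}"
        )
    return hits[0] if hits else None


def merge_ontologies(
    mhbi: OntologyGraph,
    fish: OntologyGraph,
    plan: MergePlan = MergePlan(),
    ns: Namespaces = DEFAULT_NAMESPACES,
) -> MergeResult:
    """Union both graphs, promote ``isHostedIn`` to an object property with
    range fish ``TaxonName``, and turn each resolvable host-label literal
    into an object link."""
    is_hosted_in = ns.schema_iri("isHostedIn")
    out = mhbi.copy()
    out.prefixes = {**fish.prefixes, **mhbi.prefixes}
    for iri, kind in fish.declarations.items():
        out.declare(iri, kind)
    for t in fish.triples:
        out.triples.add(t)
    for target in fish.imports:
        if target not in out.imports:
            out.imports.append(target)

    result = MergeResult(graph=out)

    # promotion: retract the datatype declaration and literal range, redeclare
    # as an object property targeting the fish taxon concept
    if out.kind_of(is_hosted_in) is NodeKind.DATATYPE_PROPERTY:
        for t in list(out.match(is_hosted_in, RDFS_RANGE, None)):
            out.discard(t)
            result.promotion_axioms += 1
        out.retract_declaration(is_hosted_in)
        out.declare(is_hosted_in, NodeKind.OBJECT_PROPERTY)
        result.promotion_axioms += 1
    fish_taxon = ns.fish_schema_iri("TaxonName")
    if not out.has(is_hosted_in, RDFS_RANGE, fish_taxon):
        out.add(Triple(is_hosted_in, RDFS_RANGE, fish_taxon))
        result.promotion_axioms += 1

    literal_triples = [
        t for t in out.match(None, is_hosted_in, None) if isinstance(t.object, Literal)
    ]
    for t in sorted(literal_triples, key=lambda t: (t.subject.full, str(t.object.value))):
        label = str(t.object.value)
        target = resolve_host(label, fish, plan, ns)
        if target is not None:
            out.discard(t)
            out.add(Triple(t.subject, is_hosted_in, target))
            result.linked += 1
            result.replaced_literal_triples += 1
        elif plan.unresolved_policy == "keep-literal":
            result.kept_literals += 1
            result.unresolved_labels.append(label)
        elif plan.unresolved_policy == "drop":
            out.discard(t)
            result.dropped += 1
            result.unresolved_labels.append(label)
        else:
            raise MergeError(
                f"merge aborted: unresolved host labels under policy 'error': {label!r}"
            )
    return result
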