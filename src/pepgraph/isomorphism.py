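"""Node-type-preserving isomorphism classes of bipartite components.

Two components are considered isomorphic only if some bijection maps protein
nodes to protein nodes and peptide nodes to peptide nodes while preserving
edges (an M-shaped and a W-shaped graph are *not* isomorphic under this
definition, although they are as uncolored graphs). Canonicalization uses
BLISS canonical labeling with the two node types as colors; the resulting key
serializes the canonical edge list plus the color vector. A brute-force
permutation search over small graphs serves as an independent validation
oracle. How many accessions or sequences a node groups is irrelevant for
isomorphism.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Sequence, Tuple

import igraph as ig

from .graphs import BipartiteComponent

__all__ = [
    "CanonicalKey",
    "IsomorphismClass",
    "canonical_form",
    "brute_force_isomorphic",
    "classify_components",
]

CanonicalKey = str

BRUTE_FORCE_NODE_LIMIT = 12


def _validate(component: BipartiteComponent) -> None:
    np_, nq = component.n_protein_nodes, component.n_peptide_nodes
    for p, q in component.edges:
        if not (0 <= p < np_ and 0 <= q < nq):
            raise ValueError("edge indices violate the bipartite structure")
    if np_ == 0 or nq == 0:
        raise ValueError("component must contain both node types")


def canonical_form(component: BipartiteComponent) -> CanonicalKey:
    """Canonical key; equal keys ⇔ type-preserving isomorphism.

    Invariant under relabeling of nodes within a type and under reordering of
    the member accessions/sequences inside a node.
    """
    _validate(component)
    np_, nq = component.n_protein_nodes, component.n_peptide_nodes
    colors = [0] * np_ + [1] * nq
    edges = [(p, np_ + q) for p, q in component.edges]
    g = ig.Graph(n=np_ + nq, edges=edges)
    perm = g.canonical_permutation(color=colors)
    canon = g.permute_vertices(perm)
    canon_colors = [0] * (np_ + nq)
    for v, target in enumerate(perm):
        canon_colors[target] = colors[v]
    edge_str = ",".join(
        f"{a}-{b}" for a, b in sorted(tuple(sorted(e.tuple)) for e in canon.es)
    )
    color_str = "".join(map(str, canon_colors))
    return f"{np_}|{nq}|{color_str}|{edge_str}"


def brute_force_isomorphic(g: BipartiteComponent, h: BipartiteComponent) -> bool:
    """Exhaustive search for a type-preserving edge-exact bijection.

    Independent of the canonical-form route; restricted to components with at
    most ``BRUTE_FORCE_NODE_LIMIT`` nodes.
    """
    for c in (g, h):
        _validate(c)
        if c.n_protein_nodes + c.n_peptide_nodes > BRUTE_FORCE_NODE_LIMIT:
            raise ValueError(
                f"brute force limited to {BRUTE_FORCE_NODE_LIMIT} nodes"
            )
    if (
        g.n_protein_nodes != h.n_protein_nodes
        or g.n_peptide_nodes != h.n_peptide_nodes
        or g.n_edges != h.n_edges
    ):
        return False
    ge, he = set(g.edges), set(h.edges)
    for pperm in permutations(range(g.n_protein_nodes)):
        for qperm in permutations(range(g.n_peptide_nodes)):
            if all((pperm[p], qperm[q]) in he for p, q in ge):
                return True
    return False


@dataclass
class IsomorphismClass:
    """All components sharing one canonical key.

    The representative is the first member encountered in the deterministic
    component order; every member shares ``size_signature`` =
    (protein nodes, peptide nodes, unique, shared, edges).
    """

    key: CanonicalKey
    representative: BipartiteComponent
    count: int
    size_signature: Tuple[int, int, int, int, int]

    def percentage(self, total: int) -> float:
        return 100.0 * self.count / total if total else 0.0


def classify_components(
    components: Sequence[BipartiteComponent],
) -> List[IsomorphismClass]:
    """Group components into isomorphism classes, largest class first.

    Iteratively compares each component's canonical key against the classes
    seen so far, adding to an existing class or opening a new one. Output is
    sorted by descending count, ties broken by ascending size signature, then
    by key.
    """
    classes: Dict[CanonicalKey, IsomorphismClass] = {}
    for comp in components:
        key = canonical_form(comp)
        if key in classes:
            classes[key].count += 1
        else:
            classes[key] = IsomorphismClass(key, comp, 1, comp.size_signature())
    return sorted(
        classes.values(), key=lambda c: (-c.count, c.size_signature, c.key)
    )
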