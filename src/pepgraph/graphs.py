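"""Collapsed bipartite peptide–protein graphs and their connected components.

Proteins with identical peptide sets are indistinguishable and collapse into
one protein node (a protein ambiguity group); peptides belonging to exactly
the same set of protein nodes collapse into one peptide node. The collapsed
graph decomposes into connected components — the units on which protein
inference and quantification operate. A peptide node is *unique* when it is
adjacent to exactly one protein node and *shared* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import (
    Dict,
    FrozenSet,
    Iterable,
    List,
    Mapping,
    Sequence,
    Tuple,
    Union,
)

import networkx as nx
import pandas as pd

from .digestion import PeptideProteinMap

__all__ = [
    "ProteinNode",
    "PeptideNode",
    "BipartiteComponent",
    "build_biadjacency",
    "collapse_nodes",
    "connected_components",
    "classify_peptide_nodes",
    "components_from_map",
    "component_to_networkx",
    "write_graphml",
]


@dataclass(frozen=True)
class ProteinNode:
    """A protein ambiguity group: accessions with identical peptide sets."""

    accessions: FrozenSet[str]

    @property
    def label(self) -> str:
        return min(self.accessions)

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass(frozen=True)
class PeptideNode:
    """Peptide sequences belonging to exactly the same set of protein nodes."""

    sequences: FrozenSet[str]

    @property
    def label(self) -> str:
        return min(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class BipartiteComponent:
    """One connected component of the collapsed graph.

    Nodes are stored in deterministic order (protein nodes by smallest member
    accession, peptide nodes by smallest member sequence); ``edges`` holds
    (protein index, peptide index) pairs into those tuples.
    """

    protein_nodes: Tuple[ProteinNode, ...]
    peptide_nodes: Tuple[PeptideNode, ...]
    edges: FrozenSet[Tuple[int, int]]

    @property
    def n_protein_nodes(self) -> int:
        return len(self.protein_nodes)

    @property
    def n_peptide_nodes(self) -> int:
        return len(self.peptide_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def peptide_degrees(self) -> List[int]:
        deg = [0] * len(self.peptide_nodes)
        for _, q in self.edges:
            deg[q] += 1
        return deg

    def protein_degrees(self) -> List[int]:
        deg = [0] * len(self.protein_nodes)
        for p, _ in self.edges:
            deg[p] += 1
        return deg

    def peptide_is_unique(self) -> List[bool]:
        return [d == 1 for d in self.peptide_degrees()]

    @property
    def n_unique_peptide_nodes(self) -> int:
        return sum(self.peptide_is_unique())

    @property
    def n_shared_peptide_nodes(self) -> int:
        return self.n_peptide_nodes - self.n_unique_peptide_nodes

    def protein_unique_shared_profile(self) -> List[Tuple[bool, bool]]:
        """Per protein node: (has a unique peptide, has a shared peptide)."""
        uniq = self.peptide_is_unique()
        has_u = [False] * self.n_protein_nodes
        has_s = [False] * self.n_protein_nodes
        for p, q in self.edges:
            if uniq[q]:
                has_u[p] = True
            else:
                has_s[p] = True
        return list(zip(has_u, has_s))

    def size_signature(self) -> Tuple[int, int, int, int, int]:
        """(protein nodes, peptide nodes, unique, shared, edges)."""
        u = self.n_unique_peptide_nodes
        return (
            self.n_protein_nodes,
            self.n_peptide_nodes,
            u,
            self.n_peptide_nodes - u,
            self.n_edges,
        )

    @property
    def min_accession(self) -> str:
        return min(n.label for n in self.protein_nodes)

    def sort_key(self):
        return (-self.n_protein_nodes, -self.n_peptide_nodes, self.min_accession)


def build_biadjacency(pmap: PeptideProteinMap) -> pd.DataFrame:
    """Binary incidence matrix, peptide sequences (rows) × accessions (columns).

    ``incidence[p, a] = 1`` iff accession ``a`` contains peptide ``p``. Rows
    and columns are sorted for reproducibility. Intended for inspection and
    small-scale tests; collapsing works directly on the map.
    """
    peptides = sorted(pmap.entries)
    accessions = sorted(pmap.included_accessions)
    col = {a: j for j, a in enumerate(accessions)}
    data = [[0] * len(accessions) for _ in peptides]
    for i, p in enumerate(peptides):
        for a in pmap.entries[p]:
            data[i][col[a]] = 1
    return pd.DataFrame(data, index=peptides, columns=accessions, dtype="int8")


def _entries_from(source) -> Mapping[str, FrozenSet[str]]:
    if isinstance(source, PeptideProteinMap):
        return source.entries
    if isinstance(source, pd.DataFrame):
        return {
            p: frozenset(source.columns[source.loc[p].to_numpy().nonzero()[0]])
            for p in source.index
            if source.loc[p].any()
        }
    return {p: frozenset(a) for p, a in dict(source).items()}


def collapse_nodes(
    source: Union[PeptideProteinMap, pd.DataFrame, Mapping[str, Iterable[str]]],
) -> Tuple[List[ProteinNode], List[PeptideNode], List[Tuple[int, int]]]:
    """Collapse indistinguishable proteins, then peptides, into grouped nodes.

    Returns (protein nodes, peptide nodes, edges as index pairs) of the whole
    collapsed graph. One pass of each collapse reaches the fixed point: after
    grouping proteins by peptide set, two peptide groups with equal protein-
    node support merge, and no further protein merge can arise because protein
    groups with different peptide sets keep different peptide-node supports.
    """
    entries = _entries_from(source)
    prot_peps: Dict[str, set] = {}
    for pep, accs in entries.items():
        for a in accs:
            prot_peps.setdefault(a, set()).add(pep)

    by_pepset: Dict[FrozenSet[str], List[str]] = {}
    for acc, peps in prot_peps.items():
        by_pepset.setdefault(frozenset(peps), []).append(acc)
    protein_nodes = sorted(
        (ProteinNode(frozenset(accs)) for accs in by_pepset.values()),
        key=lambda n: n.label,
    )
    node_of_acc = {a: i for i, n in enumerate(protein_nodes) for a in n.accessions}

    by_support: Dict[FrozenSet[int], List[str]] = {}
    for pep, accs in entries.items():
        support = frozenset(node_of_acc[a] for a in accs)
        by_support.setdefault(support, []).append(pep)
    supports = sorted(by_support, key=lambda s: min(by_support[s]))
    peptide_nodes = [PeptideNode(frozenset(by_support[s])) for s in supports]

    edges = [
        (p, q) for q, s in enumerate(supports) for p in sorted(s)
    ]
    return protein_nodes, peptide_nodes, edges


def connected_components(
    protein_nodes: Sequence[ProteinNode],
    peptide_nodes: Sequence[PeptideNode],
    edges: Iterable[Tuple[int, int]],
) -> List[BipartiteComponent]:
    """Split the collapsed graph into components, deterministically ordered.

    Components are sorted by descending protein-node count, then descending
    peptide-node count, then smallest member accession.
    """
    edges = list(edges)
    parent = list(range(len(protein_nodes) + len(peptide_nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    off = len(protein_nodes)
    for p, q in edges:
        rp, rq = find(p), find(off + q)
        if rp != rq:
            parent[rq] = rp

    groups: Dict[int, Dict[str, list]] = {}
    for i in range(len(protein_nodes)):
        groups.setdefault(find(i), {"p": [], "q": []})["p"].append(i)
    for j in range(len(peptide_nodes)):
        groups.setdefault(find(off + j), {"p": [], "q": []})["q"].append(j)

    components = []
    for g in groups.values():
        pn = sorted((protein_nodes[i] for i in g["p"]), key=lambda n: n.label)
        qn = sorted((peptide_nodes[j] for j in g["q"]), key=lambda n: n.label)
        # re-map edges into local sorted indices
        p_local = {n: k for k, n in enumerate(pn)}
        q_local = {n: k for k, n in enumerate(qn)}
        in_p = set(g["p"])
        comp_edges = frozenset(
            (p_local[protein_nodes[p]], q_local[peptide_nodes[q]])
            for p, q in edges
            if p in in_p
        )
        components.append(BipartiteComponent(tuple(pn), tuple(qn), comp_edges))
    components.sort(key=BipartiteComponent.sort_key)
    return components


def classify_peptide_nodes(component: BipartiteComponent) -> Tuple[int, int]:
    """(unique, shared) peptide-node counts; unique ⇔ degree 1."""
    u = component.n_unique_peptide_nodes
    return u, component.n_peptide_nodes - u


def components_from_map(
    source: Union[PeptideProteinMap, Mapping[str, Iterable[str]]],
) -> List[BipartiteComponent]:
    """Collapse and decompose in one call."""
    return connected_components(*collapse_nodes(source))


def component_to_networkx(component: BipartiteComponent) -> nx.Graph:
    """Undirected graph with node attributes type / members / is_unique."""
    g = nx.Graph()
    uniq = component.peptide_is_unique()
    for i, node in enumerate(component.protein_nodes):
        g.add_node(
            f"protein:{node.label}",
            node_type="protein",
            members=";".join(sorted(node.accessions)),
            bipartite=0,
        )
    for j, node in enumerate(component.peptide_nodes):
        g.add_node(
            f"peptide:{node.label}",
            node_type="peptide",
            members=";".join(sorted(node.sequences)),
            is_unique=bool(uniq[j]),
            bipartite=1,
        )
    for p, q in sorted(component.edges):
        g.add_edge(
            f"protein:{component.protein_nodes[p].label}",
            f"peptide:{component.peptide_nodes[q].label}",
        )
    return g


def write_graphml(component: BipartiteComponent, path: Union[str, Path]) -> None:
    nx.write_graphml(component_to_networkx(component), str(path))
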