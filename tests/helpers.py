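"""Shared test utilities: independent oracles and graph constructions."""

from __future__ import annotations

import re
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

from pepgraph import BipartiteComponent, components_from_map
from pepgraph.graphs import PeptideNode, ProteinNode

# Independent route to the cleavage positions: regex lookaround on K/R not
# followed by P (the production code scans characters instead).
_CLEAVE = re.compile(r"(?<=[KR])(?!P)")


def oracle_fragments(sequence: str) -> List[str]:
    """Fully cleaved tryptic fragments via regex split."""
    return [f for f in _CLEAVE.split(sequence) if f]


def oracle_candidates(sequence: str, max_missed: int) -> List[Tuple[str, int]]:
    """Every concatenation of <= max_missed+1 consecutive fragments,
    one entry per position (duplicates kept)."""
    frags = oracle_fragments(sequence)
    out = []
    for i in range(len(frags)):
        for k in range(min(max_missed, len(frags) - 1 - i) + 1):
            out.append(("".join(frags[i : i + k + 1]), k))
    return out


def component_from_edges(
    n_prot: int, n_pep: int, edges
) -> BipartiteComponent:
    """Hand-built component with synthetic single-member nodes."""
    prot = tuple(ProteinNode(frozenset({f"P{i:02d}"})) for i in range(n_prot))
    pep = tuple(PeptideNode(frozenset({f"pep{j:02d}"})) for j in range(n_pep))
    return BipartiteComponent(prot, pep, frozenset(edges))


def path_component(n_nodes: int, start_with_protein: bool) -> BipartiteComponent:
    """Path graph with alternating node types."""
    types = [
        (i % 2 == 0) == start_with_protein for i in range(n_nodes)
    ]  # True = protein
    p_idx, q_idx = {}, {}
    for i, is_prot in enumerate(types):
        if is_prot:
            p_idx[i] = len(p_idx)
        else:
            q_idx[i] = len(q_idx)
    edges = []
    for i in range(n_nodes - 1):
        a, b = (i, i + 1) if types[i] else (i + 1, i)
        edges.append((p_idx[a], q_idx[b]))
    return component_from_edges(len(p_idx), len(q_idx), edges)


def star_component(n_leaves: int, protein_center: bool) -> BipartiteComponent:
    if protein_center:
        return component_from_edges(1, n_leaves, [(0, j) for j in range(n_leaves)])
    return component_from_edges(n_leaves, 1, [(i, 0) for i in range(n_leaves)])


def entries_of(component: BipartiteComponent) -> Dict[str, FrozenSet[str]]:
    """Expand a component back to its peptide -> accessions incidence."""
    out: Dict[str, Set[str]] = {}
    for p, q in component.edges:
        for seq in component.peptide_nodes[q].sequences:
            out.setdefault(seq, set()).update(component.protein_nodes[p].accessions)
    return {s: frozenset(a) for s, a in out.items()}


def relabel(component: BipartiteComponent, rng: np.random.Generator) -> BipartiteComponent:
    """Fresh random names for every accession and sequence, then rebuild."""
    accs = sorted({a for n in component.protein_nodes for a in n.accessions})
    seqs = sorted({s for n in component.peptide_nodes for s in n.sequences})
    amap = {a: f"R{rng.integers(10**9):09d}A{i}" for i, a in enumerate(accs)}
    smap = {s: f"R{rng.integers(10**9):09d}S{i}" for i, s in enumerate(seqs)}
    entries = {
        smap[s]: frozenset(amap[a] for a in accset)
        for s, accset in entries_of(component).items()
    }
    comps = components_from_map(entries)
    assert len(comps) == 1
    return comps[0]


def random_entries(
    rng: np.random.Generator, max_prot: int = 8, max_pep: int = 15
) -> Dict[str, FrozenSet[str]]:
    """Random peptide -> accessions map (not necessarily connected)."""
    n_prot = int(rng.integers(1, max_prot + 1))
    n_pep = int(rng.integers(1, max_pep + 1))
    accs = [f"ACC{i}" for i in range(n_prot)]
    entries = {}
    for j in range(n_pep):
        k = int(rng.integers(1, n_prot + 1))
        chosen = rng.choice(n_prot, size=k, replace=False)
        entries[f"PEPTIDE{j}"] = frozenset(accs[i] for i in chosen)
    return entries
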