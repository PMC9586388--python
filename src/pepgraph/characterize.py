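"""Aggregate metrics over a set of bipartite peptide–protein components.

Covers the run-level summary (node/edge/graph/class totals plus the two
largest graphs by protein-node count), node-count distributions with a pooled
"10+" bin, the uniqueness breakdown of peptide and protein nodes, and the
cross-tabulation of peptide status between a canonical-only and a
with-isoforms database digest.

Two notions of uniqueness coexist deliberately: everywhere in the graph
metrics a peptide node is *node-unique* when adjacent to one protein node;
the isoform cross-tabulation instead uses *accession-level* uniqueness (one
matching accession), with an intermediate *isoform-unique* status for
peptides shared only among isoforms of one parent accession.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence, Tuple, Union

import pandas as pd

from .digestion import PeptideProteinMap
from .fasta_io import base_accession
from .graphs import BipartiteComponent
from .isomorphism import IsomorphismClass

__all__ = [
    "DatasetSummary",
    "UniquenessBreakdown",
    "IsoformPeptideCrossTab",
    "summarize",
    "node_count_distributions",
    "uniqueness_breakdown",
    "isoform_crosstab",
]


@dataclass
class DatasetSummary:
    """Run-level totals; largest graphs ranked by protein-node count."""

    protein_accessions: int
    protein_nodes: int
    peptide_sequences: int
    peptide_nodes: int
    edges: int
    graphs: int
    graphs_one_protein: int
    isomorphism_classes: int
    largest_graph: Tuple[int, int, int]
    second_largest_graph: Tuple[int, int, int]

    def to_dict(self) -> Dict[str, object]:
        return asdict(self)

    def to_series(self) -> pd.Series:
        d = self.to_dict()
        for name in ("largest_graph", "second_largest_graph"):
            pn, qn, e = d.pop(name)
            d[f"{name}_protein_nodes"] = pn
            d[f"{name}_peptide_nodes"] = qn
            d[f"{name}_edges"] = e
        return pd.Series(d)


def summarize(
    components: Sequence[BipartiteComponent],
    classes: Sequence[IsomorphismClass],
    pmap: Optional[PeptideProteinMap] = None,
) -> DatasetSummary:
    """Aggregate one run.

    With ``pmap`` given, accession/sequence totals come from the source map;
    otherwise they are multiset counts over the components (the natural
    reading for comparison-pooled quantitative runs, where one accession may
    appear in several pooled components).
    """
    comps = sorted(components, key=BipartiteComponent.sort_key)
    if pmap is not None:
        n_acc = len(pmap.included_accessions)
        n_seq = pmap.n_peptides
    else:
        n_acc = sum(len(n) for c in comps for n in c.protein_nodes)
        n_seq = sum(len(n) for c in comps for n in c.peptide_nodes)

    def triple(c: Optional[BipartiteComponent]) -> Tuple[int, int, int]:
        if c is None:
            return (0, 0, 0)
        return (c.n_protein_nodes, c.n_peptide_nodes, c.n_edges)

    return DatasetSummary(
        protein_accessions=n_acc,
        protein_nodes=sum(c.n_protein_nodes for c in comps),
        peptide_sequences=n_seq,
        peptide_nodes=sum(c.n_peptide_nodes for c in comps),
        edges=sum(c.n_edges for c in comps),
        graphs=len(comps),
        graphs_one_protein=sum(1 for c in comps if c.n_protein_nodes == 1),
        isomorphism_classes=len(classes),
        largest_graph=triple(comps[0] if comps else None),
        second_largest_graph=triple(comps[1] if len(comps) > 1 else None),
    )


def node_count_distributions(
    components: Sequence[BipartiteComponent], cap: int = 10
) -> Dict[str, Dict[Union[int, str], float]]:
    """Proportion of components with each exact node count, pooled at ``cap``.

    Four histograms (protein nodes, peptide nodes, unique peptide nodes,
    shared peptide nodes); bins 0..cap-1 exact plus a "{cap}+" bin; each
    histogram sums to 1.
    """
    if not components:
        raise ValueError("need at least one component")
    metrics = {
        "protein_nodes": [c.n_protein_nodes for c in components],
        "peptide_nodes": [c.n_peptide_nodes for c in components],
        "unique_peptide_nodes": [c.n_unique_peptide_nodes for c in components],
        "shared_peptide_nodes": [c.n_shared_peptide_nodes for c in components],
    }
    n = len(components)
    out: Dict[str, Dict[Union[int, str], float]] = {}
    for name, counts in metrics.items():
        hist: Dict[Union[int, str], float] = {b: 0.0 for b in range(cap)}
        hist[f"{cap}+"] = 0.0
        for c in counts:
            key: Union[int, str] = c if c < cap else f"{cap}+"
            hist[key] += 1.0 / n
        out[name] = hist
    return out


@dataclass
class UniquenessBreakdown:
    """Uniqueness percentages over peptide nodes, protein nodes and graphs."""

    peptide_nodes_unique_pct: float
    peptide_nodes_shared_pct: float
    protein_nodes_only_unique_pct: float
    protein_nodes_both_pct: float
    protein_nodes_only_shared_pct: float
    graphs_with_node_lacking_unique_pct: float

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


def uniqueness_breakdown(
    components: Sequence[BipartiteComponent],
) -> UniquenessBreakdown:
    """Percentages of unique vs shared peptide nodes, of protein nodes with
    only-unique / both / only-shared peptides, and of graphs containing at
    least one protein node without any unique peptide."""
    if not components:
        raise ValueError("need at least one component")
    n_pep = sum(c.n_peptide_nodes for c in components)
    n_uniq = sum(c.n_unique_peptide_nodes for c in components)
    n_prot = sum(c.n_protein_nodes for c in components)
    only_u = both = only_s = 0
    lacking = 0
    for c in components:
        profile = c.protein_unique_shared_profile()
        if any(not has_u for has_u, _ in profile):
            lacking += 1
        for has_u, has_s in profile:
            if has_u and has_s:
                both += 1
            elif has_u:
                only_u += 1
            else:
                only_s += 1
    return UniquenessBreakdown(
        peptide_nodes_unique_pct=100.0 * n_uniq / n_pep,
        peptide_nodes_shared_pct=100.0 * (n_pep - n_uniq) / n_pep,
        protein_nodes_only_unique_pct=100.0 * only_u / n_prot,
        protein_nodes_both_pct=100.0 * both / n_prot,
        protein_nodes_only_shared_pct=100.0 * only_s / n_prot,
        graphs_with_node_lacking_unique_pct=100.0 * lacking / len(components),
    )


ISO_ROWS = ("unique", "isoform-unique", "shared")
ISO_COLS = ("unique", "shared", "not existing")


@dataclass
class IsoformPeptideCrossTab:
    """3×3 peptide counts: with-isoforms status × canonical-only status.

    Rows classify each peptide of the with-isoforms digest at accession
    level; columns give its status in the canonical-only digest ("not
    existing" when the peptide arises only once isoforms are included).
    ``canonical_only`` counts peptides of the canonical digest absent from
    the with-isoforms digest (zero whenever the canonical database is a
    subset of the isoform database).
    """

    counts: Dict[Tuple[str, str], int]
    canonical_only: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [[self.counts.get((r, c), 0) for c in ISO_COLS] for r in ISO_ROWS],
            index=list(ISO_ROWS),
            columns=list(ISO_COLS),
        )
        df["sum"] = df.sum(axis=1)
        df.loc["sum"] = df.sum(axis=0)
        return df

    @property
    def grand_total(self) -> int:
        return sum(self.counts.values())


def _accession_status(accessions) -> str:
    if len(accessions) == 1:
        return "unique"
    if len({base_accession(a) for a in accessions}) == 1:
        return "isoform-unique"
    return "shared"


def isoform_crosstab(
    map_canonical: PeptideProteinMap,
    map_iso: PeptideProteinMap,
) -> IsoformPeptideCrossTab:
    """Cross-classify every peptide of the with-isoforms digest.

    Row: unique (one accession) / isoform-unique (several accessions, one
    base accession) / shared (several base accessions) in the with-isoforms
    map. Column: unique / shared / not existing in the canonical-only map.
    Both maps must stem from the same digestion parameters.
    """
    if (
        map_canonical.config is not None
        and map_iso.config is not None
        and map_canonical.config != map_iso.config
    ):
        raise ValueError(
            "digestion configs differ between canonical and isoform maps"
        )
    counts: Dict[Tuple[str, str], int] = {}
    for pep, accs in map_iso.entries.items():
        row = _accession_status(accs)
        canon = map_canonical.entries.get(pep)
        if canon is None:
            col = "not existing"
        elif len(canon) == 1:
            col = "unique"
        else:
            col = "shared"
        counts[(row, col)] = counts.get((row, col), 0) + 1
    lost = sum(1 for p in map_canonical.entries if p not in map_iso.entries)
    return IsoformPeptideCrossTab(counts, canonical_only=lost)
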