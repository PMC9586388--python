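"""Synthetic protein databases and peptide quant tables with planted graphs.

Proteins are concatenations of globally unique tryptic *blocks*: runs of
residues free of K, R and P that end in K or R. Digesting such a protein at
zero missed cleavages returns exactly its blocks, so the bipartite component
a group of proteins forms is known analytically from which blocks they share.
Motifs planted per component:

``smallest``  one protein, all blocks private       → 1 protein / 1 peptide node
``M``         two proteins sharing one block, one
              private block each                    → 2 / 3 nodes
``N``         protein B is a single block that A
              also carries                          → 2 / 2 nodes
``W``         three proteins; the outer two are
              single shared blocks of the middle    → 3 / 2 nodes
``random``    random connected block/protein
              incidence (ground truth = incidence)

Block uniqueness across components guarantees planted components never merge.
Isoforms copy a parent minus one block, which makes the remaining blocks
isoform-unique at accession level. The quant generator emulates that only a
fraction of theoretical peptides is ever measured (per-peptide detection),
log-normal label-free intensities, and per-replicate dropout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .digestion import DigestConfig, digest_database
from .fasta_io import ProteinRecord
from .graphs import BipartiteComponent
from .quant import QuantTable

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "MOTIF_SIGNATURES",
    "generate_database",
    "generate_quant_table",
    "degradation_report",
    "DegradationReport",
]

BLOCK_ALPHABET = "ACDEFGHINQSTVWY"  # no K/R (cleavage) and no P (rule exception)

#: (protein nodes, peptide nodes) of each pure motif after digest + collapse
MOTIF_SIGNATURES: Dict[str, Tuple[int, int]] = {
    "smallest": (1, 1),
    "M": (2, 3),
    "N": (2, 2),
    "W": (3, 2),
}


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic data set.

    Defaults emulate a spike-in style label-free experiment: five states in
    triplicate, DDA-like peptide sparsity (30% of theoretical peptides never
    detected, 10% per-replicate dropout), log-normal intensities around
    e^16 ≈ 9e6, and a motif mix dominated by the single-protein graph with
    the M shape second, as observed for database-level mammalian digests.
    """

    n_components: int = 200
    motif_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "smallest": 0.45,
            "M": 0.20,
            "N": 0.10,
            "W": 0.05,
            "random": 0.20,
        }
    )
    random_motif_params: Tuple[int, float] = (5, 0.5)  # (max proteins, edge density)
    isoform_rate: float = 0.0
    n_states: int = 5
    n_replicates: int = 3
    detection_prob: float = 0.7
    missing_prob: float = 0.1
    intensity_mu: float = 16.0
    intensity_sigma: float = 2.0
    block_len: Tuple[int, int] = (7, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        mix = dict(self.motif_mix)
        unknown = set(mix) - (set(MOTIF_SIGNATURES) | {"random"})
        if unknown:
            raise ValueError(f"unknown motifs {sorted(unknown)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("motif_mix proportions must sum to 1")
        for p in (self.detection_prob, self.missing_prob, self.isoform_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.block_len[0] < 2 or self.block_len[0] > self.block_len[1]:
            raise ValueError("infeasible block length range")
        if self.n_components < 0 or self.n_states < 1 or self.n_replicates < 1:
            raise ValueError("sizes must be positive")

    def rngs(self) -> Dict[str, np.random.Generator]:
        """Independent streams per purpose, all derived from ``seed``."""
        root = np.random.SeedSequence(self.seed)
        seqs = root.spawn(4)
        names = ("sequence", "detection", "missingness", "intensity")
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


@dataclass
class GroundTruth:
    """What was planted: motif per component and the block incidence.

    ``incidence`` is the planted peptide → accession map (before any
    isoforms are appended); ``expected_class_counts`` counts components per
    motif and sums to ``n_components``.
    """

    motifs: List[str]
    expected_class_counts: Dict[str, int]
    incidence: Dict[str, Set[str]]
    isoform_parents: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "motifs": self.motifs,
                "expected_class_counts": self.expected_class_counts,
                "incidence": {p: sorted(a) for p, a in self.incidence.items()},
                "isoform_parents": self.isoform_parents,
            },
            indent=2,
            sort_keys=True,
        )


class _BlockFactory:
    """Draws globally unique tryptic blocks."""

    def __init__(self, rng: np.random.Generator, lo: int, hi: int) -> None:
        self.rng = rng
        self.lo, self.hi = lo, hi
        self.seen: Set[str] = set()

    def new(self) -> str:
        for _ in range(10_000):
            n = int(self.rng.integers(self.lo, self.hi + 1))
            body = "".join(
                self.rng.choice(list(BLOCK_ALPHABET), size=n - 1)
            )
            block = body + ("K" if self.rng.random() < 0.5 else "R")
            if block not in self.seen:
                self.seen.add(block)
                return block
        raise RuntimeError("block space exhausted; widen block_len")


def _allot(mix: Mapping[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder apportionment of n components to motifs."""
    order = sorted(mix)
    raw = {m: mix[m] * n for m in order}
    counts = {m: int(math.floor(raw[m])) for m in order}
    rest = n - sum(counts.values())
    for m in sorted(order, key=lambda m: (raw[m] - counts[m], m), reverse=True)[:rest]:
        counts[m] += 1
    return {m: c for m, c in counts.items() if c > 0}


def _random_motif(
    rng: np.random.Generator, factory: _BlockFactory, n_max: int, density: float
) -> Tuple[List[List[str]], Dict[str, Set[int]]]:
    """Random connected protein/block incidence; returns per-protein block
    lists and block → protein-index sets."""
    n_prot = int(rng.integers(2, n_max + 1))
    n_blocks = int(rng.integers(n_prot, 2 * n_prot + 1))
    membership: Dict[str, Set[int]] = {}
    blocks_of: List[List[str]] = [[] for _ in range(n_prot)]
    for _ in range(n_blocks):
        owners = {i for i in range(n_prot) if rng.random() < density}
        if not owners:
            owners = {int(rng.integers(0, n_prot))}
        b = factory.new()
        membership[b] = owners
        for i in owners:
            blocks_of[i].append(b)
    for i in range(n_prot):  # every protein needs at least one block
        if not blocks_of[i]:
            b = factory.new()
            membership[b] = {i}
            blocks_of[i].append(b)
    # connect stray sub-components with bridging shared blocks
    parent = list(range(n_prot))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for owners in membership.values():
        it = iter(sorted(owners))
        first = find(next(it))
        for other in it:
            parent[find(other)] = first
    roots = sorted({find(i) for i in range(n_prot)})
    for a, b_root in zip(roots, roots[1:]):
        blk = factory.new()
        membership[blk] = {a, b_root}
        blocks_of[a].append(blk)
        blocks_of[b_root].append(blk)
        parent[find(b_root)] = find(a)
    return blocks_of, membership


def generate_database(
    spec: SynthSpec,
) -> Tuple[List[ProteinRecord], GroundTruth]:
    """Plant ``spec.n_components`` motif components and emit FASTA records.

    Reproducible from ``spec.seed``; isoforms (parent accession + ``-2``,
    one block deleted) are appended after the planted incidence is recorded.
    """
    rng = spec.rngs()["sequence"]
    factory = _BlockFactory(rng, *spec.block_len)
    counts = _allot(spec.motif_mix, spec.n_components)

    records: List[ProteinRecord] = []
    motifs: List[str] = []
    incidence: Dict[str, Set[str]] = {}
    iso_parents: Dict[str, str] = {}
    class_counts: Dict[str, int] = {}
    comp_id = 0

    def acc(i: int) -> str:
        return f"SYN{comp_id:05d}P{i}"

    def add_protein(i: int, blocks: Sequence[str]) -> ProteinRecord:
        a = acc(i)
        rec = ProteinRecord(
            accession=a,
            sequence="".join(blocks),
            entry_name=f"{a}_SYN",
            description=f"synthetic motif={motifs[-1]}",
        )
        records.append(rec)
        for b in blocks:
            incidence.setdefault(b, set()).add(a)
        return rec

    plan = [m for m in sorted(counts) for _ in range(counts[m])]
    rng.shuffle(plan)  # interleave motifs so accession order carries no signal
    for motif in plan:
        motifs.append(motif)
        class_counts[motif] = class_counts.get(motif, 0) + 1
        if motif == "smallest":
            n_blocks = int(rng.integers(2, 4))
            add_protein(0, [factory.new() for _ in range(n_blocks)])
        elif motif == "M":
            s = factory.new()
            add_protein(0, [factory.new(), s])
            add_protein(1, [s, factory.new()])
        elif motif == "N":
            s = factory.new()
            add_protein(0, [factory.new(), s])
            add_protein(1, [s])
        elif motif == "W":
            s1, s2 = factory.new(), factory.new()
            add_protein(0, [s1])
            add_protein(1, [s1, s2])
            add_protein(2, [s2])
        else:  # random
            n_max, density = spec.random_motif_params
            blocks_of, _ = _random_motif(rng, factory, n_max, density)
            for i, blocks in enumerate(blocks_of):
                add_protein(i, blocks)
        comp_id += 1

    if spec.isoform_rate > 0:
        iso_records: List[ProteinRecord] = []
        for rec in records:
            blocks = _split_blocks(rec.sequence)
            if len(blocks) >= 2 and rng.random() < spec.isoform_rate:
                drop = int(rng.integers(0, len(blocks)))
                kept = [b for i, b in enumerate(blocks) if i != drop]
                iso_acc = f"{rec.accession}-2"
                iso_records.append(
                    ProteinRecord(
                        accession=iso_acc,
                        sequence="".join(kept),
                        entry_name=f"{iso_acc}_SYN",
                        description=f"synthetic isoform of {rec.accession}",
                    )
                )
                iso_parents[iso_acc] = rec.accession
        records.extend(iso_records)

    truth = GroundTruth(motifs, class_counts, incidence, iso_parents)
    return records, truth


def _split_blocks(sequence: str) -> List[str]:
    """Recover the planted blocks of a sequence (cut after each K/R)."""
    blocks: List[str] = []
    start = 0
    for i, ch in enumerate(sequence):
        if ch in "KR":
            blocks.append(sequence[start : i + 1])
            start = i + 1
    return blocks


def _sample_names(spec: SynthSpec) -> Dict[str, Tuple[str, int]]:
    return {
        f"S{s + 1}_R{r + 1}": (f"S{s + 1}", r + 1)
        for s in range(spec.n_states)
        for r in range(spec.n_replicates)
    }


def generate_quant_table(
    records: Sequence[ProteinRecord],
    spec: SynthSpec,
    config: Optional[DigestConfig] = None,
    force_detect: Optional[Mapping[str, bool]] = None,
) -> QuantTable:
    """Simulate measured intensities for the theoretical peptides.

    Each theoretical peptide (digest at zero missed cleavages by default) is
    detected with ``detection_prob``; detected peptides draw log-normal
    intensities per sample and lose each replicate value independently with
    ``missing_prob``. ``force_detect`` pins the detection outcome of given
    peptides (used to construct degradation scenarios). Zeros are never
    emitted.
    """
    rngs = spec.rngs()
    if config is None:
        config = DigestConfig(
            min_len=spec.block_len[0], max_len=50, max_missed=0
        )
    pmap = digest_database(records, config)
    peptides = sorted(pmap.entries)
    detect_rng = rngs["detection"]
    draws = detect_rng.random(len(peptides))
    detected = []
    for pep, u in zip(peptides, draws):
        keep = u < spec.detection_prob
        if force_detect is not None and pep in force_detect:
            keep = force_detect[pep]
        if keep:
            detected.append(pep)

    design = _sample_names(spec)
    samples = list(design)
    inten_rng, miss_rng = rngs["intensity"], rngs["missingness"]
    values = np.exp(
        inten_rng.normal(
            spec.intensity_mu,
            spec.intensity_sigma,
            size=(len(detected), len(samples)),
        )
    )
    mask = miss_rng.random(values.shape) < spec.missing_prob
    values[mask] = np.nan
    df = pd.DataFrame(
        values, index=pd.Index(detected, name="sequence"), columns=samples
    )
    return QuantTable(df, design)


@dataclass
class DegradationReport:
    """The two opposing database→quantitative effects, as proportion deltas."""

    db_single_protein_graph_prop: float
    quant_single_protein_graph_prop: float
    delta_single_protein_graph_prop: float
    db_only_shared_protein_prop: float
    quant_only_shared_protein_prop: float
    delta_only_shared_protein_prop: float

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


def _single_prop(components: Sequence[BipartiteComponent]) -> float:
    if not components:
        return 0.0
    return sum(1 for c in components if c.n_protein_nodes == 1) / len(components)


def _only_shared_prop(components: Sequence[BipartiteComponent]) -> float:
    n = sum(c.n_protein_nodes for c in components)
    if n == 0:
        return 0.0
    only_shared = sum(
        1
        for c in components
        for has_u, _ in c.protein_unique_shared_profile()
        if not has_u
    )
    return only_shared / n


def degradation_report(
    db_components: Sequence[BipartiteComponent],
    quant_components: Sequence[BipartiteComponent],
) -> DegradationReport:
    """Compare database-level and quantitative-level component sets.

    Going from theoretical to measured peptides, graphs fall apart (the
    single-protein-graph proportion rises) while protein nodes lose their
    unique peptides (the only-shared proportion rises); both effects are
    reported as quant − database deltas.
    """
    db_s, q_s = _single_prop(db_components), _single_prop(quant_components)
    db_o, q_o = _only_shared_prop(db_components), _only_shared_prop(quant_components)
    return DegradationReport(
        db_single_protein_graph_prop=db_s,
        quant_single_protein_graph_prop=q_s,
        delta_single_protein_graph_prop=q_s - db_s,
        db_only_shared_protein_prop=db_o,
        quant_only_shared_protein_prop=q_o,
        delta_only_shared_protein_prop=q_o - db_o,
    )
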