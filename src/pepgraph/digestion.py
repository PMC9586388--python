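"""In silico tryptic digestion of protein databases.

Trypsin cleaves C-terminally of lysine (K) and arginine (R) unless the next
residue is proline (P). Peptides with up to ``max_missed`` skipped cleavage
sites are enumerated as concatenations of consecutive fully-cleaved fragments
and filtered to a length window (default 5–50 residues, the range realistic
for bottom-up MS). The result of digesting a whole database is the
peptide → protein-accession map that serves as the uncollapsed biadjacency of
the bipartite peptide–protein graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .fasta_io import ProteinRecord

__all__ = [
    "DigestConfig",
    "Peptide",
    "PeptideProteinMap",
    "cleavage_sites",
    "digest",
    "digest_database",
]


@dataclass(frozen=True)
class DigestConfig:
    """Digestion parameters.

    min_len / max_len
        Inclusive peptide length bounds in amino acids. Defaults 7 and 50.
    max_missed
        Maximum number of internal cleavage sites a peptide may span.
    enzyme
        Only ``"trypsin-no-P"`` (no cleavage before proline) is defined.
    """

    min_len: int = 7
    max_len: int = 50
    max_missed: int = 2
    enzyme: str = "trypsin-no-P"

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(f"need 1 <= min_len <= max_len, got {self}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.enzyme != "trypsin-no-P":
            raise ValueError(f"unknown enzyme rule {self.enzyme!r}")


@dataclass(frozen=True)
class Peptide:
    sequence: str
    missed_cleavages: int


def cleavage_sites(sequence: str) -> List[int]:
    """1-based positions after which trypsin cuts (K/R not followed by P).

    The C-terminus is never a cleavage site.
    """
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, config: DigestConfig) -> Set[Peptide]:
    """All tryptic peptides of one sequence under ``config``.

    Peptides with k missed cleavages are concatenations of k+1 consecutive
    fully-cleaved fragments; identical sequences arising at several positions
    are emitted once with the smallest k.
    """
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    n_frag = len(bounds) - 1
    best: Dict[str, int] = {}
    for i in range(n_frag):
        for k in range(min(config.max_missed, n_frag - 1 - i) + 1):
            pep = sequence[bounds[i] : bounds[i + k + 1]]
            if config.min_len <= len(pep) <= config.max_len:
                if pep not in best or k < best[pep]:
                    best[pep] = k
    return {Peptide(seq, k) for seq, k in best.items()}


@dataclass
class PeptideProteinMap:
    """Peptide sequence → set of protein accessions (uncollapsed biadjacency).

    ``included_accessions`` and ``excluded_accessions`` partition the source
    database: an accession is excluded when it yields no surviving peptide
    (or is a skipped decoy). ``missed_cleavages`` carries the minimum missed-
    cleavage count per peptide where known (empty for quant-derived maps).
    """

    entries: Dict[str, FrozenSet[str]]
    included_accessions: Tuple[str, ...]
    excluded_accessions: Tuple[str, ...] = ()
    missed_cleavages: Dict[str, int] = field(default_factory=dict)
    config: Optional[DigestConfig] = None

    def __post_init__(self) -> None:
        for pep, accs in self.entries.items():
            if not accs:
                raise ValueError(f"peptide {pep!r} maps to no accession")

    @property
    def n_peptides(self) -> int:
        return len(self.entries)

    def accessions_of(self, peptide: str) -> FrozenSet[str]:
        return self.entries[peptide]

    def restrict(self, peptides: Sequence[str]) -> "PeptideProteinMap":
        """Sub-map over the given peptide sequences (unknown ones dropped).

        Accessions losing all peptides move to ``excluded_accessions``; used
        to go from database level to the level of quantified peptides.
        """
        keep = {p: self.entries[p] for p in peptides if p in self.entries}
        covered = set().union(*keep.values()) if keep else set()
        included = tuple(a for a in self.included_accessions if a in covered)
        excluded = tuple(
            a
            for a in list(self.included_accessions) + list(self.excluded_accessions)
            if a not in covered
        )
        mc = {p: self.missed_cleavages[p] for p in keep if p in self.missed_cleavages}
        return PeptideProteinMap(keep, included, excluded, mc, self.config)


def digest_database(
    records: Sequence[ProteinRecord],
    config: DigestConfig,
    include_decoys: bool = False,
) -> PeptideProteinMap:
    """Digest every record and invert to the peptide → accessions map.

    Decoy records are skipped unless ``include_decoys``; skipped decoys are
    reported under ``excluded_accessions`` so that every source accession is
    accounted for exactly once.
    """
    seen = set()
    for r in records:
        if r.accession in seen:
            raise ValueError(f"duplicate accession {r.accession!r}")
        seen.add(r.accession)

    entries: Dict[str, Set[str]] = {}
    missed: Dict[str, int] = {}
    included: List[str] = []
    excluded: List[str] = []
    for rec in records:
        if rec.is_decoy and not include_decoys:
            excluded.append(rec.accession)
            continue
        peps = digest(rec.sequence, config)
        if not peps:
            excluded.append(rec.accession)
            continue
        included.append(rec.accession)
        for pep in peps:
            entries.setdefault(pep.sequence, set()).add(rec.accession)
            k = missed.get(pep.sequence)
            if k is None or pep.missed_cleavages < k:
                missed[pep.sequence] = pep.missed_cleavages
    return PeptideProteinMap(
        entries={p: frozenset(a) for p, a in entries.items()},
        included_accessions=tuple(included),
        excluded_accessions=tuple(excluded),
        missed_cleavages=missed,
        config=config,
    )
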