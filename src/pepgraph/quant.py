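"""Preprocessing of quantitative peptide-level tables.

Turns a measured peptide intensity table (label-free quantification, one
column per sample) into, per pairwise comparison of experimental states, the
set of peptides with a valid between-state ratio. The processing follows the
usual peptide-level conventions: rows exclusively matching decoy proteins are
dropped, intensities of modification variants of the same sequence are
summed, zero intensities become missing values, replicates of a state are
averaged only when enough of them are observed, and a ratio is valid only
when both state means exist.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .digestion import DigestConfig, PeptideProteinMap
from .fasta_io import ProteinRecord

__all__ = [
    "QuantTable",
    "ComparisonRatios",
    "aggregate_ptm_rows",
    "filter_quant_peptides",
    "map_quant_peptides",
    "aggregate_replicates",
    "compute_ratios",
    "enumerate_comparisons",
    "read_quant_table",
    "read_maxquant_peptides",
]

logger = logging.getLogger(__name__)


@dataclass
class QuantTable:
    """Peptide intensities plus the sample → (state, replicate) design.

    ``intensities`` is indexed by peptide sequence (or by a
    (sequence, modification) MultiIndex before PTM aggregation) with one
    column per sample; missing values are NaN. ``decoy_only`` flags rows whose
    every protein match is a decoy.
    """

    intensities: pd.DataFrame
    design: Dict[str, Tuple[str, int]]
    decoy_only: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [c for c in self.intensities.columns if c not in self.design]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        if self.decoy_only is None:
            self.decoy_only = pd.Series(False, index=self.intensities.index)
        if (self.intensities.fillna(0) < 0).any().any():
            raise ValueError("negative intensities")

    @property
    def states(self) -> List[str]:
        return sorted({s for s, _ in self.design.values()})

    def samples_of(self, state: str) -> List[str]:
        cols = [c for c in self.intensities.columns if self.design[c][0] == state]
        if not cols:
            raise ValueError(f"unknown state {state!r}")
        return cols

    @property
    def sequences(self) -> List[str]:
        idx = self.intensities.index
        if isinstance(idx, pd.MultiIndex):
            return list(dict.fromkeys(idx.get_level_values(0)))
        return list(idx)


@dataclass
class ComparisonRatios:
    """Per-peptide intensity ratios for one ordered state pair (A, B).

    ``ratios[p] = mean_A(p) / mean_B(p)``, NaN when either state mean is
    missing; ``valid_peptides`` are exactly the non-NaN keys.
    """

    comparison: Tuple[str, str]
    ratios: pd.Series

    @property
    def valid_peptides(self) -> List[str]:
        return list(self.ratios.dropna().index)


def aggregate_ptm_rows(table: QuantTable) -> QuantTable:
    """Sum modification variants of the same sequence, per sample.

    Missing values count as zero in the sum unless every variant is missing
    in that sample, in which case the result stays missing.
    """
    idx = table.intensities.index
    if not isinstance(idx, pd.MultiIndex):
        return table
    summed = table.intensities.groupby(level=0, sort=False).sum(min_count=1)
    decoy = table.decoy_only.groupby(level=0, sort=False).all()
    return QuantTable(summed, dict(table.design), decoy.loc[summed.index])


def filter_quant_peptides(table: QuantTable, config: DigestConfig) -> QuantTable:
    """Drop decoy-only rows and out-of-length sequences; zeros become NaN."""
    inten = table.intensities.replace(0, np.nan)
    keep = ~table.decoy_only.to_numpy()
    lengths = pd.Index(
        [len(s) for s in (
            inten.index.get_level_values(0)
            if isinstance(inten.index, pd.MultiIndex)
            else inten.index
        )]
    )
    keep &= (lengths >= config.min_len) & (lengths <= config.max_len)
    out = inten.loc[keep]
    logger.info(
        "quant filter: %d of %d rows kept (length in [%d, %d], non-decoy)",
        len(out), len(inten), config.min_len, config.max_len,
    )
    return QuantTable(out, dict(table.design), table.decoy_only.loc[keep])


def _kmer_index(records: Sequence[ProteinRecord], k: int) -> Dict[str, Set[int]]:
    index: Dict[str, Set[int]] = {}
    for i, rec in enumerate(records):
        seq = rec.sequence
        for j in range(len(seq) - k + 1):
            index.setdefault(seq[j : j + k], set()).add(i)
    return index


def map_quant_peptides(
    sequences: Sequence[str],
    records: Sequence[ProteinRecord],
) -> PeptideProteinMap:
    """Map peptide sequences to every non-decoy protein containing them.

    Matching is plain substring containment against the full database (a
    k-mer prefix index only prunes candidates; results equal a naive scan).
    Peptides matching no protein are logged and excluded from the map.
    """
    targets = [r for r in records if not r.is_decoy]
    if not targets:
        raise ValueError("no non-decoy records to map against")
    k = min(5, min((len(s) for s in sequences), default=5))
    index = _kmer_index(targets, k)
    entries: Dict[str, FrozenSet[str]] = {}
    unmapped = 0
    for pep in dict.fromkeys(sequences):
        cand = index.get(pep[:k], ())
        hits = frozenset(
            targets[i].accession for i in cand if pep in targets[i].sequence
        )
        if hits:
            entries[pep] = hits
        else:
            unmapped += 1
    if unmapped:
        logger.info("map_quant_peptides: %d peptides had no database match", unmapped)
    covered = set().union(*entries.values()) if entries else set()
    included = tuple(r.accession for r in targets if r.accession in covered)
    excluded = tuple(
        r.accession for r in records if r.accession not in covered
    )
    return PeptideProteinMap(entries, included, excluded)


def aggregate_replicates(
    values: Sequence[float], min_valid: int = 2
) -> float:
    """Mean of the observed replicate intensities, or NaN.

    Returns the arithmetic mean of the non-missing values when at least
    ``min_valid`` of them are observed (the triplicate rule: two or more
    missing out of three → missing), otherwise NaN.
    """
    if min_valid < 1:
        raise ValueError("min_valid must be >= 1")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one replicate value")
    obs = arr[~np.isnan(arr)]
    if obs.size < min_valid:
        return math.nan
    return float(obs.mean())


def _state_means(table: QuantTable, state: str, min_valid: int) -> pd.Series:
    sub = table.intensities[table.samples_of(state)]
    counts = sub.notna().sum(axis=1)
    means = sub.mean(axis=1)
    return means.where(counts >= min_valid)


def compute_ratios(
    table: QuantTable,
    state_a: str,
    state_b: str,
    min_valid: int = 2,
) -> ComparisonRatios:
    """Peptide ratios mean(state_a) / mean(state_b); NaN if either is missing."""
    mean_a = _state_means(table, state_a, min_valid)
    mean_b = _state_means(table, state_b, min_valid)
    ratios = mean_a / mean_b
    return ComparisonRatios((state_a, state_b), ratios)


def enumerate_comparisons(states: Sequence[str]) -> List[Tuple[str, str]]:
    """All unordered state pairs, numerator = earlier state in sort order."""
    return list(combinations(sorted(set(states)), 2))


def read_quant_table(
    path: Union[str, Path],
    design: Mapping[str, Tuple[str, int]],
    sequence_col: str = "sequence",
    sample_cols: Optional[Mapping[str, str]] = None,
    modification_col: Optional[str] = None,
    decoy_only_col: Optional[str] = None,
    sep: Optional[str] = None,
) -> QuantTable:
    """Generic wide-format reader.

    ``design`` maps sample names to (state, replicate); ``sample_cols`` maps
    sample names to table columns (default: identical). ``decoy_only_col``
    names a boolean-like column flagging rows matched only by decoys.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    sample_cols = dict(sample_cols) if sample_cols else {s: s for s in design}
    missing = [c for c in sample_cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    if modification_col is not None:
        idx = pd.MultiIndex.from_arrays(
            [df[sequence_col], df[modification_col].fillna("")],
            names=["sequence", "modification"],
        )
    else:
        idx = pd.Index(df[sequence_col], name="sequence")
    inten = df[[sample_cols[s] for s in design]].copy()
    inten.columns = list(design)
    inten.index = idx
    inten = inten.apply(pd.to_numeric, errors="coerce")
    if decoy_only_col is not None:
        decoy = df[decoy_only_col].fillna(False).astype(bool)
        decoy.index = idx
    else:
        decoy = pd.Series(False, index=idx)
    return QuantTable(inten, dict(design), decoy)


def read_maxquant_peptides(
    path: Union[str, Path],
    design: Mapping[str, Tuple[str, int]],
    intensity_prefix: str = "Intensity ",
) -> QuantTable:
    """Preset for MaxQuant ``peptides.txt``-style tables.

    Uses the ``Sequence`` column, per-sample ``Intensity <sample>`` columns
    and flags rows with ``Reverse == '+'`` as decoy-only (MaxQuant sums PTM
    variants internally, so no modification level is kept).
    """
    table = read_quant_table(
        path,
        design,
        sequence_col="Sequence",
        sample_cols={s: f"{intensity_prefix}{s}" for s in design},
        decoy_only_col=None,
        sep="\t",
    )
    df = pd.read_csv(path, sep="\t")
    if "Reverse" in df.columns:
        table.decoy_only = pd.Series(
            (df["Reverse"].fillna("") == "+").to_numpy(),
            index=table.intensities.index,
        )
    return table
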