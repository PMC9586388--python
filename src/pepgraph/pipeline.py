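"""End-to-end runs: database level and quantitative level.

``run_fasta_level`` executes read → digest → collapse → components →
classify → summarize for a protein database. ``run_quant_level`` additionally
preprocesses a peptide intensity table, builds one component set per pairwise
state comparison from the peptides with a valid ratio, and pools the
components of all comparisons into one jointly analysed multiset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import characterize, graphs, isomorphism, quant
from .digestion import DigestConfig, PeptideProteinMap, digest_database
from .fasta_io import DEFAULT_DECOY_PREFIX, read_fasta

__all__ = [
    "RunConfig",
    "FastaLevelResult",
    "QuantLevelResult",
    "StageError",
    "run_fasta_level",
    "run_quant_level",
    "write_class_table",
    "write_summary",
]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    fasta: str
    quant_table: Optional[str] = None
    min_len: int = 7
    max_len: int = 50
    max_missed: int = 2
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    design: Dict[str, List] = field(default_factory=dict)  # sample -> [state, rep]
    min_valid: int = 2
    sequence_col: str = "sequence"
    modification_col: Optional[str] = None
    decoy_only_col: Optional[str] = None
    out_dir: Optional[str] = None
    seed: int = 0

    @property
    def digest_config(self) -> DigestConfig:
        return DigestConfig(self.min_len, self.max_len, self.max_missed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class FastaLevelResult:
    pmap: PeptideProteinMap
    components: List[graphs.BipartiteComponent]
    classes: List[isomorphism.IsomorphismClass]
    summary: characterize.DatasetSummary


@dataclass
class QuantLevelResult:
    comparisons: List[Tuple[str, str]]
    per_comparison: Dict[Tuple[str, str], List[graphs.BipartiteComponent]]
    pooled_components: List[graphs.BipartiteComponent]
    classes: List[isomorphism.IsomorphismClass]
    summary: characterize.DatasetSummary


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_fasta_level(config: RunConfig) -> FastaLevelResult:
    """Database-level pipeline; raises :class:`StageError` naming the stage."""
    records = _stage("fasta_io")(read_fasta)(config.fasta, config.decoy_prefix)
    if not records:
        raise StageError("fasta_io", ValueError(f"empty database {config.fasta!r}"))
    logger.info("fasta_io: %d records", len(records))
    pmap = _stage("digestion")(digest_database)(records, config.digest_config)
    logger.info(
        "digestion: %d peptides, %d included / %d excluded accessions",
        pmap.n_peptides, len(pmap.included_accessions), len(pmap.excluded_accessions),
    )
    components = _stage("graph_builder")(graphs.components_from_map)(pmap)
    logger.info("graph_builder: %d components", len(components))
    classes = _stage("isomorphism")(isomorphism.classify_components)(components)
    logger.info("isomorphism: %d classes", len(classes))
    summary = _stage("characterize")(characterize.summarize)(
        components, classes, pmap
    )
    return FastaLevelResult(pmap, components, classes, summary)


def run_quant_level(config: RunConfig) -> QuantLevelResult:
    """Quantitative-level pipeline over all pairwise state comparisons.

    Per comparison only peptides with a valid ratio enter the graph; the
    resulting component sets are pooled as a multiset and classified jointly.
    """
    if config.quant_table is None:
        raise StageError("quant_processing", ValueError("no quant table configured"))
    records = _stage("fasta_io")(read_fasta)(config.fasta, config.decoy_prefix)
    design = {s: (st, int(r)) for s, (st, r) in config.design.items()}
    table = _stage("quant_processing")(quant.read_quant_table)(
        config.quant_table,
        design,
        sequence_col=config.sequence_col,
        modification_col=config.modification_col,
        decoy_only_col=config.decoy_only_col,
    )
    table = quant.aggregate_ptm_rows(table)
    table = quant.filter_quant_peptides(table, config.digest_config)
    pmap = _stage("quant_processing")(quant.map_quant_peptides)(
        table.sequences, records
    )
    comparisons = quant.enumerate_comparisons(table.states)
    logger.info("quant_processing: %d comparisons", len(comparisons))
    per_comparison: Dict[Tuple[str, str], List[graphs.BipartiteComponent]] = {}
    pooled: List[graphs.BipartiteComponent] = []
    for a, b in comparisons:
        ratios = _stage("quant_processing")(quant.compute_ratios)(
            table, a, b, config.min_valid
        )
        sub = pmap.restrict(ratios.valid_peptides)
        comps = _stage("graph_builder")(graphs.components_from_map)(sub)
        per_comparison[(a, b)] = comps
        pooled.extend(comps)
    pooled.sort(key=graphs.BipartiteComponent.sort_key)
    classes = _stage("isomorphism")(isomorphism.classify_components)(pooled)
    summary = _stage("characterize")(characterize.summarize)(pooled, classes)
    return QuantLevelResult(comparisons, per_comparison, pooled, classes, summary)


def write_class_table(
    classes: Sequence[isomorphism.IsomorphismClass], path
) -> pd.DataFrame:
    """Rank / count / percentage / size-signature table, also written as TSV."""
    total = sum(c.count for c in classes)
    rows = [
        {
            "rank": i + 1,
            "count": c.count,
            "percentage": round(c.percentage(total), 4),
            "protein_nodes": c.size_signature[0],
            "peptide_nodes": c.size_signature[1],
            "unique_peptide_nodes": c.size_signature[2],
            "shared_peptide_nodes": c.size_signature[3],
            "edges": c.size_signature[4],
            "key_hash": f"{hash(c.key) & 0xFFFFFFFF:08x}",
        }
        for i, c in enumerate(classes)
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "rank", "count", "percentage", "protein_nodes", "peptide_nodes",
            "unique_peptide_nodes", "shared_peptide_nodes", "edges", "key_hash",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_summary(summary: characterize.DatasetSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
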