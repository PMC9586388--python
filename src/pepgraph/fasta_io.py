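"""Reading and writing protein sequence databases in FASTA format.

Headers following the UniProt convention (``db|ACCESSION|ENTRY description``)
are split into accession, entry name and free-text description; any other
header contributes its first whitespace-delimited token as the accession.
Decoy entries are recognised by a configurable prefix on the first header
token (decoys matter only when cleaning quantitative peptide tables; the
sequence databases analysed here contain none).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["ProteinRecord", "base_accession", "read_fasta", "write_fasta"]

DEFAULT_DECOY_PREFIX = "DECOY_"

_ISOFORM_SUFFIX = re.compile(r"-\d+$")
_VALID_SEQ = re.compile(r"^[A-Z]+$")


def base_accession(accession: str) -> str:
    """Strip a trailing UniProt isoform suffix (``P12345-2`` -> ``P12345``).

    Accessions without a ``-<digits>`` suffix are returned unchanged.
    """
    if not accession:
        raise ValueError("empty accession")
    return _ISOFORM_SUFFIX.sub("", accession)


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry.

    ``base_accession`` groups isoforms under their canonical parent; it equals
    ``accession`` whenever no isoform suffix is present.
    """

    accession: str
    sequence: str
    entry_name: str = ""
    description: str = ""
    is_decoy: bool = False
    base_accession: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_accession", base_accession(self.accession))
        if not self.sequence:
            raise ValueError(f"entry {self.accession!r} has an empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set(map(chr, range(65, 91))))
            raise ValueError(
                f"entry {self.accession!r} contains invalid characters: {bad}"
            )


def _parse_header(first_token: str, rest: str, decoy_prefix: str):
    is_decoy = bool(decoy_prefix) and first_token.startswith(decoy_prefix)
    parts = first_token.split("|")
    if len(parts) >= 3 and parts[1]:
        # UniProt-style "db|ACC|NAME"; a decoy prefix sits on the db tag.
        return parts[1], parts[2], rest, is_decoy
    return first_token, "", rest, is_decoy


def read_fasta(
    path: Union[str, Path],
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> List[ProteinRecord]:
    """Parse a FASTA database into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased and a trailing ``*`` (stop codon from six-frame
    translations) is stripped. Duplicate accessions, empty sequences and
    residues outside ``A``–``Z`` raise :class:`ValueError`.
    """
    records: List[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        first, _, rest = desc.partition(" ")
        accession, entry_name, description, is_decoy = _parse_header(
            first, rest.strip(), decoy_prefix
        )
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=seq,
                entry_name=entry_name,
                description=description,
                is_decoy=is_decoy,
            )
        )
    return records


def _format_header(record: ProteinRecord, decoy_prefix: str) -> str:
    if record.entry_name:
        db = f"{decoy_prefix}sp" if record.is_decoy else "sp"
        head = f"{db}|{record.accession}|{record.entry_name}"
    else:
        head = record.accession  # simple headers carry any decoy prefix themselves
    if record.description:
        head = f"{head} {record.description}"
    return head


def write_fasta(
    records: Iterable[ProteinRecord],
    path: Union[str, Path],
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    width: int = 60,
) -> None:
    """Write records so that :func:`read_fasta` round-trips them exactly."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id="", description=_format_header(r, decoy_prefix))
        for r in records
    ]
    with open(path, "w") as handle:
        for sr in seq_records:
            handle.write(f">{sr.description}\n")
            seq = str(sr.seq)
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
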