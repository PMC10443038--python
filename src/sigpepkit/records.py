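"""Core sequence record types and FASTA I/O.

A signal peptide (SP) is the short N-terminal stretch that targets a nascent
polypeptide to the endoplasmic reticulum.  Records carry an origin tag so that
host-homologous, literature-mined, synthetic and control elements can be
distinguished throughout the toolkit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Origin(str, enum.Enum):
    """Provenance of a signal peptide element."""

    CHO_HOMOLOGOUS = "CHO_homologous"
    LITERATURE = "literature"
    SYNTHETIC = "synthetic"
    CONTROL = "control"


class InvalidResidueError(ValueError):
    """Raised when a sequence contains a non-standard amino-acid letter."""


def validate_sequence(sequence: str) -> str:
    """Upper-case *sequence* and reject anything outside the 20 standard residues.

    Ambiguity codes (X, B, Z, ...) are rejected: downstream physicochemical
    parameters and membership checks are undefined for them.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted(set(seq) - STANDARD_RESIDUES)
    if bad:
        raise InvalidResidueError(f"invalid residue(s) {''.join(bad)} in {sequence!r}")
    return seq


@dataclass(frozen=True)
class SignalPeptideRecord:
    """An identified signal-peptide amino-acid sequence.

    Parameters
    ----------
    id : short unique label (e.g. ``"E12"``, ``"NS1"``).
    sequence : uppercase amino-acid string over the 20 standard residues.
    origin : provenance tag.
    note : free text.
    ambiguous : True when the printed source sequence is not a single concrete
        string; such records are excluded from computations that need one.
    """

    id: str
    sequence: str
    origin: Origin = Origin.LITERATURE
    note: str = ""
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.ambiguous:
            object.__setattr__(self, "sequence", validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, origin: Origin = Origin.LITERATURE) -> list[SignalPeptideRecord]:
    """Read signal peptides from a FASTA file; the id is the first header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SignalPeptideRecord(id=rec.id, sequence=str(rec.seq), origin=origin))
    return records


def write_fasta(records: Iterable[SignalPeptideRecord | tuple[str, str]], path: str | Path) -> None:
    """Write records (or plain ``(id, sequence)`` pairs) as FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, SignalPeptideRecord):
            rid, seq, desc = rec.id, rec.sequence, rec.origin.value
        else:
            rid, seq = rec
            desc = ""
        out.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(out, str(path), "fasta")
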