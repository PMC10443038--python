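"""Tripartite N/H/C decomposition of signal peptides.

Signal peptides share a tripartite architecture: a short, often basic
N-region starting at the initiator methionine, a hydrophobic core H-region,
and a slightly polar C-region ending at the cleavage site.  The H-region is
located with a sliding 6-residue window: the first and last windows holding
at least four hydrophobic residues mark its approximate beginning and end.
The first residue is reserved as the minimal N-region and the final three
residues as the minimal C-region, so windows are searched strictly between
them.  Because a window may qualify while overlapping up to two flanking
non-hydrophobic residues, the window hull is trimmed to hydrophobic residues
at both ends; the flanks on either side become the N- and C-regions.

Partitions are validated against three design-rule bounds:

i.   the N-region starts with M and is at most 10 residues;
ii.  the H-region is 6-12 residues, every 6-block (tiled from the left)
     holding >= 4 hydrophobic residues, a trailing partial block pro-rata;
iii. the C-region is 3-10 residues.

Natural signal peptides frequently breach these synthetic-design bounds, so
violations are reported as flags rather than errors (strict mode raises).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .records import SignalPeptideRecord, validate_sequence

#: The nine hydrophobic residues used for H-region identification.
HYDROPHOBIC: frozenset[str] = frozenset("FIWLVMAYC")

WINDOW = 6            # sliding-window width
MIN_HYDRO = 4         # hydrophobic residues required per qualifying window
MIN_N_RESERVED = 1    # leading residues reserved as minimal N-region
MIN_C_RESERVED = 3    # trailing residues reserved as minimal C-region

N_MAX = 10
H_MIN, H_MAX = 6, 12
C_MIN, C_MAX = 3, 10


class DecompositionError(ValueError):
    """Raised when a sequence cannot be partitioned into N/H/C regions."""


@dataclass(frozen=True)
class DomainPartition:
    """An N/H/C split of a signal peptide with rule-violation flags."""

    n_region: str
    h_region: str
    c_region: str
    violations: tuple[str, ...] = field(default_factory=tuple)

    @property
    def sequence(self) -> str:
        return self.n_region + self.h_region + self.c_region

    @property
    def is_valid(self) -> bool:
        return not self.violations


def _hydro_count(window: str) -> int:
    return sum(1 for aa in window if aa in HYDROPHOBIC)


def find_h_span(sequence: str, trim: bool = True) -> tuple[int, int] | None:
    """Locate the H-region of *sequence* as a half-open index interval.

    The search region excludes position 0 and the final three positions.
    Returns ``None`` when no 6-mer in the search region holds >= 4
    hydrophobic residues.  With ``trim`` (default) non-hydrophobic residues
    are stripped from both ends of the window hull, so the returned span
    begins and ends on hydrophobic residues.
    """
    seq = validate_sequence(sequence)
    if len(seq) < MIN_N_RESERVED + WINDOW + MIN_C_RESERVED:
        raise DecompositionError(f"sequence of length {len(seq)} too short to partition")
    if seq[0] != "M":
        raise DecompositionError("sequence must start with M")

    lo, hi = MIN_N_RESERVED, len(seq) - MIN_C_RESERVED
    starts = [s for s in range(lo, hi - WINDOW + 1) if _hydro_count(seq[s : s + WINDOW]) >= MIN_HYDRO]
    if not starts:
        return None
    begin, end = starts[0], starts[-1] + WINDOW
    if trim:
        while seq[begin] not in HYDROPHOBIC:
            begin += 1
        while seq[end - 1] not in HYDROPHOBIC:
            end -= 1
    return begin, end


def validate_partition(partition: DomainPartition) -> list[str]:
    """Return every breach of the N/H/C design rules (empty list if none)."""
    n, h, c = partition.n_region, partition.h_region, partition.c_region
    violations = []
    if not n.startswith("M"):
        violations.append("N does not start with M")
    if len(n) > N_MAX:
        violations.append(f"N exceeds {N_MAX}")
    if len(h) < H_MIN:
        violations.append(f"H shorter than {H_MIN}")
    if len(h) > H_MAX:
        violations.append(f"H exceeds {H_MAX}")
    for i in range(0, len(h), WINDOW):
        block = h[i : i + WINDOW]
        # trailing partial block is assessed pro-rata: ceil(4 * len / 6)
        need = MIN_HYDRO if len(block) == WINDOW else math.ceil(MIN_HYDRO * len(block) / WINDOW)
        if _hydro_count(block) < need:
            violations.append(f"H block {i}-{i + len(block)} has <{need} hydrophobic residues")
    if len(c) < C_MIN:
        violations.append(f"C shorter than {C_MIN}")
    if len(c) > C_MAX:
        violations.append(f"C exceeds {C_MAX}")
    return violations


def decompose(record: SignalPeptideRecord | str, strict: bool = False) -> DomainPartition:
    """Split a signal peptide into its N-, H- and C-regions.

    Accepts a record or a bare sequence.  Regions either side of the located
    H-span become the N- and C-regions.  Rule breaches are attached as
    ``violations``; with ``strict=True`` any breach raises instead.
    """
    seq = record.sequence if isinstance(record, SignalPeptideRecord) else record
    seq = validate_sequence(seq)
    span = find_h_span(seq)
    if span is None:
        raise DecompositionError("no H-domain found")
    begin, end = span
    partition = DomainPartition(seq[:begin], seq[begin:end], seq[end:])
    violations = tuple(validate_partition(partition))
    partition = DomainPartition(partition.n_region, partition.h_region, partition.c_region, violations)
    if strict and violations:
        raise DecompositionError("; ".join(violations))
    return partition
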