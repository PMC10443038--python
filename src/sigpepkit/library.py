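"""Combinatorial synthetic signal-peptide library.

Synthetic domains are built from per-position residue alphabets derived from
conservation in experimentally verified human/mouse signal peptides:

* N-domain (5 positions): M, then four positions over {K, T, A, G, S, P, R}
  (residues conserved at >= 20% at positions -21..-18, last residue = -1);
* H-domain (12 positions): eleven positions over the conserved core residues
  {L, A, V}, then a final helix-breaking position over {P, G};
* C-domain (5 positions): small-residue rules give {A,G,S,L,V,I},
  {A,G,S,T,C}, {A,G,S}, {A,G,S,C}, {A,G,S,T} at positions -5..-1.

The Cartesian products give 2401 N-, 354,294 H- and 1440 C-domains, and a
fully assembled 22-mer design space of ~1.2e12 sequences.  The space is
never materialised: enumeration streams per-domain, membership is a
positional check, and sampling draws index tuples directly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

from .records import validate_sequence

Region = Literal["N", "H", "C"]

#: Fixed residue order for lexicographic, bit-reproducible enumeration.
RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _canon(residues: str) -> tuple[str, ...]:
    return tuple(sorted(set(residues), key=RESIDUE_ORDER.index))


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Per-position residue alphabets for the synthetic N-, H- and C-domains."""

    n_alphabets: tuple[tuple[str, ...], ...]
    h_alphabets: tuple[tuple[str, ...], ...]
    c_alphabets: tuple[tuple[str, ...], ...]

    @property
    def length(self) -> int:
        return len(self.n_alphabets) + len(self.h_alphabets) + len(self.c_alphabets)

    def alphabets(self, region: Region | None = None) -> tuple[tuple[str, ...], ...]:
        if region is None:
            return self.n_alphabets + self.h_alphabets + self.c_alphabets
        return {"N": self.n_alphabets, "H": self.h_alphabets, "C": self.c_alphabets}[region]


@dataclass(frozen=True)
class LibraryCounts:
    n_count: int
    h_count: int
    c_count: int

    @property
    def total(self) -> int:
        return self.n_count * self.h_count * self.c_count


def default_library_spec() -> SyntheticLibrarySpec:
    """The published synthetic-library alphabets (assembled length 22)."""
    return SyntheticLibrarySpec(
        n_alphabets=(_canon("M"),) + (_canon("KTAGSPR"),) * 4,
        h_alphabets=(_canon("LAV"),) * 11 + (_canon("PG"),),
        c_alphabets=(
            _canon("AGSLVI"),
            _canon("AGSTC"),
            _canon("AGS"),
            _canon("AGSC"),
            _canon("AGST"),
        ),
    )


def library_counts(spec: SyntheticLibrarySpec) -> LibraryCounts:
    """Per-region domain counts (products of per-position alphabet sizes)."""
    counts = []
    for region in "NHC":
        sizes = [len(a) for a in spec.alphabets(region)]  # type: ignore[arg-type]
        if any(s == 0 for s in sizes):
            raise ValueError("degenerate spec: empty alphabet")
        counts.append(math.prod(sizes))
    return LibraryCounts(*counts)


def iter_domains(spec: SyntheticLibrarySpec, region: Region) -> Iterator[str]:
    """Stream a region's domains in lexicographic (position-wise alphabet) order."""
    for combo in itertools.product(*spec.alphabets(region)):
        yield "".join(combo)


def enumerate_domains(spec: SyntheticLibrarySpec, region: Region) -> list[str]:
    """Materialise a region's full domain list (caller must know it fits)."""
    return list(iter_domains(spec, region))


def is_member(sequence: str, spec: SyntheticLibrarySpec | None = None) -> tuple[bool, list[int]]:
    """Positional membership check against the assembled library alphabets.

    Returns ``(member, failing_positions)`` where failing positions are
    0-based; a wrong length reports every out-of-range position as failing
    (-1 marks a length mismatch itself).
    """
    spec = spec or default_library_spec()
    seq = validate_sequence(sequence)
    alphabets = spec.alphabets()
    failures = []
    if len(seq) != len(alphabets):
        failures.append(-1)
    for i, (aa, alphabet) in enumerate(zip(seq, alphabets)):
        if aa not in alphabet:
            failures.append(i)
    return (not failures, failures)


def position_to_index(position: int, length: int = 22) -> int:
    """Convert a -k signal-peptide position (last residue = -1) to a 0-based index."""
    if not -length <= position <= -1:
        raise ValueError(f"position {position} outside -{length}..-1")
    return length + position


def index_to_position(index: int, length: int = 22) -> int:
    """Convert a 0-based index to the -k position convention."""
    if not 0 <= index < length:
        raise ValueError(f"index {index} outside 0..{length - 1}")
    return index - length


def sample_sequences(
    spec: SyntheticLibrarySpec, n: int, seed: int, region: Region | None = None
) -> list[str]:
    """Draw *n* distinct member sequences uniformly, without replacement.

    Index tuples are drawn directly from the Cartesian product, so the full
    design space is never materialised.  Identical seeds give identical
    samples.
    """
    alphabets = spec.alphabets(region)
    sizes = [len(a) for a in alphabets]
    total = math.prod(sizes)
    if n > total:
        raise ValueError(f"sample of {n} larger than library of {total}")
    rng = np.random.default_rng(seed)
    if total <= 1_000_000 and n > total // 2:
        # dense draw: rejection sampling would stall near exhaustion
        flat = rng.choice(total, size=n, replace=False)
        chosen = {tuple(np.unravel_index(int(f), sizes)) for f in flat}
    else:
        chosen = set()
        while len(chosen) < n:
            draw = tuple(int(rng.integers(0, s)) for s in sizes)
            chosen.add(draw)
    # sorted for a deterministic, order-independent result
    return ["".join(alphabets[i][j] for i, j in enumerate(t)) for t in sorted(chosen)]
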