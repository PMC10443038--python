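"""Adapters for external signal-peptide predictor output, plus a naive scorer.

External predictors (SignalP-family tools) are license-restricted and never
bundled; this module parses their short tabular output dialects and applies
the 0.7 probability cut-off used for candidate filtering.  Both threshold
semantics are exposed: ``strict`` keeps probability > threshold (the
SignalP6-style rule) and non-strict keeps >= threshold (the SignalP4
D-score rule) — the two scores are produced by different models and are not
interchangeable, only their cut-off convention is shared.

For fully offline runs a clearly labelled naive heuristic scorer is
provided.  It is NOT an implementation or emulation of any external
predictor: it only checks the toolkit's own design rules (M start, a
qualifying hydrophobic window, small residues at the -3/-1 cleavage
positions and no proline in the final three residues).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .decompose import HYDROPHOBIC, MIN_C_RESERVED, MIN_N_RESERVED, WINDOW, MIN_HYDRO, _hydro_count
from .records import validate_sequence

Dialect = Literal["signalp4_short", "signalp6_short"]

#: Residues accepted at the -3 and -1 cleavage-site positions (small/neutral).
SMALL_CLEAVAGE_RESIDUES = frozenset("AGSTCV")


@dataclass(frozen=True)
class PredictorScore:
    """One external-predictor record: id, SP probability, optional cleavage site."""

    sp_id: str
    sp_probability: float
    cleavage_position: int | None = None
    dialect: str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.sp_probability <= 1.0:
            raise ValueError(f"probability {self.sp_probability} outside [0, 1]")


class PredictorTableError(ValueError):
    """Raised when a predictor output table cannot be parsed."""


def _parse_signalp4_row(fields: list[str]) -> tuple[str, float, int | None]:
    # short format: name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut net
    sp_id = fields[0]
    d_score = float(fields[8])
    cleavage = int(fields[4])  # Ymax position marks the predicted cleavage
    return sp_id, d_score, cleavage


def _parse_signalp6_row(fields: list[str]) -> tuple[str, float, int | None]:
    # short format: ID  Prediction  OTHER  SP(Sec/SPI)  [CS Position]
    sp_id = fields[0]
    probability = float(fields[3])
    cleavage = None
    if len(fields) > 4 and fields[4].strip():
        token = fields[4].replace("CS pos:", "").strip()
        cleavage = int(token.split("-")[0])
    return sp_id, probability, cleavage


def parse_predictor_table(path: str | Path, dialect: Dialect) -> list[PredictorScore]:
    """Parse a short-format predictor output table into scores.

    Comment lines (``#``-prefixed) are skipped; malformed rows raise with
    their line number.
    """
    parsers = {"signalp4_short": _parse_signalp4_row, "signalp6_short": _parse_signalp6_row}
    if dialect not in parsers:
        raise PredictorTableError(f"unsupported dialect {dialect!r}")
    parse_row = parsers[dialect]
    scores = []
    sep = None if dialect == "signalp4_short" else "\t"
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            sp_id, prob, cleavage = parse_row(line.split(sep))
            scores.append(PredictorScore(sp_id, prob, cleavage, dialect))
        except (IndexError, ValueError) as exc:
            raise PredictorTableError(f"line {lineno}: {exc}") from exc
    if not scores:
        raise PredictorTableError("empty or malformed table")
    return scores


def filter_candidates(
    scores: Iterable[PredictorScore],
    threshold: float = 0.7,
    strict: bool = True,
    require_cleavage: bool = False,
) -> list[str]:
    """Ids passing the probability cut-off (strict: >, non-strict: >=)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    kept = []
    for score in scores:
        if require_cleavage and score.cleavage_position is None:
            continue
        passes = score.sp_probability > threshold if strict else score.sp_probability >= threshold
        if passes:
            kept.append(score.sp_id)
    return kept


def write_scores(scores: Iterable[PredictorScore], path: str | Path) -> None:
    """Write scores in the signalp6-style tab-separated short format."""
    lines = ["# sigpepkit score table", "# ID\tPrediction\tOTHER\tSP(Sec/SPI)\tCS Position"]
    for s in scores:
        cs = f"CS pos: {s.cleavage_position}" if s.cleavage_position is not None else ""
        lines.append(f"{s.sp_id}\tSP\t{1.0 - s.sp_probability:.6f}\t{s.sp_probability:.6f}\t{cs}")
    Path(path).write_text("\n".join(lines) + "\n")


def naive_sp_score(sequence: str) -> float:
    """Naive in-package heuristic score in [0, 1] (offline stand-in only).

    Additive components: 0.25 for an M start, 0.50 for at least one
    qualifying hydrophobic 6-window in the interior, 0.125 for small
    residues at the -3 and -1 positions, 0.125 for a proline-free final
    three residues.  Documented as non-equivalent to any external tool.
    """
    seq = validate_sequence(sequence)
    score = 0.0
    if seq[0] == "M":
        score += 0.25
    lo, hi = MIN_N_RESERVED, len(seq) - MIN_C_RESERVED
    windows = range(lo, hi - WINDOW + 1)
    if any(_hydro_count(seq[s : s + WINDOW]) >= MIN_HYDRO for s in windows):
        score += 0.50
    if len(seq) >= 3:
        if seq[-3] in SMALL_CLEAVAGE_RESIDUES and seq[-1] in SMALL_CLEAVAGE_RESIDUES:
            score += 0.125
        if "P" not in seq[-3:]:
            score += 0.125
    return min(1.0, score)


def naive_scores(sequences: dict[str, str]) -> list[PredictorScore]:
    """Score a mapping of id -> sequence with the naive heuristic."""
    out = []
    for sp_id, seq in sequences.items():
        score = naive_sp_score(seq)
        cleavage = len(seq) if score >= 0.5 else None
        out.append(PredictorScore(sp_id, score, cleavage, dialect="naive"))
    return out
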