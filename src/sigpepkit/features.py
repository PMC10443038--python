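"""Physicochemical sequence features for signal-peptide / partner contexts.

Seven named parameters describe a sequence context (the signal peptide alone
or concatenated with the first 50 residues of its partner protein):

==================== =========================================================
pi                   isoelectric point, Henderson-Hasselbalch bisection with
                     the Bjellqvist pKa set (pH units)
dipeptide_stability  Guruprasad instability index (DIWV dipeptide weights)
flexibility          mean Vihinen normalised flexibility, window 9
aliphatic_index      Ikai: X(A) + 2.9 X(V) + 3.9 (X(I) + X(L)), mole-percent
gravy                mean Kyte-Doolittle hydropathy
delta_g              sum of per-residue apparent membrane-insertion free
                     energies, Hessa et al. biological scale (kcal/mol)
gp_percent           100 (countG + countP) / length, always computed on the
                     signal peptide alone
==================== =========================================================

pi, dipeptide_stability, flexibility and gravy are delegated to Biopython's
ProtParam; the aliphatic index, the insertion free energy and GP% are
evaluated in-package.  Feature tables are min-max scaled per column with the
ranges retained so the transform is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import Flex as _VIHINEN_FLEX

from .records import SignalPeptideRecord, validate_sequence

FEATURE_NAMES = (
    "pi",
    "dipeptide_stability",
    "flexibility",
    "aliphatic_index",
    "gravy",
    "delta_g",
    "gp_percent",
)

Mode = Literal["concat7", "split14"]

#: Apparent free energy of membrane insertion per residue (kcal/mol),
#: biological scale of Hessa and co-workers.
HESSA_DELTA_G = {
    "A": 0.11, "C": -0.13, "D": 3.49, "E": 2.68, "F": -0.32,
    "G": 0.74, "H": 2.06, "I": -0.60, "K": 2.71, "L": -0.55,
    "M": -0.10, "N": 2.05, "P": 2.23, "Q": 2.36, "R": 2.58,
    "S": 0.84, "T": 0.52, "V": -0.31, "W": 0.30, "Y": 0.68,
}
DELTA_G_SCALE_ID = "hessa2005_biological"

_FLEX_WINDOW = 9


def _flexibility(seq: str) -> float:
    # Vihinen window-9 profile; sequences shorter than one window fall back
    # to the unweighted mean of per-residue scale values.
    if len(seq) < _FLEX_WINDOW:
        return float(np.mean([_VIHINEN_FLEX[aa] for aa in seq]))
    profile = ProteinAnalysis(seq).flexibility()
    return float(np.mean(profile))


def aliphatic_index(seq: str) -> float:
    """Ikai's aliphatic index on mole-percent side-chain composition."""
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def insertion_delta_g(seq: str, scale: dict[str, float] | None = None) -> float:
    """Summed per-residue apparent insertion free energy (kcal/mol)."""
    scale = scale or HESSA_DELTA_G
    return float(sum(scale[aa] for aa in seq))


def gp_percent(seq: str) -> float:
    """Percentage of glycine plus proline residues (0-100)."""
    return 100.0 * (seq.count("G") + seq.count("P")) / len(seq)


def compute_parameter(sequence: str, name: str) -> float:
    """Evaluate one named parameter on *sequence*."""
    seq = validate_sequence(sequence)
    if name == "pi":
        return float(ProteinAnalysis(seq).isoelectric_point())
    if name == "dipeptide_stability":
        return float(ProteinAnalysis(seq).instability_index())
    if name == "flexibility":
        return _flexibility(seq)
    if name == "aliphatic_index":
        return aliphatic_index(seq)
    if name == "gravy":
        return float(ProteinAnalysis(seq).gravy())
    if name == "delta_g":
        return insertion_delta_g(seq)
    if name == "gp_percent":
        return gp_percent(seq)
    raise ValueError(f"unsupported parameter {name!r}")


@dataclass(frozen=True)
class FeatureVector:
    """The seven named parameters for one sequence context."""

    pi: float
    dipeptide_stability: float
    flexibility: float
    aliphatic_index: float
    gravy: float
    delta_g: float
    gp_percent: float
    context: str = "sp_only"

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def _featurize(seq: str, sp_seq: str, context: str) -> FeatureVector:
    values = {name: compute_parameter(seq, name) for name in FEATURE_NAMES if name != "gp_percent"}
    # GP% is defined on the signal peptide only, whatever the context
    values["gp_percent"] = gp_percent(validate_sequence(sp_seq))
    return FeatureVector(context=context, **values)


def featurize_pair(
    sp: SignalPeptideRecord | str,
    partner_prefix: str = "",
    mode: Mode = "concat7",
) -> FeatureVector | tuple[FeatureVector, FeatureVector]:
    """Feature vector(s) for a signal peptide paired with a partner prefix.

    ``concat7`` computes the seven parameters on the concatenation of the
    signal peptide and the (at most 50-residue) partner prefix; ``split14``
    additionally returns the signal-peptide-only block, yielding 14 values.
    GP% is computed on the signal peptide alone in either mode.
    """
    sp_seq = sp.sequence if isinstance(sp, SignalPeptideRecord) else sp
    sp_seq = validate_sequence(sp_seq)
    prefix = validate_sequence(partner_prefix) if partner_prefix else ""
    if len(prefix) > 50:
        raise ValueError("partner prefix longer than 50 residues")
    combined = _featurize(sp_seq + prefix, sp_seq, "sp_plus_partner50" if prefix else "sp_only")
    if mode == "concat7":
        return combined
    if mode == "split14":
        return _featurize(sp_seq, sp_seq, "sp_only"), combined
    raise ValueError(f"unknown mode {mode!r}")


def build_feature_table(
    pairs: Iterable[tuple[str, str, str, str]],
    mode: Mode = "concat7",
) -> pd.DataFrame:
    """Feature table for (sp_id, molecule_id, sp_sequence, partner_prefix) rows.

    The index is ``sp_id::molecule_id``; ``split14`` doubles the columns with
    ``_sp`` / ``_ctx`` suffixes.
    """
    rows, index = [], []
    for sp_id, mol_id, sp_seq, prefix in pairs:
        index.append(f"{sp_id}::{mol_id}")
        if mode == "concat7":
            fv = featurize_pair(sp_seq, prefix, mode)
            rows.append(fv.as_dict())
        else:
            fv_sp, fv_ctx = featurize_pair(sp_seq, prefix, "split14")
            row = {f"{k}_sp": v for k, v in fv_sp.as_dict().items()}
            row.update({f"{k}_ctx": v for k, v in fv_ctx.as_dict().items()})
            rows.append(row)
    return pd.DataFrame(rows, index=index)


@dataclass(frozen=True)
class ScalingRanges:
    """Per-column (min, max) pairs retained by min-max scaling."""

    mins: pd.Series
    maxs: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        span = (self.maxs - self.mins).replace(0.0, 1.0)
        return (table[self.mins.index] - self.mins) / span

    def inverse(self, scaled: pd.DataFrame) -> pd.DataFrame:
        span = (self.maxs - self.mins).replace(0.0, 1.0)
        return scaled[self.mins.index] * span + self.mins


def minmax_scale_table(table: pd.DataFrame) -> tuple[pd.DataFrame, ScalingRanges]:
    """Min-max scale each column to [0, 1], returning the stored ranges.

    A zero-range (constant) column maps to 0 everywhere; the stored ranges
    make the transform exactly invertible on non-degenerate columns.
    """
    if len(table) < 2:
        raise ValueError("cannot scale one observation")
    ranges = ScalingRanges(table.min(axis=0), table.max(axis=0))
    return ranges.transform(table), ranges
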