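"""Seed-deterministic synthetic data generators.

Two generators give every pipeline stage a testable input with known ground
truth:

* a structured pseudo-natural signal-peptide database emulating the length
  range (15-30 residues) and tripartite architecture of experimentally
  verified mammalian signal peptides, with planted N/H/C boundaries that
  the decomposition procedure can be checked against; and
* replicate-structured titer tables whose expected value is a known linear
  function of min-max-scaled sequence features plus Gaussian noise, for
  model parameter-recovery tests.

The pseudo-natural generator draws the N-remainder and C-region from the
eleven non-hydrophobic residues and the H-core from the nine hydrophobic
residues, so boundary recovery is provable; a "hard mode" contaminates the
flanks with hydrophobic residues at a stated rate to exercise the
rule-violation flags.  Titers are clamped to [0, 1] (negative expression is
unphysical) with replicate structure of three independent transfections,
each in duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decompose import HYDROPHOBIC, DomainPartition
from .features import FEATURE_NAMES, build_feature_table, minmax_scale_table
from .records import STANDARD_RESIDUES, Origin, SignalPeptideRecord
from .screen import TITER_COLUMNS, TiterTable

NON_HYDROPHOBIC = "".join(sorted(STANDARD_RESIDUES - HYDROPHOBIC))  # D,E,G,H,K,N,P,Q,R,S,T
#: Small/polar residues used for fixture C-regions (non-hydrophobic subset).
C_REGION_RESIDUES = "GNPQST"

N_TRANSFECTIONS = 3
N_DUPLICATES = 2


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the structured signal-peptide database generator."""

    n_records: int = 100
    n_length: tuple[int, int] = (1, 5)    # total N-region length incl. the M
    h_length: tuple[int, int] = (6, 12)
    c_length: tuple[int, int] = (3, 10)
    hydrophobic_contamination: float = 0.0  # "hard mode" flank contamination rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h_length[0] < 6:
            raise ValueError("spec violates domain bounds: H must be >= 6")
        if self.c_length[0] < 3:
            raise ValueError("spec violates domain bounds: C must be >= 3")
        total_max = self.n_length[1] + self.h_length[1] + self.c_length[1]
        # generated lengths must stay inside the verified-database range 15-30
        if total_max > 30:
            raise ValueError("spec violates domain bounds: max total length > 30")
        if total_max < 15:
            raise ValueError("spec violates domain bounds: total length cannot reach 15")


def generate_structured_sp_db(
    spec: FixtureSpec | None = None,
) -> tuple[list[SignalPeptideRecord], list[DomainPartition]]:
    """Generate records with planted N/H/C structure and their ground truth.

    Each record is M + a non-hydrophobic N-remainder + a fully hydrophobic
    H-core + a small-residue C-region, with total length clipped to 15-30
    by stretching the C-region when needed.  Returns the records and the
    planted partitions (violation-free by construction in easy mode).
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    records, truths = [], []
    for i in range(spec.n_records):
        n_len = int(rng.integers(spec.n_length[0], spec.n_length[1] + 1))
        h_len = int(rng.integers(spec.h_length[0], spec.h_length[1] + 1))
        c_len = int(rng.integers(spec.c_length[0], spec.c_length[1] + 1))
        # stretch C within its bounds so the total reaches 15
        while n_len + h_len + c_len < 15 and c_len < spec.c_length[1]:
            c_len += 1
        while n_len + h_len + c_len < 15 and n_len < spec.n_length[1]:
            n_len += 1
        n_region = "M" + "".join(rng.choice(list(NON_HYDROPHOBIC), size=n_len - 1))
        h_region = "".join(rng.choice(list(sorted(HYDROPHOBIC)), size=h_len))
        c_region = "".join(rng.choice(list(C_REGION_RESIDUES), size=c_len))
        if spec.hydrophobic_contamination > 0:
            n_region = "M" + "".join(
                aa if rng.random() >= spec.hydrophobic_contamination else "L"
                for aa in n_region[1:]
            )
            c_region = "".join(
                aa if rng.random() >= spec.hydrophobic_contamination else "A"
                for aa in c_region
            )
        seq = n_region + h_region + c_region
        records.append(
            SignalPeptideRecord(f"FX{i:03d}", seq, Origin.SYNTHETIC, note="structured fixture")
        )
        truths.append(DomainPartition(n_region, h_region, c_region))
    return records, truths


def random_partner_prefixes(n: int, seed: int, length: int = 50) -> dict[str, str]:
    """Random 50-residue mature-protein prefixes keyed ``MOL00..``."""
    rng = np.random.default_rng(seed)
    alphabet = sorted(STANDARD_RESIDUES)
    return {
        f"MOL{i:02d}": "".join(rng.choice(alphabet, size=length)) for i in range(n)
    }


#: Default titer weights over the seven features; skewed toward pI, GRAVY
#: and the insertion free energy, mirroring the feature-importance ordering
#: observed for single-chain screens.
DEFAULT_TITER_WEIGHTS = {
    "pi": 0.60,
    "dipeptide_stability": 0.02,
    "flexibility": 0.02,
    "aliphatic_index": 0.06,
    "gravy": 0.10,
    "delta_g": 0.10,
    "gp_percent": 0.10,
}


def generate_titer_dataset(
    panel: Sequence[SignalPeptideRecord],
    molecules: dict[str, str],
    weights: dict[str, float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[TiterTable, pd.DataFrame, pd.Series, dict[str, float]]:
    """Synthetic replicate-level titer screen with known feature dependence.

    Every (signal peptide, molecule) combination receives an expected titer
    ``clip(w . scaled_features + eps, 0, 1)`` with ``eps ~ N(0, noise_sd^2)``
    drawn once per construct; replicate measurements add small within-assay
    jitter around that construct value (3 transfections x 2 duplicates).

    Returns ``(titer_table, feature_table, construct_targets, weights)`` —
    the raw (unscaled) feature table, the per-construct noisy targets used
    as ground truth for model recovery, and the generating weights.
    """
    if len(panel) < 5:
        raise ValueError("panel must hold at least 5 signal peptides")
    weights = dict(weights or DEFAULT_TITER_WEIGHTS)
    if set(weights) != set(FEATURE_NAMES):
        raise ValueError("weights must cover exactly the seven feature names")
    rng = np.random.default_rng(seed)

    pairs = [
        (sp.id, mol_id, sp.sequence, prefix)
        for sp in panel
        for mol_id, prefix in molecules.items()
    ]
    features = build_feature_table(pairs)
    scaled, _ = minmax_scale_table(features)
    w = pd.Series(weights)[list(FEATURE_NAMES)]
    signal = scaled[list(FEATURE_NAMES)] @ w.to_numpy()
    noise = rng.normal(0.0, noise_sd, size=len(signal))
    targets = pd.Series(
        np.clip(signal.to_numpy() + noise, 0.0, 1.0), index=features.index, name="titer"
    )

    rows = []
    for construct, target in targets.items():
        sp_id, mol_id = construct.split("::")
        for t in range(N_TRANSFECTIONS):
            transfection_effect = rng.normal(0.0, 0.01)
            for d in range(N_DUPLICATES):
                value = max(0.0, target + transfection_effect + rng.normal(0.0, 0.005))
                rows.append((construct, sp_id, mol_id, f"T{t + 1}D{d + 1}", value))
    table = TiterTable(pd.DataFrame(rows, columns=TITER_COLUMNS))
    return table, features, targets, weights
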