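"""End-to-end protein-specific synthetic signal-peptide selection.

The selection workflow chains the toolkit stages: draw a random sample from
the synthetic library, keep sequences an (external or naive) predictor
scores above the 0.7 probability cut-off, featurise each survivor with the
partner-protein prefix, rank with the trained titer model, and return the
top candidates from the 95th percentile of predictions — the route used to
nominate a minimal test panel of three constructs for a single-chain
product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import ScalingRanges, build_feature_table
from .library import SyntheticLibrarySpec, default_library_spec, sample_sequences
from .model import CandidatePanel, TiterRegressor, select_candidates
from .predictor import PredictorScore, filter_candidates, naive_scores


@dataclass(frozen=True)
class SelectionReport:
    """Outcome and provenance of one end-to-end selection run."""

    panel: CandidatePanel
    predictions: dict[str, float]
    n_sampled: int
    n_passed_filter: int
    manifest: dict = field(default_factory=dict)


def end_to_end_select(
    model: TiterRegressor,
    scaling: ScalingRanges,
    partner_prefix: str,
    sample_n: int = 40_000,
    seed: int = 0,
    spec: SyntheticLibrarySpec | None = None,
    external_scores: list[PredictorScore] | None = None,
    threshold: float = 0.7,
    strict: bool = True,
    percentile: float = 95.0,
    k: int = 3,
) -> SelectionReport:
    """Sample -> predictor filter -> featurise -> predict -> percentile top-k.

    With ``external_scores`` the filter uses parsed predictor output (matched
    by id ``SYNTH<n>``); otherwise the in-package naive scorer is used and
    flagged in the manifest.  Deterministic given ``seed``.
    """
    spec = spec or default_library_spec()
    sampled = sample_sequences(spec, sample_n, seed)
    ids = {f"SYNTH{i:06d}": seq for i, seq in enumerate(sampled)}

    if external_scores is None:
        scores = naive_scores(ids)
        scorer = "naive"
    else:
        scores = external_scores
        scorer = scores[0].dialect if scores else "external"
    passing = [sp_id for sp_id in filter_candidates(scores, threshold, strict) if sp_id in ids]
    if not passing:
        raise RuntimeError("predictor filter: no sampled sequence passed the threshold")

    pairs = [(sp_id, "TARGET", ids[sp_id], partner_prefix) for sp_id in passing]
    features = build_feature_table(pairs)
    features.index = passing
    scaled = scaling.transform(features)
    predicted = model.predict(scaled)
    predictions = dict(zip(passing, (float(v) for v in predicted)))
    panel = select_candidates(predictions, percentile=percentile, k=k)

    manifest = {
        "stage_order": ["sample", "filter", "featurize", "predict", "select"],
        "sample_n": sample_n,
        "seed": seed,
        "scorer": scorer,
        "threshold": threshold,
        "strict": strict,
        "percentile": percentile,
        "k": k,
    }
    return SelectionReport(panel, predictions, len(sampled), len(passing), manifest)
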