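"""Shared fixtures: library spec, reference panel, and the model-recovery dataset."""

from __future__ import annotations

import pytest

import sigpepkit as sk

# seeds of the standard model-recovery conditions: 40 sampled library members
# x 5 random partner prefixes = 200 rows, noise SD 0.05
PANEL_SEED, MOLECULE_SEED, TITER_SEED, MODEL_SEED = 11, 12, 13, 7
NOISE_SD = 0.05


@pytest.fixture(scope="session")
def library_spec():
    return sk.default_library_spec()


@pytest.fixture(scope="session")
def reference_panel():
    return sk.load_reference_panel()


@pytest.fixture(scope="session")
def recovery_dataset():
    """The n=200 parameter-recovery dataset: (titer_table, features, targets, weights)."""
    seqs = sk.sample_sequences(sk.default_library_spec(), 40, seed=PANEL_SEED)
    panel = [
        sk.SignalPeptideRecord(f"SP{i:02d}", s, sk.Origin.SYNTHETIC) for i, s in enumerate(seqs)
    ]
    molecules = sk.random_partner_prefixes(5, seed=MOLECULE_SEED)
    return sk.generate_titer_dataset(panel, molecules, noise_sd=NOISE_SD, seed=TITER_SEED)


@pytest.fixture(scope="session")
def scaled_recovery(recovery_dataset):
    """(scaled features, targets array, scaling ranges) for model fitting."""
    _, features, targets, _ = recovery_dataset
    scaled, ranges = sk.minmax_scale_table(features)
    return scaled, targets.to_numpy(), ranges


@pytest.fixture(scope="session")
def trained_model(scaled_recovery):
    X, y, _ = scaled_recovery
    return sk.TiterRegressor(random_state=MODEL_SEED).fit(X, y)
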