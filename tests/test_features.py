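"""Physicochemical parameters against hand-computed oracles, and table scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import sigpepkit as sk
from sigpepkit.features import FEATURE_NAMES, HESSA_DELTA_G

CONTROL_SEQ = "MGWSCIILFLVATATGVHS"  # the ISC leader

# hand-transcribed Kyte-Doolittle hydropathy values for the oracle sequences
KD_ORACLE = {"A": 1.8, "L": 3.8, "K": -3.9, "D": -3.5, "G": -0.4}


def oracle_pi(sequence: str) -> float:
    """Independent isoelectric point: net-charge root with EMBOSS pKa values."""
    pka_pos = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
    pka_neg = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

    def net_charge(ph: float) -> float:
        pos = 1 / (1 + 10 ** (ph - pka_pos["nterm"]))
        pos += sum(
            1 / (1 + 10 ** (ph - pka_pos[aa])) for aa in sequence if aa in "KRH"
        )
        neg = 1 / (1 + 10 ** (pka_neg["cterm"] - ph))
        neg += sum(
            1 / (1 + 10 ** (pka_neg[aa] - ph)) for aa in sequence if aa in "DECY"
        )
        return pos - neg

    return brentq(net_charge, 0.0, 14.0)


class TestComputeParameter:
    @pytest.mark.parametrize(
        "sequence, name, expected",
        [
            ("AAAA", "gravy", 1.8),                      # homopolymer = scale value
            ("GGGG", "aliphatic_index", 0.0),            # no A/V/I/L terms
            (CONTROL_SEQ, "gp_percent", 100 * 2 / 19),   # 2 glycines, no proline
            ("AAAAA", "dipeptide_stability", 8.0),       # 10*(4*DIWV(A,A))/5, DIWV=1.0
            ("GGGG", "dipeptide_stability", 100.05),     # DIWV(G,G) = 13.34
            ("A" * 10, "flexibility", 0.984),            # Vihinen value of Ala
        ],
    )
    def test_hand_computed_values(self, sequence, name, expected):
        assert sk.compute_parameter(sequence, name) == pytest.approx(expected, abs=1e-6)

    def test_gravy_matches_manual_mean(self):
        seq = "ALKDGA"
        expected = np.mean([KD_ORACLE[aa] for aa in seq])
        assert sk.compute_parameter(seq, "gravy") == pytest.approx(expected)

    def test_aliphatic_index_matches_formula(self):
        seq = "AVILAVILGG"  # X(A)=X(V)=X(I)=X(L)=20 mole-percent
        expected = 20 + 2.9 * 20 + 3.9 * (20 + 20)
        assert sk.compute_parameter(seq, "aliphatic_index") == pytest.approx(expected)

    def test_delta_g_matches_manual_sum(self):
        seq = "MLKAG"
        expected = -0.10 + -0.55 + 2.71 + 0.11 + 0.74
        assert sk.compute_parameter(seq, "delta_g") == pytest.approx(expected)
        assert sk.compute_parameter(seq, "delta_g") == pytest.approx(
            sum(HESSA_DELTA_G[aa] for aa in seq)
        )

    @pytest.mark.parametrize("sequence", ["KKKKKK", "DDDDDD", CONTROL_SEQ, "MKWVTFISLLFLFSSAYS"])
    def test_pi_agrees_with_independent_titration_oracle(self, sequence):
        """Bjellqvist and EMBOSS pKa sets must agree to within a pH unit."""
        assert sk.compute_parameter(sequence, "pi") == pytest.approx(
            oracle_pi(sequence), abs=1.0
        )

    def test_pi_basic_exceeds_acidic(self):
        assert sk.compute_parameter("KKKK", "pi") > sk.compute_parameter("DDDD", "pi")

    def test_gravy_within_scale_bounds(self, reference_panel):
        for rec in reference_panel:
            if rec.ambiguous:
                continue
            assert -4.5 <= sk.compute_parameter(rec.sequence, "gravy") <= 4.5

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unsupported parameter"):
            sk.compute_parameter("AAAA", "charge")

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            sk.compute_parameter("AXA", "gravy")


class TestFeaturizePair:
    def test_empty_prefix_equals_sp_alone(self):
        fv = sk.featurize_pair(CONTROL_SEQ, "")
        for name in FEATURE_NAMES:
            assert getattr(fv, name) == pytest.approx(sk.compute_parameter(CONTROL_SEQ, name))

    def test_gp_percent_ignores_partner(self):
        fv = sk.featurize_pair(CONTROL_SEQ, "G" * 50)
        assert fv.gp_percent == pytest.approx(100 * 2 / 19)

    def test_split14_sp_block_matches_concat_gp(self):
        fv_sp, fv_ctx = sk.featurize_pair(CONTROL_SEQ, "A" * 50, mode="split14")
        assert fv_sp.gp_percent == fv_ctx.gp_percent
        assert fv_sp.context == "sp_only" and fv_ctx.context == "sp_plus_partner50"

    def test_homopolymer_concatenation_gravy(self):
        fv = sk.featurize_pair("A" * 22, "A" * 50)
        assert fv.gravy == pytest.approx(1.8)

    def test_overlong_prefix_rejected(self):
        with pytest.raises(ValueError, match="longer than 50"):
            sk.featurize_pair(CONTROL_SEQ, "A" * 51)

    def test_screen_layout_has_114_rows(self):
        """38 signal peptides x 3 molecules gives the single-chain screen table."""
        panel = sk.single_chain_screen_panel()
        assert len(panel) == 38
        molecules = sk.random_partner_prefixes(3, seed=0)
        pairs = [
            (sp.id, mol, sp.sequence, prefix)
            for sp in panel
            for mol, prefix in molecules.items()
        ]
        table = sk.build_feature_table(pairs)
        assert table.shape == (114, 7)

    def test_split14_doubles_columns(self):
        pairs = [("A", "M1", CONTROL_SEQ, "A" * 50), ("B", "M1", "M" + "L" * 21, "A" * 50)]
        table = sk.build_feature_table(pairs, mode="split14")
        assert table.shape == (2, 14)


class TestMinMaxScaling:
    def test_affine_map(self):
        table = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        scaled, _ = sk.minmax_scale_table(table)
        assert scaled["x"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        table = pd.DataFrame({"x": [5.0, 5.0, 5.0], "y": [0.0, 1.0, 2.0]})
        scaled, _ = sk.minmax_scale_table(table)
        assert scaled["x"].tolist() == [0.0, 0.0, 0.0]

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        scaled, ranges = sk.minmax_scale_table(table)
        assert np.allclose(ranges.inverse(scaled), table)
        assert scaled.to_numpy().min() >= 0.0 and scaled.to_numpy().max() <= 1.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="one observation"):
            sk.minmax_scale_table(pd.DataFrame({"x": [1.0]}))

    def test_stored_ranges_apply_to_new_data(self):
        table = pd.DataFrame({"x": [0.0, 10.0]})
        _, ranges = sk.minmax_scale_table(table)
        new = ranges.transform(pd.DataFrame({"x": [5.0, 20.0]}))
        assert new["x"].tolist() == [0.5, 2.0]
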