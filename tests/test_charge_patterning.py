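import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from disorderdb import (classify_charges, composition_fractions,
                        compute_sequence_parameters, delta, delta_max,
                        fcr_ncpr, hydropathy, kappa)
from disorderdb.errors import SequenceError

from _naive_oracle import charges_of, naive_delta, naive_delta_max


class TestChargeClassification:
    @pytest.mark.parametrize("seq,expected", [
        ("DEKR", (2, 2, 0)),
        ("GGGG", (0, 0, 4)),
        ("HHHH", (0, 0, 4)),  # histidine is neutral in this charge model
    ])
    def test_counts(self, seq, expected):
        cls = classify_charges(seq)
        assert (cls.n_positive, cls.n_negative, cls.n_neutral) == expected
        assert cls.n_positive + cls.n_negative + cls.n_neutral == len(seq)

    def test_ineligible_residue_rejected(self):
        with pytest.raises(SequenceError):
            classify_charges("MKXV")

    @pytest.mark.parametrize("seq,fcr,ncpr", [
        ("DEKR", 1.0, 0.0),
        ("KKKK", 1.0, 1.0),
        ("GDGG", 0.25, -0.25),
    ])
    def test_fcr_ncpr(self, seq, fcr, ncpr):
        cls = classify_charges(seq)
        got = fcr_ncpr(cls.n_positive, cls.n_negative, len(seq))
        assert got == pytest.approx((fcr, ncpr))
        assert abs(got[1]) <= got[0] <= 1.0


class TestDelta:
    def test_alternating_hand_value(self):
        # every g=5 blob of EKEKEKEKEK has sigma 1/25; whole sequence sigma 0
        cls = classify_charges("EKEKEKEKEK")
        assert delta(cls.charges, 5) == pytest.approx((1 / 25) ** 2)

    def test_uniform_charge_gives_zero(self):
        cls = classify_charges("KKKKKK")
        assert delta(cls.charges, 5) == pytest.approx(0.0)

    def test_segregated_matches_naive_oracle(self):
        cls = classify_charges("EEEEEKKKKK")
        for g in (5, 6):
            assert delta(cls.charges, g) == pytest.approx(
                naive_delta(charges_of("EEEEEKKKKK"), g), abs=1e-12)

    def test_uncharged_undefined(self):
        with pytest.raises(SequenceError):
            delta(classify_charges("GGGGGG").charges, 5)

    def test_too_short_for_blob(self):
        with pytest.raises(SequenceError):
            delta(classify_charges("EK").charges, 5)


class TestDeltaMax:
    def test_exhaustive_matches_naive_enumeration(self):
        for seq in ("EEEEEKKKKK", "EKGKEGEK", "DDKKGG"):
            cls = classify_charges(seq)
            for g in (5, 6):
                if len(seq) < g:
                    continue
                mine = delta_max(cls.n_positive, cls.n_negative, cls.n_neutral,
                                 g, mode="exhaustive")
                assert mine == pytest.approx(
                    naive_delta_max(charges_of(seq), g), abs=1e-12)

    def test_segregated_decapeptide_attains_maximum(self):
        cls = classify_charges("EEEEEKKKKK")
        for g in (5, 6):
            dmax = delta_max(cls.n_positive, cls.n_negative, 0, g, mode="exhaustive")
            assert delta(cls.charges, g) == pytest.approx(dmax, abs=1e-12)

    def test_single_charge_placements_bounded_by_exhaustive(self):
        # one K among 7 G: exhaustive max over the 8 placements
        dmax = delta_max(1, 0, 7, 5, mode="exhaustive")
        best = max(delta(np.array([1 if i == j else 0 for i in range(8)]), 5)
                   for j in range(8))
        assert dmax == pytest.approx(best, abs=1e-14)

    def test_uncharged_composition_undefined(self):
        with pytest.raises(SequenceError):
            delta_max(0, 0, 10, 5)

    @pytest.mark.parametrize("n", range(6, 13))
    def test_constructive_equals_exhaustive_sampled_compositions(self, n):
        rng = np.random.default_rng(n)
        for _ in range(6):
            n_pos = int(rng.integers(0, n + 1))
            n_neg = int(rng.integers(0, n - n_pos + 1))
            if n_pos + n_neg == 0:
                n_pos = 1
            n0 = n - n_pos - n_neg
            for g in (5, 6):
                if n < g:
                    continue
                ex = delta_max(n_pos, n_neg, n0, g, mode="exhaustive")
                co = delta_max(n_pos, n_neg, n0, g, mode="constructive")
                assert co == pytest.approx(ex, abs=1e-12)

    @given(st.integers(min_value=12, max_value=40), st.integers(min_value=0))
    @settings(max_examples=25)
    def test_constructive_bounds_random_arrangements(self, n, seed):
        rng = np.random.default_rng(seed % 2**31)
        n_pos = int(rng.integers(1, n // 2 + 1))
        n_neg = int(rng.integers(1, n - n_pos))
        n0 = n - n_pos - n_neg
        vec = np.array([1] * n_pos + [-1] * n_neg + [0] * n0, dtype=np.int8)
        dmax = delta_max(n_pos, n_neg, n0, 5, mode="constructive")
        for _ in range(10):
            rng.shuffle(vec)
            assert delta(vec, 5) <= dmax + 1e-12


class TestKappa:
    def test_fully_segregated_is_one(self):
        assert kappa("EEEEEKKKKK").kappa == pytest.approx(1.0)

    def test_alternating_strictly_less_than_segregated(self):
        alt = kappa("EKEKEKEKEK").kappa
        assert alt is not None
        assert alt < kappa("EEEEEKKKKK").kappa
        # regression value from the exhaustive oracle
        assert alt == pytest.approx(0.0021216407355, abs=1e-10)

    def test_uncharged_undefined_sentinel(self):
        result = kappa("GGGGGGGGGG")
        assert result.kappa is None
        assert result.undefined_reason == "no charged residues"

    def test_short_sequence_undefined(self):
        assert kappa("EKEK").kappa is None

    def test_mixing_monotonicity(self):
        segregated = kappa("E" * 8 + "K" * 8).kappa
        blocky = kappa("EEEEKKKKEEEEKKKK").kappa
        alternating = kappa("EK" * 8).kappa
        assert segregated >= blocky >= alternating

    def test_proline_warning_flag(self):
        assert kappa("PPPPEEEKKK").kappa_warning
        assert not kappa("EEEEEKKKKK").kappa_warning

    @given(st.text(alphabet="EKDRGQSA", min_size=6, max_size=40))
    @settings(max_examples=40)
    def test_kappa_within_unit_interval(self, seq):
        result = kappa(seq)
        if result.kappa is not None:
            assert 0.0 <= result.kappa <= 1.0

    @given(st.text(alphabet="EKDRGQSAPLIV", min_size=6, max_size=30))
    @settings(max_examples=30)
    def test_reversal_invariance(self, seq):
        fwd, rev = kappa(seq), kappa(seq[::-1])
        if fwd.kappa is None:
            assert rev.kappa is None
        else:
            assert rev.kappa == pytest.approx(fwd.kappa, abs=1e-9)


class TestHydropathy:
    @pytest.mark.parametrize("seq,expected", [
        ("A", (1.8 + 4.5) / 9),   # 0.7
        ("R", 0.0),               # scale minimum
        ("I", 1.0),               # scale maximum
    ])
    def test_scale_values(self, seq, expected):
        mean_h, uversky_h = hydropathy(seq)
        assert mean_h == pytest.approx(expected)

    def test_homopolymer_mean_equals_uversky(self):
        for aa in "AGKE":
            mean_h, uversky_h = hydropathy(aa * 20)
            assert uversky_h == pytest.approx(mean_h)

    def test_heteropolymer_windowing_differs_from_mean(self):
        # hydrophobic residues concentrated at one terminus: clipped edge
        # windows weight them differently from the plain mean
        mean_h, uversky_h = hydropathy("IIRRRRRRRR")
        assert mean_h == pytest.approx(0.2)
        assert uversky_h != pytest.approx(mean_h)


class TestCompositionFractions:
    def test_all_promoting(self):
        f_dp, pro = composition_fractions("ARGQSPEK")
        assert f_dp == pytest.approx(1.0)
        assert pro == pytest.approx(0.125)

    def test_none_promoting(self):
        f_dp, _ = composition_fractions("WCFIYVLN")
        assert f_dp == pytest.approx(0.0)

    def test_polyproline_sets_kappa_warning(self):
        params = compute_sequence_parameters("PPPP")
        assert params.proline_content == pytest.approx(1.0)
        assert params.kappa_warning


class TestSequenceParameters:
    def test_block_consistency(self):
        params = compute_sequence_parameters("EEEEEKKKKKGGGGG")
        assert params.n_positive + params.n_negative + params.n_neutral == 15
        assert params.fcr == pytest.approx(10 / 15)
        assert params.ncpr == pytest.approx(0.0)
        assert params.kappa is not None and 0 <= params.kappa <= 1
        assert params.delta is not None and params.delta_max is not None

    def test_undefined_kappa_propagates_sentinels(self):
        params = compute_sequence_parameters("GGGGGGGGGG")
        assert params.kappa is None
        assert params.delta is None and params.delta_max is None
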