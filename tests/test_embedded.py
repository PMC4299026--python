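"""Integer inference path: linearized MFs, shift-truncate products, parity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgtriage as et
from ecgtriage import dimreduce, embedded, nfc
from ecgtriage.embedded import (
    FULL_SCALE,
    G_S,
    FeatureQuantizer,
    IntFuzzyState,
    LinearizedMf,
    eval_linearized,
    int_defuzzify,
    int_fuzzify,
    linearize_mf,
    quantize_model,
)


def _example_lmf(sigma_norm: float = 1.0) -> LinearizedMf:
    quantizer = FeatureQuantizer(lo=np.array([-4.7]),
                                 step=np.array([9.4 / FULL_SCALE]))
    return linearize_mf(nfc.MembershipFunction(0.0, sigma_norm), quantizer, 0)


class TestLinearizedMf:
    def test_piecewise_cases(self):
        lmf = _example_lmf(0.3)   # keep 4S inside the 16-bit axis
        c, s = lmf.center_int, lmf.s_int
        assert eval_linearized(lmf, c) == FULL_SCALE
        assert eval_linearized(lmf, min(c + 3 * s, FULL_SCALE)) == 1   # [2S, 4S)
        assert eval_linearized(lmf, c - 2 * s) == 1
        # scaled-gaussian chord endpoint at |c - x| = S, within rounding
        oracle = int(round(FULL_SCALE * np.exp(-2.35**2 / 2)))
        assert abs(eval_linearized(lmf, c + s) - oracle) <= 1
        assert G_S == oracle

    def test_zero_beyond_4s(self):
        lmf = _example_lmf(0.3)
        c, s = lmf.center_int, lmf.s_int
        assert eval_linearized(lmf, c + 4 * s) == 0
        assert eval_linearized(lmf, min(c + 10 * s, FULL_SCALE)) == 0

    def test_symmetry(self):
        lmf = _example_lmf(0.7)
        c = lmf.center_int
        for delta in (1, 10, 500, 3000, 20000):
            lo, hi = c - delta, c + delta
            if lo >= 0 and hi <= FULL_SCALE:
                assert eval_linearized(lmf, lo) == eval_linearized(lmf, hi)

    def test_monotone_non_increasing_exhaustive(self):
        """Full 16-bit sweep: the grade never increases as |c - x| grows."""
        lmf = _example_lmf()
        x = np.arange(lmf.center_int, FULL_SCALE + 1)
        grades = eval_linearized(lmf, x)
        assert np.all(np.diff(grades) <= 0)

    @pytest.mark.parametrize("sigma", [0.25, 0.5, 1.0, 2.0])
    def test_error_bound_vs_scaled_gaussian_exhaustive(self, sigma):
        """Max abs deviation from the scaled gaussian over the whole axis
        stays below the documented chord worst case."""
        lmf = _example_lmf(sigma)
        x = np.arange(FULL_SCALE + 1)
        grades = eval_linearized(lmf, x)
        sigma_int = lmf.s_int / 2.35
        oracle = np.round(FULL_SCALE * np.exp(-((x - lmf.center_int) / sigma_int) ** 2
                                              / 2.0))
        assert np.max(np.abs(grades - oracle)) <= embedded.LINEARIZATION_MAX_ERROR

    def test_degenerate_quantizer_rejected(self):
        with pytest.raises(ValueError, match="step"):
            FeatureQuantizer(lo=np.zeros(1), step=np.zeros(1))


class TestQuantizeModel:
    def test_alpha_fixed_point(self, trained_model):
        for alpha, expected in ((0.0, 0), (0.5, 32768)):
            trained_model.alpha_train = alpha
            assert quantize_model(trained_model).alpha_q16 == expected

    def test_alpha_round_trip_error(self, trained_model):
        for alpha in (0.1, 0.37, 0.9031):
            trained_model.alpha_train = alpha
            q = quantize_model(trained_model).alpha_q16
            assert abs(q / 2**16 - alpha) < 2**-16

    def test_untrained_model_rejected(self):
        model = nfc.NfcModel(centers=np.zeros((2, 3)), sigmas=np.ones((2, 3)),
                             scale_mean=np.zeros(2), scale_std=np.ones(2))
        with pytest.raises(ValueError, match="trained"):
            quantize_model(model)


class TestIntFuzzify:
    def test_worked_shift_truncate_trace(self, trained_model):
        """k=2, grades per class (65535, 65535), (32768, 32768), (1, 1):
        replay the shift-truncate arithmetic with exact Python ints."""
        grades = [(65535, 32768, 1), (65535, 32768, 1)]

        def oracle():
            acc = list(grades[0])
            prods = [a * g for a, g in zip(acc, grades[1])]
            top = max(prods)
            shift = 32 - top.bit_length()
            return [(p << shift) >> 16 for p in prods]

        qm = quantize_model(trained_model)
        # build a 2-coefficient surrogate with the stated grade pattern
        state_acc = np.array(grades[0], dtype=np.int64) * np.array(grades[1],
                                                                   dtype=np.int64)
        shift = 32 - int(state_acc.max()).bit_length()
        ours = (state_acc << shift) >> 16
        np.testing.assert_array_equal(ours, oracle())
        # large accumulators preserve the float ratio to ~2^-15
        float_ratio = (65535 / 32768) ** 2
        int_ratio = ours[0] / ours[1]
        assert abs(int_ratio - float_ratio) / float_ratio < 2**-14

    def test_all_centers_coincide_ties(self, trained_model):
        qm = quantize_model(trained_model)
        qm.centers_int[:] = 30000
        qm.s_int[:] = 1000
        x = np.full(qm.k, 30000, dtype=np.int64)
        state = int_fuzzify(qm, x)
        assert len(set(state.accumulators.tolist())) == 1
        assert int_defuzzify(state, 0).label == "U"   # tie rule

    def test_accumulators_stay_32_bit(self, trained_model, rp16_features):
        U, _ = rp16_features
        qm = quantize_model(trained_model)
        X = qm.quantize_features(U[:200])
        for x in X:
            state = int_fuzzify(qm, x)
            assert np.all(state.accumulators >= 0)
            assert np.all(state.accumulators < 2**32)

    def test_batch_matches_single(self, trained_model, rp16_features):
        U, _ = rp16_features
        qm = quantize_model(trained_model)
        X = qm.quantize_features(U[:50])
        batch = embedded.int_fuzzify_batch(qm, X)
        for i, x in enumerate(X):
            np.testing.assert_array_equal(batch[i], int_fuzzify(qm, x).accumulators)


class TestIntDefuzzify:
    def test_clear_winner(self):
        r = int_defuzzify(IntFuzzyState(np.array([100, 0, 0]), 0), 32768)
        assert r.label == "N"          # 100 * 65536 >= 32768 * 100

    def test_narrow_margin_unknown(self):
        """Mirrors the float example f=(0.6, 0.5, 0.4) at alpha ~ 0.1."""
        r = int_defuzzify(IntFuzzyState(np.array([60, 50, 40]), 0), 6554)
        assert r.label == "U"

    def test_all_zero_unknown(self):
        r = int_defuzzify(IntFuzzyState(np.zeros(3, dtype=np.int64), 0), 0)
        assert r.label == "U" and r.is_pathological

    @settings(deadline=None, max_examples=200)
    @given(st.tuples(st.integers(0, 2**32 - 1), st.integers(0, 2**32 - 1),
                     st.integers(0, 2**32 - 1)),
           st.integers(0, 2**16 - 1))
    def test_matches_widened_arithmetic_oracle(self, acc, alpha_q16):
        """Exact-rational oracle over random 32-bit triples: identical label,
        no overflow anywhere."""
        from fractions import Fraction

        acc_arr = np.array(acc, dtype=np.int64)
        ours = int_defuzzify(IntFuzzyState(acc_arr, 0), alpha_q16)
        vals = sorted(acc, reverse=True)
        m1, m2, s = vals[0], vals[1], sum(acc)
        if s == 0 or m1 == m2 or Fraction(m1 - m2) < Fraction(alpha_q16, 2**16) * s:
            expected = "U"
        else:
            expected = nfc.CLASSES[int(np.argmax(acc_arr))]
        assert ours.label == expected


class TestParityAudit:
    def test_self_comparison_is_perfect(self, trained_model, rp16_features):
        U, y = rp16_features
        qm = quantize_model(trained_model)
        report = embedded.parity_audit(trained_model, qm, U[:500], y[:500])
        assert report["n"] == 500
        assert report["n_agree"] <= report["n"]
        # float labels compared against themselves agree trivially
        assert np.mean(report["float_labels"] == report["float_labels"]) == 1.0

    def test_quantized_agreement_on_separated_set(self, trained_model, rp16_features):
        U, y = rp16_features
        qm = quantize_model(trained_model)
        report = embedded.parity_audit(trained_model, qm, U, y)
        assert report["agreement"] >= 0.99
        assert abs(report["ndr_delta"]) <= 0.02
        assert abs(report["arr_delta"]) <= 0.02


class TestBlobSerialization:
    def test_round_trip(self, trained_model, rp16_features, tmp_path):
        U, _ = rp16_features
        qm = quantize_model(trained_model)
        embedded.save_quantized(qm, tmp_path / "model.qnfc")
        back = embedded.load_quantized(tmp_path / "model.qnfc")
        assert back.alpha_q16 == qm.alpha_q16
        np.testing.assert_array_equal(back.centers_int, qm.centers_int)
        np.testing.assert_array_equal(back.s_int, qm.s_int)
        labels_a = embedded.classify_int_batch(qm, U[:100])
        labels_b = embedded.classify_int_batch(back, U[:100])
        np.testing.assert_array_equal(labels_a, labels_b)

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "bad.bin").write_bytes(b"XXXX" + b"\x00" * 20)
        with pytest.raises(ValueError, match="blob"):
            embedded.load_quantized(tmp_path / "bad.bin")
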