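"""Neuro-fuzzy classifier: membership, fuzzification, decision rule, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgtriage import nfc
from ecgtriage.nfc import MembershipFunction, membership_grade

from conftest import make_gaussian_features


class TestMembershipGrade:
    def test_peak_at_center(self):
        assert membership_grade(MembershipFunction(2.0, 0.5), 2.0) == 1.0

    def test_one_sigma_value(self):
        mf = MembershipFunction(0.0, 1.3)
        assert membership_grade(mf, 1.3) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_linearization_breakpoint_value(self):
        """At |u - c| = 2.35 sigma the grade is exp(-2.76125) ~ 0.0632."""
        mf = MembershipFunction(1.0, 0.4)
        assert membership_grade(mf, 1.0 + 2.35 * 0.4) == \
            pytest.approx(np.exp(-2.76125), rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(-50, 50), st.floats(0.01, 10), st.floats(-100, 100))
    def test_range_symmetry_monotonicity(self, c, sigma, u):
        from hypothesis import assume

        # stay clear of double-precision underflow of exp(-z^2/2)
        assume(((u - c) / sigma) ** 2 / 2 < 700)
        mf = MembershipFunction(c, sigma)
        g = membership_grade(mf, u)
        assert 0.0 < g <= 1.0
        assert g == pytest.approx(membership_grade(mf, 2 * c - u), rel=1e-9)
        closer = c + 0.5 * (u - c)
        assert membership_grade(mf, closer) >= g

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            MembershipFunction(0.0, 0.0)


class TestFuzzify:
    def test_product_of_grades(self, trained_model):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(trained_model.k) * 5
        f = nfc.fuzzify(trained_model, u)
        z = trained_model.normalize(u)
        oracle = np.ones(3)
        for i in range(trained_model.k):
            for l in range(3):
                oracle[l] *= np.exp(-(z[i] - trained_model.centers[i, l]) ** 2
                                    / (2 * trained_model.sigmas[i, l] ** 2))
        np.testing.assert_allclose(f, oracle, rtol=1e-9)

    def test_at_class_centers_grade_is_one(self):
        model = nfc.NfcModel(centers=np.zeros((2, 3)), sigmas=np.ones((2, 3)),
                             scale_mean=np.zeros(2), scale_std=np.ones(2))
        np.testing.assert_allclose(nfc.fuzzify(model, np.zeros(2)), 1.0)

    def test_length_mismatch_rejected(self, trained_model):
        with pytest.raises(ValueError):
            nfc.fuzzify(trained_model, np.zeros(trained_model.k + 1))


class TestDefuzzify:
    def test_clear_winner_assigned(self):
        r = nfc.defuzzify(np.array([1.0, 0.0, 0.0]), 0.5)
        assert r.label == "N" and not r.is_pathological
        assert (r.m1, r.m2, r.s) == (1.0, 0.0, 1.0)

    def test_narrow_margin_goes_unknown(self):
        """f=(0.6, 0.5, 0.4), alpha=0.1: margin 0.1 < 0.1 * 1.5 -> U."""
        r = nfc.defuzzify(np.array([0.6, 0.5, 0.4]), 0.1)
        assert r.label == "U" and r.is_pathological

    def test_alpha_zero_degenerates_to_argmax(self):
        r = nfc.defuzzify(np.array([0.2, 0.7, 0.3]), 0.0)
        assert r.label == "V"

    def test_all_zero_and_ties_yield_unknown(self):
        assert nfc.defuzzify(np.zeros(3), 0.0).label == "U"
        assert nfc.defuzzify(np.array([0.5, 0.5, 0.1]), 0.0).label == "U"

    @settings(deadline=None, max_examples=60)
    @given(st.tuples(st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 1e6)),
           st.floats(0, 1), st.floats(1e-6, 1e6))
    def test_scale_invariance(self, f, alpha, lam):
        f = np.asarray(f)
        a = nfc.defuzzify(f, alpha)
        b = nfc.defuzzify(f * lam, alpha)
        assert a.label == b.label


class TestInitModel:
    def test_constant_feature_floors_sigma(self):
        X = np.array([[5.0], [5.0], [5.0], [5.0], [5.0], [5.0]])
        y = np.array(["N", "N", "V", "V", "L", "L"])
        X = X + np.array([[0], [0], [1], [1], [2], [2]])  # distinct class values
        model = nfc.init_model(X, y)
        assert np.all(model.sigmas >= nfc.SIGMA_FLOOR)

    def test_centers_recover_cloud_means(self):
        centers = np.array([[0.0, 5.0, -5.0], [2.0, -2.0, 6.0]])
        X, y = make_gaussian_features(centers, sigma=0.5, n_per_class=4000, seed=0)
        model = nfc.init_model(X, y)
        raw_centers = model.scale_mean[:, None] + model.scale_std[:, None] * model.centers
        np.testing.assert_allclose(raw_centers, centers, atol=0.03)

    def test_permutation_invariance(self):
        X, y = make_gaussian_features(np.array([[0.0, 3.0, -3.0]]), 1.0, 50, seed=1)
        perm = np.random.default_rng(2).permutation(len(y))
        a = nfc.init_model(X, y)
        b = nfc.init_model(X[perm], y[perm])
        np.testing.assert_allclose(a.centers, b.centers, atol=1e-12)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            nfc.init_model(np.zeros((4, 2)), np.array(["N", "N", "V", "V"]))


class TestTraining:
    def test_zero_epochs_leaves_parameters(self, rp16_features):
        U, y = rp16_features
        model = nfc.init_model(U[:300], y[:300])
        out = nfc.train_model(model, U[:300], y[:300], epochs=0)
        np.testing.assert_array_equal(out.centers, model.centers)
        assert out.trained

    def test_gradients_match_finite_differences(self):
        """Analytic gradients vs central differences, max abs diff < 1e-6."""
        rng = np.random.default_rng(7)
        k, n = 3, 12
        Z = rng.standard_normal((n, k))
        Y = np.eye(3)[rng.integers(0, 3, n)]
        centers = rng.standard_normal((k, 3))
        sigmas = rng.uniform(0.5, 2.0, (k, 3))
        loss, dC, dS = nfc.loss_and_gradients(centers, sigmas, Z, Y)
        h = 1e-6
        for arr, grad in ((centers, dC), (sigmas, dS)):
            for i in range(k):
                for l in range(3):
                    arr[i, l] += h
                    lp = nfc.loss_and_gradients(centers, sigmas, Z, Y)[0]
                    arr[i, l] -= 2 * h
                    lm = nfc.loss_and_gradients(centers, sigmas, Z, Y)[0]
                    arr[i, l] += h
                    assert abs((lp - lm) / (2 * h) - grad[i, l]) < 1e-6

    def test_loss_non_increasing_on_separable_clusters(self):
        centers = np.array([[-6.0, 0.0, 6.0]])
        X, y = make_gaussian_features(centers, sigma=1.0, n_per_class=200, seed=3)
        model = nfc.init_model(X, y)
        out = nfc.train_model(model, X, y, epochs=100, learning_rate=0.05)
        losses = np.asarray(out.loss_history)
        assert np.all(np.diff(losses) <= 1e-12)
        preds = nfc.classify_batch(out, X, alpha_test=0.0)
        assert np.mean(preds == y) >= 0.99

    def test_conjugate_gradient_strategy_also_trains(self):
        centers = np.array([[-6.0, 0.0, 6.0]])
        X, y = make_gaussian_features(centers, sigma=1.0, n_per_class=100, seed=4)
        model = nfc.init_model(X, y)
        out = nfc.train_model(model, X, y, epochs=50, optimizer="cg")
        preds = nfc.classify_batch(out, X, alpha_test=0.0)
        assert np.mean(preds == y) >= 0.99

    def test_parameter_recovery_within_two_percent(self):
        """Known 3-class gaussian features, n=1,000/class: centers within 2%."""
        centers = np.array([[10.0, 20.0, 30.0], [-15.0, 5.0, 25.0]])
        X, y = make_gaussian_features(centers, sigma=1.0, n_per_class=1000, seed=5)
        model = nfc.init_model(X, y)
        model = nfc.train_model(model, X, y)
        raw = model.scale_mean[:, None] + model.scale_std[:, None] * model.centers
        rel = np.abs(raw - centers) / np.abs(centers)
        assert np.max(rel) < 0.02

    def test_unknown_optimizer_rejected(self, rp16_features):
        U, y = rp16_features
        model = nfc.init_model(U[:300], y[:300])
        with pytest.raises(ValueError, match="optimizer"):
            nfc.train_model(model, U[:300], y[:300], optimizer="adam")


class TestTuneAlpha:
    def test_returns_zero_when_already_compliant(self, trained_model, rp16_features):
        U, y = rp16_features
        alpha, ok = nfc.tune_alpha(trained_model, U, y, arr_min=0.0)
        assert alpha == 0.0 and ok

    def test_unreachable_bound_flagged(self):
        """An abnormal beat winning class N with the other fuzzy values
        underflowed to zero keeps margin ratio 1 at every alpha."""
        model = nfc.NfcModel(centers=np.array([[0.0, 100.0, -100.0]]),
                             sigmas=np.full((1, 3), 1.0),
                             scale_mean=np.zeros(1), scale_std=np.ones(1))
        X = np.array([[0.0], [0.0], [100.0], [-100.0]])
        y = np.array(["N", "V", "V", "L"])   # one V sits exactly on the N center
        alpha, ok = nfc.tune_alpha(model, X, y, arr_min=1.0)
        assert alpha == 1.0 and not ok

    def test_no_abnormal_beats_rejected(self, trained_model, rp16_features):
        U, y = rp16_features
        mask = y == "N"
        with pytest.raises(ValueError, match="abnormal"):
            nfc.tune_alpha(trained_model, U[mask], y[mask])

    def test_arr_monotone_in_alpha(self, trained_model, rp16_features):
        from ecgtriage.evaluate import compute_ndr_arr

        U, y = rp16_features
        arrs, ndrs = [], []
        for alpha in np.linspace(0, 1, 21):
            rep = compute_ndr_arr(nfc.classify_batch(trained_model, U, alpha), y)
            arrs.append(rep.arr)
            ndrs.append(rep.ndr)
        assert np.all(np.diff(arrs) >= 0)
        assert np.all(np.diff(ndrs) <= 0)


class TestSerialization:
    def test_json_round_trip(self, trained_model):
        back = nfc.NfcModel.from_json(trained_model.to_json())
        np.testing.assert_allclose(back.centers, trained_model.centers)
        np.testing.assert_allclose(back.sigmas, trained_model.sigmas)
        assert back.alpha_train == trained_model.alpha_train
        assert back.trained


def test_classify_composition(trained_model):
    rng = np.random.default_rng(9)
    u = rng.standard_normal(trained_model.k)
    direct = nfc.classify(trained_model, u, alpha_test=0.2)
    manual = nfc.defuzzify(nfc.fuzzify(trained_model, u), 0.2)
    assert direct.label == manual.label
    np.testing.assert_allclose(direct.fuzzy_values, manual.fuzzy_values)
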