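"""CSP, feature extraction, sLDA and stream classification.

The CSP implementation (whiten-then-rotate) is checked against a direct
generalized eigendecomposition oracle; the sLDA against scikit-learn's
classical LDA in the zero-shrinkage limit; windowed features against a
naive variance loop.
"""

import numpy as np
import pytest
import scipy.linalg as la

from coadaptbci.data_model import FEET, HAND, Trial
from coadaptbci.decoder import (CSPBank, MotorImageryDecoder,
                                ShrinkageCSP, ShrinkageLDA, classify_stream,
                                extract_features, features_from_moments,
                                load_model, save_model, window_moments)
from coadaptbci.preprocess import apply_filterbank, build_filterbank

FS = 256.0


def _random_spd(rng, d):
    a = rng.standard_normal((d, d))
    return a @ a.T + d * np.eye(d)


class TestShrinkageCSP:
    @pytest.mark.parametrize("d", [3, 4, 5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_generalized_eigendecomposition_oracle(self, d, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = _random_spd(rng, d), _random_spd(rng, d)
        covs = np.stack([c1, c1, c2, c2])
        y = np.array([HAND, HAND, FEET, FEET])
        csp = ShrinkageCSP(shrinkage=0.0, n_select=2).fit_from_covariances(covs, y)
        oracle = np.sort(la.eigh(c1, c1 + c2, eigvals_only=True))[::-1]
        np.testing.assert_allclose(csp.eigenvalues_, oracle, atol=1e-8)
        # each filter column solves the generalized eigenproblem
        for j, lam in enumerate(csp.eigenvalues_):
            w = csp.filters_[:, j]
            np.testing.assert_allclose(c1 @ w, lam * (c1 + c2) @ w, atol=1e-8)

    def test_identical_class_covariances_give_half_eigenvalues(self, rng):
        c = _random_spd(rng, 4)
        covs = np.stack([c] * 4)
        y = np.array([HAND, HAND, FEET, FEET])
        csp = ShrinkageCSP(shrinkage=0.0, n_select=2).fit_from_covariances(covs, y)
        np.testing.assert_allclose(csp.eigenvalues_, 0.5, atol=1e-10)

    def test_variance_contrast_recovers_discriminative_direction(self, rng):
        """Classes differing only in variance along one channel: that channel
        must dominate the extreme CSP filter."""
        d = 3
        base = np.eye(d)
        boosted = base.copy()
        boosted[0, 0] = 10.0
        covs = np.stack([boosted, boosted, base, base])
        y = np.array([HAND, HAND, FEET, FEET])
        csp = ShrinkageCSP(shrinkage=0.0, n_select=2).fit_from_covariances(covs, y)
        top = csp.filters_[:, 0] / np.linalg.norm(csp.filters_[:, 0])
        assert abs(top[0]) > 0.99

    def test_six_projections_selected_per_band(self, rng):
        covs = np.stack([_random_spd(rng, 13) for _ in range(8)])
        covs = covs[:, None].repeat(3, axis=1)          # 3 bands
        y = np.array([HAND, FEET] * 4)
        bank = CSPBank(shrinkage=0.1).fit_from_covariances(covs, y)
        assert all(len(c.selected_) == 6 for c in bank.csps_)
        assert bank.selected_filters().shape == (3, 13, 6)

    def test_one_class_absent_errors(self, rng):
        covs = np.stack([_random_spd(rng, 3) for _ in range(4)])
        with pytest.raises(ValueError, match="both classes"):
            ShrinkageCSP().fit_from_covariances(covs, np.zeros(4, int))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(10)
    fb = build_filterbank(fs=FS)
    trials = rng.standard_normal((8, 13, 2048)) * 5
    y = np.array([HAND, FEET] * 4)
    filtered = np.stack([apply_filterbank(fb, t) for t in trials])
    bank = CSPBank().fit(filtered[..., 1216:1984], y)   # 4.75-7.75 s
    return fb, bank, filtered


class TestFeatures:
    def test_vector_has_90_entries(self, fitted):
        fb, bank, filtered = fitted
        f = extract_features(filtered[0], bank, 5.5, FS)
        assert f.shape == (90,)
        assert np.all(np.isfinite(f))

    def test_doubling_amplitude_shifts_by_log4(self, fitted):
        fb, bank, filtered = fitted
        f1 = extract_features(filtered[0], bank, 5.5, FS)
        f2 = extract_features(2.0 * filtered[0], bank, 5.5, FS)
        np.testing.assert_allclose(f2 - f1, np.log(4.0), atol=1e-9)

    def test_matches_naive_variance_loop(self, fitted):
        """Each feature equals log variance of the projected band signal over
        [4.5, 5.5) computed sample by sample."""
        fb, bank, filtered = fitted
        f = extract_features(filtered[0], bank, 5.5, FS)
        lo, hi = int(4.5 * FS), int(5.5 * FS)
        k = 0
        for b, csp in enumerate(bank.csps_):
            for j in csp.selected_:
                w = csp.filters_[:, j]
                proj = [w @ filtered[0][b, :, n] for n in range(lo, hi)]
                m = sum(proj) / len(proj)
                var = sum((p - m) ** 2 for p in proj) / len(proj)
                assert f[k] == pytest.approx(np.log(var), abs=1e-9)
                k += 1

    def test_moment_cache_path_is_equivalent(self, fitted):
        fb, bank, filtered = fitted
        s, m = window_moments(filtered[0], 5.5, FS)
        np.testing.assert_allclose(features_from_moments(s, m, bank),
                                   extract_features(filtered[0], bank, 5.5, FS),
                                   atol=1e-9)

    def test_window_underrun_errors(self, fitted):
        fb, bank, filtered = fitted
        with pytest.raises(ValueError, match="window"):
            extract_features(filtered[0], bank, 0.5, FS)


class TestShrinkageLDA:
    def test_separated_clouds_perfect_training_accuracy(self, rng):
        n = 100
        x = np.vstack([rng.standard_normal((n, 2)),
                       rng.standard_normal((n, 2)) + 6.0])
        y = np.r_[np.full(n, HAND), np.full(n, FEET)]
        model = ShrinkageLDA().fit(x, y)
        assert np.mean(model.predict(x) == y) == 1.0
        assert np.all(model.decision_function(x[y == FEET]) > 0)

    def test_identical_distributions_near_chance(self, rng):
        x = rng.standard_normal((400, 3))
        y = np.r_[np.full(200, HAND), np.full(200, FEET)]
        model = ShrinkageLDA().fit(x, y)
        assert 0.35 < np.mean(model.predict(x) == y) < 0.65

    def test_full_shrinkage_aligns_with_mean_difference(self, rng):
        x = rng.standard_normal((60, 4)) @ np.diag([1, 5, 1, 3])
        y = np.r_[np.full(30, HAND), np.full(30, FEET)]
        x[y == FEET] += [1, 0, 2, 0]
        model = ShrinkageLDA(shrinkage=1.0).fit(x, y)
        delta = x[y == FEET].mean(0) - x[y == HAND].mean(0)
        cos = model.coef_ @ delta / np.linalg.norm(model.coef_) / np.linalg.norm(delta)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_zero_shrinkage_limit_matches_classical_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        x = rng.standard_normal((300, 6))
        y = np.r_[np.full(150, HAND), np.full(150, FEET)]
        x[y == FEET] += 0.8
        ours = ShrinkageLDA(shrinkage=0.0).fit(x, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(x, y)
        w1, w2 = ours.coef_, ref.coef_.ravel()
        cos = w1 @ w2 / np.linalg.norm(w1) / np.linalg.norm(w2)
        assert cos >= 0.999

    def test_class_scores_difference_is_decision_function(self, rng):
        x = rng.standard_normal((50, 4))
        y = np.r_[np.full(25, HAND), np.full(25, FEET)]
        x[y == FEET] += 1.0
        m = ShrinkageLDA().fit(x, y)
        z = m.class_scores(x)
        np.testing.assert_allclose(z[:, 1] - z[:, 0], m.decision_function(x),
                                   atol=1e-9)

    def test_undersized_class_rejected(self, rng):
        x = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            ShrinkageLDA().fit(x, np.array([HAND, HAND, FEET]))


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(20)
    trials = rng.standard_normal((12, 13, 2048)) * 5
    y = np.array([HAND, FEET] * 6)
    dec = MotorImageryDecoder().fit(trials, y)
    return dec.model_


class TestStream:
    def test_sixteen_outputs_per_second(self, model, rng):
        trial = Trial(data=rng.standard_normal((13, 2048)) * 5)
        series = classify_stream(trial, model, rate_hz=16)
        # classifiable time spans 1..8 s -> 7 s * 16 + endpoint
        assert len(series.scores) == 7 * 16 + 1
        assert series.times_s[0] == pytest.approx(1.0)
        assert series.times_s[-1] == pytest.approx(8.0)
        np.testing.assert_allclose(np.diff(series.times_s), 1 / 16)

    def test_stream_equals_batch_extraction(self, model, rng):
        """The score streamed at 5.5 s equals batch feature extraction and
        scoring at 5.5 s."""
        trial = Trial(data=rng.standard_normal((13, 2048)) * 5)
        series = classify_stream(trial, model)
        filtered = apply_filterbank(model.fb, trial.data)
        feats = extract_features(filtered, model.csp, 5.5, FS)
        batch = model.slda.decision_function(feats[None, :])[0]
        i = np.argmin(np.abs(series.times_s - 5.5))
        assert series.scores[i] == pytest.approx(batch, abs=1e-9)

    def test_zero_weights_tie_breaks_to_hand(self, model, rng):
        import copy
        m = copy.deepcopy(model)
        m.slda.coef_ = np.zeros_like(m.slda.coef_)
        m.slda.intercept_ = 0.0
        m.slda._class_w = np.zeros_like(m.slda._class_w)
        m.slda._class_b = np.zeros_like(m.slda._class_b)
        trial = Trial(data=rng.standard_normal((13, 2048)))
        series = classify_stream(trial, m)
        assert np.all(series.predictions == HAND)

    def test_rate_must_divide_fs(self, model, rng):
        trial = Trial(data=rng.standard_normal((13, 2048)))
        with pytest.raises(ValueError, match="divide"):
            classify_stream(trial, model, rate_hz=17)

    def test_serialization_reproduces_scores(self, model, rng, tmp_path):
        trial = Trial(data=rng.standard_normal((13, 2048)) * 5)
        before = classify_stream(trial, model)
        path = tmp_path / "model.h5"
        save_model(path, model)
        after = classify_stream(trial, load_model(path))
        np.testing.assert_array_equal(before.scores, after.scores)
        np.testing.assert_array_equal(before.predictions, after.predictions)
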