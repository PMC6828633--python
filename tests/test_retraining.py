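"""Softmax, confidence gating and the recurrent training schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coadaptbci.data_model import FEET, HAND, TrialTiming, segment_trials
from coadaptbci.preprocess import build_filterbank
from coadaptbci.retraining import (SEMISUPERVISED, SUPERVISED,
                                   RecurrentTrainer, RetrainPolicy,
                                   majority_label, peak_class_probability,
                                   quartile_gate, softmax)


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax([0.0, 0.0]), [0.5, 0.5])

    def test_known_value(self):
        """Direct evaluation of e/(1+e) for scores (1, 0)."""
        p = softmax([1.0, 0.0])
        assert p[0] == pytest.approx(0.7311, abs=5e-5)
        assert p[1] == pytest.approx(0.2689, abs=5e-5)

    def test_large_scores_do_not_overflow(self):
        p = softmax([1000.0, 0.0])
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p, [1.0, 0.0], atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            softmax([np.nan, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-15, 15), min_size=2, max_size=5),
           st.floats(-20, 20))
    def test_probability_axioms_and_shift_invariance(self, z, c):
        p = softmax(z)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0) and np.all(p < 1)
        np.testing.assert_allclose(softmax(np.asarray(z) + c), p, atol=1e-9)


class TestPeakProbability:
    def test_all_zero_scores_tie(self):
        peak, label = peak_class_probability(np.zeros((5, 2)))
        assert peak == pytest.approx(0.5)
        assert label == HAND

    def test_consistently_positive_scores(self):
        z = np.column_stack([np.zeros(10), np.linspace(3, 8, 10)])
        peak, label = peak_class_probability(z)
        assert label == FEET and peak > 0.95

    def test_matches_exhaustive_scan(self, rng):
        """Peak confidence equals a brute-force scan over samples x classes."""
        z = rng.standard_normal((40, 2)) * 2
        peak, label = peak_class_probability(z)
        best = (-1.0, None)
        for s in range(z.shape[0]):
            e = np.exp(z[s] - z[s].max())
            p = e / e.sum()
            for k in range(2):
                if p[k] > best[0]:
                    best = (p[k], k)
        assert peak == pytest.approx(best[0], abs=1e-12)
        assert label == best[1]

    def test_empty_period_errors(self):
        with pytest.raises(ValueError, match="empty"):
            peak_class_probability(np.zeros((0, 2)))

    def test_majority_rule(self):
        z = np.array([[0, 1], [0, 1], [1, 0.0]])
        assert majority_label(z) == FEET


class TestQuartileGate:
    def test_middle_band_kept_vs_sort_oracle(self):
        probs = np.round(np.linspace(0.51, 0.58, 8), 4)
        kept, discarded = quartile_gate(probs)
        q1, q3 = np.quantile(probs, [0.25, 0.75])
        oracle = [i for i, p in enumerate(probs) if q1 <= p <= q3]
        assert kept == oracle
        assert sorted(kept + discarded) == list(range(8))

    def test_identical_confidences_all_kept(self):
        kept, discarded = quartile_gate([0.7] * 6)
        assert kept == list(range(6)) and discarded == []

    def test_too_few_candidates_defer(self):
        with pytest.raises(ValueError, match="at least 4"):
            quartile_gate([0.5, 0.6, 0.7])


class TestPolicy:
    def test_defaults(self):
        p = RetrainPolicy()
        assert (p.first_training_tpc, p.increment_tpc,
                p.supervised_calibration_tpc) == (10, 5, 40)

    @pytest.mark.parametrize("kwargs", [
        {"mode": "oracle"},
        {"increment_tpc": 0},
        {"supervised_calibration_tpc": 5},
        {"quartile_population": "everything"},
    ])
    def test_invalid_policies_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RetrainPolicy(**kwargs)


class _Taint:
    """A label stand-in that explodes on any attempt to read it as a class."""

    def _boom(self, *a, **k):
        raise AssertionError("true label dereferenced after the switch")

    __int__ = __index__ = __eq__ = __hash__ = __bool__ = _boom


class TestSchedule:
    def test_supervised_events_every_five_tpc(self, small_session,
                                              sup_result_small):
        """Clean stream: first refit at 10 TPC, then one per 5 new TPC."""
        _, _, cfg = small_session
        events = sup_result_small.events
        assert len(events) == 1 + (cfg.n_tpc - 10) // 5
        assert events[0].n_trials_used == 2 * 10
        # refit k fires when the slower class reaches 10 + 5k accepted trials;
        # the other class may lead by a few trials within the current run
        for k, e in enumerate(events):
            threshold = 10 + 5 * k
            assert 2 * threshold <= e.n_trials_used <= 2 * threshold + cfg.run_tpc
        assert all(e.mode == SUPERVISED for e in events)

    def test_semisupervised_calibration_then_artificial(self, comparison_80):
        _, _, sup, semi = comparison_80
        calib = [e for e in semi.events if e.mode == SUPERVISED]
        post = [e for e in semi.events if e.mode == SEMISUPERVISED]
        # calibration refits stop at 40 TPC (80 trials), all on true labels
        assert all(e.label_source == "true" for e in calib)
        assert max(e.trial_index for e in calib) < 80
        assert len(post) >= 1
        assert all(e.label_source == "mixed" for e in post)
        assert all(e.trial_index >= 80 for e in post)
        # artificial labels exist only after the switch
        for t in semi.trials:
            if t.index < 80:
                assert t.artificial_label is None
            else:
                assert t.artificial_label in (HAND, FEET)
                assert 0.0 < t.peak_class_prob <= 1.0

    def test_semisupervised_retrains_fewer(self, comparison_80):
        _, _, sup, semi = comparison_80
        assert semi.n_retrainings < sup.n_retrainings

    def test_true_labels_never_read_after_switch(self, comparison_80):
        """Label firewall: post-switch trials with poisoned true labels are
        still ingested, gated and used for refits without error."""
        rec, _, _, _ = comparison_80
        fb = build_filterbank(fs=rec.fs)
        policy = RetrainPolicy(mode=SEMISUPERVISED)
        trainer = RecurrentTrainer(policy, fb)
        from coadaptbci.decoder import classify_stream
        timing = TrialTiming()
        n_semi_events = 0
        for trial in segment_trials(rec):
            scores = None
            if trainer.switched:
                trial.true_label = _Taint()
            if trainer.model is not None:
                series = classify_stream(trial, trainer.model)
                mask = series.times_s >= timing.feedback_start_s
                scores = series.class_scores[mask]
            model = trainer.observe(trial, class_scores=scores)
            if model is not None and model.label_source == "mixed":
                n_semi_events += 1
        assert n_semi_events >= 1

    def test_event_log_deterministic(self, small_session):
        from coadaptbci import run_session
        rec, _, _ = small_session
        a = run_session(rec, RetrainPolicy(mode=SUPERVISED))
        b = run_session(rec, RetrainPolicy(mode=SUPERVISED))
        assert [vars(e) for e in a.events] == [vars(e) for e in b.events]
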