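"""Recurrent training units: supervised and semi-supervised decoder refits.

The supervised unit accumulates trials, runs the statistical outlier
rejection over all available data, and refits the CSP bank and sLDA with
true class labels whenever 5 new trials per class survive (10 per class for
the first fit). The semi-supervised unit behaves identically for the first
40 trials per class; afterwards it labels incoming trials with the decoder's
own output — the softmax of the per-sample LDA scores over the feedback
period, reduced to a per-trial peak class probability — keeps only trials
whose confidence lies within the first and third quartile of the candidate
batch, and counts only gate survivors toward the retraining quota. After the
switch no fitting routine reads a true label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import FEET, HAND, Trial, TrialTiming
from .decoder import (CSPBank, DecoderModel, ShrinkageLDA,
                      features_from_moments, window_moments)
from .preprocess import (FilterBank, TrialRejectStats, apply_filterbank,
                         reject_outliers, trial_reject_stats)

SUPERVISED = "supervised"
SEMISUPERVISED = "semisupervised"


# ---------------------------------------------------------------------------
# confidence machinery
# ---------------------------------------------------------------------------

def softmax(z) -> np.ndarray:
    """Map linear class scores to probabilities: σ(z)_i = e^{z_i} / Σ_j e^{z_j}.

    Works on a 1-D score vector or row-wise on a 2-D array. Stable for large
    scores (max subtraction); every output is in (0, 1) and each row sums to
    1. Raises on NaN input.
    """
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        raise ValueError("softmax input contains NaN")
    m = z.max(axis=-1, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class ProbSeries:
    """Per-sample class probabilities over a trial's feedback period."""

    z: np.ndarray            # (n_samples, K) linear class scores
    probs: np.ndarray        # (n_samples, K) softmax probabilities

    @property
    def n_classes(self) -> int:
        return self.z.shape[1]


def prob_series(class_scores: np.ndarray) -> ProbSeries:
    z = np.atleast_2d(np.asarray(class_scores, dtype=float))
    return ProbSeries(z=z, probs=softmax(z))


def peak_class_probability(class_scores: np.ndarray) -> tuple[float, int]:
    """Per-trial confidence: the peak, over feedback samples, of the maximum
    class probability — and the class attaining it.

    Ties (all probabilities equal, peak exactly 1/K) resolve to the
    lowest-numbered class (hand) at the earliest sample, deterministically.
    """
    z = np.atleast_2d(np.asarray(class_scores, dtype=float))
    if z.shape[0] == 0:
        raise ValueError("empty feedback period: no scores to evaluate")
    p = softmax(z)
    per_sample = p.max(axis=1)
    s = int(np.argmax(per_sample))
    label = int(np.argmax(p[s]))
    return float(per_sample[s]), label


def majority_label(class_scores: np.ndarray) -> int:
    """Alternative artificial-label rule: majority vote of per-sample argmax."""
    z = np.atleast_2d(np.asarray(class_scores, dtype=float))
    votes = np.argmax(z, axis=1)
    counts = np.bincount(votes, minlength=z.shape[1])
    return int(np.argmax(counts))       # tie -> lowest class id


def quartile_gate(peak_probs, bounds: tuple[float, float] = (0.25, 0.75),
                  population=None) -> tuple[list[int], list[int]]:
    """Keep candidates whose confidence lies within [Q1, Q3] (inclusive).

    Quartiles use linear interpolation between order statistics and are
    computed over ``population`` (defaults to the candidates themselves).
    Returns ``(kept_indices, discarded_indices)``. Needs >= 4 population
    values; below that the caller should defer retraining.
    """
    probs = np.asarray(list(peak_probs), dtype=float)
    pop = probs if population is None else np.asarray(list(population), dtype=float)
    if pop.size < 4:
        raise ValueError("quartile gate needs at least 4 candidates")
    q1, q3 = np.quantile(pop, bounds)
    keep = (probs >= q1) & (probs <= q3)
    return list(np.flatnonzero(keep)), list(np.flatnonzero(~keep))


# ---------------------------------------------------------------------------
# policy / pool / events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetrainPolicy:
    """Schedule constants governing when and with what the decoder is refit.

    ``quartile_population`` selects whether the confidence gate's quartiles
    come from the current candidate batch ("batch", default) or from every
    confidence recorded so far ("pool"). ``label_rule`` picks the artificial
    label as the class at the peak-confidence sample ("peak", default) or by
    majority vote over feedback samples ("majority").
    """

    mode: str = SUPERVISED
    first_training_tpc: int = 10
    increment_tpc: int = 5
    supervised_calibration_tpc: int = 40
    quartile_bounds: tuple[float, float] = (0.25, 0.75)
    quartile_population: str = "batch"
    label_rule: str = "peak"

    def __post_init__(self) -> None:
        if self.mode not in (SUPERVISED, SEMISUPERVISED):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.first_training_tpc < 1 or self.increment_tpc < 1:
            raise ValueError("schedule counts must be >= 1")
        if self.supervised_calibration_tpc < self.first_training_tpc:
            raise ValueError("calibration must cover at least the first training")
        if self.quartile_population not in ("batch", "pool"):
            raise ValueError("quartile_population must be 'batch' or 'pool'")
        if self.label_rule not in ("peak", "majority"):
            raise ValueError("label_rule must be 'peak' or 'majority'")


@dataclass
class RetrainEvent:
    """One decoder refit, machine-readable."""

    version: int
    trial_index: int                 # stream index after which the refit ran
    mode: str                        # label regime of this refit
    n_trials_used: int
    n_rejected: int                  # rejected among all candidates at refit
    n_gate_discarded: int            # cumulative confidence-gate discards
    label_source: str                # "true" | "mixed"


@dataclass
class _Record:
    """Internal per-trial bookkeeping with cached sufficient statistics."""

    index: int
    true_label: object               # opaque after the semi-supervised switch
    reject_stats: TrialRejectStats
    csp_covs: np.ndarray             # (n_bands, n_ch, n_ch) epoch covariances
    lda_moment: np.ndarray           # (n_bands, n_ch, n_ch) window 2nd moment
    lda_mean: np.ndarray             # (n_bands, n_ch)
    post_switch: bool = False
    artificial_label: int | None = None
    peak_prob: float | None = None
    gate_discarded: bool = False     # permanently dropped by the gate
    gate_survived: bool = False      # passed the gate, counts toward quota
    in_pool: bool = False            # semi-supervised gate survivor in pool


@dataclass
class TrainingPool:
    """The labelled trials a refit may use, plus the rejection ledger."""

    records: list = field(default_factory=list)
    label_sources: list = field(default_factory=list)

    def labelled(self):
        out = []
        for rec, src in zip(self.records, self.label_sources):
            label = rec.true_label if src == "true" else rec.artificial_label
            out.append((rec, int(label)))
        return out


class RecurrentTrainer:
    """Stateful recurrent training unit (one per session).

    Feed completed trials through :meth:`observe`; it returns a new
    :class:`DecoderModel` when a refit happened (to be hot-swapped in the
    next inter-trial interval) and ``None`` otherwise.
    """

    def __init__(self, policy: RetrainPolicy, fb: FilterBank,
                 timing: TrialTiming | None = None,
                 csp_shrinkage: float | None = None,
                 lda_shrinkage: float | None = None):
        self.policy = policy
        self.fb = fb
        self.timing = timing or TrialTiming()
        self.csp_shrinkage = csp_shrinkage
        self.lda_shrinkage = lda_shrinkage
        self.model: DecoderModel | None = None
        self.events: list[RetrainEvent] = []
        self._records: list[_Record] = []
        self._n_observed = 0
        # per-class accepted-trial threshold: 10 TPC first, then +5 TPC per refit
        self._threshold_tpc = policy.first_training_tpc
        self._n_gate_discarded = 0

    # -- helpers -----------------------------------------------------------

    @property
    def switched(self) -> bool:
        """True once the semi-supervised unit stopped consuming true labels.

        The calibration budget is counted in observed trials (2 balanced
        classes x calibration TPC) so the check itself needs no labels.
        """
        return (self.policy.mode == SEMISUPERVISED
                and self._n_observed >= 2 * self.policy.supervised_calibration_tpc)

    def _cache_record(self, trial: Trial, filtered: np.ndarray) -> _Record:
        fs = self.fb.fs
        lo = int(round(self.timing.csp_epoch[0] * fs))
        hi = int(round(self.timing.csp_epoch[1] * fs))
        epoch = filtered[:, :, lo:hi]
        ec = epoch - epoch.mean(axis=-1, keepdims=True)
        covs = np.einsum("bcn,bdn->bcd", ec, ec) / ec.shape[-1]
        moment, mean = window_moments(filtered, self.timing.lda_feature_time_s, fs)
        return _Record(
            index=trial.index,
            true_label=trial.true_label,
            reject_stats=trial_reject_stats(trial.data, fs),
            csp_covs=covs,
            lda_moment=moment,
            lda_mean=mean,
        )

    def _reject_flags(self) -> list[bool]:
        if len(self._records) < 2:
            return [False] * len(self._records)
        report = reject_outliers(
            [None] * len(self._records), self.fb.fs,
            precomputed=[r.reject_stats for r in self._records])
        return report.flags

    def _artificial(self, class_scores: np.ndarray, rec: _Record) -> None:
        peak, label = peak_class_probability(class_scores)
        if self.policy.label_rule == "majority":
            label = majority_label(class_scores)
        rec.peak_prob = peak
        rec.artificial_label = label

    # -- fitting -----------------------------------------------------------

    def _label_of(self, rec: _Record) -> int:
        # post-switch records are labelled exclusively by the decoder itself
        if rec.post_switch:
            return int(rec.artificial_label)
        return int(rec.true_label)

    def _refit(self, pool_records: list[_Record], flags: list[bool],
               mode: str) -> DecoderModel | None:
        labels = np.array([self._label_of(r) for r in pool_records])
        covs = np.stack([r.csp_covs for r in pool_records])
        try:
            csp = CSPBank(shrinkage=self.csp_shrinkage).fit_from_covariances(
                covs, labels)
            feats = np.stack([
                features_from_moments(r.lda_moment, r.lda_mean, csp)
                for r in pool_records
            ])
            slda = ShrinkageLDA(shrinkage=self.lda_shrinkage).fit(feats, labels)
        except (ValueError, np.linalg.LinAlgError):
            return None
        version = len(self.events) + 1
        source = "mixed" if any(r.post_switch for r in pool_records) else "true"
        model = DecoderModel(fb=self.fb, csp=csp, slda=slda, version=version,
                             n_trials_used=len(pool_records), label_source=source)
        self.events.append(RetrainEvent(
            version=version, trial_index=self._n_observed - 1, mode=mode,
            n_trials_used=len(pool_records), n_rejected=int(np.sum(flags)),
            n_gate_discarded=self._n_gate_discarded, label_source=source))
        self.model = model
        return model

    # -- the step ----------------------------------------------------------

    def observe(self, trial: Trial, filtered: np.ndarray | None = None,
                class_scores: np.ndarray | None = None) -> DecoderModel | None:
        """Ingest one completed trial; maybe return a refit decoder.

        ``filtered`` is the trial's causal filterbank output if the caller
        (the online unit) already computed it; ``class_scores`` are the
        online per-sample LDA class scores over the feedback period, which
        the semi-supervised unit turns into the trial's confidence.
        """
        if filtered is None:
            filtered = apply_filterbank(self.fb, trial.data)
        was_switched = self.switched
        rec = self._cache_record(trial, filtered)
        rec.post_switch = was_switched
        self._records.append(rec)
        self._n_observed += 1

        if rec.post_switch:
            if class_scores is None and self.model is not None:
                from .decoder import classify_stream
                series = classify_stream(trial, self.model, filtered=filtered)
                mask = series.times_s >= self.timing.feedback_start_s
                class_scores = series.class_scores[mask]
            if class_scores is None or len(class_scores) == 0:
                raise ValueError("semi-supervised trial without feedback scores")
            self._artificial(np.asarray(class_scores), rec)
            trial.artificial_label = rec.artificial_label
            trial.peak_class_prob = rec.peak_prob

        flags = self._reject_flags()
        for r, f in zip(self._records, flags):
            if isinstance(trial, Trial) and r.index == trial.index:
                trial.rejected = bool(f)

        if not was_switched:
            return self._step_supervised(flags)
        return self._step_semisupervised(flags)

    def _step_supervised(self, flags: list[bool]) -> DecoderModel | None:
        accepted = [r for r, f in zip(self._records, flags)
                    if not f and not r.post_switch]
        counts = {HAND: 0, FEET: 0}
        for r in accepted:
            counts[int(r.true_label)] += 1
        if all(counts[k] >= self._threshold_tpc for k in (HAND, FEET)):
            model = self._refit(accepted, flags, SUPERVISED)
            if model is not None:
                self._threshold_tpc += self.policy.increment_tpc
            return model
        return None

    def _counts(self, records) -> dict[int, int]:
        counts = {HAND: 0, FEET: 0}
        for r in records:
            counts[int(r.artificial_label)] += 1
        return counts

    def _step_semisupervised(self, flags: list[bool]) -> DecoderModel | None:
        flagged = {r.index for r, f in zip(self._records, flags) if f}

        # candidates that passed rejection but have not faced the gate yet
        pending = [r for r in self._records
                   if r.post_switch and not r.gate_discarded
                   and not r.gate_survived and r.index not in flagged]
        counts = self._counts(pending)
        if (all(counts[k] >= self.policy.increment_tpc for k in (HAND, FEET))
                and len(pending) >= 4):
            if self.policy.quartile_population == "pool":
                population = [r.peak_prob for r in self._records
                              if r.peak_prob is not None]
            else:
                population = None
            kept_idx, discarded_idx = quartile_gate(
                [r.peak_prob for r in pending], self.policy.quartile_bounds,
                population=population)
            for i in discarded_idx:
                pending[i].gate_discarded = True
            for i in kept_idx:
                pending[i].gate_survived = True
            self._n_gate_discarded += len(discarded_idx)

        # only gate survivors count toward the retraining quota
        confirmed = [r for r in self._records
                     if r.gate_survived and not r.in_pool
                     and r.index not in flagged]
        c_counts = self._counts(confirmed)
        if not all(c_counts[k] >= self.policy.increment_tpc
                   for k in (HAND, FEET)):
            return None
        pool = [r for r, f in zip(self._records, flags) if not f
                and (not r.post_switch or r.in_pool or r.gate_survived)]
        model = self._refit(pool, flags, SEMISUPERVISED)
        if model is not None:
            for r in confirmed:
                r.in_pool = True
        return model

    # -- public views ------------------------------------------------------

    def pool(self) -> TrainingPool:
        flags = self._reject_flags()
        records = [r for r, f in zip(self._records, flags) if not f
                   and (not r.post_switch or r.in_pool or r.gate_survived)]
        sources = ["artificial" if r.post_switch else "true" for r in records]
        return TrainingPool(records=records, label_sources=sources)

    @property
    def n_retrainings(self) -> int:
        return len(self.events)


def step(trainer: RecurrentTrainer, trial: Trial,
         filtered: np.ndarray | None = None,
         class_scores: np.ndarray | None = None) -> DecoderModel | None:
    """Functional wrapper over :meth:`RecurrentTrainer.observe`."""
    return trainer.observe(trial, filtered=filtered, class_scores=class_scores)


__all__ = [
    "SUPERVISED", "SEMISUPERVISED", "softmax", "ProbSeries", "prob_series",
    "peak_class_probability", "majority_label", "quartile_gate",
    "RetrainPolicy", "RetrainEvent", "TrainingPool", "RecurrentTrainer", "step",
]
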