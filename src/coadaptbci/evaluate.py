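"""Session evaluation: accuracy time-courses, chance level, PSD diagnostics.

Accuracy is evaluated per classifier output time over all feedback trials;
the summary metrics are the peak of that curve and its mean over seconds
4–8 of the trial (the feedback period, i.e. seconds 1–5 after the cue).
The chance level is the upper limit of the adjusted Wald binomial interval
at p = 0.5, which accounts for the number of evaluated trials. Spectral
diagnostics use small-Laplacian derivations of C3, Cz and C4 with a 1-s
Welch window (no overlap) over the feedback period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .data_model import EEGRecording, Trial, TrialTiming
from .session_sim import SessionResult

#: small-Laplacian neighbourhoods on the 13-channel motor grid
LAPLACIAN_NEIGHBORS = {
    "C3": ("C1", "C5", "FC3", "CP3"),
    "Cz": ("C1", "C2", "FCz", "CPz"),
    "C4": ("C2", "C6", "FC4", "CP4"),
}


@dataclass
class AccuracyTimecourse:
    """Classification accuracy as a function of within-trial time."""

    times_s: np.ndarray
    accuracy: np.ndarray
    peak: float
    mean: float                         # over the evaluation window
    n_trials: int
    eval_window: tuple[float, float] = (4.0, 8.0)


def accuracy_timecourse(result: SessionResult,
                        timing: TrialTiming | None = None,
                        trial_subset=None) -> AccuracyTimecourse:
    """Per-timepoint accuracy over the evaluated feedback trials.

    ``trial_subset`` optionally restricts evaluation to the given stream
    indices (e.g. an experiment stage). Peak is the curve maximum; mean is
    taken over the half-open evaluation window [4, 8) s.
    """
    timing = timing or TrialTiming()
    trials = result.feedback_trials
    if trial_subset is not None:
        subset = set(trial_subset)
        trials = [t for t in trials if t.index in subset]
    if not trials:
        raise ValueError("no feedback trials to evaluate")
    times = trials[0].scores.times_s
    correct = np.stack([
        (t.scores.predictions == t.true_label).astype(float) for t in trials
    ])
    acc = correct.mean(axis=0)
    lo, hi = timing.eval_window
    window = (times >= lo) & (times < hi)
    return AccuracyTimecourse(
        times_s=times, accuracy=acc, peak=float(acc.max()),
        mean=float(acc[window].mean()), n_trials=len(trials),
        eval_window=timing.eval_window)


def stage_table(result: SessionResult, stages: dict[str, tuple[int, int]]
                | None = None, timing: TrialTiming | None = None
                ) -> pd.DataFrame:
    """Peak/mean accuracy per experiment stage (rows mirror the four phases
    initial / eval 1–3 of the protocol by default).

    Stage bounds are in feedback-trial-per-class counts, half-open; e.g.
    ``(0, 40)`` is the first 40 feedback TPC.
    """
    stages = stages or {"Initial (1-40 TPC)": (0, 40),
                        "Eval 1 (41-90 TPC)": (40, 90),
                        "Eval 2 (91-140 TPC)": (90, 140),
                        "Eval 3 (141-190 TPC)": (140, 10 ** 9)}
    per_class_count: dict[int, int] = {}
    stage_of_trial: dict[int, str] = {}
    for t in result.feedback_trials:
        k = per_class_count.get(t.true_label, 0)
        per_class_count[t.true_label] = k + 1
        for name, (lo, hi) in stages.items():
            if lo <= k < hi:
                stage_of_trial[t.index] = name
                break
    rows = []
    for name in stages:
        subset = [i for i, s in stage_of_trial.items() if s == name]
        if not subset:
            continue
        tc = accuracy_timecourse(result, timing=timing, trial_subset=subset)
        rows.append({"stage": name, "peak_pct": 100 * tc.peak,
                     "mean_pct": 100 * tc.mean, "n_trials": tc.n_trials})
    return pd.DataFrame(rows)


def chance_level(n_trials: int, alpha: float = 0.05) -> float:
    """Chance-level accuracy (percent) from the adjusted Wald interval.

    For a binomial proportion at p = 0.5, add two pseudo-successes and two
    pseudo-failures: p̃ = (n/2 + 2) / (n + 4) = 0.5, and return the upper
    one-sided bound p̃ + z_{1-α} sqrt(p̃(1-p̃)/(n+4)) as a percentage. For
    360 evaluated trials at α = 0.05 this is 54.3%.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = n_trials + 4
    p = (n_trials / 2.0 + 2.0) / n
    z = spstats.norm.ppf(1.0 - alpha)
    return 100.0 * (p + z * np.sqrt(p * (1.0 - p) / n))


@dataclass
class PSDReport:
    """Welch PSD of Laplacian-derived channels, per condition, in dB."""

    freqs: np.ndarray
    power_db: dict[str, dict[int, np.ndarray]]   # channel -> class -> PSD
    fs: float
    n_trials: dict[int, int] | None = None


def laplacian_derivation(rec_or_data, channel: str,
                         channel_labels=None) -> np.ndarray:
    """Small-Laplacian re-reference: center minus mean of its 4 orthogonal
    neighbours. Raises naming any missing neighbour channel."""
    if isinstance(rec_or_data, EEGRecording):
        data, labels = rec_or_data.signal, list(rec_or_data.channel_labels)
    else:
        data, labels = np.asarray(rec_or_data), list(channel_labels)
    if channel not in LAPLACIAN_NEIGHBORS:
        raise KeyError(f"no Laplacian neighbourhood defined for {channel!r}")
    missing = [c for c in (channel, *LAPLACIAN_NEIGHBORS[channel])
               if c not in labels]
    if missing:
        raise ValueError(f"missing channels for Laplacian: {missing}")
    idx = {c: labels.index(c) for c in (channel, *LAPLACIAN_NEIGHBORS[channel])}
    neigh = np.mean([data[idx[c]] for c in LAPLACIAN_NEIGHBORS[channel]], axis=0)
    return data[idx[channel]] - neigh


def laplacian_psd(trials, labels, fs: float, channel_labels,
                  timing: TrialTiming | None = None,
                  channels=("C3", "Cz", "C4")) -> PSDReport:
    """Condition-averaged Welch PSD of Laplacian C3/Cz/C4 over the feedback
    period (1-s segments, no overlap), in dB.

    ``trials`` are Trial objects or (n_ch, n_samples) arrays; ``labels`` the
    per-trial condition ids.
    """
    timing = timing or TrialTiming()
    lo = int(round(timing.feedback_start_s * fs))
    hi = int(round(timing.imagery_end_s * fs))
    nper = int(round(fs))
    power: dict[str, dict[int, list]] = {c: {} for c in channels}
    counts: dict[int, int] = {}
    for trial, lab in zip(trials, labels):
        data = trial.data if isinstance(trial, Trial) else np.asarray(trial)
        lab = int(lab)
        counts[lab] = counts.get(lab, 0) + 1
        for ch in channels:
            lap = laplacian_derivation(data, ch, channel_labels)[lo:hi]
            freqs, pxx = sps.welch(lap, fs=fs, nperseg=nper, noverlap=0)
            power[ch].setdefault(lab, []).append(pxx)
    power_db = {
        ch: {lab: 10.0 * np.log10(np.mean(p, axis=0))
             for lab, p in by_class.items()}
        for ch, by_class in power.items()
    }
    return PSDReport(freqs=freqs, power_db=power_db, fs=fs, n_trials=counts)


def summary_table(sup: SessionResult, semi: SessionResult,
                  timing: TrialTiming | None = None) -> pd.DataFrame:
    """Peak/mean accuracy and retrain counts for a paired policy comparison."""
    rows = []
    for name, res in (("supervised", sup), ("semisupervised", semi)):
        tc = accuracy_timecourse(res, timing=timing)
        rows.append({"policy": name, "peak_pct": 100 * tc.peak,
                     "mean_pct": 100 * tc.mean,
                     "n_feedback_trials": tc.n_trials,
                     "n_retrainings": res.n_retrainings})
    return pd.DataFrame(rows)


__all__ = [
    "LAPLACIAN_NEIGHBORS", "AccuracyTimecourse", "accuracy_timecourse",
    "stage_table", "chance_level", "PSDReport", "laplacian_derivation",
    "laplacian_psd", "summary_table",
]
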