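"""Core data types for co-adaptive motor-imagery BCI sessions.

Conventions
-----------
* Time is in seconds relative to trial start (fixation-cross onset = 0 s;
  the class cue appears at 3 s). Sample indexing is 0-based and windows are
  half-open ``[start, end)``, so a 1-s window holds exactly ``fs`` samples.
* Class labels are small integers: ``HAND = 0`` (right-hand motor imagery,
  LDA-negative), ``FEET = 1`` (both-feet motor imagery, LDA-positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

HAND = 0
FEET = 1
CLASS_NAMES = {HAND: "hand", FEET: "feet"}

#: Default motor-cortex montage (13 active electrodes).
DEFAULT_CHANNELS = (
    "FC3", "FCz", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CPz", "CP4",
)

_FORMAT_VERSION = 1


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with cue-event markers.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        One label per channel, in signal row order.
    events : list of (int, int)
        ``(sample_index, event_code)`` pairs; for motor-imagery sessions the
        event code is the trial's class label and the sample index marks
        trial start (fixation onset).
    """

    signal: np.ndarray
    fs: float = 256.0
    channel_labels: Sequence[str] = DEFAULT_CHANNELS
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaN")
        n = self.signal.shape[1]
        for i, (s, _) in enumerate(self.events):
            if not 0 <= s < n:
                raise ValueError(f"event {i} at sample {s} outside signal of length {n}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return list(self.channel_labels).index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass(frozen=True)
class TrialTiming:
    """Landmark times (seconds from trial start) of the 8-s trial paradigm.

    The fixation cross appears at 0 s, the class cue at 3 s, and motor
    imagery lasts until 8 s. Feedback starts 1.25 s into the imagery period.
    The CSP covariance epoch is [4.75, 7.75) s, the single LDA training
    feature is taken at 5.5 s (window [4.5, 5.5)), and accuracies are
    evaluated over [4.0, 8.0) s.
    """

    trial_len_s: float = 8.0
    cue_onset_s: float = 3.0
    imagery_start_s: float = 3.0
    imagery_end_s: float = 8.0
    feedback_start_s: float = 4.25
    csp_epoch: tuple[float, float] = (4.75, 7.75)
    lda_feature_time_s: float = 5.5
    eval_window: tuple[float, float] = (4.0, 8.0)

    def __post_init__(self) -> None:
        marks = [
            self.cue_onset_s, self.imagery_start_s, self.imagery_end_s,
            self.feedback_start_s, *self.csp_epoch, self.lda_feature_time_s,
            *self.eval_window,
        ]
        for t in marks:
            if not 0.0 <= t <= self.trial_len_s:
                raise ValueError(f"landmark {t} s outside [0, {self.trial_len_s}]")
        if abs((self.csp_epoch[1] - self.csp_epoch[0]) - 3.0) > 1e-9:
            raise ValueError("CSP epoch must be 3 s long")
        if abs(self.feedback_start_s - (self.cue_onset_s + 1.25)) > 1e-9:
            raise ValueError("feedback starts 1.25 s after cue onset")

    def n_samples(self, fs: float) -> int:
        return int(round(self.trial_len_s * fs))


@dataclass
class Trial:
    """One segmented trial.

    ``data`` runs from trial start (sample 0 = fixation onset). ``rejected``
    / ``reject_reason`` are filled by the outlier rejection;
    ``artificial_label`` and ``peak_class_prob`` only in semi-supervised
    retraining after the calibration switch.
    """

    data: np.ndarray
    true_label: int | None = None
    artificial_label: int | None = None
    rejected: bool = False
    reject_reason: str | None = None
    peak_class_prob: float | None = None
    index: int = -1  # position in the session stream

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")


@dataclass(frozen=True)
class SessionSpec:
    """Session bookkeeping: trials per class, run grouping, break positions.

    Defaults follow the 190-TPC / 19-runs-of-10 protocol with extended
    breaks after 40, 90 and 140 TPC.
    """

    n_tpc: int = 190
    n_classes: int = 2
    run_tpc: int = 10
    inter_trial_interval_s: float = 2.0
    break_positions: tuple[int, ...] = (40, 90, 140)

    def __post_init__(self) -> None:
        if self.n_tpc % self.run_tpc != 0:
            raise ValueError("n_tpc must be a whole number of runs")
        if list(self.break_positions) != sorted(set(self.break_positions)):
            raise ValueError("break positions must be strictly increasing")
        if self.break_positions and self.break_positions[-1] >= self.n_tpc:
            raise ValueError("break positions must be < n_tpc")

    @property
    def n_runs(self) -> int:
        return self.n_tpc // self.run_tpc

    @property
    def n_trials(self) -> int:
        return self.n_tpc * self.n_classes


def segment_trials(rec: EEGRecording, timing: TrialTiming | None = None) -> list[Trial]:
    """Epoch a continuous recording at its cue-event markers.

    Returns one :class:`Trial` per event, in temporal order; trial sample 0
    is the event sample (fixation onset). Raises if any event lies closer
    than one trial length to the end of the recording.
    """
    timing = timing or TrialTiming()
    n_trial = timing.n_samples(rec.fs)
    trials: list[Trial] = []
    events = sorted(rec.events, key=lambda e: e[0])
    for i, (start, code) in enumerate(events):
        if start + n_trial > rec.n_samples:
            raise ValueError(
                f"event {i} at sample {start} leaves only "
                f"{rec.n_samples - start} samples, need {n_trial}"
            )
        trials.append(Trial(data=rec.signal[:, start:start + n_trial],
                            true_label=int(code), index=i))
    return trials


# ---------------------------------------------------------------------------
# persistence (HDF5 container: /signal, /fs, /labels, /events, /meta)
# ---------------------------------------------------------------------------

def save_session(path, rec: EEGRecording, extra_meta: dict | None = None) -> None:
    """Write a recording (and optional metadata) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("fs", data=float(rec.fs))
        labels = np.array(list(rec.channel_labels), dtype=h5py.string_dtype("utf-8"))
        f.create_dataset("labels", data=labels)
        ev = np.array(rec.events, dtype=np.int64).reshape(-1, 2)
        f.create_dataset("events", data=ev)
        meta = f.create_group("meta")
        for k, v in (extra_meta or {}).items():
            meta.attrs[k] = v


def load_session(path) -> tuple[EEGRecording, dict]:
    """Read a recording written by :func:`save_session`.

    Round-trips the signal bit-exactly. Returns ``(recording, meta)``.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported session format version {version}")
        for key in ("signal", "fs", "labels", "events"):
            if key not in f:
                raise ValueError(f"truncated session file: missing /{key}")
        signal = f["signal"][()]
        fs = float(f["fs"][()])
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]
        events = [(int(s), int(c)) for s, c in f["events"][()]]
        meta = dict(f["meta"].attrs) if "meta" in f else {}
    return EEGRecording(signal=signal, fs=fs, channel_labels=labels, events=events), meta


def read_raw_eeg(path) -> EEGRecording:
    """Import an EDF(+)/GDF/BDF file with event annotations (optional path).

    Requires :mod:`mne`. Annotation onsets become events; annotation
    descriptions are mapped to integer codes in sorted-description order.
    Signal is converted from volts to microvolts.
    """
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6
    fs = float(raw.info["sfreq"])
    desc = sorted(set(raw.annotations.description))
    code = {d: i for i, d in enumerate(desc)}
    events = [
        (int(round(on * fs)), code[d])
        for on, d in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return EEGRecording(signal=signal, fs=fs, channel_labels=list(raw.ch_names),
                        events=events)


__all__ = [
    "HAND", "FEET", "CLASS_NAMES", "DEFAULT_CHANNELS",
    "EEGRecording", "TrialTiming", "Trial", "SessionSpec",
    "segment_trials", "save_session", "load_session", "read_raw_eeg",
]
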