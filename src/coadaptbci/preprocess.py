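"""Filterbank construction/application and statistical trial rejection.

The decoding frontend bandpass-filters the EEG through 15 overlapping IIR
filters spanning the mu and beta ranges. Before each recurrent retraining a
statistical outlier rejection is run on a 3–35 Hz filtered copy of the
accumulated trials: an absolute amplitude threshold (±125 μV), an abnormal
joint-probability test and an abnormal kurtosis test, the latter two at four
population standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .data_model import EEGRecording, Trial

#: The 15 default bands: 7 in the mu range, 8 in the beta range (Hz).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (6, 8), (7, 9), (8, 10), (9, 11), (10, 12), (11, 13), (12, 14),
    (14, 19), (17, 22), (20, 25), (23, 28), (26, 31), (29, 34), (32, 37),
    (35, 40),
)

DEFAULT_FILTER_ORDER = 8

REJECT_AMP_UV = 125.0
REJECT_SD_MULT = 4.0
REJECT_BAND = (3.0, 35.0)


@dataclass(frozen=True)
class FilterBank:
    """A bank of causal IIR (Butterworth) bandpass filters.

    ``order`` is the overall filter order; each bandpass is designed as a
    Butterworth of that order in second-order sections for numerical
    stability.
    """

    bands: tuple[tuple[float, float], ...]
    order: int
    fs: float
    sos: tuple[np.ndarray, ...] = field(repr=False, default=())

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def build_filterbank(bands=None, order: int = DEFAULT_FILTER_ORDER,
                     fs: float = 256.0) -> FilterBank:
    """Design the filterbank; defaults reproduce the 15 mu/beta bands.

    Raises ``ValueError`` for band edges at or above Nyquist, and verifies
    every filter is stable (all poles strictly inside the unit circle).
    """
    bands = tuple(tuple(map(float, b)) for b in (bands or DEFAULT_BANDS))
    nyq = fs / 2.0
    sos_list = []
    for lo, hi in bands:
        if not 0 < lo < hi:
            raise ValueError(f"invalid band ({lo}, {hi})")
        if hi >= nyq:
            raise ValueError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
        # scipy's N is the order of the prototype; a bandpass doubles it.
        if order % 2:
            raise ValueError("bandpass order must be even")
        sos = sps.butter(order // 2, [lo, hi], btype="bandpass", fs=fs,
                         output="sos")
        _, poles, _ = sps.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(f"unstable filter for band ({lo}, {hi}) Hz")
        sos_list.append(sos)
    return FilterBank(bands=bands, order=order, fs=fs, sos=tuple(sos_list))


def apply_filterbank(fb: FilterBank, x, fs: float | None = None) -> np.ndarray:
    """Causally filter a signal through every band of the bank.

    Parameters
    ----------
    x : EEGRecording, Trial or ndarray (channels x samples)
    fs : sampling rate of ``x`` when passing a bare array.

    Returns
    -------
    ndarray, shape (n_bands, n_channels, n_samples)
        Single-pass (causal) filtering: sample t of the output depends only
        on input samples <= t.
    """
    if isinstance(x, EEGRecording):
        data, xfs = x.signal, x.fs
    elif isinstance(x, Trial):
        data, xfs = x.data, fs if fs is not None else fb.fs
    else:
        data = np.asarray(x, dtype=float)
        xfs = fs if fs is not None else fb.fs
    if abs(xfs - fb.fs) > 1e-9:
        raise ValueError(f"input fs {xfs} != filterbank fs {fb.fs}")
    out = np.empty((fb.n_bands, *data.shape))
    for b, sos in enumerate(fb.sos):
        out[b] = sps.sosfilt(sos, data, axis=-1)
    return out


def bandpass_copy(data: np.ndarray, fs: float,
                  band: tuple[float, float] = REJECT_BAND,
                  order: int = 4) -> np.ndarray:
    """Causal Butterworth bandpass of a trial; used only by the rejection."""
    sos = sps.butter(order, list(band), btype="bandpass", fs=fs, output="sos")
    return sps.sosfilt(sos, np.asarray(data, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# statistical outlier rejection
# ---------------------------------------------------------------------------

#: Fixed histogram grid for the pooled empirical amplitude distribution used
#: by the joint-probability statistic. Values are clipped into the end bins.
_JP_EDGE_UV = 1000.0
_JP_NBINS = 256


@dataclass
class TrialRejectStats:
    """Cached per-trial statistics so the pool-level rejection is O(bins).

    Computed once per trial from its 3–35 Hz filtered copy.
    """

    max_abs_uv: float
    kurtosis: float                      # per-channel kurtosis, channel-averaged
    hist_counts: np.ndarray              # (n_channels, _JP_NBINS) int64
    n_samples: int


def trial_reject_stats(data: np.ndarray, fs: float) -> TrialRejectStats:
    """Filter one trial to 3–35 Hz and cache its rejection statistics."""
    filt = bandpass_copy(data, fs)
    edges = np.linspace(-_JP_EDGE_UV, _JP_EDGE_UV, _JP_NBINS + 1)
    clipped = np.clip(filt, -_JP_EDGE_UV, _JP_EDGE_UV - 1e-9)
    counts = np.empty((filt.shape[0], _JP_NBINS), dtype=np.int64)
    for c in range(filt.shape[0]):
        counts[c] = np.histogram(clipped[c], bins=edges)[0]
    kurt = float(np.mean(spstats.kurtosis(filt, axis=-1, fisher=True, bias=True)))
    return TrialRejectStats(
        max_abs_uv=float(np.max(np.abs(filt))),
        kurtosis=kurt,
        hist_counts=counts,
        n_samples=filt.shape[1],
    )


@dataclass
class RejectionReport:
    """Outcome of the statistical outlier rejection over a trial population."""

    flags: list[bool]
    reasons: list[str | None]            # "amplitude" | "jointprob" | "kurtosis"
    max_abs_uv: np.ndarray
    jointprob: np.ndarray
    kurtosis: np.ndarray
    amp_threshold_uv: float
    sd_mult: float

    @property
    def n_rejected(self) -> int:
        return int(np.sum(self.flags))

    def accepted_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.flags) if not f]


def _jointprob_scores(stats: list[TrialRejectStats]) -> np.ndarray:
    """Mean negative log-likelihood of each trial's samples under the pooled
    per-channel empirical amplitude distribution, averaged over channels."""
    pooled = np.sum([s.hist_counts for s in stats], axis=0)  # (C, B)
    total = pooled.sum(axis=1, keepdims=True).astype(float)
    p = pooled / total
    logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -50.0)
    scores = np.empty(len(stats))
    for i, s in enumerate(stats):
        nll = -(s.hist_counts * logp).sum(axis=1) / s.n_samples
        scores[i] = float(np.mean(nll))
    return scores


def reject_outliers(trials, fs: float,
                    amp_uv: float = REJECT_AMP_UV,
                    sd_mult: float = REJECT_SD_MULT,
                    precomputed: list[TrialRejectStats] | None = None
                    ) -> RejectionReport:
    """Flag contaminated trials in a population of >= 2 trials.

    Pipeline (on a 3–35 Hz filtered copy; the caller's unfiltered data is
    what later enters training):

    1. amplitude: any sample beyond ±``amp_uv`` — flagged unconditionally;
    2. joint probability: trial score more than ``sd_mult`` SD *above* the
       population mean (one-sided: improbable amplitude content);
    3. kurtosis: channel-averaged kurtosis more than ``sd_mult`` SD from the
       population mean (two-sided).

    A zero-SD population flags nothing for that statistic. Population
    statistics use all input trials, so flags depend on the population but
    are invariant to its ordering.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("rejection needs at least 2 trials")
    if precomputed is None:
        stats = [trial_reject_stats(t.data if isinstance(t, Trial) else t, fs)
                 for t in trials]
    else:
        stats = list(precomputed)
        if len(stats) != len(trials):
            raise ValueError("precomputed stats length mismatch")

    max_abs = np.array([s.max_abs_uv for s in stats])
    jp = _jointprob_scores(stats)
    ku = np.array([s.kurtosis for s in stats])

    flags: list[bool] = [False] * len(trials)
    reasons: list[str | None] = [None] * len(trials)

    for i in np.flatnonzero(max_abs > amp_uv):
        flags[i], reasons[i] = True, "amplitude"

    def _zflag(values: np.ndarray, reason: str, two_sided: bool) -> None:
        sd = float(np.std(values))
        if sd == 0.0:
            return
        z = (values - float(np.mean(values))) / sd
        bad = np.abs(z) > sd_mult if two_sided else z > sd_mult
        for i in np.flatnonzero(bad):
            if not flags[i]:
                flags[i], reasons[i] = True, reason

    _zflag(jp, "jointprob", two_sided=False)
    _zflag(ku, "kurtosis", two_sided=True)

    return RejectionReport(flags=flags, reasons=reasons, max_abs_uv=max_abs,
                           jointprob=jp, kurtosis=ku, amp_threshold_uv=amp_uv,
                           sd_mult=sd_mult)


__all__ = [
    "DEFAULT_BANDS", "DEFAULT_FILTER_ORDER", "REJECT_AMP_UV", "REJECT_SD_MULT",
    "REJECT_BAND", "FilterBank", "build_filterbank", "apply_filterbank",
    "bandpass_copy", "TrialRejectStats", "trial_reject_stats",
    "RejectionReport", "reject_outliers",
]
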