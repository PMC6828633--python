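"""Synthetic two-class motor-imagery EEG sessions with controllable ERD.

The generator emulates the signal features the decoder exploits: pink (1/f)
background noise on every channel, band-limited mu (8–12 Hz) and beta
(16–24 Hz) idle rhythms over the sensorimotor hot spots C3, Cz and C4, and
class-dependent event-related desynchronization — right-hand imagery
attenuates the contralateral C3 rhythms, both-feet imagery the central Cz
rhythms — during the imagery period of each 8-s trial. A fixed spatial
mixing matrix leaks each source into its grid neighbours (a crude stand-in
for volume conduction, without which spatial filtering would be pointless).
High-amplitude artifact bursts can be injected to exercise the outlier
rejection. Identical configuration and seed reproduce the session bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data_model import (DEFAULT_CHANNELS, FEET, HAND, EEGRecording,
                         TrialTiming)

#: electrode-grid adjacency used for the volume-conduction mixing
_NEIGHBOR_PAIRS = (
    ("C5", "C3"), ("C3", "C1"), ("C1", "Cz"), ("Cz", "C2"),
    ("C2", "C4"), ("C4", "C6"),
    ("FC3", "C3"), ("FCz", "Cz"), ("FC4", "C4"),
    ("CP3", "C3"), ("CPz", "Cz"), ("CP4", "C4"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the ERD session generator.

    ``erd_depth`` is the fractional amplitude attenuation of the class's
    target rhythm during imagery: either a single float applied to the
    default topography (hand → C3, feet → Cz, both bands) or an explicit
    mapping ``{class: {channel: depth}}``. Amplitudes are μV RMS.
    """

    seed: int = 0
    n_tpc: int = 190
    run_tpc: int = 10
    fs: float = 256.0
    timing: TrialTiming = field(default_factory=TrialTiming)
    inter_trial_interval_s: float = 2.0
    noise_exponent: float = 1.0
    noise_scale: float = 5.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (16.0, 24.0)
    mu_amp: float = 7.0
    beta_amp: float = 3.5
    erd_depth: float | dict = 0.25
    mixing_leak: float = 0.25
    ramp_s: float = 0.5
    artifact_rate: float = 0.0
    artifact_amp: float = 500.0

    def depth_map(self) -> dict[int, dict[str, float]]:
        if isinstance(self.erd_depth, dict):
            m = self.erd_depth
        else:
            d = float(self.erd_depth)
            m = {HAND: {"C3": d}, FEET: {"Cz": d}}
        for cls in m.values():
            for ch, d in cls.items():
                if not 0.0 <= d <= 1.0:
                    raise ValueError(f"erd_depth {d} for {ch} outside [0, 1]")
        return m


def mixing_matrix(leak: float,
                  channels=DEFAULT_CHANNELS) -> np.ndarray:
    """Row-normalized ``I + leak * adjacency`` volume-conduction mixing."""
    n = len(channels)
    idx = {c: i for i, c in enumerate(channels)}
    m = np.eye(n)
    for a, b in _NEIGHBOR_PAIRS:
        if a in idx and b in idx:
            m[idx[a], idx[b]] = leak
            m[idx[b], idx[a]] = leak
    return m / m.sum(axis=1, keepdims=True)


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               fs: float, exponent: float, rms: float) -> np.ndarray:
    """Power-law (1/f^exponent power) noise, shaped in the Fourier domain."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x *= rms / x.std(axis=-1, keepdims=True)
    return x


def _band_noise(rng: np.random.Generator, n_samples: int, fs: float,
                band: tuple[float, float], rms: float) -> np.ndarray:
    sos = sps.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x * (rms / x.std())


def class_sequence(rng: np.random.Generator, n_tpc: int,
                   run_tpc: int) -> np.ndarray:
    """Balanced pseudo-random labels: each run holds run_tpc of each class."""
    if n_tpc % run_tpc != 0:
        raise ValueError("n_tpc must be a whole number of runs")
    runs = []
    for _ in range(n_tpc // run_tpc):
        run = np.repeat([HAND, FEET], run_tpc)
        runs.append(rng.permutation(run))
    return np.concatenate(runs)


def generate_session(cfg: SyntheticConfig) -> tuple[EEGRecording, np.ndarray]:
    """Produce a continuous session recording and its true labels.

    Returns ``(recording, labels)``; the recording's events carry the labels
    as event codes at each trial-start sample. With ``erd_depth`` 0 the two
    classes are statistically identical.
    """
    depth = cfg.depth_map()
    rng = np.random.default_rng(cfg.seed)
    labels = class_sequence(rng, cfg.n_tpc, cfg.run_tpc)
    n_trials = labels.size
    trial_len = cfg.timing.n_samples(cfg.fs)
    iti = int(round(cfg.inter_trial_interval_s * cfg.fs))
    n_samples = n_trials * (trial_len + iti) + iti
    channels = list(DEFAULT_CHANNELS)
    cidx = {c: i for i, c in enumerate(channels)}

    raw = pink_noise(rng, len(channels), n_samples, cfg.fs,
                     cfg.noise_exponent, cfg.noise_scale)
    starts = iti + np.arange(n_trials) * (trial_len + iti)

    # idle rhythms with class-dependent imagery-period attenuation
    ramp_n = int(round(cfg.ramp_s * cfg.fs))
    half = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp_n) / max(ramp_n, 1))
    img_lo = int(round(cfg.timing.imagery_start_s * cfg.fs))
    img_hi = int(round(cfg.timing.imagery_end_s * cfg.fs))
    for band, amp in ((cfg.mu_band, cfg.mu_amp), (cfg.beta_band, cfg.beta_amp)):
        for src in ("C3", "Cz", "C4"):
            osc = _band_noise(rng, n_samples, cfg.fs, band, amp)
            env = np.ones(n_samples)
            for t, (start, lab) in enumerate(zip(starts, labels)):
                d = depth.get(int(lab), {}).get(src, 0.0)
                if d <= 0.0:
                    continue
                lo, hi = start + img_lo, start + img_hi
                env[lo:lo + ramp_n] = 1.0 - d * half
                env[lo + ramp_n:hi] = 1.0 - d
                rec_hi = min(hi + ramp_n, n_samples)
                env[hi:rec_hi] = 1.0 - d * (1.0 - half[:rec_hi - hi])
            raw[cidx[src]] += osc * env

    signal = mixing_matrix(cfg.mixing_leak, channels) @ raw
    events = [(int(s), int(l)) for s, l in zip(starts, labels)]
    rec = EEGRecording(signal=signal, fs=cfg.fs, channel_labels=channels,
                       events=events)
    if cfg.artifact_rate > 0:
        rec, _ = inject_artifacts(rec, cfg.artifact_rate, cfg.artifact_amp,
                                  seed=int(rng.integers(2 ** 31)),
                                  timing=cfg.timing)
    return rec, labels


def inject_artifacts(rec: EEGRecording, rate: float, amp: float,
                     seed: int = 0, timing: TrialTiming | None = None
                     ) -> tuple[EEGRecording, list[int]]:
    """Add high-amplitude transient bursts to a random subset of trials.

    Each affected trial receives a Hann-enveloped 8-Hz burst (0.5 s) of peak
    amplitude ``amp`` μV on one random channel — within the 3–35 Hz band so
    it reliably trips the ±125 μV rejection threshold when ``amp`` exceeds
    it. Returns a new recording and the affected trial indices.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("artifact rate must be in [0, 1]")
    timing = timing or TrialTiming()
    rng = np.random.default_rng(seed)
    signal = rec.signal.copy()
    trial_len = timing.n_samples(rec.fs)
    burst_n = int(round(0.5 * rec.fs))
    t = np.arange(burst_n) / rec.fs
    burst = np.hanning(burst_n) * np.sin(2 * np.pi * 8.0 * t)
    burst *= amp / np.max(np.abs(burst))
    affected = []
    for i, (start, _) in enumerate(sorted(rec.events, key=lambda e: e[0])):
        if rng.random() >= rate:
            continue
        ch = int(rng.integers(rec.n_channels))
        off = int(rng.integers(trial_len - burst_n))
        signal[ch, start + off:start + off + burst_n] += burst
        affected.append(i)
    out = EEGRecording(signal=signal, fs=rec.fs,
                       channel_labels=list(rec.channel_labels),
                       events=list(rec.events))
    return out, affected


__all__ = [
    "SyntheticConfig", "mixing_matrix", "pink_noise", "class_sequence",
    "generate_session", "inject_artifacts",
]
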