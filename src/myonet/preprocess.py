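"""EMG envelope extraction and gait-cycle epoching.

First stage of the muscle-connectivity chain: the raw multichannel EMG is
band-pass re-filtered (0.5-70 Hz, 4th-order Butterworth applied
forward-backward so the filter is zero-phase), down-sampled to 200 Hz with a
zero-phase anti-alias FIR, and rectified by taking the magnitude of the
analytic (Hilbert) signal of each channel.  Envelopes are then cut into gait
cycles (right heel strike to the next right heel strike) and time-normalized
to a fixed number of phase points per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .synthetic import EmgRecording

__all__ = ["EnvelopeSet", "CycleEpochs", "make_envelopes", "smooth_envelopes",
           "epoch_by_cycles"]


@dataclass
class EnvelopeSet:
    """Non-negative EMG envelopes at the analysis rate (200 Hz)."""

    sample_rate_hz: float
    channel_labels: tuple[str, ...]
    envelopes: np.ndarray  # (8, n_samples), >= 0
    filter_record: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.envelopes.shape[1] / self.sample_rate_hz


@dataclass
class CycleEpochs:
    """Per-gait-cycle envelope segments plus phase-normalized versions."""

    epochs: list[np.ndarray]              # each (8, cycle_samples)
    normalized_epochs: np.ndarray         # (n_cycles, 8, n_phase_points)
    channel_labels: tuple[str, ...]
    sample_rate_hz: float

    @property
    def n_cycles(self) -> int:
        return len(self.epochs)

    def concatenated(self) -> np.ndarray:
        """(8, n_cycles * n_phase_points) matrix of normalized epochs."""
        return np.concatenate(list(self.normalized_epochs), axis=1)


def make_envelopes(rec: EmgRecording, band_hz: tuple[float, float] = (0.5, 70.0),
                   fs_out: float = 200.0, filter_order: int = 4) -> EnvelopeSet:
    """Band-pass filter, decimate and Hilbert-rectify a raw EMG recording.

    Filtering happens at the native rate, then the signal is resampled to
    ``fs_out`` (polyphase FIR, zero-phase), then the envelope is taken as the
    magnitude of the analytic signal.
    """
    fs = rec.sample_rate_hz
    if fs < fs_out:
        raise ValueError(f"sample rate {fs} Hz below target {fs_out} Hz")
    x = np.asarray(rec.signal, float)
    if not np.isfinite(x).all():
        raise ValueError("signal contains NaN or infinite values")
    if band_hz[1] >= fs_out / 2:
        raise ValueError("upper band edge must lie below the output Nyquist")

    sos = sps.butter(filter_order, band_hz, btype="bandpass", fs=fs,
                     output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    if fs != fs_out:
        frac = Fraction(fs_out / fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    env = np.abs(sps.hilbert(x, axis=1))
    return EnvelopeSet(
        sample_rate_hz=fs_out, channel_labels=tuple(rec.channel_labels),
        envelopes=env,
        filter_record={"band_hz": list(band_hz), "order": filter_order,
                       "zero_phase": True, "fs_in": fs, "fs_out": fs_out,
                       "envelope": "hilbert-magnitude"},
    )


def smooth_envelopes(env: EnvelopeSet, cutoff_hz: float = 8.0,
                     filter_order: int = 4) -> EnvelopeSet:
    """Zero-phase low-pass of the envelopes for synergy extraction.

    The Hilbert magnitude of a broadband interference signal carries large
    multiplicative demodulation noise; synergy NMF operates on the slow
    activation profile, so its input is conventionally low-pass smoothed
    (default cutoff 8 Hz).  The spectral/connectivity chain keeps the
    unsmoothed envelopes.  Tiny filter-ringing negatives are clipped to zero.
    """
    if cutoff_hz <= 0 or cutoff_hz >= env.sample_rate_hz / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = sps.butter(filter_order, cutoff_hz, btype="lowpass",
                     fs=env.sample_rate_hz, output="sos")
    sm = sps.sosfiltfilt(sos, env.envelopes, axis=1)
    np.clip(sm, 0.0, None, out=sm)
    record = dict(env.filter_record)
    record["synergy_lowpass_hz"] = cutoff_hz
    return EnvelopeSet(sample_rate_hz=env.sample_rate_hz,
                       channel_labels=env.channel_labels, envelopes=sm,
                       filter_record=record)


def epoch_by_cycles(env: EnvelopeSet, rec: EmgRecording,
                    n_phase_points: int = 200) -> CycleEpochs:
    """Cut envelopes into right-heel-strike-to-right-heel-strike cycles.

    Trailing partial cycles are dropped, never padded; each complete cycle is
    linearly resampled to ``n_phase_points`` phase points.
    """
    hs = np.asarray(rec.heel_strikes.get("right", []), float)
    if hs.size < 2:
        raise ValueError("need at least two right heel strikes")
    fs = env.sample_rate_hz
    n = env.envelopes.shape[1]
    idx = np.round(hs * fs).astype(int)
    epochs: list[np.ndarray] = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b <= n and b > a:
            epochs.append(env.envelopes[:, a:b])
    if not epochs:
        raise ValueError("no complete gait cycle inside the recording")
    norm = np.empty((len(epochs), env.envelopes.shape[0], n_phase_points))
    for i, ep in enumerate(epochs):
        L = ep.shape[1]
        xi = np.linspace(0.0, L - 1.0, n_phase_points)
        xp = np.arange(L)
        for ch in range(ep.shape[0]):
            norm[i, ch] = np.interp(xi, xp, ep[ch])
    return CycleEpochs(epochs=epochs, normalized_epochs=norm,
                       channel_labels=env.channel_labels, sample_rate_hz=fs)
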