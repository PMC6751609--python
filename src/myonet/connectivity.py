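"""Spectral estimation and intermuscular connectivity.

Steps 2-4 of the muscle-network chain:

* normalized envelope power spectral density on a 2 Hz grid (35 bins covering
  0-70 Hz, each channel normalized to unit total power),
* undirected intermuscular coherence (IMCoh): magnitude-squared coherence of
  envelope pairs, Welch estimate with 1 s Hanning windows and 75 % overlap,
  cross- and auto-spectra pooled across windows and trials before forming the
  ratio,
* a multivariate autoregressive (MVAR) model of the eight envelopes with the
  order selected by Akaike's information criterion, from whose coefficients
  partial directed coherence (PDC, column-normalized convention) gives the
  directed muscle network,
* validation of the MVAR model by comparing its implied magnitude-squared
  coherence with the nonparametric Welch coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from statsmodels.tsa.api import VAR

from .preprocess import EnvelopeSet

__all__ = [
    "BIN_EDGES_HZ", "BIN_CENTERS_HZ", "N_BINS",
    "SpectrumSet", "ConnectivitySpectra", "MvarModel", "MvarValidation",
    "normalized_psd", "imcoh", "fit_mvar", "pdc", "validate_mvar",
    "undirected_pairs", "directed_pairs",
]

#: contiguous [2k, 2k+2) Hz analysis bands, k = 0..34, labeled by centers
BIN_EDGES_HZ = np.arange(0.0, 72.0, 2.0)
BIN_CENTERS_HZ = np.arange(1.0, 70.0, 2.0)
N_BINS = 35


def undirected_pairs(labels: Sequence[str]) -> tuple[tuple[str, str], ...]:
    n = len(labels)
    return tuple((labels[i], labels[j]) for i in range(n)
                 for j in range(i + 1, n))


def directed_pairs(labels: Sequence[str]) -> tuple[tuple[str, str], ...]:
    return tuple((s, t) for s in labels for t in labels if s != t)


def _bin_average(freqs: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Average the last axis of ``values`` into the 35 2 Hz analysis bands."""
    out = np.zeros(values.shape[:-1] + (N_BINS,))
    which = np.digitize(freqs, BIN_EDGES_HZ) - 1
    for b in range(N_BINS):
        m = which == b
        if m.any():
            out[..., b] = values[..., m].mean(axis=-1)
    return out


@dataclass
class SpectrumSet:
    """Per-channel normalized PSD on the 2 Hz grid (rows sum to 1)."""

    bin_centers_hz: np.ndarray
    psd: np.ndarray  # (8, 35)
    channel_labels: tuple[str, ...]


@dataclass
class ConnectivitySpectra:
    """Pair-by-frequency coupling values (IMCoh or PDC), all in [0, 1]."""

    directed: bool
    pair_labels: tuple[tuple[str, str], ...]
    values: np.ndarray  # (n_pairs, 35)
    estimator: str  # "IMCoh" | "PDC"
    bin_centers_hz: np.ndarray = field(
        default_factory=lambda: BIN_CENTERS_HZ.copy())
    channel_labels: tuple[str, ...] = ()
    mvar_order: int | None = None
    n_segments: int | None = None

    def __post_init__(self) -> None:
        n = len(self.channel_labels) or 8
        expected = n * (n - 1) if self.directed else n * (n - 1) // 2
        if len(self.pair_labels) != expected and self.channel_labels:
            raise ValueError(
                f"{'directed' if self.directed else 'undirected'} spectra "
                f"need {expected} pairs, got {len(self.pair_labels)}")
        if self.values.shape != (len(self.pair_labels), len(self.bin_centers_hz)):
            raise ValueError("values shape inconsistent with pair/bin labels")

    def value(self, a: str, b: str) -> np.ndarray:
        """Spectrum for pair (a, b); order-insensitive if undirected."""
        pairs = list(self.pair_labels)
        if (a, b) in pairs:
            return self.values[pairs.index((a, b))]
        if not self.directed and (b, a) in pairs:
            return self.values[pairs.index((b, a))]
        raise KeyError((a, b))


@dataclass
class MvarModel:
    """VAR(p) model of the envelope set, order chosen by AIC."""

    order_p: int
    coefficients: np.ndarray       # (p, 8, 8); rows: target, cols: source
    noise_covariance: np.ndarray   # (8, 8)
    aic_trace: dict[int, float]
    stable: bool
    sample_rate_hz: float
    channel_labels: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class MvarValidation:
    """Agreement between model-implied and Welch coherence, per pair."""

    pair_labels: tuple[tuple[str, str], ...]
    correlation: np.ndarray
    mean_abs_diff: np.ndarray
    flagged: tuple[tuple[str, str], ...]
    threshold: float

    @property
    def passed(self) -> bool:
        return len(self.flagged) == 0


# ----------------------------------------------------------------------------
# PSD


def normalized_psd(env: EnvelopeSet, window_s: float = 1.0,
                   overlap: float = 0.75) -> SpectrumSet:
    """Welch PSD of each envelope, aggregated to 2 Hz bins and normalized to
    unit total power per channel."""
    fs = env.sample_rate_hz
    nperseg = int(round(window_s * fs))
    if env.envelopes.shape[1] < nperseg:
        raise ValueError("record shorter than one analysis window")
    if env.duration_s < 2.0:
        raise ValueError("need at least 2 s of data")
    freqs, p = sps.welch(env.envelopes, fs=fs, window="hann",
                         nperseg=nperseg,
                         noverlap=int(round(overlap * nperseg)),
                         detrend="constant", axis=1)
    # DC is removed by detrending; keep only informative lines below 70 Hz
    keep = (freqs > 0) & (freqs < BIN_EDGES_HZ[-1])
    binned = _bin_average(freqs[keep], p[:, keep])
    binned /= binned.sum(axis=1, keepdims=True)
    return SpectrumSet(bin_centers_hz=BIN_CENTERS_HZ.copy(), psd=binned,
                       channel_labels=env.channel_labels)


# ----------------------------------------------------------------------------
# IMCoh


def _segment_fft(x: np.ndarray, fs: float, window_s: float,
                 overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """Windowed segment FFTs: returns (freqs, Z[n_seg, n_ch, n_freq])."""
    nperseg = int(round(window_s * fs))
    step = nperseg - int(round(overlap * nperseg))
    n = x.shape[1]
    if n < nperseg:
        raise ValueError("record shorter than one analysis window")
    starts = np.arange(0, n - nperseg + 1, step)
    win = sps.get_window("hann", nperseg)
    segs = np.stack([x[:, s:s + nperseg] for s in starts])  # (S, C, L)
    segs = segs - segs.mean(axis=2, keepdims=True)
    z = np.fft.rfft(segs * win, axis=2)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, z


def imcoh(trials: Sequence[EnvelopeSet], window_s: float = 1.0,
          overlap: float = 0.75, trial_mode: str = "pooled") -> ConnectivitySpectra:
    """Magnitude-squared intermuscular coherence over all unordered pairs.

    ``trial_mode='pooled'`` (default) pools Welch segments of all trials into
    one cross-spectral average before forming the coherence ratio;
    ``'per_trial'`` averages the per-trial coherency magnitudes across trials
    and then squares (the literal two-trial averaging-then-squaring reading).
    """
    if not trials:
        raise ValueError("need at least one trial")
    labels = trials[0].channel_labels
    for t in trials:
        if t.channel_labels != labels:
            raise ValueError("channel sets differ across trials")
    fs = trials[0].sample_rate_hz
    pairs = undirected_pairs(labels)

    per_trial_msc = []
    s_accum = None
    n_segments = 0
    freqs = None
    for t in trials:
        freqs, z = _segment_fft(t.envelopes, fs, window_s, overlap)
        if z.shape[0] < 2:
            raise ValueError("need at least 2 windows per trial")
        s = np.einsum("scf,sdf->cdf", z, np.conj(z))
        n_segments += z.shape[0]
        if trial_mode == "pooled":
            s_accum = s if s_accum is None else s_accum + s
        elif trial_mode == "per_trial":
            auto = np.real(np.einsum("ccf->cf", s))
            coh_mag = np.abs(s) / np.sqrt(auto[:, None, :] * auto[None, :, :])
            per_trial_msc.append(coh_mag)
        else:
            raise ValueError(f"unknown trial_mode {trial_mode!r}")

    if trial_mode == "pooled":
        auto = np.real(np.einsum("ccf->cf", s_accum))
        msc = np.abs(s_accum) ** 2 / (auto[:, None, :] * auto[None, :, :])
    else:
        msc = np.mean(per_trial_msc, axis=0) ** 2

    keep = (freqs > 0) & (freqs < BIN_EDGES_HZ[-1])
    idx = {m: i for i, m in enumerate(labels)}
    rows = np.stack([msc[idx[a], idx[b]][keep] for a, b in pairs])
    values = _bin_average(freqs[keep], rows)
    values = np.clip(values, 0.0, 1.0)
    return ConnectivitySpectra(
        directed=False, pair_labels=pairs, values=values, estimator="IMCoh",
        channel_labels=labels, n_segments=n_segments)


# ----------------------------------------------------------------------------
# MVAR + PDC


def fit_mvar(env: EnvelopeSet, max_order: int = 20) -> MvarModel:
    """Least-squares VAR fit of the (demeaned) envelopes at the
    AIC-minimizing order among 1..max_order."""
    x = np.asarray(env.envelopes, float).T
    n, c = x.shape
    if n <= 8 * max_order:
        raise ValueError("record too short for the requested max order")
    x = x - x.mean(axis=0)
    # same effective sample for every candidate order, as in standard
    # information-criterion order selection
    aic_trace: dict[int, float] = {}
    for p in range(1, max_order + 1):
        try:
            res_p = VAR(x[max_order - p:]).fit(p, trend="n")
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular regressor matrix in VAR({p}) fit: "
                             f"{exc}") from exc
        aic_trace[p] = float(res_p.aic)
    order = min(aic_trace, key=aic_trace.get)
    res = VAR(x).fit(order, trend="n")
    stable = bool(res.is_stable())
    return MvarModel(order_p=order, coefficients=np.asarray(res.coefs),
                     noise_covariance=np.asarray(res.sigma_u),
                     aic_trace=aic_trace, stable=stable,
                     sample_rate_hz=env.sample_rate_hz,
                     channel_labels=env.channel_labels)


def _a_bar(model: MvarModel, freqs_hz: np.ndarray) -> np.ndarray:
    """A(f) = I - sum_p A_p exp(-i 2 pi f p / fs), shape (F, C, C)."""
    c = model.n_channels
    p = model.order_p
    fs = model.sample_rate_hz
    ph = np.exp(-2j * np.pi * np.outer(freqs_hz, np.arange(1, p + 1)) / fs)
    a = np.eye(c)[None, :, :] - np.einsum("fp,pij->fij", ph,
                                          model.coefficients)
    return a


def pdc(model: MvarModel,
        bin_centers_hz: np.ndarray | None = None) -> ConnectivitySpectra:
    """Partial directed coherence from the MVAR coefficients.

    Column-normalized convention: PDC(j->i, f) = |A(f)_ij| /
    sqrt(sum_k |A(f)_kj|^2), so the squared PDC over all targets i (diagonal
    included) sums to one for every source j and frequency.
    """
    if not model.stable:
        raise ValueError("MVAR model is unstable; PDC undefined")
    freqs = BIN_CENTERS_HZ if bin_centers_hz is None else np.asarray(
        bin_centers_hz, float)
    a = _a_bar(model, freqs)
    denom = np.sqrt((np.abs(a) ** 2).sum(axis=1))  # (F, C): per source column
    vals = np.abs(a) / denom[:, None, :]
    labels = model.channel_labels
    pairs = directed_pairs(labels)
    idx = {m: i for i, m in enumerate(labels)}
    rows = np.stack([vals[:, idx[t], idx[s]] for s, t in pairs])
    return ConnectivitySpectra(
        directed=True, pair_labels=pairs, values=rows, estimator="PDC",
        bin_centers_hz=freqs, channel_labels=labels,
        mvar_order=model.order_p)


def mvar_coherence(model: MvarModel,
                   bin_centers_hz: np.ndarray | None = None) -> ConnectivitySpectra:
    """Magnitude-squared coherence implied by the MVAR spectral matrix
    S(f) = H(f) Sigma H(f)^H with H = A(f)^-1."""
    freqs = BIN_CENTERS_HZ if bin_centers_hz is None else np.asarray(
        bin_centers_hz, float)
    a = _a_bar(model, freqs)
    h = np.linalg.inv(a)
    s = h @ model.noise_covariance @ np.conj(np.swapaxes(h, 1, 2))
    auto = np.real(np.einsum("fcc->fc", s))
    msc = np.abs(s) ** 2 / (auto[:, :, None] * auto[:, None, :])
    labels = model.channel_labels
    pairs = undirected_pairs(labels)
    idx = {m: i for i, m in enumerate(labels)}
    rows = np.stack([msc[:, idx[x], idx[y]] for x, y in pairs])
    return ConnectivitySpectra(
        directed=False, pair_labels=pairs, values=np.clip(rows, 0.0, 1.0),
        estimator="IMCoh", bin_centers_hz=freqs, channel_labels=labels,
        mvar_order=model.order_p)


def validate_mvar(model: MvarModel, nonparam: ConnectivitySpectra,
                  corr_threshold: float = 0.7,
                  mad_threshold: float = 0.05) -> MvarValidation:
    """Compare model-implied coherence with the Welch coherence, per pair.

    A pair is flagged when its spectral correlation falls below
    ``corr_threshold`` *and* the mean absolute difference exceeds
    ``mad_threshold``: near-flat spectra (uncoupled channels) have no shape to
    correlate, so correlation alone would spuriously flag them.
    """
    if nonparam.directed or nonparam.estimator != "IMCoh":
        raise ValueError("validation expects undirected Welch coherence")
    if tuple(nonparam.channel_labels) != tuple(model.channel_labels):
        raise ValueError("channel sets of model and spectra differ")
    modeled = mvar_coherence(model, nonparam.bin_centers_hz)
    if modeled.pair_labels != nonparam.pair_labels:
        raise ValueError("pair sets differ")
    corr = np.empty(len(nonparam.pair_labels))
    mad = np.empty_like(corr)
    for i in range(len(corr)):
        a, b = modeled.values[i], nonparam.values[i]
        sa, sb = a.std(), b.std()
        corr[i] = np.corrcoef(a, b)[0, 1] if sa > 0 and sb > 0 else 1.0
        mad[i] = np.abs(a - b).mean()
    flagged = tuple(p for p, c, d in zip(nonparam.pair_labels, corr, mad)
                    if c < corr_threshold and d > mad_threshold)
    return MvarValidation(pair_labels=nonparam.pair_labels, correlation=corr,
                          mean_abs_diff=mad, flagged=flagged,
                          threshold=corr_threshold)
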