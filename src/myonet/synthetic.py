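"""Synthetic gait-EMG generator with planted ground truth.

Emulates the statistical structure that the muscle-network / signal-synergy
analysis assumes, so every downstream estimator can be validated against a
known generative model:

* envelope-level structure is a non-negative synergy product ``W_true @ C(t)``
  with cycle-to-cycle jitter of the recruitment curves,
* band-limited stochastic *common drives* shared by muscle subsets create
  intermuscular coherence at chosen frequency bands,
* lagged directed couplings create partial-directed-coherence asymmetry,
* the envelope amplitude-modulates a zero-mean broadband carrier (surrogate
  interference EMG) so that the rectification step of the pipeline is
  meaningfully exercised.

Two presets bundle the study conditions: ``HC`` (healthy-control-like: two
synergies concentrated on the ankle muscles, 10 Hz common drives over the
distal muscle pairs, low cycle-to-cycle jitter) and ``DM1`` (patient-like:
five synergies, dominant ~6 Hz envelope modulation, additional common drives
at 5/8/18/35 Hz over proximal-distal and crossed pairs, bidirectional lagged
couplings, high jitter).

A 2-minute centre-of-pressure (COP) trace generator (AR(1) per axis) supports
the posturography metrics, and :func:`synthetic_connectivity` builds
pair-by-frequency connectivity matrices with planted frequency components for
validating the spectral NMF decomposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import signal as sps

__all__ = [
    "MUSCLES",
    "GeneratorConfig",
    "DriveBand",
    "DirectedCoupling",
    "EmgRecording",
    "CopTrace",
    "preset",
    "generate_emg",
    "generate_cop",
    "synthetic_connectivity",
    "gaussian_bump_profiles",
    "write_emg_recording",
    "read_emg_recording",
    "write_cop_trace",
    "read_cop_trace",
    "config_to_yaml",
    "config_from_yaml",
]

#: Channel order used throughout: SENIAM muscles x side (l/r).
MUSCLES = ("RF_l", "BF_l", "TA_l", "G_l", "RF_r", "BF_r", "TA_r", "G_r")

_DISTAL = ("TA_l", "G_l", "TA_r", "G_r")
_PROXIMAL = ("RF_l", "BF_l", "RF_r", "BF_r")


@dataclass(frozen=True)
class DriveBand:
    """A band-limited common neural drive shared by a muscle subset.

    The drive is realized as white noise band-pass filtered to the 2 Hz
    analysis bin containing ``center_hz`` (the analysis grid uses contiguous
    [2k, 2k+2) Hz bins), scaled to unit SD and added to the envelope of every
    muscle in ``muscles`` with amplitude ``gain`` times the muscle's envelope
    SD.  A subset of size one yields a per-muscle (incoherent) modulation that
    shapes the PSD without creating intermuscular coherence.
    """

    center_hz: float
    bandwidth_hz: float
    muscles: tuple[str, ...]
    gain: float


@dataclass(frozen=True)
class DirectedCoupling:
    """Lagged linear influence of one muscle's envelope onto another."""

    source: str
    target: str
    lag_samples: int
    gain: float


@dataclass
class GeneratorConfig:
    """Full specification of the generative model (one subject)."""

    preset_name: str = "custom"
    n_synergies_true: int = 2
    #: non-negative (8 muscles x k_true) mixing matrix
    synergy_matrix_true: np.ndarray = field(
        default_factory=lambda: np.ones((8, 2)))
    #: per-synergy non-negative periodic activation over gait phase [0, 1)
    recruitment_profiles: np.ndarray = field(
        default_factory=lambda: np.ones((2, 200)))
    cycle_duration_s: float = 1.05
    n_cycles: int = 60
    drive_bands: tuple[DriveBand, ...] = ()
    directed_couplings: tuple[DirectedCoupling, ...] = ()
    noise_sd: float = 0.03
    recruitment_jitter: float = 0.05
    sample_rate_hz: int = 1000
    seed: int = 0
    #: tonic activity added to each muscle, as a fraction of its peak drive
    baseline_level: float = 0.15
    stance_fraction: float = 0.6
    #: if False the raw signal is the envelope itself (no carrier noise)
    carrier: bool = True
    subject_id: str = "S00"
    group: str = "custom"

    def validate(self) -> None:
        w = np.asarray(self.synergy_matrix_true, float)
        if self.n_synergies_true <= 0:
            raise ValueError("n_synergies_true must be positive")
        if w.shape != (len(MUSCLES), self.n_synergies_true):
            raise ValueError(
                f"synergy_matrix_true must be {len(MUSCLES)} x "
                f"{self.n_synergies_true}, got {w.shape}")
        if (w < 0).any():
            raise ValueError("synergy_matrix_true must be non-negative")
        if not (w.max(axis=0) > 0).all():
            raise ValueError("every synergy column needs a positive entry")
        if np.asarray(self.recruitment_profiles).shape[0] != self.n_synergies_true:
            raise ValueError("one recruitment profile per synergy required")
        if (np.asarray(self.recruitment_profiles) < 0).any():
            raise ValueError("recruitment profiles must be non-negative")
        for b in self.drive_bands:
            if not (0 < b.center_hz <= 70):
                raise ValueError(
                    f"drive band center {b.center_hz} Hz outside (0, 70]")
            if b.bandwidth_hz <= 0:
                raise ValueError("drive band bandwidth must be positive")
            unknown = set(b.muscles) - set(MUSCLES)
            if unknown:
                raise ValueError(f"unknown muscles in drive band: {unknown}")
        for c in self.directed_couplings:
            if c.source not in MUSCLES or c.target not in MUSCLES:
                raise ValueError("coupling references unknown muscle")
            if c.lag_samples <= 0:
                raise ValueError("coupling lag must be positive")
        if self.n_cycles <= 0 or self.cycle_duration_s <= 0:
            raise ValueError("n_cycles and cycle_duration_s must be positive")
        if self.recruitment_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise_sd must be non-negative")


@dataclass
class EmgRecording:
    """Raw multichannel EMG with channel labels, sample rate and gait events."""

    subject_id: str
    group: str
    sample_rate_hz: float
    channel_labels: tuple[str, ...]
    signal: np.ndarray  # (8, n_samples) mV
    heel_strikes: dict[str, np.ndarray]  # side -> timestamps (s)
    toe_offs: dict[str, np.ndarray]
    #: planted noise-free envelopes (8, n_samples); None for imported data
    true_envelopes: np.ndarray | None = None
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        if len(self.channel_labels) != 8:
            raise ValueError("exactly 8 channels required")
        if len(set(self.channel_labels)) != 8:
            raise ValueError("channel labels must be unique")
        for side, hs in self.heel_strikes.items():
            hs = np.asarray(hs, float)
            if not (np.diff(hs) > 0).all():
                raise ValueError(f"{side} heel strikes must strictly increase")
            to = np.asarray(self.toe_offs.get(side, []), float)
            for t in to:
                i = np.searchsorted(hs, t)
                if i == 0 or i == len(hs):
                    continue  # toe-off outside a complete cycle: tolerated
                if not (hs[i - 1] < t < hs[i]):
                    raise ValueError(
                        f"{side} toe-off {t} not strictly inside a cycle")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sample_rate_hz


@dataclass
class CopTrace:
    """Centre-of-pressure trace on a force platform (x=ML, y=AP, in mm)."""

    sample_rate_hz: float
    xy: np.ndarray  # (n, 2)
    condition: str = "eyes_open"
    duration_s: float = 120.0

    def __post_init__(self) -> None:
        n_expected = self.duration_s * self.sample_rate_hz
        if abs(self.xy.shape[0] - n_expected) > 1:
            raise ValueError("xy length inconsistent with duration and rate")


# ----------------------------------------------------------------------------
# recruitment profiles


def gaussian_bump_profiles(
    centers: Sequence[Sequence[float]],
    widths: Sequence[Sequence[float]],
    n_phase: int = 200,
) -> np.ndarray:
    """Build periodic recruitment curves as sums of circular Gaussian bumps.

    ``centers[k]``/``widths[k]`` list the bump phases and SDs (in cycle
    fraction) of synergy ``k``; curves are evaluated on ``n_phase`` points of
    the phase grid [0, 1) and peak-normalized to 1.
    """
    phase = np.arange(n_phase) / n_phase
    profiles = np.zeros((len(centers), n_phase))
    for k, (cs, ws) in enumerate(zip(centers, widths)):
        for c, w in zip(cs, ws):
            d = phase - c
            d -= np.round(d)  # circular distance
            profiles[k] += np.exp(-0.5 * (d / w) ** 2)
        profiles[k] /= profiles[k].max()
    return profiles


# ----------------------------------------------------------------------------
# presets


def _w_from_spec(entries: dict[int, dict[str, float]]) -> np.ndarray:
    k = len(entries)
    w = np.zeros((len(MUSCLES), k))
    for col, weights in entries.items():
        for m, v in weights.items():
            w[MUSCLES.index(m), col] = v
    return w


def preset(name: str) -> GeneratorConfig:
    """Return the generator configuration for a named study group.

    ``HC``: two synergies (plantarflexor / dorsiflexor, concentrated on G and
    TA of both sides -- the ankle strategy), 10 Hz common drives over the
    distal muscle pairs, low recruitment jitter, cycle duration 1.05 s
    (cadence ~1.9 steps/s).

    ``DM1``: five synergies spread over proximal and distal muscles, dominant
    ~6 Hz envelope modulation on every muscle, common drives at 5, 8, 18 and
    35 Hz over proximal-distal and crossed muscle pairs, bidirectional lagged
    couplings, high recruitment jitter, cycle duration 1.4 s.
    """
    if name == "HC":
        w = _w_from_spec({
            0: {"G_l": 1.0, "G_r": 1.0, "RF_l": 0.15, "RF_r": 0.15},
            1: {"TA_l": 1.0, "TA_r": 1.0, "BF_l": 0.2, "BF_r": 0.2},
        })
        profiles = gaussian_bump_profiles(
            centers=[(0.45, 0.95), (0.05, 0.55)],
            widths=[(0.10, 0.10), (0.09, 0.09)],
        )
        bands = [
            DriveBand(10.0, 2.0, ("TA_l", "TA_r"), 1.5),
            DriveBand(10.0, 2.0, ("G_l", "G_r"), 1.5),
            DriveBand(10.0, 2.0, ("TA_l", "G_l"), 1.0),
            DriveBand(10.0, 2.0, ("TA_r", "G_r"), 1.0),
        ] + [DriveBand(10.0, 2.0, (m,), 1.4) for m in _PROXIMAL]
        couplings = [
            DirectedCoupling("TA_l", "G_l", 15, 0.4),
            DirectedCoupling("TA_r", "G_r", 15, 0.4),
            DirectedCoupling("G_l", "G_r", 20, 0.3),
        ]
        return GeneratorConfig(
            preset_name="HC", group="HC", n_synergies_true=2,
            synergy_matrix_true=w, recruitment_profiles=profiles,
            cycle_duration_s=1.05, n_cycles=60,
            drive_bands=tuple(bands), directed_couplings=tuple(couplings),
            noise_sd=0.03, recruitment_jitter=0.05,
        )
    if name == "DM1":
        w = _w_from_spec({
            0: {"RF_r": 1.0, "BF_r": 0.7},
            1: {"RF_l": 1.0, "BF_l": 0.7},
            2: {"TA_l": 1.0, "TA_r": 0.8, "RF_l": 0.3},
            3: {"G_l": 1.0, "G_r": 0.8, "BF_r": 0.3},
            4: {"RF_l": 0.6, "TA_r": 0.9, "G_l": 0.7, "BF_l": 0.3},
        })
        profiles = gaussian_bump_profiles(
            centers=[(0.05,), (0.25,), (0.45,), (0.65,), (0.85,)],
            widths=[(0.07,), (0.07,), (0.07,), (0.07,), (0.07,)],
        )
        bands = (
            # dominant incoherent ~6 Hz modulation on every muscle
            [DriveBand(6.0, 2.0, (m,), 2.0) for m in MUSCLES]
            + [
                # commingled coherent drives over proximal-distal/crossed pairs
                DriveBand(5.0, 2.0, ("RF_r", "G_l"), 0.7),
                DriveBand(5.0, 2.0, ("RF_r", "G_r"), 0.7),
                DriveBand(8.0, 2.0, ("RF_r", "TA_l"), 0.7),
                DriveBand(8.0, 2.0, ("RF_l", "TA_r"), 0.7),
                DriveBand(18.0, 2.0, ("TA_l", "TA_r"), 0.6),
                DriveBand(18.0, 2.0, ("RF_l", "RF_r"), 0.6),
                DriveBand(35.0, 2.0, ("G_l", "G_r"), 0.6),
                DriveBand(35.0, 2.0, ("BF_l", "BF_r"), 0.6),
            ]
        )
        couplings = [
            DirectedCoupling("RF_r", "TA_l", 20, 0.4),
            DirectedCoupling("TA_l", "RF_r", 25, 0.4),
            DirectedCoupling("G_l", "G_r", 15, 0.35),
            DirectedCoupling("G_r", "G_l", 18, 0.35),
        ]
        return GeneratorConfig(
            preset_name="DM1", group="DM1", n_synergies_true=5,
            synergy_matrix_true=w, recruitment_profiles=profiles,
            cycle_duration_s=1.4, n_cycles=45,
            drive_bands=tuple(bands), directed_couplings=tuple(couplings),
            noise_sd=0.03, recruitment_jitter=0.30,
        )
    raise ValueError(f"unknown preset {name!r} (expected 'HC' or 'DM1')")


# ----------------------------------------------------------------------------
# EMG generation


def _band_noise(rng: np.random.Generator, n: int, center_hz: float,
                fs: float) -> np.ndarray:
    """Unit-SD noise band-limited to the 2 Hz analysis bin containing center."""
    lo = 2.0 * np.floor(center_hz / 2.0)
    hi = lo + 2.0
    lo = max(lo, 0.25)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _recruitment_matrix(config: GeneratorConfig,
                        rng: np.random.Generator, n: int) -> np.ndarray:
    """(k x n) recruitment curves with per-cycle log-normal amplitude jitter
    and smooth phase shifts."""
    k = config.n_synergies_true
    fs = config.sample_rate_hz
    spc = config.cycle_duration_s * fs  # samples per cycle
    profiles = np.asarray(config.recruitment_profiles, float)
    n_phase = profiles.shape[1]
    c = np.zeros((k, n))
    t = np.arange(n)
    cycle_idx = np.minimum((t / spc).astype(int), config.n_cycles - 1)
    phase = t / spc - cycle_idx
    jit = config.recruitment_jitter
    amp = np.exp(rng.normal(0.0, jit, size=(config.n_cycles, k)))
    shift = rng.normal(0.0, 0.05 * jit, size=(config.n_cycles, k))
    grid = np.arange(n_phase) / n_phase
    for j in range(k):
        prof = profiles[j]
        ph = (phase - shift[cycle_idx, j]) % 1.0
        # periodic linear interpolation of the profile
        c[j] = np.interp(ph, grid, prof, period=1.0)
        c[j] *= amp[cycle_idx, j]
    return c


def generate_emg(config: GeneratorConfig) -> EmgRecording:
    """Generate one subject's 8-channel gait EMG from the planted model.

    The noise-free envelopes (synergy product + common drives + directed
    couplings, clipped at zero) are returned in ``true_envelopes``; the raw
    ``signal`` is those envelopes amplitude-modulating a zero-mean broadband
    carrier plus additive sensor noise.  Bit-identical under identical
    config/seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    n = int(round(config.n_cycles * config.cycle_duration_s * fs))

    w = np.asarray(config.synergy_matrix_true, float)
    c = _recruitment_matrix(config, rng, n)
    env = w @ c
    peak = env.max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    env = env + config.baseline_level * peak

    # common drives (added on the pre-drive per-muscle scale)
    scale = env.std(axis=1)
    scale[scale == 0] = env.mean(axis=1)[scale == 0]
    scale[scale == 0] = 1.0
    for band in config.drive_bands:
        x = _band_noise(rng, n, band.center_hz, fs)
        for m in band.muscles:
            i = MUSCLES.index(m)
            env[i] += band.gain * scale[i] * x

    # directed lagged couplings (source envelope fluctuation into target)
    env_pre = env.copy()
    for cp in config.directed_couplings:
        si, ti = MUSCLES.index(cp.source), MUSCLES.index(cp.target)
        lag = cp.lag_samples
        src = env_pre[si] - env_pre[si].mean()
        env[ti, lag:] += cp.gain * src[:-lag]

    np.clip(env, 0.0, None, out=env)

    if config.carrier:
        carrier = rng.standard_normal(env.shape)
        sig = env * carrier
    else:
        sig = env.copy()
    if config.noise_sd > 0:
        sig = sig + config.noise_sd * rng.standard_normal(env.shape)

    t_cycle = config.cycle_duration_s
    hs_r = np.arange(config.n_cycles + 1) * t_cycle
    hs_l = hs_r[:-1] + 0.5 * t_cycle
    to_r = hs_r[:-1] + config.stance_fraction * t_cycle
    to_l = hs_l + config.stance_fraction * t_cycle
    dur = n / fs
    return EmgRecording(
        subject_id=config.subject_id, group=config.group,
        sample_rate_hz=fs, channel_labels=MUSCLES, signal=sig,
        heel_strikes={"right": hs_r[hs_r <= dur + 1e-9],
                      "left": hs_l[hs_l <= dur + 1e-9]},
        toe_offs={"right": to_r[to_r <= dur + 1e-9],
                  "left": to_l[to_l <= dur + 1e-9]},
        true_envelopes=env, n_cycles=config.n_cycles,
    )


# ----------------------------------------------------------------------------
# COP generation


def generate_cop(sigma_ap_mm: float, sigma_ml_mm: float,
                 drift_model: str = "ar1", duration_s: float = 120.0,
                 rate_hz: float = 50.0, seed: int = 0,
                 condition: str = "eyes_open",
                 tau_s: float = 1.0) -> CopTrace:
    """Bounded correlated random-walk COP trace.

    Each axis is a stationary first-order autoregressive process with
    stationary SD ``sigma_ap_mm`` (AP, y) / ``sigma_ml_mm`` (ML, x) and
    correlation time ``tau_s``; ``drift_model='white'`` degenerates to
    independent samples.
    """
    if sigma_ap_mm <= 0 or sigma_ml_mm <= 0:
        raise ValueError("sigmas must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    if drift_model not in ("ar1", "white"):
        raise ValueError(f"unknown drift model {drift_model!r}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    phi = 0.0 if drift_model == "white" else float(np.exp(-1.0 / (tau_s * rate_hz)))
    sigmas = np.array([sigma_ml_mm, sigma_ap_mm])
    innov_sd = sigmas * np.sqrt(1.0 - phi ** 2)
    x0 = rng.normal(0.0, sigmas)  # stationary start
    e = rng.normal(0.0, 1.0, size=(n, 2)) * innov_sd
    e[0] = x0  # recursion seeds itself with the stationary draw
    xy = sps.lfilter([1.0], [1.0, -phi], e, axis=0)
    return CopTrace(sample_rate_hz=rate_hz, xy=xy, condition=condition,
                    duration_s=duration_s)


# ----------------------------------------------------------------------------
# planted connectivity ensembles


def synthetic_connectivity(band_centers_hz: Sequence[float] = (5, 8, 18, 35),
                           n_pairs: int = 28, noise_sd: float = 0.04,
                           band_width_hz: float = 2.0, seed: int = 0):
    """Pair-by-frequency connectivity matrix with planted frequency components.

    Each planted component is a Gaussian spectral bump centred on one of
    ``band_centers_hz`` carried by a disjoint subset of pairs with random
    positive edge weights; non-negative noise perturbs the product.  Returns a
    :class:`myonet.connectivity.ConnectivitySpectra` (undirected, IMCoh-like)
    whose ground-truth factors are attached as ``true_signatures`` /
    ``true_edge_weights``.
    """
    from .connectivity import BIN_CENTERS_HZ, ConnectivitySpectra

    rng = np.random.default_rng(seed)
    k = len(band_centers_hz)
    sig = np.zeros((k, len(BIN_CENTERS_HZ)))
    for j, c in enumerate(band_centers_hz):
        # align each bump with the 2 Hz analysis bin containing its center,
        # as the EMG drive bands do
        c_bin = 2.0 * np.floor(c / 2.0) + 1.0
        sig[j] = np.exp(-0.5 * ((BIN_CENTERS_HZ - c_bin) / band_width_hz) ** 2)
        sig[j] /= sig[j].max()
    order = np.argsort(band_centers_hz)
    sig = sig[order]

    groups = np.array_split(rng.permutation(n_pairs), k)
    weights = np.zeros((k, n_pairs))
    for j, g in enumerate(groups):
        weights[j, g] = rng.uniform(0.5, 1.0, size=len(g))
    x = weights.T @ sig
    x = x + rng.normal(0.0, noise_sd, size=x.shape)
    np.clip(x, 0.0, None, out=x)
    scale = 0.8 / x.max()
    x *= scale

    pair_labels = tuple(
        (MUSCLES[i], MUSCLES[j]) for i in range(8) for j in range(i + 1, 8)
    )[:n_pairs]
    conn = ConnectivitySpectra(
        directed=False, pair_labels=pair_labels, values=x,
        estimator="IMCoh", bin_centers_hz=BIN_CENTERS_HZ.copy(),
        channel_labels=MUSCLES,
    )
    conn.true_signatures = sig
    conn.true_edge_weights = weights * scale
    return conn


# ----------------------------------------------------------------------------
# text I/O


def write_emg_recording(rec: EmgRecording, prefix: str | Path) -> None:
    """Write ``<prefix>.tsv`` (header of channel labels, one column per
    channel) and ``<prefix>.json`` (sample rate, gait events, metadata)."""
    prefix = Path(prefix)
    header = "\t".join(rec.channel_labels)
    np.savetxt(prefix.with_suffix(".tsv"), rec.signal.T, fmt="%.6g",
               delimiter="\t", header=header, comments="")
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "sample_rate_hz": rec.sample_rate_hz,
        "channel_labels": list(rec.channel_labels),
        "heel_strikes": {s: np.asarray(v).tolist()
                         for s, v in rec.heel_strikes.items()},
        "toe_offs": {s: np.asarray(v).tolist()
                     for s, v in rec.toe_offs.items()},
        "n_cycles": rec.n_cycles,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_emg_recording(prefix: str | Path) -> EmgRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    with open(prefix.with_suffix(".tsv")) as fh:
        labels = tuple(fh.readline().strip().split("\t"))
    data = np.loadtxt(prefix.with_suffix(".tsv"), skiprows=1, delimiter="\t")
    missing = set(meta["channel_labels"]) - set(labels)
    if missing:
        raise ValueError(f"missing channel(s) in {prefix}.tsv: {sorted(missing)}")
    return EmgRecording(
        subject_id=meta["subject_id"], group=meta["group"],
        sample_rate_hz=meta["sample_rate_hz"], channel_labels=labels,
        signal=data.T,
        heel_strikes={s: np.asarray(v) for s, v in meta["heel_strikes"].items()},
        toe_offs={s: np.asarray(v) for s, v in meta["toe_offs"].items()},
        n_cycles=meta.get("n_cycles"),
    )


def write_cop_trace(trace: CopTrace, path: str | Path) -> None:
    np.savetxt(path, trace.xy, fmt="%.6g", delimiter="\t",
               header=f"x_ml_mm\ty_ap_mm\t# rate_hz={trace.sample_rate_hz} "
                      f"condition={trace.condition}", comments="")


def read_cop_trace(path: str | Path, sample_rate_hz: float | None = None,
                   condition: str = "eyes_open") -> CopTrace:
    with open(path) as fh:
        header = fh.readline()
    rate = sample_rate_hz
    if rate is None:
        for tok in header.replace("\t", " ").split():
            if tok.startswith("rate_hz="):
                rate = float(tok.split("=")[1])
            if tok.startswith("condition="):
                condition = tok.split("=")[1]
    if rate is None:
        raise ValueError("sample rate neither in header nor given")
    xy = np.loadtxt(path, skiprows=1, delimiter="\t")
    return CopTrace(sample_rate_hz=rate, xy=xy, condition=condition,
                    duration_s=xy.shape[0] / rate)


def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    d = {
        "preset_name": config.preset_name,
        "n_synergies_true": config.n_synergies_true,
        "synergy_matrix_true": np.asarray(config.synergy_matrix_true).tolist(),
        "recruitment_profiles": np.asarray(config.recruitment_profiles).tolist(),
        "cycle_duration_s": config.cycle_duration_s,
        "n_cycles": config.n_cycles,
        "drive_bands": [[b.center_hz, b.bandwidth_hz, list(b.muscles), b.gain]
                        for b in config.drive_bands],
        "directed_couplings": [[c.source, c.target, c.lag_samples, c.gain]
                               for c in config.directed_couplings],
        "noise_sd": config.noise_sd,
        "recruitment_jitter": config.recruitment_jitter,
        "sample_rate_hz": config.sample_rate_hz,
        "seed": config.seed,
        "baseline_level": config.baseline_level,
        "stance_fraction": config.stance_fraction,
        "carrier": config.carrier,
        "subject_id": config.subject_id,
        "group": config.group,
    }
    Path(path).write_text(yaml.safe_dump(d))


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["synergy_matrix_true"] = np.asarray(d["synergy_matrix_true"], float)
    d["recruitment_profiles"] = np.asarray(d["recruitment_profiles"], float)
    d["drive_bands"] = tuple(
        DriveBand(b[0], b[1], tuple(b[2]), b[3]) for b in d["drive_bands"])
    d["directed_couplings"] = tuple(
        DirectedCoupling(*c) for c in d["directed_couplings"])
    cfg = GeneratorConfig(**d)
    cfg.validate()
    return cfg


def with_subject(config: GeneratorConfig, subject_id: str,
                 seed: int) -> GeneratorConfig:
    """Copy of ``config`` re-identified for one subject with its own seed."""
    return replace(config, subject_id=subject_id, seed=seed)
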