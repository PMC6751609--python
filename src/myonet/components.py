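"""Frequency decomposition of connectivity spectra (step 5).

The pair-by-frequency connectivity matrix (IMCoh or PDC) is factorized into
``K`` non-negative frequency components by alternating least squares with
non-negativity enforced through exact non-negative-least-squares sub-solves:

    values (pairs x bins)  ~=  edge_weights.T (pairs x K) @ signatures (K x bins)

Each component couples a *spectral signature* (its frequency profile over the
35 2 Hz bins) with per-pair edge weights (the strength with which each muscle
pair expresses that component).  Because each ALS sub-problem is solved
exactly, the Frobenius reconstruction error is non-increasing across
iterations.  Components are reported in canonical order of ascending spectral
centroid (low- to high-frequency), with signatures scaled to unit maximum and
the scale absorbed into the edge weights.

The number of components is selected as the smallest ``K`` whose
reconstruction VAF reaches a threshold (default 90 %), mirroring the synergy
rank rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .connectivity import BIN_CENTERS_HZ, ConnectivitySpectra

__all__ = ["FrequencyComponents", "decompose_spectra", "select_K"]


@dataclass
class FrequencyComponents:
    """NMF factorization of connectivity spectra into frequency components."""

    n_components_K: int
    spectral_signatures: np.ndarray   # (K, 35), unit maximum per row
    edge_weights: np.ndarray          # (K, n_pairs)
    vaf_curve: dict[int, float]       # candidate K -> VAF (%)
    source_estimator: str
    pair_labels: tuple[tuple[str, str], ...]
    bin_centers_hz: np.ndarray = field(
        default_factory=lambda: BIN_CENTERS_HZ.copy())
    directed: bool = False
    channel_labels: tuple[str, ...] = ()
    vaf_pct: float = float("nan")
    threshold_reached: bool = True
    error_trace: np.ndarray | None = None

    @property
    def centroids_hz(self) -> np.ndarray:
        s = self.spectral_signatures
        tot = s.sum(axis=1)
        tot[tot == 0] = 1.0
        return (s * self.bin_centers_hz).sum(axis=1) / tot

    def reconstruction(self) -> np.ndarray:
        return self.edge_weights.T @ self.spectral_signatures


def _vaf(x: np.ndarray, recon: np.ndarray) -> float:
    return 100.0 * (1.0 - np.linalg.norm(x - recon) ** 2
                    / np.linalg.norm(x) ** 2)


def _als(x: np.ndarray, w0: np.ndarray, h0: np.ndarray, max_iter: int,
         tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating NNLS for x ~= w h; returns (w, h, error trace)."""
    w, h = w0.copy(), h0.copy()
    errs = []
    prev = np.inf
    for _ in range(max_iter):
        # rows of w given h:  min ||h.T w_i - x_i||
        for i in range(x.shape[0]):
            w[i], _ = nnls(h.T, x[i])
        # columns of h given w
        for f in range(x.shape[1]):
            h[:, f], _ = nnls(w, x[:, f])
        err = np.linalg.norm(x - w @ h)
        errs.append(err)
        if prev - err < tol * max(prev, 1e-30):
            break
        prev = err
    return w, h, np.asarray(errs)


def decompose_spectra(conn: ConnectivitySpectra, K: int,
                      n_restarts: int = 5, seed: int = 0,
                      max_iter: int = 500, tol: float = 1e-6,
                      init: tuple[np.ndarray, np.ndarray] | None = None,
                      ) -> FrequencyComponents:
    """Rank-``K`` non-negative ALS factorization of the connectivity matrix.

    Best of ``n_restarts`` random initializations (plus ``init`` if given,
    e.g. a warm start from the rank-(K-1) solution) is retained; deterministic
    under ``seed``.
    """
    x = np.asarray(conn.values, float)
    if (x < 0).any():
        raise ValueError("connectivity values must be non-negative")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(x.shape):
        raise ValueError(f"K={K} exceeds min(n_pairs, n_bins)={min(x.shape)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(x.mean(), 1e-12) / K)
    best = None
    inits = []
    if init is not None:
        inits.append((np.maximum(init[0], 1e-9), np.maximum(init[1], 1e-9)))
    for _ in range(n_restarts):
        inits.append((rng.uniform(1e-6, 1.0, (x.shape[0], K)) * scale,
                      rng.uniform(1e-6, 1.0, (K, x.shape[1])) * scale))
    for w0, h0 in inits:
        w, h, errs = _als(x, w0, h0, max_iter, tol)
        if best is None or errs[-1] < best[2][-1]:
            best = (w, h, errs)
    w, h, errs = best

    # canonical form: unit-max signatures, centroid-ascending order
    m = h.max(axis=1)
    live = m > 0
    h[live] /= m[live, None]
    w[:, live] *= m[live]
    sig, wts = h, w.T
    tot = sig.sum(axis=1)
    tot[tot == 0] = 1.0
    centroids = (sig * conn.bin_centers_hz).sum(axis=1) / tot
    order = np.argsort(centroids)
    sig, wts = sig[order], wts[order]

    return FrequencyComponents(
        n_components_K=K, spectral_signatures=sig, edge_weights=wts,
        vaf_curve={K: _vaf(x, wts.T @ sig)}, source_estimator=conn.estimator,
        pair_labels=conn.pair_labels,
        bin_centers_hz=np.asarray(conn.bin_centers_hz, float),
        directed=conn.directed, channel_labels=tuple(conn.channel_labels),
        vaf_pct=_vaf(x, wts.T @ sig), error_trace=errs)


def select_K(conn: ConnectivitySpectra, vaf_threshold_pct: float = 90.0,
             K_max: int = 8, n_restarts: int = 5, seed: int = 0,
             max_iter: int = 500, tol: float = 1e-6) -> FrequencyComponents:
    """Decomposition at the smallest K whose VAF reaches the threshold.

    Each candidate K warm-starts from the previous best solution (augmented
    with one small random component) in addition to its random restarts, which
    makes the VAF curve non-decreasing.  If the threshold is unreachable at
    ``K_max`` the best model is returned with ``threshold_reached=False``.
    """
    if not (0 < vaf_threshold_pct <= 100):
        raise ValueError("threshold must be in (0, 100]")
    rng = np.random.default_rng(seed)
    vaf_curve: dict[int, float] = {}
    prev = None
    result = None
    for K in range(1, K_max + 1):
        init = None
        if prev is not None:
            w_prev = prev.edge_weights.T
            h_prev = prev.spectral_signatures
            init = (np.hstack([w_prev,
                               rng.uniform(0, 1e-3, (w_prev.shape[0], 1))]),
                    np.vstack([h_prev,
                               rng.uniform(0, 1e-3, (1, h_prev.shape[1]))]))
        fc = decompose_spectra(conn, K, n_restarts=n_restarts,
                               seed=seed + K, max_iter=max_iter, tol=tol,
                               init=init)
        vaf_curve[K] = fc.vaf_pct
        prev = fc
        result = fc
        if fc.vaf_pct >= vaf_threshold_pct:
            break
    result.vaf_curve = vaf_curve
    result.threshold_reached = result.vaf_pct >= vaf_threshold_pct
    return result
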