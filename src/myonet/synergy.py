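"""Muscle-synergy extraction by Lee-Seung multiplicative-update NMF.

The muscle-by-time envelope matrix M (8 muscles x n samples) is factorized as

    M = W C + E,      W (m x k) >= 0,  C (k x n) >= 0,

where the columns of the synergy matrix W are muscle weighting patterns, the
rows of C their recruitment curves, and E the residual.  The number of
synergies is the smallest k whose reconstruction VAF,
``100 * (1 - ||E||_F^2 / ||M||_F^2)``, reaches 90 %.  Multiplicative updates
guarantee a non-increasing Frobenius objective; the best of several random
restarts is retained and W columns are unit-normalized (Euclidean) with the
scale absorbed into C.

Cycle-to-cycle synergy variability is quantified by matching synergies across
gait cycles (Hungarian assignment on W-column cosine similarity) and
reporting the matched similarity, the dispersion of the recruitment curves
and the per-cycle selected-k distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SynergyModel", "CycleVariability",
    "nmf_lee_seung", "vaf", "select_n_synergies", "cycle_variability",
    "scale_rows_unit_variance", "match_synergies",
]

_EPS = 1e-12


@dataclass
class SynergyModel:
    """One NMF synergy decomposition M ~= W C (+ per-candidate VAF curve)."""

    k: int
    W: np.ndarray  # (m, k), columns unit-norm
    C: np.ndarray  # (k, n)
    E: np.ndarray  # (m, n) residual
    vaf_pct: float
    vaf_curve: dict[int, float] = field(default_factory=dict)
    objective_trace: np.ndarray | None = None
    threshold_reached: bool = True
    per_cycle_models: list["SynergyModel"] | None = None
    channel_labels: tuple[str, ...] = ()

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class CycleVariability:
    """Across-cycle synergy stability summary."""

    w_similarity_mean: float      # mean matched W cosine sim over cycle pairs
    c_dispersion_cv: float        # coefficient of variation of C curves
    k_distribution: dict[int, int]
    n_cycles: int


def vaf(M: np.ndarray, E: np.ndarray) -> float:
    """Variability accounted for: 100 * (1 - ||E||_F^2 / ||M||_F^2)."""
    M, E = np.asarray(M, float), np.asarray(E, float)
    if M.shape != E.shape:
        raise ValueError("M and E must have identical shapes")
    denom = np.linalg.norm(M) ** 2
    if denom == 0:
        raise ValueError("VAF undefined for an all-zero matrix")
    return 100.0 * (1.0 - np.linalg.norm(E) ** 2 / denom)


def per_muscle_vaf(M: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Diagnostic row-wise VAF (one value per muscle)."""
    M, E = np.asarray(M, float), np.asarray(E, float)
    denom = (M ** 2).sum(axis=1)
    denom[denom == 0] = np.nan
    return 100.0 * (1.0 - (E ** 2).sum(axis=1) / denom)


def scale_rows_unit_variance(M: np.ndarray) -> np.ndarray:
    """Divide each muscle's envelope by its SD (keeps non-negativity)."""
    M = np.asarray(M, float)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return M / sd


def _multiplicative_nmf(M: np.ndarray, w0: np.ndarray, h0: np.ndarray,
                        max_iter: int, tol: float,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w, h = w0.copy(), h0.copy()
    errs = []
    prev = np.inf
    for _ in range(max_iter):
        h *= (w.T @ M) / (w.T @ w @ h + _EPS)
        w *= (M @ h.T) / (w @ h @ h.T + _EPS)
        err = np.linalg.norm(M - w @ h)
        errs.append(err)
        if prev - err < tol * max(prev, 1e-30):
            break
        prev = err
    return w, h, np.asarray(errs)


def nmf_lee_seung(M: np.ndarray, k: int, seed: int = 0, n_restarts: int = 20,
                  max_iter: int = 1000, tol: float = 1e-6,
                  init: tuple[np.ndarray, np.ndarray] | None = None,
                  channel_labels: tuple[str, ...] = ()) -> SynergyModel:
    """Rank-``k`` Lee-Seung NMF of a non-negative matrix, best of restarts.

    Initialization is uniform random in (0, 1] scaled by the data norm;
    deterministic under ``seed``.  An explicit ``init`` (e.g. warm start) is
    tried in addition to the random restarts.
    """
    M = np.asarray(M, float)
    if (M < 0).any():
        raise ValueError("M must be non-negative")
    if k < 1 or k > min(M.shape):
        raise ValueError(f"k must be in [1, {min(M.shape)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(M.mean(), _EPS) / k)
    inits = []
    if init is not None:
        inits.append((np.maximum(init[0], _EPS), np.maximum(init[1], _EPS)))
    for _ in range(n_restarts):
        inits.append((rng.uniform(_EPS, 1.0, (M.shape[0], k)) * scale,
                      rng.uniform(_EPS, 1.0, (k, M.shape[1])) * scale))
    best = None
    for w0, h0 in inits:
        w, h, errs = _multiplicative_nmf(M, w0, h0, max_iter, tol)
        if best is None or errs[-1] < best[2][-1]:
            best = (w, h, errs)
    w, c, errs = best
    norms = np.linalg.norm(w, axis=0)
    live = norms > 0
    w[:, live] /= norms[live]
    c[live] *= norms[live, None]
    e = M - w @ c
    return SynergyModel(k=k, W=w, C=c, E=e, vaf_pct=vaf(M, e),
                        objective_trace=errs, channel_labels=channel_labels)


def select_n_synergies(M: np.ndarray, threshold_pct: float = 90.0,
                       k_max: int = 8, seed: int = 0, n_restarts: int = 20,
                       max_iter: int = 1000, tol: float = 1e-6,
                       normalize: bool = True,
                       channel_labels: tuple[str, ...] = ()) -> SynergyModel:
    """Smallest k whose VAF reaches the threshold (default 90 %).

    ``normalize=True`` applies per-muscle unit-variance scaling before the
    factorization so that weak muscles still influence the rank choice.  Each
    candidate k warm-starts from the previous solution plus one small random
    component, making the VAF curve non-decreasing.  If the threshold is
    unreachable the k_max model is returned flagged.
    """
    if not (0 < threshold_pct <= 100):
        raise ValueError("threshold must be in (0, 100]")
    M = np.asarray(M, float)
    if normalize:
        M = scale_rows_unit_variance(M)
    rng = np.random.default_rng(seed)
    k_max = min(k_max, min(M.shape))
    vaf_curve: dict[int, float] = {}
    prev = None
    model = None
    for k in range(1, k_max + 1):
        init = None
        if prev is not None:
            init = (np.hstack([prev.W, rng.uniform(0, 1e-3,
                                                   (M.shape[0], 1))]),
                    np.vstack([prev.C, rng.uniform(0, 1e-3,
                                                   (1, M.shape[1]))]))
        model = nmf_lee_seung(M, k, seed=seed + k, n_restarts=n_restarts,
                              max_iter=max_iter, tol=tol, init=init,
                              channel_labels=channel_labels)
        vaf_curve[k] = model.vaf_pct
        prev = model
        if model.vaf_pct >= threshold_pct:
            break
    model.vaf_curve = vaf_curve
    model.threshold_reached = model.vaf_pct >= threshold_pct
    return model


def _cosine_matrix(wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(wa, axis=0, keepdims=True)
    nb = np.linalg.norm(wb, axis=0, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (wa / na).T @ (wb / nb)


def match_synergies(wa: np.ndarray, wb: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hungarian assignment of W columns maximizing summed cosine similarity.

    Returns (columns of a, matched columns of b, their similarities); only
    min(k_a, k_b) pairs are matched.
    """
    sim = _cosine_matrix(wa, wb)
    rows, cols = linear_sum_assignment(-sim)
    return rows, cols, sim[rows, cols]


def cycle_variability(per_cycle: list[SynergyModel]) -> CycleVariability:
    """Across-cycle synergy stability from per-gait-cycle NMF models."""
    if len(per_cycle) < 2:
        raise ValueError("need at least two gait cycles")
    for m in per_cycle:
        if not m.W.any() or not np.asarray(m.C).any():
            raise ValueError("all-zero cycle model")

    sims = []
    for a, b in combinations(per_cycle, 2):
        _, _, s = match_synergies(a.W, b.W)
        sims.append(s.mean())
    w_similarity = float(np.mean(sims))

    ks = [m.k for m in per_cycle]
    k_mode = max(set(ks), key=ks.count)
    common = [m for m in per_cycle if m.k == k_mode]
    ref = common[0]
    curves = []
    for m in common:
        if m.C.shape != ref.C.shape:
            continue
        _, cols, _ = match_synergies(ref.W, m.W)
        curves.append(m.C[cols])
    stack = np.stack(curves)  # (cycles, k, n)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    mask = mean > 1e-9 * max(mean.max(), 1e-30)
    cv = float((sd[mask] / mean[mask]).mean()) if mask.any() else 0.0

    k_distribution = {k: ks.count(k) for k in sorted(set(ks))}
    return CycleVariability(w_similarity_mean=w_similarity,
                            c_dispersion_cv=cv,
                            k_distribution=k_distribution,
                            n_cycles=len(per_cycle))
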