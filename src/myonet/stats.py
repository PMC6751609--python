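"""Group statistics: normality check, factorial ANOVA with partial eta
squared, Bonferroni-corrected post-hoc t-tests, Spearman correlation, and the
regression of synergy variance on connectivity summaries.

The factorial ANOVA is a fixed-effects general linear model on cell values
(responses in long format with categorical factor columns).  Note the caveat:
treating the within-subject muscle-pair and frequency-bin levels as
fixed-effect cells ignores subject-level correlation; the model reproduces
the reported analysis shape, it is not a mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats

__all__ = [
    "StatResult", "RegressionReport",
    "ks_normality", "anova", "bonferroni", "spearman",
    "synergy_on_connectivity_regression", "component_band_means",
]


@dataclass
class StatResult:
    effect_label: str
    F: float
    df: tuple[float, float]
    p: float
    eta_sq: float  # partial eta squared
    posthoc: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class RegressionReport:
    r_squared: float
    F: float
    df: tuple[float, float]
    p: float
    coefficients: dict[str, float]
    n: int


def ks_normality(sample: np.ndarray) -> float:
    """One-sample Kolmogorov-Smirnov p-value against a normal with the
    sample's mean and SD.

    Estimating the reference parameters from the same sample makes the test
    conservative (the Lilliefors correction is not applied); it is used here
    as a screening check only.
    """
    x = np.asarray(sample, float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    return float(sstats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, p * m)."""
    p = np.atleast_1d(np.asarray(pvals, float))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("x and y must be equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)


def anova(data: pd.DataFrame, response: str, factors: list[str],
          interactions: bool = True,
          posthoc_factor: str | None = None) -> list[StatResult]:
    """Fixed-effects factorial ANOVA (type-II sums of squares).

    Returns one :class:`StatResult` per main effect / interaction with F,
    degrees of freedom, p and partial eta squared
    ``SS_effect / (SS_effect + SS_error)``.  If ``posthoc_factor`` is given,
    Bonferroni-corrected pairwise t-tests between its levels are attached to
    that factor's result.
    """
    if not factors:
        raise ValueError("need at least one factor")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    df = data.rename(columns={response: "_y"}).copy()
    op = " * " if interactions else " + "
    formula = "_y ~ " + op.join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = float(table.loc["Residual", "df"])
    results = []
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        ss = float(row["sum_sq"])
        label = name.replace("C(", "").replace(")", "")
        res = StatResult(
            effect_label=label, F=float(row["F"]),
            df=(float(row["df"]), df_err), p=float(row["PR(>F)"]),
            eta_sq=ss / (ss + ss_err))
        results.append(res)
    if posthoc_factor is not None:
        levels = sorted(data[posthoc_factor].unique())
        contrasts, raw = [], []
        for a, b in combinations(levels, 2):
            xa = data.loc[data[posthoc_factor] == a, response]
            xb = data.loc[data[posthoc_factor] == b, response]
            raw.append(sstats.ttest_ind(xa, xb).pvalue)
            contrasts.append(f"{a} vs {b}")
        corrected = bonferroni(raw)
        for res in results:
            if res.effect_label == posthoc_factor:
                res.posthoc = list(zip(contrasts, corrected.tolist()))
    return results


def component_band_means(values: np.ndarray, bin_centers_hz: np.ndarray,
                         signatures: np.ndarray,
                         rel_height: float = 0.5) -> np.ndarray:
    """Reduce a (pairs x bins) connectivity matrix to one mean per frequency
    component: the average over all pairs of the bins where the component's
    spectral signature exceeds ``rel_height`` of its maximum."""
    feats = []
    for sig in signatures:
        band = sig >= rel_height * sig.max() if sig.max() > 0 else sig > -1
        feats.append(values[:, band].mean())
    return np.asarray(feats)


def synergy_on_connectivity_regression(pdc_features: np.ndarray,
                                       synergy_variance: np.ndarray,
                                       feature_names: list[str] | None = None,
                                       ) -> RegressionReport:
    """OLS regression of per-subject synergy variance on per-subject PDC
    summaries (e.g. per-component mean PDC from
    :func:`component_band_means`)."""
    x = np.atleast_2d(np.asarray(pdc_features, float))
    if x.shape[0] == 1 and np.asarray(synergy_variance).size != 1:
        x = x.T
    y = np.asarray(synergy_variance, float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("response length must match the number of subjects")
    if n <= p + 1:
        raise ValueError(
            f"{n} subjects cannot estimate {p} predictors plus an intercept")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    names = ["const"] + (feature_names or [f"x{i}" for i in range(p)])
    fit = sm.OLS(y, design).fit()
    return RegressionReport(
        r_squared=float(fit.rsquared), F=float(fit.fvalue),
        df=(float(fit.df_model), float(fit.df_resid)),
        p=float(fit.f_pvalue),
        coefficients=dict(zip(names, fit.params.tolist())), n=n)
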