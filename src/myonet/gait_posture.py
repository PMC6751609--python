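"""Spatiotemporal gait parameters and centre-of-pressure posture metrics.

Gait: the gait cycle duration (GCD) is the mean interval between consecutive
right heel strikes, the step cadence is 2/GCD (two steps per cycle; normative
~1.9 steps/s against the ~1.1 s normative GCD) and the stance:swing ratio
(SSR) compares the heel-strike-to-toe-off stance with the toe-off-to-next-
heel-strike swing (normative 60:40, i.e. 1.5).

Posture: the COP path length is the summed point-to-point displacement of the
centre of pressure; sway is summarized by the area of the 90 % prediction
ellipse of the (mean-removed) COP along its principal axes,
``pi * chi2_2(0.90) * sigma1 * sigma2``; the Romberg quotient is the
eyes-closed / eyes-open ellipse-area ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .synthetic import CopTrace

__all__ = [
    "GaitParameters", "CopMetrics",
    "gait_parameters", "cop_path_length", "sway_ellipse_area",
    "romberg_quotient", "cop_metrics",
]


@dataclass
class GaitParameters:
    gcd_s: float          # mean gait-cycle duration
    cadence_hz: float     # steps per second (2 per cycle)
    ssr: float            # stance:swing ratio
    speed_m_s: float | None = None


@dataclass
class CopMetrics:
    path_length_mm: float
    ellipse_area_mm2: float
    romberg_quotient: float | None = None
    condition: str = "eyes_open"


def _side_ssr(hs: np.ndarray, to: np.ndarray) -> float | None:
    stance, swing = [], []
    for a, b in zip(hs[:-1], hs[1:]):
        inside = to[(to > a) & (to < b)]
        if inside.size != 1:
            continue
        stance.append(inside[0] - a)
        swing.append(b - inside[0])
    if not stance:
        return None
    return float(np.mean(stance) / np.mean(swing))


def gait_parameters(heel_strikes: dict[str, np.ndarray],
                    toe_offs: dict[str, np.ndarray],
                    walkway_length_m: float | None = None,
                    walk_time_s: float | None = None) -> GaitParameters:
    """Spatiotemporal gait summary from per-side heel-strike/toe-off events."""
    hs_r = np.asarray(heel_strikes.get("right", []), float)
    if hs_r.size < 2:
        raise ValueError("need at least two right heel strikes")
    for side, ev in list(heel_strikes.items()) + list(toe_offs.items()):
        ev = np.asarray(ev, float)
        if ev.size > 1 and not (np.diff(ev) > 0).all():
            raise ValueError(f"{side} events are not strictly increasing")
    gcd = float(np.mean(np.diff(hs_r)))
    ratios = []
    for side in ("right", "left"):
        hs = np.asarray(heel_strikes.get(side, []), float)
        to = np.asarray(toe_offs.get(side, []), float)
        if hs.size >= 2 and to.size:
            r = _side_ssr(hs, to)
            if r is not None:
                ratios.append(r)
    if not ratios:
        raise ValueError("no usable stance/swing interval on either side")
    speed = None
    if walkway_length_m is not None and walk_time_s:
        speed = walkway_length_m / walk_time_s
    return GaitParameters(gcd_s=gcd, cadence_hz=2.0 / gcd,
                          ssr=float(np.mean(ratios)), speed_m_s=speed)


def cop_path_length(trace: CopTrace) -> float:
    """Total COP displacement (mm): sum of consecutive Euclidean steps."""
    xy = np.asarray(trace.xy, float)
    if xy.shape[0] < 2:
        raise ValueError("need at least two samples")
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def sway_ellipse_area(trace: CopTrace, coverage: float = 0.90) -> float:
    """Area (mm^2) of the prediction ellipse covering ``coverage`` of sway.

    Principal-axis SDs come from the 2x2 covariance of the mean-removed COP;
    the area is ``pi * chi2_2(coverage) * sigma1 * sigma2`` (chi-square
    quantile 4.6052 at 90 %).
    """
    xy = np.asarray(trace.xy, float)
    if xy.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    centred = xy - xy.mean(axis=0)
    cov = np.cov(centred.T)
    eigvals = np.linalg.eigvalsh(cov)
    if (eigvals <= 0).any():
        return 0.0
    q = chi2.ppf(coverage, df=2)
    return float(np.pi * q * np.sqrt(eigvals[0] * eigvals[1]))


def romberg_quotient(area_ec_mm2: float, area_eo_mm2: float) -> float:
    """Eyes-closed over eyes-open sway-ellipse area."""
    if area_eo_mm2 <= 0:
        raise ValueError("eyes-open area must be positive")
    return area_ec_mm2 / area_eo_mm2


def cop_metrics(eyes_open: CopTrace,
                eyes_closed: CopTrace | None = None) -> CopMetrics:
    """Per-subject posture row: path length, 90 % ellipse, Romberg quotient."""
    area_eo = sway_ellipse_area(eyes_open)
    rq = None
    if eyes_closed is not None:
        rq = romberg_quotient(sway_ellipse_area(eyes_closed), area_eo)
    return CopMetrics(path_length_mm=cop_path_length(eyes_open),
                      ellipse_area_mm2=area_eo, romberg_quotient=rq,
                      condition=eyes_open.condition)
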