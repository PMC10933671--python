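"""Deterministic bench-side scores: IHC immunoreactivity, Ki67 banding,
median-effect dose-response fits and the Loewe combination index.

IHC immunoreactivity score (IRS)
    The product of a staining-degree score (0-3, assigned by the
    pathologist) and a positive-rate score derived from the fraction of
    positive cells: 0-5% -> 0, 6-25% -> 1, 26-50% -> 2, 51-75% -> 3,
    >75% -> 4.  The printed bins leave a 5%-6% gap; it is resolved as
    half-open intervals on the percentage line ((5, 25] -> 1, etc.), so
    every fraction maps to exactly one score.  The IRS therefore ranges
    over 0-12.

Ki67 banding
    Three proliferative-index bands on the positive rate: <50% low,
    50-70% mid, >70% high (band edges inclusive on the mid band).

Median-effect dose-response (Chou-Talalay)
    The median-effect equation fa/(1-fa) = (D/Dm)^m is linear in
    log space: log(fa/(1-fa)) = m*(log D - log Dm).  A least-squares line
    through the observed (dose, affected-fraction) points yields the slope
    m and midpoint Dm, from which any IC_x follows in closed form:
    IC_x = Dm * (x/(1-x))^(1/m).  The combination index of a dose pair
    (dA, dB) achieving a joint affected fraction x is the Loewe sum
    CI = dA/IC_x(A) + dB/IC_x(B); CI < 1 indicates synergy, CI = 1
    additivity, CI > 1 antagonism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

FA_EPS = 1e-4
R2_WARN_THRESHOLD = 0.9


# ---------------------------------------------------------------------------
# IHC scores
# ---------------------------------------------------------------------------

def positive_rate_points(fraction: float) -> int:
    """Positive-rate score (0-4) from the fraction of positive cells.

    Bins (half-open on the percentage line): [0, 5] -> 0, (5, 25] -> 1,
    (25, 50] -> 2, (50, 75] -> 3, (75, 100] -> 4.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    pct = fraction * 100.0
    for points, upper in enumerate((5.0, 25.0, 50.0, 75.0)):
        if pct <= upper:
            return points
    return 4


def irs(staining_degree: int, positive_fraction: float) -> int:
    """Immunoreactivity score: staining degree (0-3) x rate points (0-4)."""
    if staining_degree not in (0, 1, 2, 3):
        raise ValueError(f"staining degree must be 0-3, got {staining_degree}")
    return staining_degree * positive_rate_points(positive_fraction)


def ki67_band(fraction: float) -> str:
    """Ki67 proliferative-index band: <50% low, 50-70% mid, >70% high."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction < 0.5:
        return "low"
    if fraction <= 0.7:
        return "mid"
    return "high"


# ---------------------------------------------------------------------------
# Median-effect dose-response
# ---------------------------------------------------------------------------

@dataclass
class MedianEffectFit:
    """Fitted median-effect parameters: slope m, midpoint Dm, fit R^2."""

    m: float
    dm: float
    r_squared: float

    def ic(self, x: float) -> float:
        """Dose producing affected fraction ``x`` (e.g. 0.5 for IC50)."""
        if not (0.0 < x < 1.0):
            raise ValueError("x must be in (0, 1)")
        return float(self.dm * (x / (1.0 - x)) ** (1.0 / self.m))

    def fa(self, dose: float) -> float:
        """Predicted affected fraction at ``dose``."""
        if dose < 0:
            raise ValueError("dose must be non-negative")
        if dose == 0:
            return 0.0
        ratio = (dose / self.dm) ** self.m
        return float(ratio / (1.0 + ratio))


def median_effect_fit(doses, fa) -> MedianEffectFit:
    """Least-squares median-effect fit on log(fa/(1-fa)) vs log(dose).

    Requires at least 3 positive dose levels; affected fractions are
    clipped to (1e-4, 1-1e-4) before the logit.  Non-monotone data still
    fits, but an R^2 below 0.9 is flagged with a warning.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape or doses.ndim != 1:
        raise ValueError("doses and fa must be 1-D arrays of equal length")
    if len(doses) < 3:
        raise ValueError("need at least 3 dose levels")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    fa = np.clip(fa, FA_EPS, 1.0 - FA_EPS)
    x = np.log(doses)
    y = np.log(fa / (1.0 - fa))
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        raise ValueError("degenerate fit: zero median-effect slope")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    if r2 < R2_WARN_THRESHOLD:
        logger.warning("median-effect fit R^2 = %.3f (< %.2f)", r2,
                       R2_WARN_THRESHOLD)
    return MedianEffectFit(m=float(slope), dm=float(np.exp(-intercept / slope)),
                           r_squared=r2)


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    dose_a: float,
    dose_b: float,
    combo_fa: float,
) -> float:
    """Loewe combination index at the combination's affected fraction.

    CI = dA / IC_x(A) + dB / IC_x(B), evaluated at x = ``combo_fa``.
    A zero-dose pair returns CI = 0 and is flagged as degenerate.
    """
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be non-negative")
    if not (0.0 < combo_fa < 1.0):
        raise ValueError("combo_fa must be in (0, 1)")
    if dose_a == 0 and dose_b == 0:
        logger.warning("combination with both doses 0: CI degenerate (0)")
        return 0.0
    return float(dose_a / fit_a.ic(combo_fa) + dose_b / fit_b.ic(combo_fa))


def simulate_median_effect(doses, m: float, dm: float) -> np.ndarray:
    """Noiseless affected fractions under the median-effect model."""
    doses = np.asarray(doses, dtype=float)
    ratio = (doses / dm) ** m
    return ratio / (1.0 + ratio)
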