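"""Circular statistics on 24-hour phases.

Peak times live on a 24 h circle; arithmetic means and differences are
meaningless when values straddle midnight, so every aggregate here goes
through the resultant-vector representation.
"""

from __future__ import annotations

import numpy as np

PERIOD_H = 24.0

__all__ = [
    "PERIOD_H",
    "wrap_hours",
    "circular_mean_hours",
    "circular_diff_hours",
    "circular_sd_hours",
]


def wrap_hours(t: float | np.ndarray, period: float = PERIOD_H):
    """Reduce a time (or array of times) to [0, period)."""
    return np.asarray(t, dtype=float) % period


def circular_mean_hours(phases_h, period: float = PERIOD_H) -> float:
    """Mean phase as the angle of the mean resultant vector, in [0, period).

    Raises ``ValueError`` when the resultant vector has (numerically) zero
    length, in which case the mean direction is undefined.
    """
    phases_h = np.asarray(phases_h, dtype=float)
    if phases_h.size == 0:
        raise ValueError("need at least one phase")
    ang = 2.0 * np.pi * phases_h / period
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    r = np.hypot(c, s)
    if r < 1e-12:
        raise ValueError("mean phase undefined: zero resultant length")
    h = float((np.arctan2(s, c) * period / (2.0 * np.pi)) % period)
    return 0.0 if period - h < 1e-9 else h


def circular_diff_hours(a_h, b_h, period: float = PERIOD_H):
    """Signed wrapped difference a − b in (−period/2, period/2].

    The antipodal difference maps to +period/2 (deterministic boundary
    convention).
    """
    d = (np.asarray(a_h, dtype=float) - np.asarray(b_h, dtype=float)) % period
    half = period / 2.0
    out = np.where(d > half, d - period, d)
    # exact antipode: keep +half, not -half
    out = np.where(np.isclose(d, half), half, out)
    if out.ndim == 0:
        return float(out)
    return out


def circular_sd_hours(phases_h, period: float = PERIOD_H) -> float:
    """Circular standard deviation sqrt(−2 ln R), rescaled to hours."""
    phases_h = np.asarray(phases_h, dtype=float)
    ang = 2.0 * np.pi * phases_h / period
    r = float(np.hypot(np.cos(ang).mean(), np.sin(ang).mean()))
    r = min(r, 1.0)
    if r <= 1e-300:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(r)) * period / (2.0 * np.pi))
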