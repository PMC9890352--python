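"""Circular statistics for clock times on the 24-hour circle.

Clock times (minutes after midnight) are treated as angles; means and
spreads come from the mean resultant vector, and agreement between two sets
of times uses the angular (sine-deviation) circular-circular correlation,
which is invariant to rotating either variable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "circular_mean",
    "circular_sd",
    "circular_diff",
    "circular_corr",
    "accuracy_report",
    "UndefinedStatisticError",
]

MINUTES_PER_DAY = 1440
_RAD_PER_MIN = 2.0 * np.pi / MINUTES_PER_DAY
_HOURS_PER_RAD = 12.0 / np.pi

_RESULTANT_TOL = 1e-9


class UndefinedStatisticError(ValueError):
    """The requested circular statistic is undefined for these inputs."""


def _to_radians(minutes) -> np.ndarray:
    return np.asarray(minutes, dtype=float) * _RAD_PER_MIN


def circular_mean(times: Sequence[float]) -> int:
    """Circular mean of clock times, to the nearest minute.

    Raises :class:`UndefinedStatisticError` when the mean resultant vector
    is (numerically) zero, e.g. for an antipodal pair.
    """
    theta = _to_radians(times)
    if theta.size == 0:
        raise UndefinedStatisticError("circular mean of an empty set")
    s, c = np.sin(theta).mean(), np.cos(theta).mean()
    if np.hypot(s, c) <= _RESULTANT_TOL:
        raise UndefinedStatisticError("mean resultant vector is zero")
    mean_rad = np.arctan2(s, c) % (2.0 * np.pi)
    return int(round(mean_rad / _RAD_PER_MIN)) % MINUTES_PER_DAY


def circular_sd(times: Sequence[float]) -> float:
    """Circular standard deviation in hours, sqrt(-2 ln Rbar) rescaled."""
    theta = _to_radians(times)
    if theta.size == 0:
        raise UndefinedStatisticError("circular SD of an empty set")
    rbar = np.hypot(np.sin(theta).mean(), np.cos(theta).mean())
    rbar = min(rbar, 1.0)
    if rbar <= _RESULTANT_TOL:
        raise UndefinedStatisticError("mean resultant vector is zero")
    return float(np.sqrt(-2.0 * np.log(rbar)) * _HOURS_PER_RAD)


def circular_diff(t1, t2) -> float:
    """Shortest distance around the 24-h circle, in hours (0 to 12)."""
    delta = (np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float)) / 60.0
    delta = np.abs(delta) % 24.0
    out = np.minimum(delta, 24.0 - delta)
    return float(out) if out.ndim == 0 else out


def circular_corr(est: Sequence[float], rep: Sequence[float]) -> float:
    """Circular-circular correlation between two sets of clock times.

    The angular correlation via sine deviations from the circular means:

        rho = sum sin(a_i - abar) sin(b_i - bbar)
              / sqrt(sum sin^2(a_i - abar) * sum sin^2(b_i - bbar))

    It equals 1 when one variable is the other plus a constant offset and
    is undefined (raises) when either variable is constant.
    """
    alpha, beta = _to_radians(est), _to_radians(rep)
    if alpha.shape != beta.shape or alpha.size < 3:
        raise ValueError("need equal-length sequences of at least 3 pairs")
    sa = np.sin(alpha - _circ_mean_rad(alpha))
    sb = np.sin(beta - _circ_mean_rad(beta))
    denom = np.sqrt((sa * sa).sum() * (sb * sb).sum())
    if denom <= _RESULTANT_TOL:
        raise UndefinedStatisticError("constant sequence: correlation undefined")
    return float((sa * sb).sum() / denom)


def _circ_mean_rad(theta: np.ndarray) -> float:
    return float(np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()))


def accuracy_report(pairs: Sequence[tuple]) -> dict:
    """Accuracy summary for (estimated, reported) clock-time pairs.

    Counts estimates within 1 and within 2 hours of the report (boundary
    inclusive: exactly 60 minutes counts as within 1 hour), plus the
    circular correlation where defined.
    """
    if len(pairs) == 0:
        raise ValueError("accuracy_report needs at least one pair")
    est = np.array([p[0] for p in pairs], dtype=float)
    rep = np.array([p[1] for p in pairs], dtype=float)
    diffs = circular_diff(est, rep)
    diffs = np.atleast_1d(diffs)
    try:
        rho = circular_corr(est, rep) if est.size >= 3 else None
    except UndefinedStatisticError:
        rho = None
    return {
        "n": int(est.size),
        "within_1h": int((diffs <= 1.0).sum()),
        "within_2h": int((diffs <= 2.0).sum()),
        "circ_corr": rho,
    }
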