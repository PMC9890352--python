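"""The unified piecewise-quadratic circadian posting model.

Posting frequency per 15-minute bin, in hours x after bedtime, is

    r(x) = a*x**2 + b*x + c    for -S <= x <= E   (the nighttime depletion)
    r(x) = d                   otherwise          (the flat daytime rate)

with the flat height d fixed by normalization so the 96 bins sum to one:

    d = (1 - sum of r over the parabolic bin starts) / (96 - k)

where k is the number of parabolic bins. S and E are found by exhaustive
grid search in 15-minute increments, with (a, b, c) an ordinary
least-squares quadratic on the section for each candidate (S, E), keeping
the combination with the lowest mean squared error over all 96 bins.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .fingerprint import N_BINS, X_GRID, RelativeProfile

__all__ = [
    "UnifiedModel",
    "FitError",
    "eval_model",
    "flat_height",
    "fit_quadratic",
    "fit_unified",
    "reference_model",
    "S_GRID_MAX",
    "E_GRID_MAX",
]

#: Grid-search bounds on the parabolic section, hours before/after bedtime.
#: Chosen to cover physiologic sleep windows inside the 24-h relative frame.
S_GRID_MAX = 6.0
E_GRID_MAX = 11.75

_MIN_SECTION_BINS = 3
_MSE_TIE_TOL = 1e-12


class FitError(RuntimeError):
    """Raised when no valid (S, E) combination yields a usable model."""


def _section_mask(S: float, E: float) -> np.ndarray:
    return (X_GRID >= -S - 1e-9) & (X_GRID <= E + 1e-9)


@dataclass
class UnifiedModel:
    """Fitted parameters of the piecewise circadian model.

    S, E
        Hours before / after bedtime of the first and last parabolic bin
        start (nonnegative multiples of 0.25 h).
    a, b, c
        Quadratic coefficients on the section, signed; for a real
        depletion a > 0 with the minimum inside the section.
    d
        Flat daytime height per bin, from the normalization equation.
    mse, pearson
        Fit diagnostics against the training profile (None for models
        constructed from published coefficients rather than a fit).
    """

    S: float
    E: float
    a: float
    b: float
    c: float
    d: float
    mse: Optional[float] = None
    pearson: Optional[float] = None

    def __post_init__(self) -> None:
        mask = _section_mask(self.S, self.E)
        if mask.sum() < _MIN_SECTION_BINS:
            raise ValueError("parabolic section must contain at least 3 bins")
        if self.d < 0:
            raise ValueError("flat height d must be nonnegative")
        vals = self._raw_values()
        if (vals < -1e-12).any():
            raise ValueError("modeled frequencies must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("modeled frequencies must sum to 1")

    def _raw_values(self) -> np.ndarray:
        mask = _section_mask(self.S, self.E)
        vals = np.full(N_BINS, self.d)
        xs = X_GRID[mask]
        vals[mask] = self.a * xs * xs + self.b * xs + self.c
        return vals

    @property
    def n_parabolic_bins(self) -> int:
        return int(_section_mask(self.S, self.E).sum())

    @property
    def nadir_x(self) -> float:
        """Location of the parabola's vertex, hours after bedtime."""
        return -self.b / (2.0 * self.a)

    @property
    def nadir_value(self) -> float:
        """Modeled frequency at the parabola's minimum, c - b^2/(4a)."""
        return self.c - self.b * self.b / (4.0 * self.a)

    def depletion_fraction(self) -> float:
        """Depth of the nighttime lull relative to the daytime rate, 1 - min/d."""
        return 1.0 - self.nadir_value / self.d

    def to_dict(self) -> dict:
        out = asdict(self)
        out["grid_spec"] = {
            "n_bins": N_BINS,
            "bin_hours": 0.25,
            "x_min": float(X_GRID[0]),
            "s_max": S_GRID_MAX,
            "e_max": E_GRID_MAX,
        }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "UnifiedModel":
        keys = ("S", "E", "a", "b", "c", "d", "mse", "pearson")
        return cls(**{k: data.get(k) for k in keys})

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "UnifiedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def eval_model(m: UnifiedModel) -> np.ndarray:
    """Expected posting frequency in each of the 96 relative bins."""
    vals = m._raw_values()
    return np.clip(vals, 0.0, None)  # guards -1e-16 float dust only


def flat_height(S: float, E: float, a: float, b: float, c: float) -> float:
    """Flat-section height d making the full 96-bin curve sum to one.

    Returns the (possibly negative) solution of the normalization
    equation; the grid search discards combinations where d < 0. The
    section may not cover all 96 bins.
    """
    mask = _section_mask(S, E)
    k = int(mask.sum())
    if not _MIN_SECTION_BINS <= k < N_BINS:
        raise ValueError(f"parabolic section must have 3..95 bins, got {k}")
    xs = X_GRID[mask]
    return (1.0 - float(np.sum(a * xs * xs + b * xs + c))) / (N_BINS - k)


def fit_quadratic(
    profile: RelativeProfile, S: float, E: float
) -> tuple[float, float, float]:
    """OLS quadratic through the profile values on the section's bin starts."""
    mask = _section_mask(S, E)
    if mask.sum() < _MIN_SECTION_BINS:
        raise ValueError("parabolic section must contain at least 3 bins")
    coeffs = np.polyfit(X_GRID[mask], profile.values[mask], 2)
    a, b, c = (float(v) for v in coeffs)
    return a, b, c


def _candidate(profile: RelativeProfile, S: float, E: float):
    """Fit one (S, E) run; return (mse, model values, coeffs, d) or None if invalid."""
    mask = _section_mask(S, E)
    k = int(mask.sum())
    if k < _MIN_SECTION_BINS or k >= N_BINS:
        return None
    a, b, c = fit_quadratic(profile, S, E)
    d = flat_height(S, E, a, b, c)
    if d < 0:
        return None
    vals = np.full(N_BINS, d)
    xs = X_GRID[mask]
    vals[mask] = a * xs * xs + b * xs + c
    if (vals < 0).any():
        return None
    mse = float(np.mean((vals - profile.values) ** 2))
    return mse, vals, (a, b, c), d


def fit_unified(
    profile: RelativeProfile,
    s_max: float = S_GRID_MAX,
    e_max: float = E_GRID_MAX,
) -> UnifiedModel:
    """Exhaustive grid search over parabola cut points (S, E).

    Sweeps S in {0, 0.25, ..., s_max} and E in {0.25, ..., e_max} hours;
    combinations whose flat height comes out negative, or whose modeled
    curve dips below zero, are discarded. Equal-mse ties (within 1e-12)
    resolve to the narrower section, then the smaller S, so output is
    deterministic.
    """
    best = None  # (mse, width, S, E, vals, coeffs, d)
    n_s = int(round(s_max / 0.25)) + 1
    n_e = int(round(e_max / 0.25))
    for i in range(n_s):
        S = 0.25 * i
        for j in range(1, n_e + 1):
            E = 0.25 * j
            cand = _candidate(profile, S, E)
            if cand is None:
                continue
            mse, vals, coeffs, d = cand
            width = int(round((S + E) / 0.25)) + 1
            if best is None:
                better = True
            elif mse < best[0] - _MSE_TIE_TOL:
                better = True
            elif mse <= best[0] + _MSE_TIE_TOL:
                better = (width, S) < (best[1], best[2])
            else:
                better = False
            if better:
                best = (mse, width, S, E, vals, coeffs, d)
    if best is None:
        raise FitError("no valid (S, E) combination on the grid")
    mse, _, S, E, vals, (a, b, c), d = best
    if vals.std() == 0.0 or profile.values.std() == 0.0:
        pearson = None  # flat curve: correlation undefined
    else:
        pearson = float(np.corrcoef(vals, profile.values)[0, 1])
    return UnifiedModel(S=S, E=E, a=a, b=b, c=c, d=d, mse=mse, pearson=pearson)


def reference_model() -> UnifiedModel:
    """The published best-fit model for aggregate posting around bedtime.

    Coefficient magnitudes 4.12e-4, 3.81e-3, 1.06e-2 with the linear term
    signed negative so the minimum lies inside the section (S=0.75, E=10);
    the flat height is recomputed from the normalization equation rather
    than copied, so the curve sums to one exactly.
    """
    S, E, a, b, c = 0.75, 10.0, 4.12e-4, -3.81e-3, 1.06e-2
    d = flat_height(S, E, a, b, c)
    return UnifiedModel(S=S, E=E, a=a, b=b, c=c, d=d)
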