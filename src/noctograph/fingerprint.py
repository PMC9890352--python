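"""Circadian fingerprints and bedtime-relative profiles.

A circadian fingerprint is a 96-vector giving the fraction of a user's posts
falling in each 15-minute bin of the local 24-hour day. Recasting a
fingerprint relative to a bedtime is a pure cyclic permutation that puts the
bin containing the bedtime at offset zero; averaged across users it yields
the aggregate profile the unified model is fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .ingest import GRID_MINUTES, EmptyInputError, LocalizedPosts, MINUTES_PER_DAY

__all__ = [
    "N_BINS",
    "X_GRID",
    "CircadianFingerprint",
    "RelativeProfile",
    "compute_fingerprint",
    "to_relative",
    "from_relative",
    "aggregate_profiles",
]

N_BINS = MINUTES_PER_DAY // GRID_MINUTES  # 96
#: Relative-coordinate bin starts: hours after bedtime, -12.00 .. +11.75.
X_GRID = -12.0 + 0.25 * np.arange(N_BINS)
X_GRID.setflags(write=False)
_ZERO_INDEX = 48  # index of x = 0 on X_GRID

_SUM_TOL = 1e-9


def _check_distribution(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (N_BINS,):
        raise ValueError(f"expected {N_BINS} bins, got shape {values.shape}")
    if (values < 0).any():
        raise ValueError("bin values must be nonnegative")
    if abs(values.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"bin values must sum to 1 (got {values.sum()!r})")
    return values


@dataclass
class CircadianFingerprint:
    """Fraction of a user's posts in each 15-minute bin of the local day.

    Bin ``i`` covers local minutes ``[15*i, 15*(i+1))``. Values are stored
    as fractions summing to one (display layers may multiply by 100).
    """

    values: np.ndarray = field(repr=False)
    n_posts: int = 0

    def __post_init__(self) -> None:
        self.values = _check_distribution(self.values)


@dataclass
class RelativeProfile:
    """A fingerprint (or average of fingerprints) in bedtime-relative time.

    ``values[j]`` is the posting fraction in the bin starting ``X_GRID[j]``
    hours after bedtime; ``n_users`` records how many fingerprints were
    averaged.
    """

    values: np.ndarray = field(repr=False)
    n_users: int = 1

    def __post_init__(self) -> None:
        self.values = _check_distribution(self.values)

    @property
    def x_grid(self) -> np.ndarray:
        return X_GRID


def compute_fingerprint(posts: LocalizedPosts) -> CircadianFingerprint:
    """Bin a user's local posting minutes into the 96-bin fingerprint."""
    n = posts.n_posts
    if n == 0:
        raise EmptyInputError("cannot fingerprint a user with zero posts")
    counts = np.bincount(posts.local_minutes // GRID_MINUTES, minlength=N_BINS)
    return CircadianFingerprint(values=counts / n, n_posts=n)


def _bedtime_bin(bedtime_minutes: int) -> int:
    b = int(bedtime_minutes)
    if not 0 <= b < MINUTES_PER_DAY or b % GRID_MINUTES != 0:
        raise ValueError("bedtime must be on the 15-minute grid in [0, 1440)")
    return b // GRID_MINUTES


def to_relative(fp: CircadianFingerprint, bedtime_minutes: int) -> RelativeProfile:
    """Recast a fingerprint so the bedtime bin sits at offset x = 0.

    The clock bin containing the bedtime maps to ``X_GRID == 0``; the result
    is a cyclic permutation of the fingerprint values.
    """
    k = _bedtime_bin(bedtime_minutes)
    idx = (k + np.arange(N_BINS) - _ZERO_INDEX) % N_BINS
    return RelativeProfile(values=fp.values[idx], n_users=1)


def from_relative(profile: RelativeProfile, bedtime_minutes: int) -> np.ndarray:
    """Invert :func:`to_relative`: clock-bin values given the bedtime."""
    k = _bedtime_bin(bedtime_minutes)
    out = np.empty(N_BINS)
    idx = (k + np.arange(N_BINS) - _ZERO_INDEX) % N_BINS
    out[idx] = profile.values
    return out


def aggregate_profiles(profiles: Sequence[RelativeProfile]) -> RelativeProfile:
    """Element-wise mean of per-user relative profiles, weighting users equally."""
    if len(profiles) == 0:
        raise EmptyInputError("cannot aggregate an empty list of profiles")
    stack = np.stack([p.values for p in profiles])
    return RelativeProfile(values=stack.mean(axis=0), n_users=len(profiles))


def fingerprints_to_frame(
    fps: dict[str, CircadianFingerprint]
) -> pd.DataFrame:
    """Serialize fingerprints as a table: one row per user, 96 labeled columns."""
    cols = [f"{(GRID_MINUTES * i) // 60:02d}:{(GRID_MINUTES * i) % 60:02d}" for i in range(N_BINS)]
    rows = {a: fp.values for a, fp in fps.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.insert(0, "n_posts", [fps[a].n_posts for a in df.index])
    df.index.name = "author_id"
    return df


def profile_to_frame(profile: RelativeProfile) -> pd.DataFrame:
    """Serialize a relative profile as a two-column table (x offset, fraction)."""
    return pd.DataFrame(
        {"hours_after_bedtime": X_GRID, "fraction": profile.values}
    ).assign(n_users=profile.n_users)
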