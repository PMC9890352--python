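"""Synthetic cohorts with the statistical structure the method assumes.

Each simulated user has a true habitual bedtime drawn from a von Mises law
on the 24-hour circle (default mean 23:45, concentration giving a circular
SD near 1.5 h, mirroring a survey cohort whose mean reported bedtime falls
just before midnight), and posts whose minutes-of-day are i.i.d. draws from
the unified-model template for that bedtime, optionally blended with a
Dirichlet daytime-noise component. Bot archetypes are generated so each
trips exactly one filtration rule. Output round-trips through the same
file formats the ingest layer reads, so every pipeline stage is testable
without any download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fingerprint import N_BINS
from .ingest import GRID_MINUTES, format_clock, round_bedtime
from .model import UnifiedModel, eval_model, reference_model

__all__ = ["SyntheticSpec", "SyntheticUser", "SyntheticCohort",
           "simulate_user", "simulate_cohort", "simulate_bot", "write_cohort"]

_ZERO_INDEX = 48

#: Default bedtime population: von Mises mean 23:45, kappa 6.5 (~1.5 h SD).
DEFAULT_BEDTIME_MEAN = 23 * 60 + 45
DEFAULT_KAPPA = 6.5
DEFAULT_ZONES = (
    "America/New_York",
    "America/Chicago",
    "America/Los_Angeles",
    "Europe/London",
    "UTC",
)
_EPOCH_START = 1_577_836_800  # 2020-01-01T00:00Z, start of the simulated span


@dataclass
class SyntheticSpec:
    """Study conditions for a simulated cohort."""

    n_users: int = 159
    posts_per_user: Union[int, tuple[int, int]] = 2000
    bedtime_mean: int = DEFAULT_BEDTIME_MEAN  # minutes after midnight
    bedtime_kappa: float = DEFAULT_KAPPA
    model: Optional[UnifiedModel] = None  # defaults to the published fit
    noise: float = 0.0  # Dirichlet blend weight on each user's template
    span_days: int = 365
    zones: Sequence[str] = DEFAULT_ZONES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be positive")
        if self.bedtime_kappa < 0:
            raise ValueError("concentration must be nonnegative")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")
        if self.model is None:
            self.model = reference_model()


@dataclass
class SyntheticUser:
    author_id: str
    true_bedtime: int  # minutes, 15-min grid
    tz_name: str
    epochs: np.ndarray = field(repr=False)


@dataclass
class SyntheticCohort:
    spec: SyntheticSpec
    users: list[SyntheticUser]

    def __iter__(self):
        return iter(self.users)

    def __len__(self) -> int:
        return len(self.users)


def _template_probs(m: UnifiedModel, bedtime: int) -> np.ndarray:
    """Clock-bin probabilities for a user with the given bedtime."""
    vals = eval_model(m)
    k = bedtime // GRID_MINUTES
    base = np.roll(vals, -_ZERO_INDEX)
    probs = np.roll(base, k)
    return probs / probs.sum()


def _minutes_to_epochs(minutes: np.ndarray, days: np.ndarray, tz_name: str) -> np.ndarray:
    """Local (day, minute-of-day) pairs to UTC epoch seconds, DST-aware."""
    naive = (pd.Timestamp("2020-01-01")
             + pd.to_timedelta(days, unit="D")
             + pd.to_timedelta(minutes, unit="m"))
    idx = pd.DatetimeIndex(naive).tz_localize(
        tz_name, ambiguous=np.zeros(len(naive), dtype=bool),
        nonexistent="shift_forward")
    return (idx.asi8 // 10**9).astype(np.int64)


def simulate_user(
    bedtime: int,
    n: int,
    m: Optional[UnifiedModel] = None,
    noise: float = 0.0,
    seed: Union[int, np.random.SeedSequence] = 0,
    tz_name: str = "UTC",
    span_days: int = 365,
) -> np.ndarray:
    """Draw n post epochs for a user with the given true bedtime.

    Post minutes-of-day are i.i.d. from the bedtime-shifted model template,
    blended with a user-level Dirichlet perturbation when ``noise > 0``;
    each post gets uniform minute jitter within its 15-minute bin and a
    date uniform over the span, then is converted to UTC epoch seconds in
    the user's zone. Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if m is None:
        m = reference_model()
    rng = np.random.default_rng(seed)
    probs = _template_probs(m, int(bedtime))
    if noise > 0.0:
        perturb = rng.dirichlet(np.ones(N_BINS))
        probs = (1.0 - noise) * probs + noise * perturb
        probs = probs / probs.sum()
    bins = rng.choice(N_BINS, size=n, p=probs)
    minutes = bins * GRID_MINUTES + rng.integers(0, GRID_MINUTES, size=n)
    days = rng.integers(0, span_days, size=n)
    return np.sort(_minutes_to_epochs(minutes, days, tz_name))


def simulate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Simulate a labeled cohort under the given study conditions.

    Bedtimes are von Mises draws rounded to the 15-minute grid; each user
    gets an independent child seed, so the cohort is reproducible as a
    whole and per user.
    """
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    child_seeds = np.random.SeedSequence(spec.seed + 1).spawn(spec.n_users)

    mu_rad = spec.bedtime_mean / 1440 * 2 * np.pi
    if np.isinf(spec.bedtime_kappa):
        raw = np.full(spec.n_users, mu_rad)
    else:
        raw = rng.vonmises(mu_rad, spec.bedtime_kappa, size=spec.n_users)
    bed_minutes = (raw % (2 * np.pi)) / (2 * np.pi) * 1440
    bedtimes = [round_bedtime(int(b) % 1440) for b in bed_minutes]

    users = []
    for i, (bt, cs) in enumerate(zip(bedtimes, child_seeds)):
        if isinstance(spec.posts_per_user, tuple):
            lo, hi = spec.posts_per_user
            n = int(rng.integers(lo, hi + 1))
        else:
            n = int(spec.posts_per_user)
        tz = spec.zones[i % len(spec.zones)]
        epochs = simulate_user(bt, n, spec.model, spec.noise, cs, tz,
                               spec.span_days)
        users.append(SyntheticUser(author_id=f"user{i:04d}", true_bedtime=bt,
                                   tz_name=tz, epochs=epochs))
    return SyntheticCohort(spec=spec, users=users)


def simulate_bot(archetype: str, seed: int = 0) -> tuple[str, np.ndarray]:
    """A posting record that trips exactly one bot-filtration rule.

    Archetypes: ``burst`` (nine posts in one minute), ``volume`` (2**14
    lifetime posts), ``periodic`` (3% of posts at one minute-of-day),
    ``named`` (bot-like username, otherwise ordinary record).
    """
    rng = np.random.default_rng(seed)
    decade = 10 * 365
    if archetype == "burst":
        # 9 posts in one minute out of 600: burst fires, 9/600 = 1.5% < 2%
        base = _spread_epochs(rng, 591, decade)
        t0 = _EPOCH_START + 100 * 86400 + 600 * 60
        burst = t0 + rng.choice(60, size=9, replace=False)
        return "journal_keeper_7", np.sort(np.concatenate([base, burst]))
    if archetype == "volume":
        return "prolific_poster", _spread_epochs(rng, 2**14, decade)
    if archetype == "periodic":
        base = _spread_epochs(rng, 970, decade)
        days = rng.choice(decade, size=30, replace=False)
        fixed = _EPOCH_START + days * 86400 + 300 * 60  # 05:00 UTC daily
        return "daily_diarist", np.sort(np.concatenate([base, fixed]))
    if archetype == "named":
        return "moderator_jane", _spread_epochs(rng, 300, decade)
    raise ValueError(f"unknown archetype {archetype!r}")


def _spread_epochs(rng: np.random.Generator, n: int, span_days: int) -> np.ndarray:
    """Epochs in distinct minutes with near-uniform minute-of-day coverage."""
    days = rng.integers(0, span_days, size=n)
    minute_of_day = rng.permutation(np.arange(n) % 1440)
    epochs = _EPOCH_START + days * 86400 + minute_of_day * 60 + rng.integers(0, 60, size=n)
    return np.sort(epochs)


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write posts.ndjson, meta.csv and truth.csv in the ingest dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    posts_path = out_dir / "posts.ndjson"
    with open(posts_path, "w") as fh:
        for u in cohort:
            for e in u.epochs:
                fh.write(json.dumps({"author": u.author_id, "created_utc": int(e)}) + "\n")
    meta = pd.DataFrame({
        "author_id": [u.author_id for u in cohort],
        "tz_name": [u.tz_name for u in cohort],
        "reported_bedtime": [format_clock(u.true_bedtime) for u in cohort],
    })
    meta_path = out_dir / "meta.csv"
    meta.to_csv(meta_path, index=False)
    truth = meta.rename(columns={"reported_bedtime": "true_bedtime"})
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    return {"posts": posts_path, "meta": meta_path, "truth": truth_path}
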