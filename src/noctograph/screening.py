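"""Bot filtration, eligibility thresholds, and bedtime-outlier exclusion.

Four heuristics flag suspected automated accounts: a burst of nine or more
posts within a single minute, a lifetime volume of 2**14 posts or more, at
least 2% of all posts recurring at the same exact minute-of-day, or a
username containing a bot-like substring. Survey respondents (the training
cohort) are exempt from the bot rules — prompt-appropriate answers are
themselves evidence of human activity — but both cohorts face the 250-post
activity floor, and reported bedtimes more than two circular standard
deviations from the cohort circular mean are excluded once, without
re-iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .circstats import circular_diff, circular_mean, circular_sd
from .estimate import DEFAULT_MIN_POSTS

__all__ = [
    "BotFlags",
    "EligibilityDecision",
    "bot_flags",
    "check_eligibility",
    "exclude_outliers",
    "BURST_THRESHOLD",
    "VOLUME_THRESHOLD",
    "PERIODICITY_THRESHOLD",
    "NAME_SUBSTRINGS",
]

BURST_THRESHOLD = 9
VOLUME_THRESHOLD = 2**14
PERIODICITY_THRESHOLD = 0.02
NAME_SUBSTRINGS = ("bot", "admin", "mod", "auto")


@dataclass(frozen=True)
class BotFlags:
    burst: bool
    volume: bool
    periodicity: bool
    name: bool

    @property
    def is_bot(self) -> bool:
        return self.burst or self.volume or self.periodicity or self.name


@dataclass(frozen=True)
class EligibilityDecision:
    reasons: tuple[str, ...]

    @property
    def eligible(self) -> bool:
        return not self.reasons


def bot_flags(
    epochs: np.ndarray,
    username: str,
    local_minutes: Optional[np.ndarray] = None,
) -> BotFlags:
    """Evaluate the four bot heuristics on one account's posting record.

    The burst rule counts posts per UTC epoch minute. The periodicity rule
    tallies minute-of-day recurrence: scheduled bots run on local or UTC
    clocks, so the UTC minute-of-day is always checked and the local one
    too when localized posts are supplied; either tally crossing 2% fires
    the flag.
    """
    epochs = np.asarray(epochs, dtype=np.int64)
    n = epochs.size
    burst = False
    periodicity = False
    if n:
        _, per_minute = np.unique(epochs // 60, return_counts=True)
        burst = bool(per_minute.max() >= BURST_THRESHOLD)
        tallies = [np.bincount((epochs // 60) % 1440, minlength=1440)]
        if local_minutes is not None:
            tallies.append(np.bincount(np.asarray(local_minutes, dtype=np.int64),
                                       minlength=1440))
        periodicity = any(t.max() / n >= PERIODICITY_THRESHOLD for t in tallies)
    volume = n >= VOLUME_THRESHOLD
    low = username.lower()
    name = any(sub in low for sub in NAME_SUBSTRINGS)
    return BotFlags(burst=burst, volume=volume, periodicity=periodicity, name=name)


def check_eligibility(
    n_posts: int,
    context: str,
    flags: Optional[BotFlags] = None,
    has_timezone: bool = True,
    bedtime_outlier: bool = False,
    min_posts: int = DEFAULT_MIN_POSTS,
) -> EligibilityDecision:
    """Combine the inclusion/exclusion rules into one decision.

    ``context`` is ``"training"`` (survey respondents: bot flags ignored,
    the cohort-wide 2-SD bedtime rule applies via *bedtime_outlier*) or
    ``"application"`` (bot flags apply, no reported bedtime to screen).
    """
    if context not in ("training", "application"):
        raise ValueError("context must be 'training' or 'application'")
    reasons = []
    if n_posts < min_posts:
        reasons.append("too_few_posts")
    if not has_timezone:
        reasons.append("no_timezone")
    if context == "application" and flags is not None and flags.is_bot:
        reasons.append("bot_flagged")
    if context == "training" and bedtime_outlier:
        reasons.append("bedtime_outlier")
    return EligibilityDecision(reasons=tuple(reasons))


def exclude_outliers(bedtimes: Sequence[int]) -> np.ndarray:
    """Single-pass 2-SD circular outlier mask over reported bedtimes.

    Computes the circular mean and circular SD of all bedtimes and keeps
    those within two SDs (circular distance) of the mean. Applied once:
    the mean and SD are not recomputed after exclusion.

    Returns a boolean inclusion mask aligned with the input.
    """
    bedtimes = np.asarray(bedtimes, dtype=float)
    if bedtimes.size < 2:
        raise ValueError("outlier exclusion needs at least 2 bedtimes")
    mu = circular_mean(bedtimes)
    sd_hours = circular_sd(bedtimes)
    dists = circular_diff(bedtimes, mu)
    return np.atleast_1d(dists) <= 2.0 * sd_hours
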