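"""Bedtime estimation by template matching.

The fitted unified model encodes no particular bedtime; relabeling its
bedtime point with each of the 96 candidate clock times yields a bank of
bedtime-specific template curves (pure rotations of one another). A user's
bedtime estimate is the label of the template whose curve best matches the
user's circadian fingerprint by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .circstats import circular_diff, circular_mean, UndefinedStatisticError
from .fingerprint import (
    N_BINS,
    CircadianFingerprint,
    compute_fingerprint,
)
from .ingest import GRID_MINUTES, LocalizedPosts, format_clock
from .model import UnifiedModel, eval_model

__all__ = ["TemplateSet", "BedtimeEstimate", "make_templates", "estimate_bedtime",
           "estimate_batch", "estimates_to_frame", "DEFAULT_MIN_POSTS"]

DEFAULT_MIN_POSTS = 250
_ZERO_INDEX = 48  # x = 0 position on the relative grid
_RHO_TIE_TOL = 1e-12


@dataclass
class TemplateSet:
    """96 bedtime-specific curves on clock-time bins.

    Row k is the unified model curve cyclically shifted so its bedtime
    point lands on clock bin k (bedtime label 15*k minutes); row k+1 is
    row k rotated by one bin. Rank vectors are precomputed since Spearman
    correlation only needs ranks (rotating a template rotates its ranks).
    """

    templates: np.ndarray = field(repr=False)
    _ranks: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.templates.shape != (N_BINS, N_BINS):
            raise ValueError(f"expected ({N_BINS}, {N_BINS}) template matrix")
        if self._ranks is None:
            base = rankdata(self.templates[0], method="average")
            self._ranks = np.stack(
                [np.roll(base, k) for k in range(N_BINS)]
            )

    def bedtime_label(self, k: int) -> int:
        """Bedtime in minutes after midnight encoded by template k."""
        return GRID_MINUTES * int(k)


@dataclass
class BedtimeEstimate:
    """One user's estimated habitual bedtime.

    ``status`` is ``"ok"`` for a real estimate, ``"too_few_posts"`` or
    ``"degenerate"`` when none could be made (then bedtime and rho are
    None).
    """

    author_id: str
    bedtime: Optional[int]  # minutes after midnight, 15-min grid
    rho: Optional[float]
    n_posts: int
    status: str = "ok"


def make_templates(m: UnifiedModel) -> TemplateSet:
    """Build the 96 bedtime-specific template curves from a fitted model."""
    vals = eval_model(m)
    # template 0: bedtime at clock bin 0 -> clock bin i holds the model
    # value at relative index (i + 48) mod 96
    base = np.roll(vals, -_ZERO_INDEX)
    templates = np.stack([np.roll(base, k) for k in range(N_BINS)])
    return TemplateSet(templates=templates)


def _break_ties(tied_bins: np.ndarray) -> int:
    """Deterministic argmax tie-break across equally correlated templates.

    Prefer the candidate closest (circularly) to the circular mean of all
    tied candidates; any remaining tie goes to the earliest clockwise from
    12:00 noon. Avoids a systematic pull toward midnight.
    """
    minutes = tied_bins * GRID_MINUTES
    try:
        center = circular_mean(minutes)
        dists = np.array([circular_diff(m, center) for m in minutes])
        tied_bins = tied_bins[np.isclose(dists, dists.min(), atol=1e-12)]
    except UndefinedStatisticError:
        pass  # antipodal tie set: fall through to the clockwise rule
    order = (tied_bins - N_BINS // 2) % N_BINS  # clockwise rank from noon
    return int(tied_bins[np.argmin(order)])


def estimate_bedtime(fp: CircadianFingerprint, ts: TemplateSet,
                     author_id: str = "") -> BedtimeEstimate:
    """Estimate a user's bedtime as the best-matching template's label.

    Matching is Spearman correlation (average ranks for ties, which the
    flat template section makes pervasive). Fingerprints with fewer than
    two distinct values have no defined correlation and come back flagged
    rather than estimated.
    """
    if np.unique(fp.values).size < 2 or np.count_nonzero(fp.values) < 2:
        return BedtimeEstimate(author_id=author_id, bedtime=None, rho=None,
                               n_posts=fp.n_posts, status="degenerate")
    fr = rankdata(fp.values, method="average")
    fr = fr - fr.mean()
    tr = ts._ranks - ts._ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((fr * fr).sum() * (tr * tr).sum(axis=1))
    rhos = tr @ fr / denom
    best = rhos.max()
    tied = np.flatnonzero(rhos >= best - _RHO_TIE_TOL)
    k = tied[0] if tied.size == 1 else _break_ties(tied)
    return BedtimeEstimate(
        author_id=author_id,
        bedtime=ts.bedtime_label(k),
        rho=float(rhos[k]),
        n_posts=fp.n_posts,
        status="ok",
    )


def estimate_batch(
    users: Iterable[LocalizedPosts],
    ts: TemplateSet,
    min_posts: int = DEFAULT_MIN_POSTS,
) -> list[BedtimeEstimate]:
    """Estimate bedtimes for a cohort, skipping users below the post floor.

    Skipped users appear in the output with status ``"too_few_posts"``
    so the caller can audit attrition; per-user results are identical to
    calling :func:`estimate_bedtime` one user at a time.
    """
    out = []
    for lp in users:
        if lp.n_posts < min_posts:
            out.append(BedtimeEstimate(author_id=lp.author_id, bedtime=None,
                                       rho=None, n_posts=lp.n_posts,
                                       status="too_few_posts"))
            continue
        out.append(estimate_bedtime(compute_fingerprint(lp), ts,
                                    author_id=lp.author_id))
    return out


def estimates_to_frame(estimates: Iterable[BedtimeEstimate]) -> pd.DataFrame:
    """Tabulate estimates: author_id, estimated_bedtime HH:MM, rho, n_posts, status."""
    rows = [
        {
            "author_id": e.author_id,
            "estimated_bedtime": format_clock(e.bedtime) if e.bedtime is not None else "",
            "rho": e.rho,
            "n_posts": e.n_posts,
            "status": e.status,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)


def bedtime_histogram(estimates: Iterable[BedtimeEstimate]) -> pd.Series:
    """Counts of estimated bedtimes by 15-minute bin (ok estimates only)."""
    mins = [e.bedtime for e in estimates if e.status == "ok"]
    labels = [format_clock(GRID_MINUTES * k) for k in range(N_BINS)]
    counts = np.bincount(np.asarray(mins, dtype=int) // GRID_MINUTES,
                         minlength=N_BINS) if mins else np.zeros(N_BINS, int)
    return pd.Series(counts, index=labels, name="n_users")
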