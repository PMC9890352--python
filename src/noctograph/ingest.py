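"""Reading post time stamps, time-zone localization, and bedtime normalization.

Post records arrive as UTC epoch seconds keyed by an opaque author id, either
as newline-delimited JSON in the PushShift dialect (``{"author": ...,
"created_utc": ...}``) or as CSV with an ``author_id,utc_epoch`` header.
Localization converts each stamp to the wall-clock minute-of-day in the
author's IANA time zone, DST-aware per post. Reported bedtimes are clock
times snapped onto the 15-minute grid the rest of the pipeline lives on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

__all__ = [
    "PostGroups",
    "LocalizedPosts",
    "read_posts",
    "read_metadata",
    "localize",
    "round_bedtime",
    "parse_clock",
    "format_clock",
]

MINUTES_PER_DAY = 1440
GRID_MINUTES = 15


class EmptyInputError(ValueError):
    """Raised when a file or collection holds no usable records."""


@dataclass
class PostGroups:
    """Raw UTC post stamps grouped by author.

    ``groups`` maps author_id to a sorted integer array of epoch seconds;
    ``n_skipped`` counts records dropped for missing or non-integer fields.
    Duplicate (author, epoch) pairs are retained: bursts are signal for
    bot filtration.
    """

    groups: dict[str, np.ndarray]
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, author_id: str) -> np.ndarray:
        return self.groups[author_id]

    def __iter__(self):
        return iter(self.groups.items())


@dataclass
class LocalizedPosts:
    """One author's posts as local minutes-of-day in their home zone."""

    author_id: str
    tz_name: str
    local_minutes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.local_minutes = np.asarray(self.local_minutes, dtype=np.int64)
        if self.local_minutes.size and (
            self.local_minutes.min() < 0 or self.local_minutes.max() >= MINUTES_PER_DAY
        ):
            raise ValueError("local minutes-of-day must lie in [0, 1439]")

    @property
    def n_posts(self) -> int:
        return int(self.local_minutes.size)


def _records_from_ndjson(path: Path):
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                yield str(obj["author"]), int(obj["created_utc"])
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                yield None


def _records_from_csv(path: Path):
    df = pd.read_csv(path, dtype={"author_id": str})
    if not {"author_id", "utc_epoch"} <= set(df.columns):
        raise ValueError(f"{path}: CSV must have columns author_id,utc_epoch")
    epochs = pd.to_numeric(df["utc_epoch"], errors="coerce")
    for author, epoch in zip(df["author_id"], epochs):
        if pd.isna(author) or pd.isna(epoch) or float(epoch) != int(epoch):
            yield None
        else:
            yield str(author), int(epoch)


def read_posts(path: Union[str, Path], format: str = "ndjson") -> PostGroups:
    """Read post records from *path* and group them by author.

    Parameters
    ----------
    path
        File of post records.
    format
        ``"ndjson"`` (PushShift dialect, keys ``author``/``created_utc``)
        or ``"csv"`` (header ``author_id,utc_epoch``).

    Returns
    -------
    PostGroups
        Epoch arrays per author plus a tally of skipped malformed records.

    Raises
    ------
    EmptyInputError
        If no valid record survives parsing.
    """
    path = Path(path)
    if format == "ndjson":
        records = _records_from_ndjson(path)
    elif format == "csv":
        records = _records_from_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'ndjson' or 'csv'")

    buckets: dict[str, list[int]] = {}
    skipped = 0
    for rec in records:
        if rec is None:
            skipped += 1
            continue
        author, epoch = rec
        if not author or epoch < 0:
            skipped += 1
            continue
        buckets.setdefault(author, []).append(epoch)
    if not buckets:
        raise EmptyInputError(f"{path}: no valid post records")
    groups = {a: np.sort(np.asarray(v, dtype=np.int64)) for a, v in buckets.items()}
    return PostGroups(groups=groups, n_skipped=skipped)


def read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read the per-user metadata CSV: ``author_id,tz_name[,reported_bedtime]``.

    ``reported_bedtime`` values are "HH:MM" local clock strings; they are
    parsed to minutes after midnight in a ``reported_minutes`` column
    (NaN where absent). Inputs are assumed already resolved to a clock time.
    """
    df = pd.read_csv(path, dtype=str)
    if not {"author_id", "tz_name"} <= set(df.columns):
        raise ValueError(f"{path}: metadata CSV must have columns author_id,tz_name")
    if "reported_bedtime" in df.columns:
        df["reported_minutes"] = df["reported_bedtime"].map(
            lambda s: parse_clock(s) if isinstance(s, str) and s.strip() else np.nan
        )
    else:
        df["reported_minutes"] = np.nan
    return df


def localize(epochs: np.ndarray, tz_name: str, author_id: str = "") -> LocalizedPosts:
    """Convert UTC epoch seconds to local minutes-of-day in an IANA zone.

    Each stamp is converted at its own instant, so zones that observe DST
    get the correct offset per post.
    """
    try:
        ZoneInfo(tz_name)
    except Exception as exc:  # KeyError or ZoneInfoNotFoundError
        raise ValueError(f"unknown IANA time zone {tz_name!r}") from exc
    epochs = np.asarray(epochs, dtype=np.int64)
    idx = pd.to_datetime(epochs, unit="s", utc=True).tz_convert(tz_name)
    minutes = (idx.hour * 60 + idx.minute).to_numpy(dtype=np.int64)
    return LocalizedPosts(author_id=author_id, tz_name=tz_name, local_minutes=minutes)


def localize_groups(posts: PostGroups, meta: pd.DataFrame) -> dict[str, LocalizedPosts]:
    """Localize every author in *posts* that has a zone in *meta*.

    Authors without metadata are omitted (screening reports them as
    ``no_timezone``).
    """
    zones = dict(zip(meta["author_id"], meta["tz_name"]))
    out = {}
    for author, epochs in posts:
        tz = zones.get(author)
        if tz is None or (isinstance(tz, float) and np.isnan(tz)):
            continue
        out[author] = localize(epochs, tz, author_id=author)
    return out


def round_bedtime(minutes: int) -> int:
    """Round a clock time in minutes after midnight to the 15-minute grid.

    Rounding is circular (23:53 wraps to 00:00). Ties at the 7/8-minute
    midpoint follow the nearest-integer-minute convention: an offset of 7
    minutes past a grid point rounds down, 8 rounds up.
    """
    m = int(minutes)
    if not 0 <= m < MINUTES_PER_DAY:
        raise ValueError("clock time must lie in [0, 1440) minutes")
    return ((m + 7) // GRID_MINUTES * GRID_MINUTES) % MINUTES_PER_DAY


def parse_clock(text: str) -> int:
    """Parse "HH:MM" to minutes after midnight."""
    hh, mm = text.strip().split(":")
    h, m = int(hh), int(mm)
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"invalid clock time {text!r}")
    return h * 60 + m


def format_clock(minutes: Union[int, float]) -> str:
    """Render minutes after midnight as "HH:MM"."""
    m = int(round(minutes)) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"
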