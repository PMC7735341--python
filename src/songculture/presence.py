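"""Daily song-presence summaries from duty-cycled acoustic recordings.

Every recorded file is graded 0 (no song), 1 (song present but low
signal-to-noise ratio) or 2 (high-SNR song suitable for transcription).
Presence is any file with category >= 1; the daily metric is the percentage
of files per calendar day containing song, per recording site.  Singing is
deemed to have ceased on the last day with presence at any site only when it
is followed by at least five consecutive fully recorded days with no song
anywhere; otherwise the record is right-censored.

A "full day of recordings" is a day whose file count matches the
duty-cycle-expected count (96 files for a 900 s cycle) within a configurable
tolerance.  Percentages are per recorded file, never per second.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "FileRecord",
    "CessationResult",
    "daily_presence",
    "cessation_date",
    "FILES_PER_DAY",
]

#: files per day under the 900 s duty cycle (86400 / 900)
FILES_PER_DAY = 96

VALID_CATEGORIES = {0, 1, 2}


@dataclass(frozen=True)
class FileRecord:
    """One recorded file: site, start timestamp and song category (0/1/2)."""

    site: str
    start_time: dt.datetime
    category: int

    def __post_init__(self):
        if not self.site:
            raise ValueError("site label must be non-empty")
        if self.category not in VALID_CATEGORIES:
            raise ValueError(
                f"invalid category {self.category!r} for file at "
                f"{self.site} {self.start_time} (must be 0, 1 or 2)"
            )


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        for col in ("site", "start_time", "category"):
            if col not in df.columns:
                raise ValueError(f"records table is missing column {col!r}")
        df["start_time"] = pd.to_datetime(df["start_time"])
        cat = pd.to_numeric(df["category"], errors="raise").astype(int)
        bad = ~cat.isin(list(VALID_CATEGORIES))
        if bad.any():
            i = int(bad.idxmax())
            raise ValueError(
                f"invalid category {df['category'].iloc[i]!r} in record {i} "
                f"({df['site'].iloc[i]} {df['start_time'].iloc[i]})"
            )
        df["category"] = cat
        return df[["site", "start_time", "category"]]
    rows = [(r.site, pd.Timestamp(r.start_time), r.category) for r in records]
    return pd.DataFrame(rows, columns=["site", "start_time", "category"])


def daily_presence(records: Iterable[FileRecord] | pd.DataFrame) -> pd.DataFrame:
    """Percentage of files per site-day containing song (category >= 1).

    Returns a frame with columns site, date, percent, n_files, ordered by
    site then date.  Days with no recorded files do not appear (they are
    absent, not zero).  The result is invariant to input record order.
    """
    df = _records_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["site", "date", "percent", "n_files"])
    df["date"] = df["start_time"].dt.date
    df["has_song"] = df["category"] >= 1
    out = (
        df.groupby(["site", "date"], sort=True)
        .agg(percent=("has_song", "mean"), n_files=("has_song", "size"))
        .reset_index()
    )
    out["percent"] = 100.0 * out["percent"]
    return out


@dataclass
class CessationResult:
    """Outcome of the five-quiet-day cessation rule."""

    last_presence_date: dt.date | None
    ceased: bool                 # rule satisfied (>= 5 full quiet days follow)
    censored: bool               # record ended before the rule could be checked
    gap_dates: list = field(default_factory=list)  # not-fully-recorded days seen


def cessation_date(
    daily: pd.DataFrame,
    expected_files_per_day: int = FILES_PER_DAY,
    tolerance: int = 0,
    quiet_days_required: int = 5,
) -> CessationResult:
    """Apply the cessation rule to a :func:`daily_presence` table.

    Vocal presence is deemed to have ceased on the last date with presence at
    any site when the following ``quiet_days_required`` consecutive days are
    fully recorded (every site's file count within ``tolerance`` of
    ``expected_files_per_day``) and have zero presence at every site.  If the
    record ends sooner the result is right-censored.  Days that are not fully
    recorded are reported as gaps.
    """
    if daily.empty:
        return CessationResult(None, False, False)
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    sites = sorted(daily["site"].unique())
    start, end = daily["date"].min(), daily["date"].max()
    all_days = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]

    by_day = daily.groupby("date")
    presence: dict[dt.date, bool] = {}
    full: dict[dt.date, bool] = {}
    gaps = []
    for day in all_days:
        if day not in by_day.groups:
            presence[day] = False
            full[day] = False
            gaps.append(day)
            continue
        sub = by_day.get_group(day)
        presence[day] = bool((sub["percent"] > 0).any())
        covered = set(sub["site"]) == set(sites)
        counts_ok = (
            (sub["n_files"] - expected_files_per_day).abs() <= tolerance
        ).all()
        full[day] = covered and bool(counts_ok)
        if not full[day]:
            gaps.append(day)

    presence_days = [d for d in all_days if presence[d]]
    if not presence_days:
        return CessationResult(None, False, False, gaps)
    last = presence_days[-1]
    following = [last + dt.timedelta(days=i + 1) for i in range(quiet_days_required)]
    if following[-1] > end:
        return CessationResult(last, False, True, gaps)
    ok = all(full.get(d, False) and not presence.get(d, False) for d in following)
    # quiet days exist but some are incomplete recordings: still censored,
    # the rule cannot be confirmed
    return CessationResult(last, ok, not ok, gaps)
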