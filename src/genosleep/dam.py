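"""Activity-monitor parsing and sleep/death scoring.

Monitor files are tab-delimited with 42 columns per row, one row per 30-s
reading:

    reading_index  date("%d %b %y")  time("%H:%M:%S")  status
    five unused zero columns  light_flag  count_ch1 ... count_ch32

``status == 1`` marks a valid reading; any other value flags the row as a
monitor error.  Flagged rows keep their place on the time grid but their
counts are zeroed and the row is reported in the record's ``n_invalid_rows``
and ``valid`` mask.

Sleep is scored as maximal runs of consecutive zero-count bins lasting at
least ``min_sleep_min`` (default 5 min, i.e. 10 bins) — the field-standard
inactivity definition.  Analysis windows start at the first lights-on (ZT0).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "BIN_SECONDS",
    "ActivityRecord",
    "SleepSummary",
    "DamFormatError",
    "read_dam_file",
    "write_dam_file",
    "score_sleep",
    "waking_activity",
    "rhythmicity_index",
    "detect_death",
    "starvation_survival",
    "apply_exclusions",
]

BIN_SECONDS = 30
_BINS_PER_DAY = 24 * 3600 // BIN_SECONDS
_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"
_N_CHANNELS = 32
_N_COLUMNS = 4 + 5 + 1 + _N_CHANNELS


class DamFormatError(ValueError):
    """Raised for malformed monitor files; messages name the offending row."""


@dataclass
class ActivityRecord:
    """One fly's 30-s binned beam-break counts on a strictly regular grid."""

    fly_id: str
    channel: int
    start: _dt.datetime
    counts: np.ndarray
    lights_on_hour: float = 8.0
    light_hours: float = 12.0
    status: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-d")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not 1 <= self.channel <= _N_CHANNELS:
            raise ValueError(f"channel must be 1..{_N_CHANNELS}")
        if not 0.0 < self.light_hours < 24.0:
            raise ValueError("light_hours must lie in (0, 24)")
        if self.valid is None:
            self.valid = np.ones(len(self.counts), dtype=bool)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def n_invalid_rows(self) -> int:
        return int((~self.valid).sum())

    @property
    def duration_hours(self) -> float:
        return len(self.counts) * BIN_SECONDS / 3600.0

    def zeitgeber_hours(self) -> np.ndarray:
        """Hours since the most recent lights-on, per bin."""
        clock0 = self.start.hour + self.start.minute / 60.0 + self.start.second / 3600.0
        offsets = np.arange(len(self.counts)) * (BIN_SECONDS / 3600.0)
        return np.mod(clock0 + offsets - self.lights_on_hour, 24.0)

    def is_light(self) -> np.ndarray:
        return self.zeitgeber_hours() < self.light_hours


@dataclass
class SleepSummary:
    fly_id: str
    window_days: int
    total_sleep_min: float
    day_sleep_min: float
    night_sleep_min: float
    bout_count_day: float
    bout_count_night: float
    mean_bout_len_min: float
    waking_activity_per_min: float
    waking_defined: bool
    rhythmicity_index: float = math.nan
    included: bool = True


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_dam_file(path, lights_on_hour: float = 8.0, light_hours: float = 12.0) -> list[ActivityRecord]:
    """Parse one monitor file into 32 per-channel records.

    Raises :class:`DamFormatError` (naming the 1-based row) on a wrong column
    count, an unparseable date/time, or an irregular/non-monotone time grid.
    """
    path = Path(path)
    times: list[_dt.datetime] = []
    statuses: list[int] = []
    counts_rows: list[list[int]] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _N_COLUMNS:
                raise DamFormatError(
                    f"{path.name} row {row_no}: expected {_N_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            try:
                ts = _dt.datetime.strptime(
                    f"{fields[1]} {fields[2]}", f"{_DATE_FMT} {_TIME_FMT}"
                )
            except ValueError as exc:
                raise DamFormatError(f"{path.name} row {row_no}: bad date/time") from exc
            try:
                status = int(fields[3])
                row_counts = [int(v) for v in fields[-_N_CHANNELS:]]
            except ValueError as exc:
                raise DamFormatError(f"{path.name} row {row_no}: non-integer field") from exc
            times.append(ts)
            statuses.append(status)
            counts_rows.append(row_counts)

    if not times:
        raise DamFormatError(f"{path.name}: empty file")
    for i in range(1, len(times)):
        delta = (times[i] - times[i - 1]).total_seconds()
        if delta != BIN_SECONDS:
            raise DamFormatError(
                f"{path.name} row {i + 1}: irregular timestamp step of {delta:.0f}s "
                f"(expected {BIN_SECONDS}s)"
            )

    status_arr = np.asarray(statuses)
    valid = status_arr == 1
    matrix = np.asarray(counts_rows)
    matrix[~valid, :] = 0  # flagged monitor rows carry no usable counts

    records = []
    for ch in range(_N_CHANNELS):
        records.append(
            ActivityRecord(
                fly_id=f"{path.stem}_ch{ch + 1:02d}",
                channel=ch + 1,
                start=times[0],
                counts=matrix[:, ch],
                lights_on_hour=lights_on_hour,
                light_hours=light_hours,
                status=status_arr.copy(),
                valid=valid.copy(),
            )
        )
    return records


def write_dam_file(records: Sequence[ActivityRecord], path) -> None:
    """Write up to 32 records sharing one time grid as a monitor file."""
    if not records:
        raise ValueError("no records to write")
    if len(records) > _N_CHANNELS:
        raise ValueError(f"at most {_N_CHANNELS} records per monitor file")
    n = len(records[0])
    start = records[0].start
    for rec in records[1:]:
        if len(rec) != n or rec.start != start:
            raise ValueError("all records in a monitor file must share one time grid")
    by_channel = {}
    for rec in records:
        if rec.channel in by_channel:
            raise ValueError(f"duplicate channel {rec.channel}")
        by_channel[rec.channel] = rec

    lights_on = records[0].lights_on_hour
    light_hours = records[0].light_hours
    with open(path, "w") as fh:
        for i in range(n):
            ts = start + _dt.timedelta(seconds=i * BIN_SECONDS)
            zt = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0 - lights_on) % 24.0
            light_flag = 1 if zt < light_hours else 0
            row = [str(i + 1), ts.strftime(_DATE_FMT), ts.strftime(_TIME_FMT), "1"]
            row += ["0"] * 5 + [str(light_flag)]
            for ch in range(1, _N_CHANNELS + 1):
                rec = by_channel.get(ch)
                row.append(str(int(rec.counts[i])) if rec is not None else "0")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero bins as (start_index, length)."""
    zero = counts == 0
    if not zero.any():
        return []
    padded = np.concatenate(([False], zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _first_zt0_index(record: ActivityRecord) -> int:
    zt = record.zeitgeber_hours()
    tol = BIN_SECONDS / 3600.0 / 2.0
    hits = np.flatnonzero(zt < tol)
    if len(hits) == 0:
        raise ValueError(f"{record.fly_id}: record never reaches lights-on (ZT0)")
    return int(hits[0])


def score_sleep(
    record: ActivityRecord,
    window_days: int | None = None,
    min_sleep_min: float = 5.0,
    boundary: str = "prorate",
) -> SleepSummary:
    """Score sleep architecture over whole 24-h windows starting at ZT0.

    Sleep bouts are maximal zero-count runs of at least ``min_sleep_min``.
    Day/night minutes are split at lights-off; with ``boundary='prorate'`` a
    bout spanning the boundary contributes its bins to each phase (bins are
    atomic, so this is an exact pro-rata split), with ``boundary='onset'``
    the whole bout is assigned to the phase in which it starts.  Reported
    minutes are per 24 h, averaged over the window.
    """
    if boundary not in ("prorate", "onset"):
        raise ValueError("boundary must be 'prorate' or 'onset'")
    start_idx = _first_zt0_index(record)
    avail_days = (len(record) - start_idx) // _BINS_PER_DAY
    if window_days is None:
        window_days = avail_days
    if window_days < 1 or avail_days < window_days:
        raise ValueError(
            f"{record.fly_id}: record holds {avail_days} whole day(s) after first "
            f"lights-on but {window_days} requested"
        )
    n_bins = window_days * _BINS_PER_DAY
    counts = record.counts[start_idx : start_idx + n_bins]
    is_day = record.is_light()[start_idx : start_idx + n_bins]

    min_bins = int(round(min_sleep_min * 60.0 / BIN_SECONDS))
    bouts = [(s, ln) for s, ln in _zero_runs(counts) if ln >= min_bins]
    asleep = np.zeros(n_bins, dtype=bool)
    for s, ln in bouts:
        asleep[s : s + ln] = True

    to_min = BIN_SECONDS / 60.0
    if boundary == "prorate":
        day_bins = int((asleep & is_day).sum())
        night_bins = int((asleep & ~is_day).sum())
    else:
        day_bins = sum(ln for s, ln in bouts if is_day[s])
        night_bins = sum(ln for s, ln in bouts if not is_day[s])

    day_sleep = day_bins * to_min / window_days
    night_sleep = night_bins * to_min / window_days
    bout_count_day = sum(1 for s, _ in bouts if is_day[s]) / window_days
    bout_count_night = sum(1 for s, _ in bouts if not is_day[s]) / window_days
    mean_bout = float(np.mean([ln for _, ln in bouts]) * to_min) if bouts else math.nan

    waking_min = (n_bins - int(asleep.sum())) * to_min
    if waking_min > 0:
        waking = float(counts.sum()) / waking_min
        defined = True
    else:
        waking = math.nan
        defined = False

    return SleepSummary(
        fly_id=record.fly_id,
        window_days=window_days,
        total_sleep_min=day_sleep + night_sleep,
        day_sleep_min=day_sleep,
        night_sleep_min=night_sleep,
        bout_count_day=bout_count_day,
        bout_count_night=bout_count_night,
        mean_bout_len_min=mean_bout,
        waking_activity_per_min=waking,
        waking_defined=defined,
    )


def waking_activity(record: ActivityRecord, summary: SleepSummary) -> float:
    """Counts per waking minute; NaN (flagged in the summary) if never awake."""
    if not summary.waking_defined:
        return math.nan
    return summary.waking_activity_per_min


def rhythmicity_index(
    record: ActivityRecord,
    coarse_minutes: int = 30,
    period_hours: float = 24.0,
    search_hours: float = 4.0,
    alpha: float = 0.05,
) -> tuple[float, bool, str]:
    """Autocorrelation-based circadian rhythmicity score.

    The 30-s counts are pooled into ``coarse_minutes`` bins; the score is the
    peak autocorrelation at lags within ``period_hours +/- search_hours``,
    divided by a Bonferroni-adjusted large-lag significance envelope
    (z_{1-alpha/2K}/sqrt(N) for K candidate lags).  A score of 1 therefore
    marks the alpha-level significance boundary; flies scoring below the
    conventional threshold of 1 are excluded.  This statistic is an
    interpretation of the usual actogram "rhythmic index", not a reproduction
    of any particular program's score; its scaling is configurable here.

    Returns (score, included, reason); constant records are excluded with
    reason 'dead/flat' and a score of 0.
    """
    if record.duration_hours < 3 * 24:
        raise ValueError(f"{record.fly_id}: need >= 3 days of data for rhythmicity")
    per = int(coarse_minutes * 60 // BIN_SECONDS)
    n_coarse = len(record.counts) // per
    x = record.counts[: n_coarse * per].reshape(n_coarse, per).sum(axis=1).astype(float)
    x = x - x.mean()
    denom = float((x**2).sum())
    if denom == 0.0:
        return 0.0, False, "dead/flat"

    dt_h = coarse_minutes / 60.0
    lag_lo = max(1, int(round((period_hours - search_hours) / dt_h)))
    lag_hi = min(n_coarse - 2, int(round((period_hours + search_hours) / dt_h)))
    if lag_hi < lag_lo:
        raise ValueError("record too short for the requested lag window")
    acf = np.array([float((x[:-k] * x[k:]).sum()) / denom for k in range(lag_lo, lag_hi + 1)])
    n_lags = lag_hi - lag_lo + 1
    envelope = _stats.norm.ppf(1.0 - alpha / 2.0 / n_lags) / math.sqrt(n_coarse)
    score = float(acf.max() / envelope)
    return score, score >= 1.0, "" if score >= 1.0 else "arrhythmic"


def detect_death(record: ActivityRecord, flat_tail_hours: float = 12.0) -> float | None:
    """Death time from a terminal flat tail, per the last-waking-bout rule.

    If the record ends with at least ``flat_tail_hours`` of zero counts, the
    death time (hours from record start) is the end of the last nonzero bin;
    an all-zero record yields 0.0.  Otherwise returns None.
    """
    nonzero = np.flatnonzero(record.counts)
    n = len(record.counts)
    last = int(nonzero[-1]) if len(nonzero) else -1
    tail_hours = (n - 1 - last) * BIN_SECONDS / 3600.0
    if tail_hours >= flat_tail_hours:
        return (last + 1) * BIN_SECONDS / 3600.0
    return None


def starvation_survival(
    records: Iterable[ActivityRecord],
    groups: dict[str, str] | str | None = None,
    flat_tail_hours: float = 12.0,
) -> pd.DataFrame:
    """Per-fly survival table: detected death (event=1) or censoring at end.

    ``groups`` maps fly_id -> group label, or is one label for all flies.
    Times are hours from record start.
    """
    rows = []
    for rec in records:
        if isinstance(groups, dict):
            group = groups.get(rec.fly_id, "all")
        else:
            group = groups if groups is not None else "all"
        death = detect_death(rec, flat_tail_hours=flat_tail_hours)
        if death is None:
            rows.append(
                {"subject_id": rec.fly_id, "time": rec.duration_hours, "event": 0, "group": group}
            )
        else:
            rows.append({"subject_id": rec.fly_id, "time": death, "event": 1, "group": group})
    return pd.DataFrame(rows)


def apply_exclusions(
    records: Sequence[ActivityRecord],
    dead_tail_hours: float = 24.0,
    ri_threshold: float = 1.0,
) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Fixed-order exclusion pipeline: dead flies first, then arrhythmic.

    Returns the surviving records and a log with one row per excluded fly
    (fly_id, stage, reason, value).
    """
    log_rows = []
    alive: list[ActivityRecord] = []
    for rec in records:
        death = detect_death(rec, flat_tail_hours=dead_tail_hours)
        if death is not None:
            log_rows.append(
                {"fly_id": rec.fly_id, "stage": "dead", "reason": "dead/flat", "value": death}
            )
        else:
            alive.append(rec)

    kept: list[ActivityRecord] = []
    for rec in alive:
        score, included, reason = rhythmicity_index(rec)
        if included and score >= ri_threshold:
            kept.append(rec)
        else:
            log_rows.append(
                {
                    "fly_id": rec.fly_id,
                    "stage": "arrhythmic",
                    "reason": reason or "arrhythmic",
                    "value": score,
                }
            )
    log = pd.DataFrame(log_rows, columns=["fly_id", "stage", "reason", "value"])
    return kept, log
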