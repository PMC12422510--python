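"""Epoch-level accelerometer processing.

Reads ActiGraph-style count series, reintegrates them to 60-second
epochs, flags the overnight window (23:00-06:00) and non-wear bouts
(>=60 min of consecutive zero counts, tolerating brief non-zero
interruptions), and accounts daily wear time. All downstream intensity
classification and modelling operates on the flagged 60-s series
produced here.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InvalidParameterError,
    InvalidTargetError,
    UnsupportedEpochError,
)

VALID_EPOCH_LENGTHS = (1, 5, 10, 15, 30, 60)

#: Analysis window: epochs starting in [23:00, 06:00) are excluded as
#: presumed sleep, leaving at most 17 h = 1020 min/day of observable wear.
OVERNIGHT_START_HOUR = 23
OVERNIGHT_END_HOUR = 6
MAX_DAILY_WEAR_MIN = (24 - (OVERNIGHT_START_HOUR - OVERNIGHT_END_HOUR)) * 60


@dataclass
class EpochSeries:
    """One participant-wave's timestamped count sequence.

    Epoch ``i`` starts at ``start_time + i * epoch_length`` seconds;
    the series is gap-free by construction (gaps must be resolved at
    read time). ``wear_flag`` is True where the device is considered
    worn; ``excluded_flag`` is True inside the overnight window.
    """

    participant_id: str
    wave_index: int
    start_time: pd.Timestamp
    epoch_length: int
    counts: np.ndarray
    wear_flag: np.ndarray = field(default=None)  # type: ignore[assignment]
    excluded_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.wear_flag is None:
            self.wear_flag = np.ones(len(self.counts), dtype=bool)
        if self.excluded_flag is None:
            self.excluded_flag = np.zeros(len(self.counts), dtype=bool)
        self.wear_flag = np.asarray(self.wear_flag, dtype=bool)
        self.excluded_flag = np.asarray(self.excluded_flag, dtype=bool)
        self.start_time = pd.Timestamp(self.start_time)
        if self.epoch_length not in VALID_EPOCH_LENGTHS:
            raise UnsupportedEpochError(
                f"epoch length {self.epoch_length}s must divide 60s "
                f"(one of {VALID_EPOCH_LENGTHS})"
            )
        if not (len(self.counts) == len(self.wear_flag) == len(self.excluded_flag)):
            raise ValueError("counts and flag arrays must have equal length")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.wave_index < 1:
            raise ValueError("wave_index must be a positive integer")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_length, unit="s"
        )

    def copy(self) -> "EpochSeries":
        return replace(
            self,
            counts=self.counts.copy(),
            wear_flag=self.wear_flag.copy(),
            excluded_flag=self.excluded_flag.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flagged epoch table: timestamp, counts, wear, excluded."""
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "counts": self.counts,
                "wear": self.wear_flag,
                "excluded": self.excluded_flag,
            }
        )


@dataclass(frozen=True)
class NonWearBout:
    """Half-open epoch-index span of one detected non-wear bout."""

    start_index: int
    end_index: int
    interruption_minutes: int

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")

    @property
    def span(self) -> int:
        return self.end_index - self.start_index


# ---------------------------------------------------------------------------
# Reading


_ACTIGRAPH_HEADER_RE = re.compile(r"^-+\s*$|ActiGraph|Actigraph", re.IGNORECASE)


def _parse_actigraph_header(lines: Sequence[str]) -> tuple[pd.Timestamp, int, int]:
    """Extract start time and epoch period from an ActiGraph header block.

    Returns (start_time, epoch_length_seconds, n_header_lines).
    """
    start_date = start_time = epoch = None
    n_header = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if re.match(r"^-+\s*$", stripped) and i > 0:
            n_header = i + 1
            break
        m = re.search(r"Start Time[:\s]+(\S+)", stripped, re.IGNORECASE)
        if m:
            start_time = m.group(1)
        m = re.search(r"Start Date[:\s]+(\S+)", stripped, re.IGNORECASE)
        if m:
            start_date = m.group(1)
        m = re.search(
            r"Epoch Period \(hh:mm:ss\)[:\s]+(\d+):(\d+):(\d+)", stripped, re.IGNORECASE
        )
        if m:
            h, mi, s = (int(g) for g in m.groups())
            epoch = h * 3600 + mi * 60 + s
    if start_date is None or start_time is None or epoch is None:
        raise FormatError("ActiGraph header missing start date/time or epoch period")
    ts = pd.to_datetime(f"{start_date} {start_time}", dayfirst=False)
    return ts, epoch, n_header


def read_epoch_csv(
    path,
    *,
    epoch_length: int | None = None,
    timestamp_col: str = "timestamp",
    counts_col: str = "counts",
    participant_id: str = "unknown",
    wave_index: int = 1,
    on_gap: Literal["error", "zero_fill"] = "error",
) -> EpochSeries:
    """Read a raw epoch CSV into an :class:`EpochSeries`.

    Two dialects are accepted: a plain header-bearing CSV with a
    timestamp column and a counts column, or an ActiGraph export whose
    header block carries the start date/time and epoch period followed
    by one count per line. Timestamp gaps are a hard error by default
    (``on_gap='zero_fill'`` inserts zero-count epochs instead; note that
    zero-filling can manufacture apparent non-wear).
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    if lines and _ACTIGRAPH_HEADER_RE.search(lines[0]):
        start, header_epoch, n_header = _parse_actigraph_header(lines)
        eff_epoch = epoch_length or header_epoch
        body = "\n".join(lines[n_header:])
        counts = pd.read_csv(io.StringIO(body), header=None).iloc[:, 0].to_numpy()
        if eff_epoch not in VALID_EPOCH_LENGTHS:
            raise UnsupportedEpochError(f"epoch length {eff_epoch}s does not divide 60s")
        return EpochSeries(participant_id, wave_index, start, eff_epoch, counts)

    df = pd.read_csv(io.StringIO(text))
    if counts_col not in df.columns:
        raise FormatError(f"missing counts column {counts_col!r}")
    if timestamp_col not in df.columns:
        raise FormatError(f"missing timestamp column {timestamp_col!r}")
    try:
        ts = pd.to_datetime(df[timestamp_col])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamps: {exc}") from None
    if len(ts) == 0:
        raise FormatError("empty epoch file")
    diffs = ts.diff().dropna().dt.total_seconds()
    if (diffs <= 0).any():
        raise FormatError("non-monotone timestamps")
    if len(ts) > 1:
        inferred = int(diffs.min())
    else:
        inferred = epoch_length or 60
    eff_epoch = epoch_length or inferred
    if eff_epoch not in VALID_EPOCH_LENGTHS:
        raise UnsupportedEpochError(f"epoch length {eff_epoch}s does not divide 60s")

    counts = pd.to_numeric(df[counts_col], errors="coerce")
    if counts.isna().any():
        bad = df.index[counts.isna()].tolist()
        raise FormatError(f"malformed count values at rows {bad}")

    expected = ts.iloc[0] + pd.to_timedelta(np.arange(len(ts)) * eff_epoch, unit="s")
    if not ts.reset_index(drop=True).equals(pd.Series(expected)):
        if on_gap == "error":
            raise FormatError(
                "timestamp gaps detected; pass on_gap='zero_fill' to insert "
                "zero-count epochs"
            )
        full_index = pd.date_range(ts.iloc[0], ts.iloc[-1], freq=f"{eff_epoch}s")
        filled = (
            pd.Series(counts.to_numpy(), index=ts.to_numpy())
            .reindex(full_index, fill_value=0)
            .to_numpy()
        )
        return EpochSeries(participant_id, wave_index, ts.iloc[0], eff_epoch, filled)

    return EpochSeries(
        participant_id, wave_index, ts.iloc[0], eff_epoch, counts.to_numpy()
    )


# ---------------------------------------------------------------------------
# Processing


def reintegrate(series: EpochSeries, target: int = 60) -> EpochSeries:
    """Sum counts into non-overlapping ``target``-second windows.

    Windows are anchored at the series start; a trailing partial window
    is dropped. Flags are reset (reintegration precedes flagging).
    """
    if target % series.epoch_length != 0:
        raise InvalidTargetError(
            f"target {target}s is not a multiple of epoch length "
            f"{series.epoch_length}s"
        )
    k = target // series.epoch_length
    n_windows = len(series) // k
    summed = series.counts[: n_windows * k].reshape(n_windows, k).sum(axis=1)
    return EpochSeries(
        series.participant_id,
        series.wave_index,
        series.start_time,
        target,
        summed,
    )


def flag_overnight(series: EpochSeries) -> EpochSeries:
    """Mark epochs starting in [23:00, 06:00) as overnight-excluded.

    The boundary is half-open on epoch start times: an epoch starting at
    exactly 06:00 is retained, one starting at 23:00 is excluded.
    Returns a flagged copy.
    """
    if series.epoch_length != 60:
        raise UnsupportedEpochError("overnight flagging requires 60-s epochs")
    out = series.copy()
    hours = out.timestamps.hour
    out.excluded_flag |= (hours >= OVERNIGHT_START_HOUR) | (hours < OVERNIGHT_END_HOUR)
    return out


def _zero_runs(z: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) spans of maximal runs of True in ``z``."""
    if len(z) == 0:
        return []
    padded = np.concatenate(([False], z, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_nonwear(
    series: EpochSeries,
    min_bout: int = 60,
    tolerance: int = 2,
    interruption_mode: Literal["per_interruption", "per_bout"] = "per_interruption",
) -> list[NonWearBout]:
    """Detect non-wear bouts and clear ``wear_flag`` inside them.

    A bout is a maximal window that begins and ends on zero-count
    epochs, spans at least ``min_bout`` minutes, and whose interior
    non-zero interruptions are within tolerance. Under the default
    ``per_interruption`` semantics each interruption may last at most
    ``tolerance`` consecutive non-zero epochs (any count magnitude, any
    number of interruptions); under ``per_bout`` the total interrupted
    minutes per bout may not exceed ``tolerance``. Detection runs over
    all epochs including the overnight window — physical non-wear does
    not respect clock cut-offs — and the overnight exclusion is applied
    independently.

    The series' ``wear_flag`` is updated in place (interruption epochs
    included); the detected bouts are returned. Re-running on an
    already-flagged series is a no-op on the flags.
    """
    if series.epoch_length != 60:
        raise UnsupportedEpochError("non-wear detection requires 60-s epochs")
    if min_bout < tolerance + 2:
        raise InvalidParameterError(
            f"min_bout ({min_bout}) must be at least tolerance + 2 "
            f"({tolerance + 2}): a bout must contain zeros on both sides "
            "of any interruption"
        )
    z = series.counts == 0
    bouts: list[NonWearBout]
    if interruption_mode == "per_interruption":
        bouts = _detect_per_interruption(z, min_bout, tolerance)
    elif interruption_mode == "per_bout":
        bouts = _detect_per_bout(z, min_bout, tolerance)
    else:
        raise InvalidParameterError(f"unknown interruption_mode {interruption_mode!r}")
    for b in bouts:
        series.wear_flag[b.start_index : b.end_index] = False
    return bouts


def _detect_per_interruption(
    z: np.ndarray, min_bout: int, tolerance: int
) -> list[NonWearBout]:
    # Non-zero runs longer than `tolerance` break candidate windows; within
    # each unbroken segment the maximal candidate runs from its first to its
    # last zero epoch.
    nz_runs = _zero_runs(~z)
    breakers = [r for r in nz_runs if r[1] - r[0] > tolerance]
    bouts = []
    for seg_start, seg_end in zip(
        [0] + [e for _, e in breakers], [s for s, _ in breakers] + [len(z)]
    ):
        idx = np.flatnonzero(z[seg_start:seg_end])
        if len(idx) == 0:
            continue
        lo = seg_start + int(idx[0])
        hi = seg_start + int(idx[-1]) + 1
        if hi - lo >= min_bout:
            interruption = int((~z[lo:hi]).sum())
            bouts.append(NonWearBout(lo, hi, interruption))
    return bouts


def _detect_per_bout(z: np.ndarray, min_bout: int, tolerance: int) -> list[NonWearBout]:
    # Maximal zero-bounded windows whose total interrupted minutes <= tolerance.
    zeros = np.flatnonzero(z)
    if len(zeros) == 0:
        return []
    nz_prefix = np.concatenate(([0], np.cumsum(~z)))
    bouts: list[NonWearBout] = []
    j = 0
    prev_end = -1
    for i in range(len(zeros)):
        if j < i:
            j = i
        # furthest zero j such that interior non-zeros <= tolerance
        while j + 1 < len(zeros) and (
            nz_prefix[zeros[j + 1] + 1] - nz_prefix[zeros[i]] <= tolerance
        ):
            j += 1
        lo, hi = int(zeros[i]), int(zeros[j]) + 1
        if hi - lo >= min_bout and hi > prev_end:
            bouts.append(NonWearBout(lo, hi, int(nz_prefix[hi] - nz_prefix[lo])))
            prev_end = hi
    return bouts


def wear_minutes(series: EpochSeries) -> pd.Series:
    """Worn, non-excluded minutes per calendar date of epoch start.

    Assumes non-wear and overnight flags are already applied. With a
    full 24-h day the maximum is 1020 min (06:00-23:00).
    """
    if series.epoch_length != 60:
        raise UnsupportedEpochError("wear accounting requires 60-s epochs")
    worn = series.wear_flag & ~series.excluded_flag
    dates = series.timestamps.date
    return pd.Series(worn.astype(int)).groupby(pd.Series(dates)).sum().rename("wear_min")


def process_series(
    series: EpochSeries,
    *,
    target_epoch: int = 60,
    nonwear_min_bout: int = 60,
    nonwear_tolerance: int = 2,
    interruption_mode: Literal["per_interruption", "per_bout"] = "per_interruption",
) -> EpochSeries:
    """Full epoch pipeline: reintegrate, flag non-wear, flag overnight."""
    out = reintegrate(series, target_epoch)
    detect_nonwear(
        out, nonwear_min_bout, nonwear_tolerance, interruption_mode=interruption_mode
    )
    return flag_overnight(out)
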