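"""Day- and wave-level summaries of flagged epoch series.

Classifies each worn minute into sedentary (<=100 CPM), light
(101-2294 CPM) or moderate-to-vigorous (>=2295 CPM) intensity using the
Evenson youth cut-points, applies the valid-day (>=600 wear minutes)
and valid-file (>=2 valid weekdays and >=1 valid weekend day) rules,
and standardizes each wave's intensity minutes to the participant's
mean daily wear time pooled across waves:

    std_I(wave) = raw_I(wave) / wear(wave) * pooled_mean_wear

computed separately for the all-days, weekday and weekend streams, so
that between-wave wear differences do not masquerade as behaviour
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochSeries
from .errors import InvalidParameterError, UndefinedProportionError

#: Evenson et al. count thresholds (counts per 60-s epoch).
SED_MAX_CPM = 100
MVPA_MIN_CPM = 2295

VALID_DAY_MIN_WEAR = 600
VALID_FILE_MIN_WEEKDAYS = 2
VALID_FILE_MIN_WEEKEND = 1

INTENSITIES = ("sed", "lpa", "mvpa")
STREAMS = ("all", "weekday", "weekend")


@dataclass(frozen=True)
class CutPoints:
    """Intensity thresholds in counts per minute; overridable via config."""

    sed_max: int = SED_MAX_CPM
    mvpa_min: int = MVPA_MIN_CPM

    def __post_init__(self) -> None:
        if not 0 <= self.sed_max < self.mvpa_min:
            raise InvalidParameterError("require 0 <= sed_max < mvpa_min")


def classify_intensity(cpm: int, cutpoints: CutPoints = CutPoints()) -> str:
    """Classify one 60-s epoch count into 'sed', 'lpa' or 'mvpa'.

    The partition is exhaustive and exclusive: <=100 CPM sedentary,
    101-2294 CPM light, >=2295 CPM MVPA at the default cut-points.
    """
    if cpm < 0:
        raise ValueError("counts per minute must be non-negative")
    if cpm <= cutpoints.sed_max:
        return "sed"
    if cpm < cutpoints.mvpa_min:
        return "lpa"
    return "mvpa"


def classify_intensity_array(
    cpm: np.ndarray, cutpoints: CutPoints = CutPoints()
) -> np.ndarray:
    """Vectorised :func:`classify_intensity`; returns an object array of labels."""
    cpm = np.asarray(cpm)
    if (cpm < 0).any():
        raise ValueError("counts per minute must be non-negative")
    out = np.where(
        cpm <= cutpoints.sed_max, "sed", np.where(cpm < cutpoints.mvpa_min, "lpa", "mvpa")
    )
    return out


def summarize_days(
    series: EpochSeries, cutpoints: CutPoints = CutPoints()
) -> pd.DataFrame:
    """Per-calendar-day summary of a flagged 60-s epoch series.

    Returns one row per date with wear minutes, minutes in each
    intensity over worn non-excluded epochs, the weekday/weekend day
    type and the valid-day flag. sed+lpa+mvpa equals wear exactly.
    """
    if series.epoch_length != 60:
        raise InvalidParameterError("day summaries require 60-s epochs")
    ts = series.timestamps
    worn = series.wear_flag & ~series.excluded_flag
    labels = classify_intensity_array(series.counts, cutpoints)
    df = pd.DataFrame(
        {
            "date": ts.date,
            "worn": worn,
            "sed": worn & (labels == "sed"),
            "lpa": worn & (labels == "lpa"),
            "mvpa": worn & (labels == "mvpa"),
        }
    )
    g = df.groupby("date", sort=True).sum()
    out = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "wave_index": series.wave_index,
            "date": g.index,
            "wear_min": g["worn"].astype(int),
            "sed_min": g["sed"].astype(int),
            "lpa_min": g["lpa"].astype(int),
            "mvpa_min": g["mvpa"].astype(int),
        }
    ).reset_index(drop=True)
    iso = pd.to_datetime(out["date"]).dt.dayofweek  # Mon=0 .. Sun=6
    out["day_type"] = np.where(iso >= 5, "weekend", "weekday")
    out["valid"] = out["wear_min"] >= VALID_DAY_MIN_WEAR
    return out


def valid_file(days: pd.DataFrame) -> bool:
    """True iff the wave has >=2 valid weekdays and >=1 valid weekend day."""
    if len(days) == 0:
        return False
    v = days[days["valid"]]
    n_weekday = int((v["day_type"] == "weekday").sum())
    n_weekend = int((v["day_type"] == "weekend").sum())
    return n_weekday >= VALID_FILE_MIN_WEEKDAYS and n_weekend >= VALID_FILE_MIN_WEEKEND


def build_wave_summaries(days: pd.DataFrame) -> pd.DataFrame:
    """Aggregate valid days of one participant-wave into per-stream means.

    The wave must already have passed :func:`valid_file` (on the
    all-days rule; streams inherit). A stream with zero valid days is
    omitted. Raw intensity minutes are stream-specific arithmetic means
    over valid days; the ``std_*`` columns are filled later by
    :func:`standardize_wear` once all of a participant's waves are
    available.
    """
    v = days[days["valid"]]
    rows = []
    for stream in STREAMS:
        sel = v if stream == "all" else v[v["day_type"] == stream]
        if len(sel) == 0:
            continue
        rows.append(
            {
                "participant_id": days["participant_id"].iloc[0],
                "wave_index": days["wave_index"].iloc[0],
                "stream": stream,
                "n_valid_days": len(sel),
                "mean_wear_min": sel["wear_min"].mean(),
                "raw_sed": sel["sed_min"].mean(),
                "raw_lpa": sel["lpa_min"].mean(),
                "raw_mvpa": sel["mvpa_min"].mean(),
            }
        )
    return pd.DataFrame(rows)


def standardize_wear(waves: pd.DataFrame) -> pd.DataFrame:
    """Wear-standardize one participant's wave summaries, per stream.

    For each stream independently, every wave's intensity minutes are
    rescaled by the ratio of the participant's pooled mean daily wear
    (valid days of that stream, pooled across waves) to the wave's own
    mean wear:

        std_I(w) = raw_I(w) / mean_wear(w) * pooled_mean_wear

    so standardized sed+lpa+mvpa equals the pooled mean wear for every
    wave. With a single wave (or equal wear across waves) standardized
    and raw values coincide.
    """
    out = waves.copy()
    for col in ("std_sed", "std_lpa", "std_mvpa", "pooled_mean_wear"):
        out[col] = np.nan
    for (pid, stream), grp in out.groupby(["participant_id", "stream"], sort=False):
        if (grp["mean_wear_min"] <= 0).any():
            raise UndefinedProportionError(
                f"participant {pid} stream {stream}: zero mean wear"
            )
        # day-weighted pooled mean over all valid days across waves
        pooled = (grp["mean_wear_min"] * grp["n_valid_days"]).sum() / grp[
            "n_valid_days"
        ].sum()
        scale = pooled / grp["mean_wear_min"]
        out.loc[grp.index, "std_sed"] = grp["raw_sed"] * scale
        out.loc[grp.index, "std_lpa"] = grp["raw_lpa"] * scale
        out.loc[grp.index, "std_mvpa"] = grp["raw_mvpa"] * scale
        out.loc[grp.index, "pooled_mean_wear"] = pooled
    return out


def summarize_wave(series: EpochSeries, cutpoints: CutPoints = CutPoints()):
    """Convenience: days + validity for one flagged wave series.

    Returns ``(day_table, wave_table, is_valid_file)``; the wave table
    is empty when the wave fails the valid-file rule.
    """
    days = summarize_days(series, cutpoints)
    ok = valid_file(days)
    waves = build_wave_summaries(days) if ok else pd.DataFrame()
    return days, waves, ok
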