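"""Covariate derivation, inclusion rules and descriptive change statistics.

Harmonises the participant-level variables used in the longitudinal
models — decimal age at each wave, the child/adolescent dichotomy at
baseline (<10 vs >=10 years), meteorological season of measurement,
LMS-based BMI z-scores with a configurable weight-category cutoff
table, and binary maternal-education / ethnicity indicators — then
applies the cohort inclusion rules (control arms only for intervention
studies, >=2 valid waves, first three waves) and computes baseline /
follow-up / change summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError, MissingAgeError

DAYS_PER_YEAR = 365.25  # leap-safe decimal-age denominator

AGE_GROUP_THRESHOLD = 10.0  # years; child < 10 <= adolescent

_NORTH_SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}
_SEASON_SHIFT = {"winter": "summer", "spring": "autumn", "summer": "winter", "autumn": "spring"}


@dataclass
class WaveObservation:
    """Per-wave metadata for one participant."""

    wave_index: int
    assessment_date: date | None = None
    proxy_date: date | None = None
    provided_age: float | None = None
    height_m: float | None = None
    weight_kg: float | None = None
    bmi_z: float | None = None


@dataclass
class ParticipantRecord:
    """Demographics and per-wave metadata for one participant."""

    participant_id: str
    study_id: str
    sex: str  # 'male' | 'female'
    dob: date | None = None
    ethnicity: str | None = None  # 'white' | 'non-white'
    maternal_education: str | None = None  # 'low-mid' | 'high'
    intervention_arm: str = "none"  # 'control' | 'intervention' | 'none'
    waves: dict[int, WaveObservation] = field(default_factory=dict)


@dataclass(frozen=True)
class ChangeSummary:
    """Baseline-to-follow-up change in one outcome for one participant."""

    outcome: str
    baseline_min: float
    followup_min: float

    @property
    def abs_change(self) -> float:
        return self.followup_min - self.baseline_min

    @property
    def rel_change_pct(self) -> float:
        return self.abs_change / self.baseline_min * 100.0


def decimal_age(record: ParticipantRecord, wave_index: int) -> float:
    """Decimal age in years at a wave of measurement.

    Preference order: date of birth to the first accelerometer day;
    an investigator-provided age; date of birth to a proxy date (e.g.
    questionnaire completion). Elapsed days are divided by 365.25.
    """
    obs = record.waves.get(wave_index)
    if obs is None:
        raise MissingAgeError(
            f"participant {record.participant_id}: no wave {wave_index}"
        )
    if record.dob is not None and obs.assessment_date is not None:
        return (obs.assessment_date - record.dob).days / DAYS_PER_YEAR
    if obs.provided_age is not None:
        return float(obs.provided_age)
    if record.dob is not None and obs.proxy_date is not None:
        return (obs.proxy_date - record.dob).days / DAYS_PER_YEAR
    raise MissingAgeError(
        f"participant {record.participant_id} wave {wave_index}: "
        "no resolvable age source"
    )


def age_group(baseline_age: float) -> str:
    """Dichotomise baseline age: 'child' (<10 y) vs 'adolescent' (>=10 y)."""
    if baseline_age < 0:
        raise ValueError("age must be non-negative")
    return "child" if baseline_age < AGE_GROUP_THRESHOLD else "adolescent"


def season_of(when: date, hemisphere: str = "north") -> str:
    """Meteorological season of a measurement date.

    Northern mapping: Dec-Feb winter, Mar-May spring, Jun-Aug summer,
    Sep-Nov autumn; the southern hemisphere is shifted six months.
    """
    season = _NORTH_SEASONS[when.month]
    if hemisphere == "south":
        season = _SEASON_SHIFT[season]
    elif hemisphere != "north":
        raise ConfigError(f"unknown hemisphere {hemisphere!r}")
    return season


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """LMS (Box-Cox power / median / coefficient-of-variation) z-score.

    z = ((x/M)**L - 1) / (L*S) for L != 0, and ln(x/M)/S in the L -> 0
    limit. The caller matches the (L, M, S) reference row on age and
    sex; reference tables (e.g. British 1990, IOTF) are external inputs.
    """
    if x <= 0:
        raise ValueError("measurement must be positive")
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be positive")
    if L == 0:
        return math.log(x / M) / S
    # expm1 keeps the L -> 0 limit accurate where (x/M)**L - 1 would
    # cancel catastrophically
    return math.expm1(L * math.log(x / M)) / (L * S)


@dataclass(frozen=True)
class WeightCutoffs:
    """BMI z-score thresholds for the three-way weight classification."""

    underweight_max: float  # z below this -> underweight
    overweight_min: float  # z at or above this -> overweight-obese

    def __post_init__(self) -> None:
        if not self.underweight_max < self.overweight_min:
            raise ConfigError("underweight cutoff must lie below overweight cutoff")


def weight_category(bmi_z: float, cutoffs: WeightCutoffs) -> str:
    """Classify a BMI z-score as underweight / normal / overweight-obese."""
    if cutoffs is None:
        raise ConfigError("weight-category cutoffs must be supplied")
    if bmi_z < cutoffs.underweight_max:
        return "underweight"
    if bmi_z >= cutoffs.overweight_min:
        return "overweight-obese"
    return "normal"


def weight_group(category: str) -> str:
    """Dichotomise for interaction models: under/normal vs overweight-obese."""
    return "overweight-obese" if category == "overweight-obese" else "under-normal"


MAX_WAVES = 3


def apply_inclusion(
    records: Mapping[str, ParticipantRecord],
    wave_summaries: pd.DataFrame,
    intervention_studies: set[str] | None = None,
) -> pd.DataFrame:
    """Apply the cohort inclusion rules to a wave-summary table.

    Drops intervention-arm participants of flagged intervention
    studies, truncates each participant to their first three valid
    waves, and keeps only participants with two or more valid waves.
    Idempotent. ``wave_summaries`` must carry participant_id and
    wave_index columns (one or more rows per wave, e.g. per stream).
    """
    intervention_studies = intervention_studies or set()
    df = wave_summaries.copy()

    def keep_participant(pid: str) -> bool:
        rec = records.get(pid)
        if rec is None:
            return False
        if rec.study_id in intervention_studies and rec.intervention_arm != "control":
            return False
        return True

    df = df[df["participant_id"].map(keep_participant)]
    # first three waves per participant
    first3 = (
        df[["participant_id", "wave_index"]]
        .drop_duplicates()
        .sort_values(["participant_id", "wave_index"])
        .groupby("participant_id")
        .head(MAX_WAVES)
    )
    df = df.merge(first3, on=["participant_id", "wave_index"])
    n_waves = df.groupby("participant_id")["wave_index"].nunique()
    keep = n_waves[n_waves >= 2].index
    return df[df["participant_id"].isin(keep)].reset_index(drop=True)


def change_summary(waves: pd.DataFrame, outcome: str) -> ChangeSummary:
    """Baseline-to-follow-up change for one participant and outcome.

    Baseline is the first valid wave, follow-up the last retained wave
    (the third for three-wave participants). ``waves`` must be one
    participant's rows of a single stream with a ``std_<outcome>``
    column; rows are sorted by wave before differencing so a reversed
    input never yields baseline-minus-follow-up.
    """
    if outcome not in ("sed", "lpa", "mvpa"):
        raise ValueError(f"unknown outcome {outcome!r}")
    if waves["participant_id"].nunique() > 1:
        raise ValueError("change_summary expects a single participant")
    w = waves.sort_values("wave_index")
    if w["wave_index"].nunique() < 2:
        raise InsufficientDataError("change requires at least two valid waves")
    col = f"std_{outcome}" if f"std_{outcome}" in w.columns else outcome
    return ChangeSummary(
        outcome=outcome,
        baseline_min=float(w[col].iloc[0]),
        followup_min=float(w[col].iloc[-1]),
    )


def build_analysis_table(
    wave_summaries: pd.DataFrame,
    records: Mapping[str, ParticipantRecord],
    *,
    hemisphere_by_study: Mapping[str, str] | None = None,
    weight_cutoffs: WeightCutoffs | None = None,
) -> pd.DataFrame:
    """Assemble the analysis-ready long table for the mixed models.

    Joins standardized wave summaries (one row per
    participant-wave-stream, ``std_*`` columns) with derived
    covariates: decimal age per wave, the baseline age-group
    dichotomy, season of measurement, sex, weight group (when a BMI
    z-score and cutoff table are available), maternal education and
    ethnicity. Outcome columns are named sed / lpa / mvpa and hold the
    wear-standardized min/day used by the models.
    """
    hemis = hemisphere_by_study or {}
    rows = []
    for _, wrow in wave_summaries.iterrows():
        pid = wrow["participant_id"]
        rec = records.get(pid)
        if rec is None:
            continue
        w = int(wrow["wave_index"])
        age = decimal_age(rec, w)
        obs = rec.waves.get(w)
        when = obs.assessment_date or obs.proxy_date if obs else None
        season = (
            season_of(when, hemis.get(rec.study_id, "north")) if when else None
        )
        wgroup = None
        if obs is not None and obs.bmi_z is not None and weight_cutoffs is not None:
            wgroup = weight_group(weight_category(obs.bmi_z, weight_cutoffs))
        rows.append(
            {
                "study_id": rec.study_id,
                "participant_id": pid,
                "wave_index": w,
                "stream": wrow["stream"],
                "age": age,
                "sex": rec.sex,
                "season": season,
                "weight_group": wgroup,
                "maternal_education": rec.maternal_education,
                "ethnicity": rec.ethnicity,
                "sed": wrow["std_sed"],
                "lpa": wrow["std_lpa"],
                "mvpa": wrow["std_mvpa"],
                "n_valid_days": wrow.get("n_valid_days"),
                "mean_wear_min": wrow.get("mean_wear_min"),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        base = (
            out.sort_values("wave_index")
            .groupby("participant_id")["age"]
            .first()
            .rename("baseline_age")
        )
        out = out.merge(base, on="participant_id")
        out["age_group"] = out["baseline_age"].map(age_group)
    return out


def cohort_change_table(analysis: pd.DataFrame, stream: str = "all") -> pd.DataFrame:
    """Descriptive change statistics across the cohort.

    For each outcome: mean (SD) of baseline, follow-up and absolute
    change, and median (IQR) of relative change, mirroring the usual
    presentation of accelerometer change tables.
    """
    rows = []
    sel = analysis[analysis["stream"] == stream] if "stream" in analysis else analysis
    for outcome in ("sed", "lpa", "mvpa"):
        per = []
        for pid, grp in sel.groupby("participant_id"):
            try:
                cs = change_summary(grp, outcome)
            except InsufficientDataError:
                continue
            per.append((cs.baseline_min, cs.followup_min, cs.abs_change, cs.rel_change_pct))
        if not per:
            continue
        arr = np.asarray(per)
        q1, med, q3 = np.percentile(arr[:, 3], [25, 50, 75])
        rows.append(
            {
                "outcome": outcome,
                "n": len(per),
                "baseline_mean": arr[:, 0].mean(),
                "baseline_sd": arr[:, 0].std(ddof=1),
                "followup_mean": arr[:, 1].mean(),
                "followup_sd": arr[:, 1].std(ddof=1),
                "change_mean": arr[:, 2].mean(),
                "change_sd": arr[:, 2].std(ddof=1),
                "rel_change_median": med,
                "rel_change_iqr": q3 - q1,
            }
        )
    return pd.DataFrame(rows)
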