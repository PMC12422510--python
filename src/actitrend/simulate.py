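"""Synthetic multi-study accelerometer cohorts with known truths.

Pooled children's accelerometry databases are access-controlled, so
every part of this package is exercised against simulated data whose
generating parameters are user-specified and recorded. Two tiers are
generated from one configuration:

* a wave-level analysis table (participant demographics, decimal age
  per wave, season, and behaviour compositions following a linear
  age model with study and participant random intercepts), cheap
  enough for repeated model-recovery experiments; and
* optional epoch-level 60-s count traces per participant-wave day,
  embedding overnight sleep (23:00-06:00 zeros), injected non-wear
  bouts with brief interruptions, and intensity-graded counts, for
  end-to-end processing tests.

Default parameters emulate a pooled cohort of school-aged children
followed over two to three assessment waves: baseline age centred at
10.6 y (SD 2.1, truncated to the 4.1-15.8 y observation range),
follow-up gaps of about 2.5 y to the second and 4.3 y cumulative to
the third wave, 44.5% boys, 89.2% white, 26.9% low/mid maternal
education, sedentary time rising ~25 min/day per year while light and
moderate-to-vigorous activity fall ~22 and ~2.5 min/day per year.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import WeightCutoffs, age_group, season_of, weight_category, weight_group
from .days import MVPA_MIN_CPM, SED_MAX_CPM
from .epochs import EpochSeries
from .errors import ConfigError, InfeasibleTargetError

OUTCOMES = ("sed", "lpa", "mvpa")


def _default_season_effects() -> dict:
    # small seasonal displacements (min/day), reference = spring
    return {
        "sed": {"summer": -8.0, "autumn": 3.0, "winter": 10.0},
        "lpa": {"summer": 5.0, "autumn": -2.0, "winter": -7.0},
        "mvpa": {"summer": 3.0, "autumn": -1.0, "winter": -3.0},
    }


@dataclass
class SimConfig:
    """Generating parameters for a synthetic pooled cohort.

    Fixed effects are per outcome: ``intercepts`` give expected
    min/day at the centring age for a male participant in spring,
    ``slopes`` the annual change, ``sex_effects`` the female-minus-male
    level shift, ``season_effects`` displacements from spring.
    ``interactions[outcome][moderator]`` adds that amount to the age
    slope in the moderator's non-reference level (e.g. girls);
    ``stream_slope_deltas[outcome]`` shifts the weekend-stream slope
    relative to weekdays. Random intercepts are drawn per study and
    per participant with the given SDs; outcomes are truncated to
    [0, wear_target] (events counted in the truth record).
    """

    n_studies: int = 5
    participants_per_study: int = 100
    wave_counts: tuple[int, ...] = (2, 3)
    wave_count_probs: tuple[float, ...] = (0.5, 0.5)
    baseline_age_mean: float = 10.6
    baseline_age_sd: float = 2.1
    baseline_age_range: tuple[float, float] = (4.1, 15.8)
    gap1_mean: float = 2.5
    gap1_sd: float = 1.4
    cum_gap2_mean: float = 4.3
    cum_gap2_sd: float = 1.1
    min_gap: float = 0.5
    age_center: float = 10.0
    intercepts: dict = field(
        default_factory=lambda: {"sed": 350.0, "lpa": 390.0, "mvpa": 56.0}
    )
    slopes: dict = field(
        default_factory=lambda: {"sed": 24.9, "lpa": -22.4, "mvpa": -2.5}
    )
    sex_effects: dict = field(
        default_factory=lambda: {"sed": 18.0, "lpa": 2.0, "mvpa": -20.0}
    )
    season_effects: dict = field(default_factory=_default_season_effects)
    interactions: dict = field(default_factory=dict)
    stream_slope_deltas: dict = field(default_factory=dict)
    sd_study: dict = field(
        default_factory=lambda: {"sed": 18.0, "lpa": 16.0, "mvpa": 2.0}
    )
    sd_participant: dict = field(
        default_factory=lambda: {"sed": 40.0, "lpa": 35.0, "mvpa": 7.0}
    )
    sd_residual: dict = field(
        default_factory=lambda: {"sed": 30.0, "lpa": 28.0, "mvpa": 5.0}
    )
    wear_target: float = 850.0
    streams: tuple[str, ...] = ("all",)
    prop_male: float = 0.445
    prop_white: float = 0.892
    prop_low_mid_education: float = 0.269
    bmi_z_mean: float = 0.34
    bmi_z_sd: float = 1.1
    weight_cutoffs: tuple[float, float] = (-2.0, 1.33)
    # trace options
    nonwear_bouts_per_day: int = 1
    nonwear_duration_range: tuple[int, int] = (60, 120)
    interruption_prob: float = 0.3
    mvpa_count_cap: int = 10_000

    def validate(self) -> None:
        for d in (self.sd_study, self.sd_participant, self.sd_residual):
            if any(v < 0 for v in d.values()):
                raise ConfigError("variance-component SDs must be non-negative")
        lo, hi = self.baseline_age_range
        # expected composition must fit inside the wear target over the
        # observable age span (baseline range plus maximal follow-up)
        for a in np.linspace(lo, hi + self.cum_gap2_mean + 3 * self.cum_gap2_sd, 25):
            total = sum(
                self.intercepts[o] + self.slopes[o] * (a - self.age_center)
                for o in OUTCOMES
            )
            if total > self.wear_target + 1e-9:
                raise ConfigError(
                    f"expected sed+lpa+mvpa = {total:.1f} min/day exceeds the "
                    f"wear target {self.wear_target} at age {a:.1f}"
                )


@dataclass
class SimTruth:
    """Generating truths stored alongside every simulated dataset."""

    seed: int
    fixed: dict
    study_effects: pd.DataFrame  # study_id x outcome
    participant_effects: pd.DataFrame  # participant_id x outcome
    expected: pd.DataFrame  # per-row expected outcome values
    truncation_count: int

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "fixed": self.fixed,
            "study_effects": self.study_effects.to_dict(orient="list"),
            "participant_effects": self.participant_effects.to_dict(orient="list"),
            "truncation_count": self.truncation_count,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (ranges here are wide; cheap)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: SimConfig, seed: int = 0) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a wave-level analysis table and its truth record.

    The returned table has one row per participant-wave-stream with
    columns study_id, participant_id, wave_index, stream, age,
    baseline_age, age_group, sex, season, bmi_z, weight_group,
    maternal_education, ethnicity and the outcome columns sed / lpa /
    mvpa in (already wear-standardized) min/day. The same seed and
    config reproduce the table exactly.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lo, hi = config.baseline_age_range
    cutoffs = WeightCutoffs(*config.weight_cutoffs)

    study_eff = pd.DataFrame(
        {o: rng.normal(0.0, config.sd_study[o], config.n_studies) for o in OUTCOMES},
        index=[f"study{s:02d}" for s in range(config.n_studies)],
    )

    rows = []
    part_eff_rows = {}
    trunc = 0
    for s in range(config.n_studies):
        sid = f"study{s:02d}"
        for p in range(config.participants_per_study):
            pid = f"{sid}_p{p:03d}"
            sex = "male" if rng.random() < config.prop_male else "female"
            ethnicity = "white" if rng.random() < config.prop_white else "non-white"
            mat_ed = (
                "low-mid"
                if rng.random() < config.prop_low_mid_education
                else "high"
            )
            bmi_z = rng.normal(config.bmi_z_mean, config.bmi_z_sd)
            wgroup = weight_group(weight_category(bmi_z, cutoffs))
            a0 = float(_truncnorm(rng, config.baseline_age_mean, config.baseline_age_sd, lo, hi, 1)[0])
            n_waves = int(rng.choice(config.wave_counts, p=config.wave_count_probs))
            gap1 = max(config.min_gap, rng.normal(config.gap1_mean, config.gap1_sd))
            # cumulative gap to wave 3 follows its nominal distribution
            # except where the minimum inter-wave gap floors the increment
            cum2 = gap1 + max(
                config.min_gap,
                rng.normal(config.cum_gap2_mean - gap1, config.cum_gap2_sd),
            )
            ages = [a0, a0 + gap1, a0 + cum2][:n_waves]
            ueff = {o: rng.normal(0.0, config.sd_participant[o]) for o in OUTCOMES}
            part_eff_rows[pid] = ueff
            agrp = age_group(a0)
            for w, a in enumerate(ages, start=1):
                month = int(rng.integers(1, 13))
                season = season_of(date(2010, month, 15), "north")
                resid = {
                    (o, st): rng.normal(0.0, config.sd_residual[o])
                    for o in OUTCOMES
                    for st in config.streams
                }
                for stream in config.streams:
                    row = {
                        "study_id": sid,
                        "participant_id": pid,
                        "wave_index": w,
                        "stream": stream,
                        "age": a,
                        "baseline_age": a0,
                        "age_group": agrp,
                        "sex": sex,
                        "season": season,
                        "bmi_z": bmi_z,
                        "weight_group": wgroup,
                        "maternal_education": mat_ed,
                        "ethnicity": ethnicity,
                    }
                    for o in OUTCOMES:
                        slope = config.slopes[o]
                        if stream == "weekend":
                            slope = slope + config.stream_slope_deltas.get(o, 0.0)
                        inter = config.interactions.get(o, {})
                        if sex == "female":
                            slope += inter.get("sex", 0.0)
                        if agrp == "adolescent":
                            slope += inter.get("age_group", 0.0)
                        if wgroup == "overweight-obese":
                            slope += inter.get("weight_group", 0.0)
                        if mat_ed == "high":
                            slope += inter.get("maternal_education", 0.0)
                        if ethnicity == "non-white":
                            slope += inter.get("ethnicity", 0.0)
                        mu = (
                            config.intercepts[o]
                            + slope * (a - config.age_center)
                            + (config.sex_effects[o] if sex == "female" else 0.0)
                            + config.season_effects[o].get(season, 0.0)
                        )
                        expected = mu + study_eff.loc[sid, o] + ueff[o]
                        y = expected + resid[(o, stream)]
                        y_t = float(np.clip(y, 0.0, config.wear_target))
                        if y_t != y:
                            trunc += 1
                        row[o] = y_t
                        row[f"expected_{o}"] = expected
                    rows.append(row)

    table = pd.DataFrame(rows)
    expected = table[
        ["participant_id", "wave_index", "stream"]
        + [f"expected_{o}" for o in OUTCOMES]
    ].copy()
    table = table.drop(columns=[f"expected_{o}" for o in OUTCOMES])
    truth = SimTruth(
        seed=seed,
        fixed={
            "intercepts": dict(config.intercepts),
            "slopes": dict(config.slopes),
            "sex_effects": dict(config.sex_effects),
            "season_effects": {k: dict(v) for k, v in config.season_effects.items()},
            "interactions": {k: dict(v) for k, v in config.interactions.items()},
            "stream_slope_deltas": dict(config.stream_slope_deltas),
            "age_center": config.age_center,
        },
        study_effects=study_eff,
        participant_effects=pd.DataFrame(part_eff_rows).T,
        expected=expected,
        truncation_count=trunc,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Epoch-level trace rendering


def render_day(
    sed_min: int,
    lpa_min: int,
    mvpa_min: int,
    *,
    day: date,
    nonwear: list[tuple[int, int, int]] | None = None,
    rng: np.random.Generator | None = None,
    participant_id: str = "sim",
    wave_index: int = 1,
    mvpa_count_cap: int = 10_000,
) -> EpochSeries:
    """Render one full calendar day of 60-s epochs from minute targets.

    The day runs 00:00-24:00 (1440 epochs). Overnight epochs
    (23:00-06:00) are zeros; ``nonwear`` bouts are given as
    (start_minute_within_06:00-23:00, duration_min, interruption_min)
    and are rendered as zeros with ``interruption_min`` non-zero
    minutes in their middle. Exactly the requested sedentary / light /
    MVPA minutes are placed at shuffled worn positions, with counts
    drawn uniformly inside each intensity's CPM interval; worn
    sedentary epochs draw counts in [1, 100] so an injected zero bout
    never silently extends. Window minutes beyond the targets are
    rendered as trailing zeros contiguous with a bout or the overnight
    block, so they are always re-detected as non-wear and the
    processed wear time equals the target total exactly.
    """
    rng = rng or np.random.default_rng(0)
    nonwear = nonwear or []
    window = 17 * 60  # 06:00-23:00
    occupied = np.zeros(window, dtype=bool)
    for start, dur, _ in nonwear:
        if start < 0 or start + dur > window:
            raise InfeasibleTargetError("non-wear bout outside the 06:00-23:00 window")
        if occupied[start : start + dur].any():
            raise InfeasibleTargetError("overlapping non-wear bouts")
        occupied[start : start + dur] = True
    worn_avail = window - int(occupied.sum())
    total = sed_min + lpa_min + mvpa_min
    if min(sed_min, lpa_min, mvpa_min) < 0 or total > worn_avail:
        raise InfeasibleTargetError(
            f"targets sum to {total} min but only {worn_avail} worn minutes remain"
        )

    counts_window = np.zeros(window, dtype=np.int64)
    for start, dur, interrupt in nonwear:
        if interrupt:
            if interrupt > dur - 2:
                raise InfeasibleTargetError("interruption longer than bout interior")
            mid = start + dur // 2 - interrupt // 2
            counts_window[mid : mid + interrupt] = rng.integers(1, 101, interrupt)

    leftover = worn_avail - total
    if leftover:
        # trailing free slots stay zero; every such chunk abuts an injected
        # bout or the overnight block, so it is re-absorbed into non-wear
        free = np.flatnonzero(~occupied)
        occupied[free[len(free) - leftover :]] = True

    labels = np.array(["sed"] * sed_min + ["lpa"] * lpa_min + ["mvpa"] * mvpa_min)
    rng.shuffle(labels)
    worn_idx = np.flatnonzero(~occupied)
    for idx, lab in zip(worn_idx, labels):
        if lab == "sed":
            counts_window[idx] = rng.integers(1, SED_MAX_CPM + 1)
        elif lab == "lpa":
            counts_window[idx] = rng.integers(SED_MAX_CPM + 1, MVPA_MIN_CPM)
        else:
            counts_window[idx] = rng.integers(MVPA_MIN_CPM, mvpa_count_cap + 1)

    counts = np.zeros(1440, dtype=np.int64)
    counts[6 * 60 : 23 * 60] = counts_window
    return EpochSeries(
        participant_id,
        wave_index,
        pd.Timestamp(day),
        60,
        counts,
    )


def render_traces(
    row: pd.Series | dict,
    config: SimConfig,
    *,
    day: date = date(2010, 6, 7),
    rng: np.random.Generator | None = None,
) -> tuple[EpochSeries, dict]:
    """Render one analysis-table row as a single-day 60-s count trace.

    The row's (possibly fractional) sed / lpa / mvpa minutes are
    rounded to integer minute targets scaled to fit the worn window
    left after injecting the configured non-wear bouts. Returns the
    series together with the integer targets actually rendered, so a
    round trip through the processing modules can be checked exactly.
    """
    rng = rng or np.random.default_rng(0)
    window = 17 * 60
    nonwear = []
    cursor = 30
    for _ in range(config.nonwear_bouts_per_day):
        dur = int(rng.integers(*config.nonwear_duration_range))
        start = int(rng.integers(cursor, max(cursor + 1, window - dur - 120)))
        interrupt = int(rng.integers(1, 3)) if rng.random() < config.interruption_prob else 0
        nonwear.append((start, dur, interrupt))
        cursor = start + dur + 5
    worn_avail = window - sum(d for _, d, _ in nonwear)

    raw = np.array([float(row["sed"]), float(row["lpa"]), float(row["mvpa"])])
    if raw.sum() <= 0:
        raise InfeasibleTargetError("row has no positive activity to render")
    scaled = raw / raw.sum() * min(worn_avail, raw.sum())
    ints = np.floor(scaled).astype(int)
    remainder = int(round(scaled.sum())) - int(ints.sum())
    ints[0] += remainder  # leftover minutes to sedentary
    targets = {"sed": int(ints[0]), "lpa": int(ints[1]), "mvpa": int(ints[2])}
    series = render_day(
        targets["sed"],
        targets["lpa"],
        targets["mvpa"],
        day=day,
        nonwear=nonwear,
        rng=rng,
        participant_id=str(row.get("participant_id", "sim")),
        wave_index=int(row.get("wave_index", 1)),
        mvpa_count_cap=config.mvpa_count_cap,
    )
    targets["nonwear"] = nonwear
    targets["wear_min"] = int(ints.sum())
    return series, targets


def render_wave_traces(
    row,
    config: SimConfig,
    *,
    start_day: date = date(2010, 6, 7),
    n_days: int = 7,
    rng: np.random.Generator | None = None,
) -> tuple[EpochSeries, list[dict]]:
    """Render ``n_days`` consecutive days (default Mon-Sun) as one series."""
    rng = rng or np.random.default_rng(0)
    all_counts = []
    targets = []
    for d in range(n_days):
        day_series, t = render_traces(
            row, config, day=start_day + timedelta(days=d), rng=rng
        )
        all_counts.append(day_series.counts)
        targets.append(t)
    return (
        EpochSeries(
            str(row.get("participant_id", "sim")),
            int(row.get("wave_index", 1)),
            pd.Timestamp(start_day),
            60,
            np.concatenate(all_counts),
        ),
        targets,
    )


# ---------------------------------------------------------------------------
# Deterministic boundary fixtures


def make_fixture_suite(out_dir) -> list[Path]:
    """Write small deterministic CSV fixtures for protocol boundaries.

    Covers the 59- vs 60-minute non-wear boundary, 2- vs 3-minute
    interruptions, the 599- vs 600-minute valid-day rule, the
    intensity cut-point edges (0/100/101/2294/2295 CPM) and a
    valid-file failure case (valid Monday and Tuesday only).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def epoch_csv(name: str, counts, start="2010-06-07 06:00:00"):
        ts = pd.date_range(start, periods=len(counts), freq="60s")
        path = out / name
        pd.DataFrame({"timestamp": ts, "counts": counts}).to_csv(path, index=False)
        written.append(path)
        return path

    pad = [500] * 5
    epoch_csv("bout_60min.csv", pad + [0] * 60 + pad)
    epoch_csv("bout_59min.csv", pad + [0] * 59 + pad)
    epoch_csv("interruption_2min.csv", pad + [0] * 30 + [150, 150] + [0] * 30 + pad)
    epoch_csv("interruption_3min.csv", pad + [0] * 30 + [150] * 3 + [0] * 30 + pad)
    epoch_csv("cutpoint_edges.csv", [0, 100, 101, 2294, 2295])
    # 600 vs 599 worn minutes inside 06:00-23:00, remainder non-wear zeros
    epoch_csv("day_600min.csv", [50] * 600 + [0] * 420)
    epoch_csv("day_599min.csv", [50] * 599 + [0] * 421)

    days = pd.DataFrame(
        {
            "participant_id": "fx",
            "wave_index": 1,
            "date": pd.date_range("2010-06-07", periods=7).date,  # Mon..Sun
            "wear_min": [700, 700, 100, 100, 100, 100, 100],
            "sed_min": [700, 700, 100, 100, 100, 100, 100],
            "lpa_min": 0,
            "mvpa_min": 0,
            "day_type": ["weekday"] * 5 + ["weekend"] * 2,
            "valid": [True, True, False, False, False, False, False],
        }
    )
    p = out / "invalid_file.csv"
    days.to_csv(p, index=False)
    written.append(p)
    return written
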