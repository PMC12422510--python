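"""Three-level mixed-effects estimation of annual behaviour change.

The central model regresses wear-standardized daily minutes of an
outcome (sedentary time, LPA or MVPA) on decimal age, adjusted for sex
and season, with random intercepts for study and for participant
nested within study; time points are the first level. The age
coefficient is the estimated change in daily minutes per year of age.
Stratified fits and age-by-moderator interaction fits probe effect
modification by day of the week, sex, baseline age group, weight
group, maternal education and ethnicity.

Estimation is restricted maximum likelihood via ``statsmodels``
``MixedLM`` (study as the grouping factor, a variance component for
participants within study); confidence intervals and p-values are
Wald-based, matching the beta (95% CI) presentation conventional in
this literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import DegenerateDesignError

OUTCOMES = ("sed", "lpa", "mvpa")

#: Reference level per categorical term (first level = reference).
REFERENCE_LEVELS: Mapping[str, str] = {
    "sex": "male",
    "season": "spring",
    "day_type": "weekday",
    "age_group": "child",
    "weight_group": "under-normal",
    "maternal_education": "low-mid",
    "ethnicity": "white",
}

MODERATORS = ("day_type", "sex", "age_group", "weight_group", "maternal_education", "ethnicity")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed-model fit."""

    outcome: str = "sed"
    exposure: str = "age"
    adjust: tuple[str, ...] = ("sex", "season")
    stream: str = "all"
    strata: str | None = None
    moderator: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.strata is not None and self.moderator is not None:
            raise ValueError("strata and moderator are mutually exclusive in one fit")
        if self.moderator is not None and self.moderator not in MODERATORS:
            raise ValueError(f"moderator must be one of {MODERATORS}")


@dataclass
class ModelResult:
    """Tidy fixed-effect table plus variance components and metadata."""

    terms: pd.DataFrame  # columns: term, beta, ci_low, ci_high, p
    study_var: float
    participant_var: float
    residual_var: float
    n_obs: int
    n_participants: int
    n_studies: int
    converged: bool
    n_dropped: int = 0
    spec: ModelSpec | None = None

    def __getitem__(self, term: str) -> pd.Series:
        row = self.terms[self.terms["term"] == term]
        if len(row) != 1:
            raise KeyError(term)
        return row.iloc[0]

    @property
    def age_beta(self) -> float:
        return float(self[self.spec.exposure if self.spec else "age"]["beta"])

    def to_frame(self) -> pd.DataFrame:
        df = self.terms.copy()
        df["n_obs"] = self.n_obs
        df["n_participants"] = self.n_participants
        df["n_studies"] = self.n_studies
        df["convergence_flag"] = self.converged
        return df


def _cat(term: str) -> str:
    ref = REFERENCE_LEVELS.get(term)
    if ref is None:
        return term
    return f"C({term}, Treatment('{ref}'))"


def _clean_term(name: str) -> str:
    """'C(sex, Treatment('male'))[T.female]' -> 'sex[female]'; keep 'age'."""
    out = name
    for term, ref in REFERENCE_LEVELS.items():
        out = out.replace(f"C({term}, Treatment('{ref}'))", term)
    out = out.replace("[T.", "[")
    return out


class ThreeLevelMixedModel(BaseEstimator):
    """Sex- and season-adjusted three-level linear mixed model.

    Random intercepts are placed on study and on participant within
    study (time points are level one); ``random_slope=True`` adds a
    participant-level random age slope as a sensitivity option.
    Setting ``moderator`` adds the moderator main effect and an
    age-by-moderator interaction; the age row then carries the
    reference-level slope and the implied non-reference slope is their
    sum. The ``day_type`` moderator expects weekday and weekend rows
    stacked per wave (``stream`` in {'weekday','weekend'}) sharing the
    participant random intercept.

    Parameters
    ----------
    outcome : {'sed', 'lpa', 'mvpa'}
        Column holding wear-standardized daily minutes.
    exposure : str
        Continuous exposure column, decimal age in years.
    adjust : tuple of str
        Categorical adjustment covariates (default sex + season).
    moderator : str or None
        Optional binary effect modifier for an interaction fit.
    random_slope : bool
        Add a participant-level random slope on the exposure.
    reml : bool
        Restricted (True, default) vs full maximum likelihood.

    Attributes
    ----------
    result_ : ModelResult
        Tidy coefficient table, variance components, metadata.
    params_ : pandas.Series
        Fixed-effect estimates keyed by cleaned term names.
    converged_ : bool
        False flags a singular or non-converged fit (never silent).
    """

    def __init__(
        self,
        outcome: str = "sed",
        exposure: str = "age",
        adjust: tuple[str, ...] = ("sex", "season"),
        moderator: str | None = None,
        random_slope: bool = False,
        reml: bool = True,
    ):
        self.outcome = outcome
        self.exposure = exposure
        self.adjust = adjust
        self.moderator = moderator
        self.random_slope = random_slope
        self.reml = reml

    # -- formula assembly ---------------------------------------------------

    def _formula(self, data: pd.DataFrame) -> tuple[str, list[str]]:
        spec = ModelSpec(
            outcome=self.outcome,
            exposure=self.exposure,
            adjust=tuple(self.adjust),
            moderator=self.moderator,
        )
        rhs = [self.exposure]
        covars = [self.outcome, self.exposure, "study_id", "participant_id"]
        adjust = [a for a in self.adjust if a != self.moderator]
        for term in adjust:
            rhs.append(_cat(term))
            covars.append(term)
        if self.moderator is not None:
            rhs.append(_cat(self.moderator))
            rhs.append(f"{self.exposure}:{_cat(self.moderator)}")
            covars.append(self.moderator)
        return f"{self.outcome} ~ " + " + ".join(rhs), covars

    # -- fitting ------------------------------------------------------------

    def fit(self, data: pd.DataFrame, y=None) -> "ThreeLevelMixedModel":
        """Fit by REML on an analysis table (one row per wave [x stream])."""
        formula, covars = self._formula(data)
        covars = [c for c in covars if c in data.columns]
        missing = [c for c in (self.outcome, self.exposure, "study_id", "participant_id") if c not in data.columns]
        if missing:
            raise KeyError(f"analysis table lacks columns {missing}")
        rows = data.dropna(subset=covars)
        n_dropped = len(data) - len(rows)

        if rows["study_id"].nunique() < 2:
            raise DegenerateDesignError("need >=2 studies for a study-level intercept")
        if rows.groupby("participant_id").size().max() < 2:
            raise DegenerateDesignError("no participant contributes >=2 observations")
        if self.moderator is not None and rows[self.moderator].nunique() < 2:
            raise DegenerateDesignError(
                f"moderator {self.moderator!r} has a single level"
            )

        vcf = {"participant": "0 + C(participant_id)"}
        if self.random_slope:
            vcf["participant_slope"] = f"0 + C(participant_id):{self.exposure}"
        md = smf.mixedlm(
            formula,
            rows,
            groups="study_id",
            re_formula="1",
            vc_formula=vcf,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = md.fit(reml=self.reml)

        k_fe = md.k_fe
        names = [_clean_term(n) for n in res.model.exog_names]
        beta = np.asarray(res.params)[:k_fe]
        se = np.asarray(res.bse)[:k_fe]
        z = beta / se
        from scipy import stats

        p = 2 * stats.norm.sf(np.abs(z))
        ci_low = beta - 1.959963984540054 * se
        ci_high = beta + 1.959963984540054 * se
        terms = pd.DataFrame(
            {"term": names, "beta": beta, "se": se, "ci_low": ci_low,
             "ci_high": ci_high, "p": p}
        )
        self.result_ = ModelResult(
            terms=terms,
            study_var=float(np.asarray(res.cov_re)[0, 0]),
            participant_var=float(res.vcomp[0]),
            residual_var=float(res.scale),
            n_obs=len(rows),
            n_participants=rows["participant_id"].nunique(),
            n_studies=rows["study_id"].nunique(),
            converged=bool(res.converged),
            n_dropped=n_dropped,
            spec=ModelSpec(
                outcome=self.outcome,
                exposure=self.exposure,
                adjust=tuple(a for a in self.adjust if a != self.moderator),
                moderator=self.moderator,
            ),
        )
        self.params_ = pd.Series(beta, index=names)
        self.conf_int_ = terms.set_index("term")[["ci_low", "ci_high"]]
        self.pvalues_ = pd.Series(p, index=names)
        self.vc_ = {
            "study": self.result_.study_var,
            "participant": self.result_.participant_var,
            "residual": self.result_.residual_var,
        }
        self.converged_ = self.result_.converged
        self.n_obs_ = self.result_.n_obs
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level (fixed-effects-only) prediction."""
        from patsy import dmatrix

        formula, _ = self._formula(data)
        rhs = formula.split("~", 1)[1]
        X = np.asarray(dmatrix(rhs, data, return_type="dataframe"))
        return X @ self.params_.to_numpy()


# ---------------------------------------------------------------------------
# Functional surface


def fit_three_level(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one three-level mixed model described by ``spec``.

    Rows are filtered to ``spec.stream`` when a stream column is
    present (except for the stacked day-of-week moderator design).
    """
    rows = _select_stream(data, spec)
    est = ThreeLevelMixedModel(
        outcome=spec.outcome,
        exposure=spec.exposure,
        adjust=spec.adjust,
        moderator=spec.moderator,
    ).fit(rows)
    return est.result_


def _select_stream(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if "stream" not in data.columns:
        return data
    if spec.moderator == "day_type":
        rows = data[data["stream"].isin(["weekday", "weekend"])].copy()
        rows["day_type"] = rows["stream"]
        return rows
    return data[data["stream"] == spec.stream]


def fit_stratified(
    data: pd.DataFrame, spec: ModelSpec, strata_var: str
) -> dict[str, ModelResult]:
    """Independent fits per stratum level; degenerate strata are skipped."""
    rows = _select_stream(data, spec)
    levels = [lv for lv in rows[strata_var].dropna().unique()]
    if len(levels) < 2:
        warnings.warn(
            f"stratum variable {strata_var!r} has {len(levels)} level(s)",
            stacklevel=2,
        )
    out: dict[str, ModelResult] = {}
    base = ModelSpec(
        outcome=spec.outcome,
        exposure=spec.exposure,
        adjust=tuple(a for a in spec.adjust if a != strata_var),
        stream=spec.stream,
    )
    for lv in levels:
        sub = rows[rows[strata_var] == lv]
        try:
            out[str(lv)] = fit_three_level(sub, base)
        except DegenerateDesignError as exc:
            warnings.warn(f"stratum {lv!r} skipped: {exc}", stacklevel=2)
    return out


def fit_interaction(data: pd.DataFrame, spec: ModelSpec, moderator: str) -> ModelResult:
    """Age-by-moderator interaction fit.

    Reports the reference-level age slope, the moderator main effect
    and the interaction; the non-reference slope is age beta plus the
    interaction beta.
    """
    ispec = ModelSpec(
        outcome=spec.outcome,
        exposure=spec.exposure,
        adjust=spec.adjust,
        stream=spec.stream,
        moderator=moderator,
    )
    return fit_three_level(data, ispec)


def interaction_term_name(result: ModelResult) -> str:
    """Name of the age-by-moderator row in an interaction result."""
    spec = result.spec
    prefix = f"{spec.exposure}:{spec.moderator}["
    for t in result.terms["term"]:
        if t.startswith(prefix):
            return t
    raise KeyError(f"no interaction term with prefix {prefix!r}")


def implied_moderator_slope(result: ModelResult) -> float:
    """Non-reference-level age slope implied by an interaction fit.

    The age row of an interaction model carries the reference-level
    slope; adding the age-by-moderator coefficient gives the slope in
    the other group (e.g. boys 23.5 + interaction 2.5 = girls 26.0).
    """
    return float(result.age_beta + result[interaction_term_name(result)]["beta"])


def tidy_report(
    results: ModelResult | Iterable[ModelResult] | Mapping[str, ModelResult],
    decimals: int = 1,
) -> pd.DataFrame:
    """Long coefficient table with formatted 'beta (95% CI)' strings.

    Estimates are rounded to one decimal for display, mirroring the
    reporting convention of the field; full precision is retained in
    the numeric columns.
    """
    if isinstance(results, ModelResult):
        items: list[tuple[str, ModelResult]] = [("model", results)]
    elif isinstance(results, Mapping):
        items = list(results.items())
    else:
        items = [(f"model{i}", r) for i, r in enumerate(results)]
    frames = []
    for label, res in items:
        df = res.to_frame()
        df.insert(0, "model", label)
        fmt = lambda v: f"{v:.{decimals}f}"
        df["formatted"] = [
            f"{fmt(b)} ({fmt(lo)}, {fmt(hi)})"
            for b, lo, hi in zip(df["beta"], df["ci_low"], df["ci_high"])
        ]
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["model", "term", "beta", "se", "ci_low", "ci_high", "p",
                     "n_obs", "n_participants", "n_studies", "convergence_flag",
                     "formatted"]
        )
    return pd.concat(frames, ignore_index=True)
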