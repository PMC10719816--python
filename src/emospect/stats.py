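"""Analytic layer: stratified prevalence with chi-square tests, per-emotion
logistic regressions (odds ratios with Wald CIs), the sentiment-on-emotions
linear model, and nested satisfaction models with the R-squared increase
attributable to sentiment.

Conventions
-----------
* Reference levels: sildenafil (drug), ">=65" (age), "short" (duration).
* Wald 95% CIs with z = 1.959964; no small-sample or multiplicity
  adjustment.
* Missing data: listwise deletion per model; the two nested satisfaction
  models are fitted on identical rows so their R-squared difference is
  guaranteed non-negative.
* Rating year enters linear models as a continuous covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .annotate import EmotionProfile
from .lexicon import PRIMARY_EMOTIONS
from .preprocess import ReviewRecord
from .sentiment import SentimentScore

__all__ = [
    "REFERENCE_LEVELS",
    "Z_95",
    "TermResult",
    "RegressionResult",
    "PrevalenceTable",
    "DeltaR2Result",
    "StatsInputError",
    "CollinearityError",
    "SeparationError",
    "prevalence_table",
    "fit_logit",
    "fit_ols",
    "fit_emotion_logit",
    "fit_sentiment_on_emotions",
    "fit_satisfaction_models",
    "standardize_satisfaction",
    "build_frame",
]

Z_95 = 1.959964

REFERENCE_LEVELS = {"drug": "sildenafil", "age_band": ">=65", "duration_band": "short"}

_LEVEL_ORDER = {
    "drug": ("sildenafil", "vardenafil", "tadalafil"),
    "age_band": ("<44", "45-64", ">=65"),
    "duration_band": ("short", "mid", "long"),
}


class StatsInputError(ValueError):
    """Bad or degenerate model input."""


class CollinearityError(StatsInputError):
    """Rank-deficient design; carries the aliased column names."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"design matrix is rank deficient; aliased columns: {aliased}")


class SeparationError(StatsInputError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclass(frozen=True)
class TermResult:
    beta: float
    se: float
    p: float
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class RegressionResult:
    model_id: str
    terms: dict[str, TermResult]
    n_used: int
    r_squared: Optional[float] = None
    adj_r_squared: Optional[float] = None
    reference_levels: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PrevalenceTable:
    stratifier: Optional[str]
    levels: tuple[str, ...]
    n_per_level: dict[str, int]
    percent: dict[tuple[str, str], float]  # (level, emotion) -> % of reviews
    se: dict[tuple[str, str], float]  # proportion-scale SE sqrt(p(1-p)/n)
    chi_square: float
    dof: int
    p_value: float
    per_emotion_tests: dict[str, tuple[float, int, float]]  # emotion -> (chi2, dof, p)


@dataclass(frozen=True)
class DeltaR2Result:
    r2_with: float
    r2_without: float
    delta: float
    adj_r2_with: float
    adj_r2_without: float

    def __post_init__(self):
        if not math.isclose(self.delta, self.r2_with - self.r2_without, abs_tol=1e-12):
            raise ValueError("delta must equal r2_with - r2_without")

    @classmethod
    def from_r2(cls, r2_with, r2_without, adj_with=float("nan"), adj_without=float("nan")):
        return cls(r2_with, r2_without, r2_with - r2_without, adj_with, adj_without)


# ---------------------------------------------------------------------------
# data assembly


def build_frame(
    records: Sequence[ReviewRecord],
    profiles: Optional[Sequence[EmotionProfile]] = None,
    sentiments: Optional[Sequence[SentimentScore]] = None,
) -> pd.DataFrame:
    """One row per review joining record fields, emotion flags, sentiment."""
    df = pd.DataFrame(
        {
            "review_id": [r.review_id for r in records],
            "drug": [r.drug for r in records],
            "age_band": [r.age_band for r in records],
            "duration_band": [r.duration_band for r in records],
            "rating_year": [r.rating_year for r in records],
            "satisfaction_5": [r.satisfaction_5 for r in records],
        }
    ).set_index("review_id")
    if profiles is not None:
        pf = pd.DataFrame(
            {p: [prof.flags[p] for prof in profiles] for p in PRIMARY_EMOTIONS},
            index=[prof.review_id for prof in profiles],
        )
        df = df.join(pf, how="inner")
    if sentiments is not None:
        sf = pd.Series({s.review_id: s.compound for s in sentiments}, name="compound")
        df = df.join(sf, how="inner")
    return df


def _dummies(df: pd.DataFrame, var: str) -> pd.DataFrame:
    ref = REFERENCE_LEVELS[var]
    levels = [lv for lv in _LEVEL_ORDER[var] if lv != ref]
    out = pd.DataFrame(index=df.index)
    for lv in levels:
        if (df[var] == lv).any():
            out[f"{var}[{lv}]"] = (df[var] == lv).astype(float)
    return out


def _design(df: pd.DataFrame, covariates: Iterable[str], extra: Iterable[str] = ()) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    for col in extra:
        X[col] = df[col].astype(float)
    for var in covariates:
        X = pd.concat([X, _dummies(df, var)], axis=1)
    return X


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns linearly dependent on the columns before them."""
    aliased = []
    basis: list[np.ndarray] = []
    for name in X.columns:
        col = X[name].to_numpy(float)
        if basis:
            B = np.column_stack(basis)
            coef, *_ = np.linalg.lstsq(B, col, rcond=None)
            if np.linalg.norm(col - B @ coef) < 1e-8 * max(1.0, np.linalg.norm(col)):
                aliased.append(name)
                continue
        basis.append(col)
    return aliased


# ---------------------------------------------------------------------------
# prevalence / chi-square


def prevalence_table(
    profiles: Sequence[EmotionProfile],
    records: Sequence[ReviewRecord],
    stratifier: Optional[str] = None,
) -> PrevalenceTable:
    """Percent (and SE) of reviews expressing each emotion per stratum.

    The single reported chi-square tests the stratifier-level x emotion
    mention-count contingency table (counts of reviews mentioning each
    emotion); per-emotion presence x level tests are also returned.
    """
    df = build_frame(records, profiles=profiles)
    if stratifier is None:
        df = df.assign(_level="all")
        level_col = "_level"
        levels = ["all"]
    else:
        if stratifier not in _LEVEL_ORDER:
            raise StatsInputError(f"unknown stratifier {stratifier!r}")
        level_col = stratifier
        df = df[df[level_col].notna()]
        levels = [lv for lv in _LEVEL_ORDER[stratifier] if (df[level_col] == lv).any()]

    n_per_level: dict[str, int] = {}
    percent: dict[tuple[str, str], float] = {}
    se: dict[tuple[str, str], float] = {}
    counts = np.zeros((len(levels), len(PRIMARY_EMOTIONS)))
    for i, lv in enumerate(levels):
        sub = df[df[level_col] == lv]
        n = len(sub)
        n_per_level[lv] = n
        for j, emo in enumerate(PRIMARY_EMOTIONS):
            k = int(sub[emo].sum())
            p = k / n if n else float("nan")
            counts[i, j] = k
            percent[(lv, emo)] = 100.0 * p
            se[(lv, emo)] = math.sqrt(p * (1 - p) / n) if n else float("nan")

    if stratifier is not None and counts.sum() == 0:
        raise StatsInputError("zero-total contingency table: chi-square undefined")
    if len(levels) > 1 and (counts.sum(axis=1) > 0).all():
        keep = counts[:, counts.sum(axis=0) > 0]
        chi2, p_val, dof, _ = sps.chi2_contingency(keep, correction=False)
    else:
        chi2, p_val, dof = float("nan"), float("nan"), 0

    per_emotion: dict[str, tuple[float, int, float]] = {}
    if len(levels) > 1:
        for emo in PRIMARY_EMOTIONS:
            tab = np.array(
                [
                    [
                        int(df[(df[level_col] == lv)][emo].sum()),
                        int((df[df[level_col] == lv][emo] == 0).sum()),
                    ]
                    for lv in levels
                ]
            )
            if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
                c, pv, d, _ = sps.chi2_contingency(tab, correction=False)
                per_emotion[emo] = (float(c), int(d), float(pv))

    return PrevalenceTable(
        stratifier=stratifier,
        levels=tuple(levels),
        n_per_level=n_per_level,
        percent=percent,
        se=se,
        chi_square=float(chi2),
        dof=int(dof),
        p_value=float(p_val),
        per_emotion_tests=per_emotion,
    )


# ---------------------------------------------------------------------------
# model fits


def _check_design(X: pd.DataFrame) -> None:
    aliased = _aliased_columns(X)
    if aliased:
        raise CollinearityError(aliased)


def fit_logit(y: pd.Series, X: pd.DataFrame, model_id: str = "logit") -> RegressionResult:
    """Maximum-likelihood logistic fit with ORs and Wald 95% CIs."""
    yv = y.to_numpy(float)
    if len(set(yv)) < 2:
        raise SeparationError(f"{model_id}: outcome has a single class")
    _check_design(X)
    try:
        res = sm.Logit(yv, X.to_numpy(float)).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError subclasses
        raise SeparationError(f"{model_id}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(f"{model_id}: logistic fit did not converge")
    if np.any(np.abs(res.params) > 30):
        bad = [c for c, b in zip(X.columns, res.params) if abs(b) > 30]
        raise SeparationError(f"{model_id}: quasi-complete separation in terms {bad}")
    terms = {}
    for name, b, s, p in zip(X.columns, res.params, res.bse, res.pvalues):
        terms[name] = TermResult(
            beta=float(b),
            se=float(s),
            p=float(p),
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * s)),
            ci_high=float(np.exp(b + Z_95 * s)),
        )
    return RegressionResult(
        model_id=model_id,
        terms=terms,
        n_used=int(len(yv)),
        reference_levels=dict(REFERENCE_LEVELS),
    )


def fit_ols(y: pd.Series, X: pd.DataFrame, model_id: str = "ols") -> RegressionResult:
    _check_design(X)
    res = sm.OLS(y.to_numpy(float), X.to_numpy(float)).fit()
    # degenerate outcome: zero total variance means a flat fit, not NaN
    r2 = float(res.rsquared) if res.centered_tss > 0 else 0.0
    adj = float(res.rsquared_adj) if res.centered_tss > 0 else 0.0
    terms = {}
    for name, b, s, p in zip(X.columns, res.params, res.bse, res.pvalues):
        terms[name] = TermResult(
            beta=float(b),
            se=float(s),
            p=float(p),
            ci_low=float(b - Z_95 * s),
            ci_high=float(b + Z_95 * s),
        )
    return RegressionResult(
        model_id=model_id,
        terms=terms,
        n_used=int(res.nobs),
        r_squared=r2,
        adj_r_squared=adj,
        reference_levels=dict(REFERENCE_LEVELS),
    )


def fit_emotion_logit(
    profiles: Sequence[EmotionProfile],
    records: Sequence[ReviewRecord],
    emotion: str,
    covariates: Sequence[str] = ("drug", "age_band", "duration_band"),
) -> RegressionResult:
    """flag ~ drug + age + duration with the conventional reference levels."""
    if emotion not in PRIMARY_EMOTIONS:
        raise StatsInputError(f"unknown emotion {emotion!r}")
    df = build_frame(records, profiles=profiles)
    df = df.dropna(subset=list(covariates))
    if df.empty:
        raise StatsInputError("empty design after listwise deletion")
    X = _design(df, covariates)
    return fit_logit(df[emotion], X, model_id=f"logit[{emotion}]")


def fit_sentiment_on_emotions(
    profiles: Sequence[EmotionProfile],
    sentiments: Sequence[SentimentScore],
    records: Sequence[ReviewRecord],
) -> RegressionResult:
    """compound ~ 6 emotion flags + drug + age + duration + rating year."""
    df = build_frame(records, profiles=profiles, sentiments=sentiments)
    df = df.dropna(subset=["drug", "age_band", "duration_band", "rating_year", "compound"])
    if df.empty:
        raise StatsInputError("empty design after listwise deletion")
    X = _design(df, ("drug", "age_band", "duration_band"), extra=list(PRIMARY_EMOTIONS) + ["rating_year"])
    return fit_ols(df["compound"], X, model_id="sentiment~emotions")


def fit_satisfaction_models(
    records: Sequence[ReviewRecord],
    sentiments: Sequence[SentimentScore],
) -> tuple[DeltaR2Result, RegressionResult, RegressionResult]:
    """Nested satisfaction models on identical rows.

    Model 1: satisfaction ~ sentiment + drug + age + duration + year;
    Model 2 drops sentiment.  The returned delta uses unadjusted R^2,
    which is non-negative by construction for nested least squares.
    """
    df = build_frame(records, sentiments=sentiments)
    df = df.dropna(
        subset=["satisfaction_5", "compound", "drug", "age_band", "duration_band", "rating_year"]
    )
    if df.empty:
        raise StatsInputError("empty design after listwise deletion")
    X2 = _design(df, ("drug", "age_band", "duration_band"), extra=["rating_year"])
    X1 = X2.copy()
    X1.insert(1, "sentiment", df["compound"].astype(float))
    m1 = fit_ols(df["satisfaction_5"], X1, model_id="satisfaction~sentiment+covariates")
    m2 = fit_ols(df["satisfaction_5"], X2, model_id="satisfaction~covariates")
    delta = DeltaR2Result.from_r2(
        m1.r_squared, m2.r_squared, m1.adj_r_squared, m2.adj_r_squared
    )
    return delta, m1, m2


def standardize_satisfaction(raw: int, scale: int) -> int:
    """Map a native Likert rating onto the 1-5 scale.

    10-point ratings convert by ceiling(raw/2), preserving integer levels
    and both endpoints.
    """
    if scale not in (5, 10):
        raise StatsInputError(f"unsupported satisfaction scale {scale}")
    if not (1 <= raw <= scale):
        raise StatsInputError(f"satisfaction {raw} outside [1, {scale}]")
    if scale == 5:
        return int(raw)
    return math.ceil(raw / 2)
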