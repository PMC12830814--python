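"""Quintile / per-SD logistic association models and the five nested
prediction models (base covariates, clinical covariates, and clinical plus
one of the three scores)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from metaprs.exceptions import FitError, InvalidConfigError

BASE_COVARIATES = ("age", "age2", "sex")
CLINICAL_COVARIATES = ("art", "statin", "bmi", "sbp", "smoking")
SCORE_COLUMNS = ("score_t2d", "score_meta_inflammation", "score_meta_lipids")


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    covariates: tuple[str, ...]
    score: str | None = None  # column name of the per-SD score term
    score_coding: str = "per_sd"  # or "quintile"

    def __post_init__(self) -> None:
        if self.score_coding not in ("per_sd", "quintile"):
            raise InvalidConfigError(f"bad score coding {self.score_coding!r}")


def default_specs(
    n_pcs: int = 10,
    include_platform: bool = True,
    include_art_statin: bool = True,
) -> list[ModelSpec]:
    """Models 1-5.  The reduced variant (no platform/ART/statin terms)
    matches the secondary-cohort analysis."""
    pcs = tuple(f"pc{i + 1}" for i in range(n_pcs))
    base = BASE_COVARIATES + pcs
    if include_platform:
        base = base + ("platform",)
    clinical = tuple(
        c
        for c in CLINICAL_COVARIATES
        if include_art_statin or c not in ("art", "statin")
    )
    m2 = base + clinical
    return [
        ModelSpec(1, base),
        ModelSpec(2, m2),
        ModelSpec(3, m2, score="score_t2d"),
        ModelSpec(4, m2, score="score_meta_inflammation"),
        ModelSpec(5, m2, score="score_meta_lipids"),
    ]


@dataclass
class EffectEstimate:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI does not bracket the odds ratio")


def quintile_bin(scores: np.ndarray) -> np.ndarray:
    """Quintile labels 1..5 with cut points at the in-cohort 20/40/60/80
    percentiles (linear-interpolation quantiles); values exactly on a cut
    fall in the lower bin."""
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(scores)) < 5:
        raise InvalidConfigError("need >= 5 distinct values to form quintiles")
    cuts = np.quantile(scores, [0.2, 0.4, 0.6, 0.8], method="linear")
    return 1 + np.searchsorted(cuts, scores, side="left")


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise FitError("missing values in design matrix")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise FitError("rank-deficient design matrix")


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import warnings

    _check_design(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # we raise FitError ourselves
            res = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    se = np.sqrt(np.diag(res.cov_params()))
    if np.any(~np.isfinite(se)) or np.any(np.abs(res.params) > 30):
        bad = X.columns[int(np.argmax(np.abs(res.params)))]
        raise FitError(f"separation suspected for term {bad!r}")
    return res


def fit_or_model(
    outcome: np.ndarray,
    score: np.ndarray,
    covariates: pd.DataFrame | None = None,
    coding: str = "per_sd",
) -> list[EffectEstimate]:
    """Odds ratios with Wald 95% CIs from a maximum-likelihood logistic
    fit.  ``coding="quintile"`` uses indicator terms for Q1, Q2, Q4, Q5
    with the middle fifth (Q3) as the omitted reference."""
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise FitError("outcome must contain both classes")
    parts: dict[str, np.ndarray] = {"const": np.ones(len(y))}
    if coding == "per_sd":
        terms = ["per_sd"]
        parts["per_sd"] = np.asarray(score, dtype=float)
    elif coding == "quintile":
        q = quintile_bin(np.asarray(score, dtype=float))
        terms = ["Q1", "Q2", "Q4", "Q5"]
        for t, level in zip(terms, (1, 2, 4, 5)):
            parts[t] = (q == level).astype(float)
    else:
        raise InvalidConfigError(f"unknown coding {coding!r}")
    if covariates is not None:
        for c in covariates.columns:
            parts[c] = covariates[c].to_numpy(dtype=float)
    X = pd.DataFrame(parts)
    res = _fit_logit(y, X)
    se = np.sqrt(np.diag(res.cov_params()))
    out = []
    for t in terms:
        i = X.columns.get_loc(t)
        coef = res.params[i]
        out.append(
            EffectEstimate(
                term=t,
                odds_ratio=float(np.exp(coef)),
                ci_low=float(np.exp(coef - 1.96 * se[i])),
                ci_high=float(np.exp(coef + 1.96 * se[i])),
                p_value=float(res.pvalues[i]),
                n=int(len(y)),
            )
        )
    return out


@dataclass
class BatteryFit:
    spec: ModelSpec
    params: pd.Series
    loglik: float
    loglik_null: float
    linear_predictor: np.ndarray
    fitted_prob: np.ndarray
    n: int


@dataclass
class BatteryResult:
    fits: dict[int, BatteryFit]
    outcome: np.ndarray
    rows: np.ndarray  # positional index of complete-case rows

    def __getitem__(self, model_id: int) -> BatteryFit:
        return self.fits[model_id]


def run_model_battery(
    data: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    outcome_col: str = "outcome",
) -> BatteryResult:
    """Fit all model specs on the shared complete-case rows of ``data``.

    ``data`` holds the outcome, every covariate named by the specs, and the
    per-SD score columns.  Aborts naming the model id if any fit fails.
    """
    specs = specs if specs is not None else default_specs()
    used: list[str] = [outcome_col]
    for spec in specs:
        used.extend(spec.covariates)
        if spec.score:
            used.append(spec.score)
    used = list(dict.fromkeys(used))
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise InvalidConfigError(f"battery input missing columns: {missing_cols}")
    cc = data[used].dropna()
    rows = np.asarray([data.index.get_loc(i) for i in cc.index])
    y = cc[outcome_col].to_numpy(dtype=float)

    llnull = float(
        sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    )
    fits: dict[int, BatteryFit] = {}
    for spec in specs:
        cols = list(spec.covariates) + ([spec.score] if spec.score else [])
        X = pd.concat(
            [pd.Series(1.0, index=cc.index, name="const"), cc[cols]], axis=1
        )
        try:
            res = _fit_logit(y, X)
        except FitError as exc:
            raise FitError(f"model {spec.model_id} failed: {exc}") from exc
        lp = X.to_numpy(dtype=float) @ res.params
        fits[spec.model_id] = BatteryFit(
            spec=spec,
            params=pd.Series(res.params, index=X.columns),
            loglik=float(res.llf),
            loglik_null=llnull,
            linear_predictor=lp,
            fitted_prob=1.0 / (1.0 + np.exp(-lp)),
            n=len(y),
        )
    return BatteryResult(fits=fits, outcome=y.astype(int), rows=rows)
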