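"""Meta-score construction: elastic-net logistic fit of the outcome on
standardized component scores (confounders unpenalized), model selection
by ten-fold cross-validated AUC, and the weighted-average combination

    meta_i = (sum_k beta_k * Z_ik) / (sum_k beta_k).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from metaprs.elasticnet import enet_path, lambda_path
from metaprs.exceptions import FitError, InvalidConfigError, ScoreError
from metaprs.scoring import StandardizedScoreMatrix

#: trait subsets of the two packaged meta-score presets
INFLAMMATION_TRAITS = ("T2D", "IL-1ra", "IL-6", "IL-8", "TNF-R1", "CRP")
LIPIDS_TRAITS = ("T2D", "LDL-C", "HDL-C", "TG")
PRESET_TRAITS = {"inflammation": INFLAMMATION_TRAITS, "lipids": LIPIDS_TRAITS}


@dataclass
class ElasticNetConfig:
    l1_grid: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0)
    path_length: int = 20
    lambda_min_ratio: float = 0.01
    n_folds: int = 10
    fold_seed: int = 0
    #: parsimony slack: select the largest penalty whose mean CV-AUC is
    #: within this many fold-SDs of the best mean.  The default 0 selects
    #: the exact CV-AUC maximum; positive values guard against the
    #: winner's curse of grid selection when screening for real signal.
    cv_slack_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise InvalidConfigError("n_folds must be >= 2")
        if not self.l1_grid:
            raise InvalidConfigError("l1_grid must be non-empty")
        if any(not (0.0 < a <= 1.0) for a in self.l1_grid):
            raise InvalidConfigError("mixing parameters must lie in (0, 1]")


@dataclass
class MetaPRSModel:
    """Frozen per-trait log-odds weights plus fit provenance."""

    traits: tuple[str, ...]
    beta: dict[str, float]
    l1_ratio: float = np.nan
    lam: float = np.nan
    cv_auc: float = np.nan
    standardization: str = "in-sample"
    covariate_names: tuple[str, ...] = ()

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[t] for t in self.traits])

    def to_json(self) -> str:
        return json.dumps(
            {
                "traits": list(self.traits),
                "beta": self.beta,
                "l1_ratio": self.l1_ratio,
                "lambda": self.lam,
                "cv_auc": self.cv_auc,
                "standardization": self.standardization,
                "covariate_names": list(self.covariate_names),
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "MetaPRSModel":
        d = json.loads(text)
        return cls(
            traits=tuple(d["traits"]),
            beta={k: float(v) for k, v in d["beta"].items()},
            l1_ratio=d.get("l1_ratio", np.nan),
            lam=d.get("lambda", np.nan),
            cv_auc=d.get("cv_auc", np.nan),
            standardization=d.get("standardization", "in-sample"),
            covariate_names=tuple(d.get("covariate_names", ())),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MetaPRSModel":
        return cls.from_json(Path(path).read_text())


def _fast_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks (ties count one half)."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    m = int(y.sum())
    n = len(y) - m
    if m == 0 or n == 0:
        raise FitError("AUC undefined: single outcome class")
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def fit_component_weights(
    Z: StandardizedScoreMatrix | pd.DataFrame,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    config: ElasticNetConfig | None = None,
    traits: tuple[str, ...] | None = None,
) -> MetaPRSModel:
    """Select per-trait log-odds weights by cross-validated AUC.

    The design is [intercept | trait Z columns | covariates]; only the
    trait columns are penalized.  Folds are stratified by outcome and
    drawn once from ``config.fold_seed``; the grid point (mixing
    parameter, penalty) with the highest mean out-of-fold AUC wins, ties
    preferring the larger penalty.
    """
    config = config or ElasticNetConfig()
    zdf = Z.z if isinstance(Z, StandardizedScoreMatrix) else Z
    if traits is not None:
        missing = [t for t in traits if t not in zdf.columns]
        if missing:
            raise ScoreError(f"missing trait columns: {missing}")
        zdf = zdf[list(traits)]
    trait_names = tuple(zdf.columns)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise FitError("outcome must contain both classes")

    cov_names: tuple[str, ...] = ()
    blocks = [np.ones((len(y), 1)), zdf.to_numpy(dtype=float)]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(covariates.columns)
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
            cov_names = tuple(f"cov{i}" for i in range(cov.shape[1]))
        blocks.append(cov)
    X = np.column_stack(blocks)
    if np.isnan(X).any():
        raise FitError("missing values in design matrix")
    k_traits = len(trait_names)
    pf = np.zeros(X.shape[1])
    pf[1 : 1 + k_traits] = 1.0

    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.fold_seed
    )
    folds = list(skf.split(X, y))
    for _, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2:
            raise FitError("a CV fold contains a single outcome class")

    best = None  # (auc, se_at_best, l1, lam_idx, lams, mean_auc_path)
    for l1 in config.l1_grid:
        lams = lambda_path(
            X, y, pf, l1, config.path_length, config.lambda_min_ratio
        )
        fold_aucs = np.zeros((len(folds), len(lams)))
        for f, (tr, te) in enumerate(folds):
            betas = enet_path(X[tr], y[tr], lams, l1, pf)
            lp = X[te] @ betas.T  # (n_te, n_lams)
            for i in range(len(lams)):
                fold_aucs[f, i] = _fast_auc(lp[:, i], y[te])
        mean_auc = fold_aucs.mean(axis=0)
        sd_auc = fold_aucs.std(axis=0, ddof=1)
        i_best = int(np.argmax(mean_auc))  # ties -> larger penalty
        if best is None or mean_auc[i_best] > best[0] + 1e-12:
            best = (
                float(mean_auc[i_best]), float(sd_auc[i_best]),
                l1, i_best, lams, mean_auc,
            )

    cv_auc, cv_sd, l1_sel, i_sel, lams, auc_path = best
    if config.cv_slack_sd > 0:
        ok = np.flatnonzero(auc_path >= cv_auc - config.cv_slack_sd * cv_sd)
        i_sel = int(ok[0])
        cv_auc = float(auc_path[i_sel])
    betas = enet_path(X, y, lams[: i_sel + 1], l1_sel, pf)
    beta_full = betas[-1]
    if not np.all(np.isfinite(beta_full)):
        raise FitError("non-finite coefficients at the selected grid point")
    beta = {t: float(beta_full[1 + i]) for i, t in enumerate(trait_names)}
    return MetaPRSModel(
        traits=trait_names,
        beta=beta,
        l1_ratio=float(l1_sel),
        lam=float(lams[i_sel]),
        cv_auc=cv_auc,
        covariate_names=cov_names,
    )


def _meta_combine(zdf: pd.DataFrame, model: MetaPRSModel) -> np.ndarray:
    missing = [t for t in model.traits if t not in zdf.columns]
    if missing:
        raise ScoreError(f"trait columns missing from score matrix: {missing}")
    b = model.beta_vector
    denom = float(b.sum())
    if denom == 0.0:
        raise ScoreError("weighted average undefined: sum of beta is zero")
    if denom < 0.0:
        raise ScoreError("sum of beta is negative; refusing to flip score sign")
    z = zdf[list(model.traits)].to_numpy(dtype=float)
    return (z @ b) / denom


def build_metaprs(
    Z: StandardizedScoreMatrix | pd.DataFrame, model: MetaPRSModel
) -> np.ndarray:
    """Weighted average of standardized component scores."""
    zdf = Z.z if isinstance(Z, StandardizedScoreMatrix) else Z
    return _meta_combine(zdf, model)


def apply_metaprs(
    Z_new: StandardizedScoreMatrix | pd.DataFrame, model: MetaPRSModel
) -> np.ndarray:
    """Apply a frozen model to a new cohort (no refitting; trait columns
    matched by label)."""
    zdf = Z_new.z if isinstance(Z_new, StandardizedScoreMatrix) else Z_new
    return _meta_combine(zdf, model)
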