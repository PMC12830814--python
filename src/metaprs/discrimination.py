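"""Discrimination statistics: AUC with DeLong variance, the paired DeLong
test, Nagelkerke pseudo-R2, continuous NRI with bootstrap CI, and the
assembled per-model report."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from metaprs.epi import BatteryResult
from metaprs.exceptions import FitError, InvalidConfigError


@dataclass
class ROCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_events: int
    n_nonevents: int


@dataclass
class NRIResult:
    nri: float
    event_component: float
    nonevent_component: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components via midranks.

    V10 (per event) and V01 (per nonevent); both have mean equal to the
    Mann-Whitney AUC with ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    cases = scores[y == 1]
    controls = scores[y == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise FitError("AUC undefined: single outcome class")
    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    return v10, v01


def auc(predictions: np.ndarray, outcome: np.ndarray) -> ROCResult:
    """Mann-Whitney AUC with DeLong SE and Wald 95% CI (clipped to [0,1])."""
    v10, v01 = _placements(predictions, outcome)
    a = float(np.mean(v10))
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(max(var, 0.0)))
    return ROCResult(
        auc=a,
        se=se,
        ci_low=float(max(0.0, a - 1.96 * se)),
        ci_high=float(min(1.0, a + 1.96 * se)),
        n_events=m,
        n_nonevents=n,
    )


def delong_test(
    pred_a: np.ndarray, pred_b: np.ndarray, outcome: np.ndarray
) -> tuple[float, float, float]:
    """Paired DeLong test for two correlated AUCs on identical rows.

    Returns (AUC_A - AUC_B, z, two-sided p)."""
    if len(pred_a) != len(pred_b) or len(pred_a) != len(outcome):
        raise InvalidConfigError("prediction vectors must share rows")
    va10, va01 = _placements(pred_a, outcome)
    vb10, vb01 = _placements(pred_b, outcome)
    auc_a, auc_b = float(np.mean(va10)), float(np.mean(vb10))
    diff = auc_a - auc_b
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        if abs(diff) < 1e-15:
            return 0.0, 0.0, 1.0  # identical predictors: degenerate case
        raise FitError("zero DeLong variance with unequal AUCs")
    z = diff / se
    return float(diff), float(z), float(2.0 * norm.sf(abs(z)))


def nagelkerke_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Cox-Snell R2 rescaled by its maximum 1 - exp(2*L0/n)."""
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    if loglik_full < loglik_null - 1e-8:
        raise InvalidConfigError("full-model log-likelihood below null")
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_full))
    max_cs = 1.0 - np.exp((2.0 / n) * loglik_null)
    if max_cs <= 0.0:
        return 0.0
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))


def _nri_point(
    risk_old: np.ndarray, risk_new: np.ndarray, outcome: np.ndarray
) -> tuple[float, float, float]:
    ev = outcome == 1
    up = risk_new > risk_old
    down = risk_new < risk_old
    p_up_e = np.mean(up[ev])
    p_down_e = np.mean(down[ev])
    p_up_ne = np.mean(up[~ev])
    p_down_ne = np.mean(down[~ev])
    event = float(p_up_e - p_down_e)
    nonevent = float(p_down_ne - p_up_ne)
    return event + nonevent, event, nonevent


def continuous_nri(
    risk_old: np.ndarray,
    risk_new: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> NRIResult:
    """Category-free NRI with a seeded percentile bootstrap over
    individuals.  Ties in risk contribute to neither direction."""
    risk_old = np.asarray(risk_old, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    if np.any((risk_old < 0) | (risk_old > 1) | (risk_new < 0) | (risk_new > 1)):
        raise InvalidConfigError("risks must lie in [0, 1]")
    if len({len(risk_old), len(risk_new), len(outcome)}) != 1:
        raise InvalidConfigError("inputs must share rows")
    if outcome.sum() == 0 or outcome.sum() == len(outcome):
        raise FitError("NRI undefined: single outcome class")
    nri, event, nonevent = _nri_point(risk_old, risk_new, outcome)

    rng = np.random.default_rng(seed)
    n = len(outcome)
    boots = []
    attempts = 0
    while len(boots) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        ysum = outcome[idx].sum()
        if ysum == 0 or ysum == n:
            continue  # resample: both classes required
        boots.append(_nri_point(risk_old[idx], risk_new[idx], outcome[idx])[0])
    boots = np.asarray(boots)
    lo, hi = np.percentile(boots, [2.5, 97.5]) if len(boots) else (np.nan, np.nan)
    return NRIResult(
        nri=nri,
        event_component=event,
        nonevent_component=nonevent,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=len(boots),
        seed=seed,
    )


@dataclass
class DiscriminationReport:
    """Per-model discrimination table plus pairwise DeLong p-values.

    ``table`` has one row per model with AUC (with CI), full-model
    Nagelkerke R2, score-specific R2 (increment over Model 2), and NRI
    against both reference models.  Percentages use the 0-100 scale.
    """

    table: pd.DataFrame
    delong: pd.DataFrame
    n_boot: int = 0
    seed: int = 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "delong_p": {
                f"{a}_vs_{b}": float(self.delong.loc[a, b])
                for a in self.delong.index
                for b in self.delong.columns
                if a < b
            },
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def build_report(
    battery: BatteryResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> DiscriminationReport:
    """Assemble the per-model discrimination table.

    NRI convention: Model 2 is compared against Model 1; Models 3-5 are
    compared against Model 2 (column ``nri_vs_m2``) and, for reference,
    against Model 1 (column ``nri_vs_m1``).
    """
    y = battery.outcome
    ids = sorted(battery.fits)
    rocs = {i: auc(battery[i].linear_predictor, y) for i in ids}
    r2 = {
        i: nagelkerke_r2(battery[i].loglik_null, battery[i].loglik, battery[i].n)
        for i in ids
    }
    rows = []
    for i in ids:
        roc = rocs[i]
        row = {
            "model": i,
            "auc_pct": 100 * roc.auc,
            "auc_ci_low_pct": 100 * roc.ci_low,
            "auc_ci_high_pct": 100 * roc.ci_high,
            "full_r2_pct": 100 * r2[i],
            "prs_r2_pct": np.nan,
            "nri_vs_m1_pct": np.nan,
            "nri_vs_m1_ci_low_pct": np.nan,
            "nri_vs_m1_ci_high_pct": np.nan,
            "nri_vs_m2_pct": np.nan,
            "nri_vs_m2_ci_low_pct": np.nan,
            "nri_vs_m2_ci_high_pct": np.nan,
        }
        if i >= 3 and 2 in battery.fits:
            row["prs_r2_pct"] = 100 * (r2[i] - r2[2])
        for ref, tag in ((1, "nri_vs_m1"), (2, "nri_vs_m2")):
            if i > ref and ref in battery.fits:
                res = continuous_nri(
                    battery[ref].fitted_prob,
                    battery[i].fitted_prob,
                    y,
                    n_boot=n_boot,
                    seed=seed + 1000 * ref + i,
                )
                row[f"{tag}_pct"] = 100 * res.nri
                row[f"{tag}_ci_low_pct"] = 100 * res.ci_low
                row[f"{tag}_ci_high_pct"] = 100 * res.ci_high
        rows.append(row)

    delong_mat = pd.DataFrame(
        np.ones((len(ids), len(ids))), index=ids, columns=ids
    )
    for a in ids:
        for b in ids:
            if a < b:
                _, _, p = delong_test(
                    battery[a].linear_predictor, battery[b].linear_predictor, y
                )
                delong_mat.loc[a, b] = p
                delong_mat.loc[b, a] = p
    return DiscriminationReport(
        table=pd.DataFrame(rows), delong=delong_mat, n_boot=n_boot, seed=seed
    )
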