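"""Variant/sample QC, principal components, and cross-platform
harmonization.

Filters follow a fixed order so that each removed item carries exactly one
(first-failing) reason code: call rate -> MAF -> HWE -> strand-ambiguous ->
multi-allelic.  HWE and pi-hat operate on hard-called genotypes (dosages
rounded; entries farther than 0.1 from an integer treated as missing for
those tests only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from metaprs.dosage import DosageMatrix, is_ambiguous
from metaprs.exceptions import EmptyPanelError, InvalidConfigError


@dataclass
class QCThresholds:
    variant_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-05
    sample_call_rate_min: float = 0.90
    pihat_max: float = 0.9
    platform_p_remove: float = 5e-08
    n_pcs: int = 10

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "sample_call_rate_min", "pihat_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.1):
                raise InvalidConfigError(f"{name} out of range: {v}")
        for name in ("hwe_p_min", "platform_p_remove"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidConfigError(f"{name} must lie in (0,1): {v}")


#: named presets mirroring the cohort-specific thresholds
PRESETS = {
    "cnics": QCThresholds(
        variant_call_rate_min=0.95,
        maf_min=0.01,
        hwe_p_min=1e-05,
        sample_call_rate_min=0.90,
        pihat_max=0.9,
        platform_p_remove=5e-08,
    ),
    # first genotyping batch: missing rate > 10% excluded, HWE p < 1e-12
    "regards1": QCThresholds(
        variant_call_rate_min=0.90,
        maf_min=0.01,
        hwe_p_min=1e-12,
        sample_call_rate_min=0.90,
        pihat_max=0.9,
        platform_p_remove=5e-08,
    ),
    # second batch: missing rate > 5% excluded, HWE p < 1e-05
    "regards2": QCThresholds(
        variant_call_rate_min=0.95,
        maf_min=0.01,
        hwe_p_min=1e-05,
        sample_call_rate_min=0.98,
        pihat_max=0.9,
        platform_p_remove=5e-08,
    ),
}


@dataclass
class QCReport:
    """Per-variant and per-sample metrics with pass/fail reason codes."""

    variants: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n_variants_removed(self) -> int:
        if self.variants is None:
            return 0
        return int((~self.variants["pass"]).sum())

    @property
    def n_samples_removed(self) -> int:
        if self.samples is None:
            return 0
        return int((~self.samples["pass"]).sum())

    def summary(self) -> dict:
        out: dict = {"notes": list(self.notes)}
        if self.variants is not None:
            fails = self.variants.loc[~self.variants["pass"], "reason"]
            out["variants_removed"] = self.n_variants_removed
            out["variant_reasons"] = fails.value_counts().to_dict()
        if self.samples is not None:
            fails = self.samples.loc[~self.samples["pass"], "reason"]
            out["samples_removed"] = self.n_samples_removed
            out["sample_reasons"] = fails.value_counts().to_dict()
        return out


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums the probabilities, given the allele counts, of every heterozygote
    count whose conditional probability does not exceed that of the
    observed table.  No mid-p correction.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("empty genotype table")
    n_AA, n_Aa, n_aa = counts
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    # heterozygote counts sharing the observed parity, 0..rare
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logsumexp(logp)
    obs = logp[np.flatnonzero(hets == n_Aa)[0]]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-12])))
    return min(p, 1.0)


def _hwe_from_calls(calls: np.ndarray) -> np.ndarray:
    """HWE exact p per variant from an (n, m) hard-call matrix."""
    out = np.ones(calls.shape[1])
    for j in range(calls.shape[1]):
        g = calls[:, j]
        g = g[g >= 0]
        if len(g) == 0:
            continue
        out[j] = hwe_exact_p(
            int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2))
        )
    return out


def variant_qc(
    dosages: DosageMatrix, thresholds: QCThresholds
) -> tuple[DosageMatrix, QCReport]:
    """Remove variants failing call rate, MAF, HWE, ambiguity or
    multi-allelic checks, in that order."""
    if dosages.n_variants == 0:
        raise EmptyPanelError("no variants in input")
    call_rate = dosages.variant_call_rates()
    maf = dosages.mafs()
    calls = dosages.hard_calls()
    hwe_p = _hwe_from_calls(calls)
    var = dosages.variants
    ambiguous = np.array(
        [is_ambiguous(r, a) for r, a in zip(var["ref"], var["alt"])]
    )
    keys = var["chrom"].astype(str) + ":" + var["pos"].astype(str)
    multi = (
        keys.duplicated(keep=False).to_numpy()
        | var["alt"].astype(str).str.contains(",").to_numpy()
    )

    reason = np.full(dosages.n_variants, "", dtype=object)
    reason[multi] = "multi_allelic"
    reason[ambiguous] = "ambiguous_strand"
    reason[hwe_p < thresholds.hwe_p_min] = "hwe"
    reason[maf < thresholds.maf_min] = "maf"
    reason[call_rate < thresholds.variant_call_rate_min] = "call_rate"
    keep = reason == ""

    report = QCReport(
        variants=pd.DataFrame(
            {
                "id": var["id"],
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "pass": keep,
                "reason": reason,
            }
        )
    )
    if not keep.any():
        raise EmptyPanelError("variant QC removed every variant")
    return dosages.subset_variants(keep), report


def pihat_matrix(dosages: DosageMatrix) -> np.ndarray:
    """Method-of-moments pi-hat for all sample pairs from IBS counts,
    using sample allele frequencies; estimates clipped to [0, 1]."""
    calls = dosages.hard_calls().astype(float)
    valid = calls >= 0
    g = np.where(valid, calls, 0.0)
    n_obs = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, g.sum(axis=0) / (2.0 * np.maximum(n_obs, 1)), 0.5)
    p = np.clip(p, 1e-6, 1 - 1e-6)
    q = 1.0 - p
    e0_ibd0 = 2.0 * p**2 * q**2
    e1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_ibd0 = 1.0 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2.0 * p * q
    e2_ibd1 = 1.0 - e1_ibd1

    a = [(valid & (calls == k)).astype(float) for k in (0.0, 1.0, 2.0)]
    v = valid.astype(float)
    n_pair = v @ v.T
    obs2 = a[0] @ a[0].T + a[1] @ a[1].T + a[2] @ a[2].T
    obs0 = a[0] @ a[2].T + a[2] @ a[0].T
    obs1 = n_pair - obs0 - obs2

    def pair_expect(e: np.ndarray) -> np.ndarray:
        return (v * e) @ v.T

    E0_0, E1_0, E2_0 = pair_expect(e0_ibd0), pair_expect(e1_ibd0), pair_expect(e2_ibd0)
    E1_1, E2_1 = pair_expect(e1_ibd1), pair_expect(e2_ibd1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(E0_0 > 0, obs0 / E0_0, 0.0)
        p1 = np.where(E1_1 > 0, (obs1 - p0 * E1_0) / E1_1, 0.0)
        p2 = np.where(n_pair > 0, (obs2 - p0 * E2_0 - p1 * E2_1) / n_pair, 0.0)
    pihat = np.clip(0.5 * p1 + p2, 0.0, 1.0)
    np.fill_diagonal(pihat, 1.0)
    return pihat


def sample_qc(
    dosages: DosageMatrix, thresholds: QCThresholds
) -> tuple[DosageMatrix, QCReport]:
    """Remove low-call-rate samples, then one member of every pair whose
    pi-hat exceeds the threshold (the lower-call-rate member; ties break to
    the later sample index)."""
    call_rate = dosages.sample_call_rates()
    low = call_rate < thresholds.sample_call_rate_min
    reason = np.full(dosages.n_individuals, "", dtype=object)
    reason[low] = "call_rate"
    max_pihat = np.zeros(dosages.n_individuals)
    notes = []

    kept_idx = np.flatnonzero(~low)
    if len(kept_idx) < 2:
        notes.append("fewer than 2 samples after call-rate filter; pi-hat skipped")
    else:
        sub = dosages.subset_samples(kept_idx)
        ph = pihat_matrix(sub)
        off = ph - np.diag(np.diag(ph))
        max_pihat[kept_idx] = off.max(axis=1)
        removed_local: set[int] = set()
        ii, jj = np.where(np.triu(ph, k=1) > thresholds.pihat_max)
        for i, j in zip(ii, jj):
            if i in removed_local or j in removed_local:
                continue
            cr_i, cr_j = call_rate[kept_idx[i]], call_rate[kept_idx[j]]
            drop = j if cr_i >= cr_j else i  # tie -> later index
            removed_local.add(int(drop))
        for loc in removed_local:
            reason[kept_idx[loc]] = "pihat"

    keep = reason == ""
    report = QCReport(
        samples=pd.DataFrame(
            {
                "sample": dosages.samples,
                "call_rate": call_rate,
                "max_pihat": max_pihat,
                "pass": keep,
                "reason": reason,
            }
        ),
        notes=notes,
    )
    if not keep.any():
        raise EmptyPanelError("sample QC removed every sample")
    return dosages.subset_samples(keep), report


def compute_pcs(dosages: DosageMatrix, n_pcs: int = 10) -> np.ndarray:
    """Top principal components of the standardized dosage matrix.

    Per variant: center by 2*p_hat, scale by sqrt(2*p_hat*(1-p_hat)),
    missing entries set to 0 after centering; returns the leading left
    singular vectors (unit-norm columns, ordered by singular value)."""
    if n_pcs >= min(dosages.n_individuals, dosages.n_variants):
        raise InvalidConfigError(
            "n_pcs must be smaller than both matrix dimensions"
        )
    d = dosages.dosages
    p = np.nanmean(d, axis=0) / 2.0
    var_ok = (p > 0) & (p < 1) & np.isfinite(p)
    if not var_ok.all():
        warnings.warn(
            f"excluding {int((~var_ok).sum())} zero-variance variants from PCA",
            stacklevel=2,
        )
    d = d[:, var_ok]
    p = p[var_ok]
    x = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x = np.where(np.isnan(x), 0.0, x)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    u = u[:, :n_pcs]
    # deterministic sign: largest-magnitude loading positive
    for k in range(u.shape[1]):
        if u[np.argmax(np.abs(u[:, k])), k] < 0:
            u[:, k] = -u[:, k]
    return u


def _logistic_irls(
    X: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None,
    max_iter: int = 30, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic fit; returns (beta, SEs, converged)."""
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    converged = False
    cov = np.full((k, k), np.nan)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-10:
            break
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.nan), False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            try:
                cov = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                return beta, np.full(k, np.nan), False
            break
    if not converged:
        return beta, np.full(k, np.nan), False
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return beta, se, True


def _platform_assoc_p(
    dosage_col: np.ndarray, y: np.ndarray, covars: np.ndarray,
    beta_init: np.ndarray,
) -> tuple[float, str]:
    """Wald p for the dosage coefficient in logit(platform) ~ dosage + PCs."""
    d = dosage_col.copy()
    miss = np.isnan(d)
    if miss.any():
        d[miss] = np.nanmean(d) if np.isfinite(np.nanmean(d)) else 0.0
    if np.std(d) == 0:
        return 1.0, ""
    X = np.column_stack([covars[:, :1], d, covars[:, 1:]])
    beta0 = np.insert(beta_init, 1, 0.0)
    beta, se, ok = _logistic_irls(X, y, beta0)
    if not ok or not np.isfinite(se[1]) or se[1] > 1e3 or abs(beta[1]) > 20:
        return 0.0, "separation"
    z = beta[1] / se[1]
    return float(2.0 * norm.sf(abs(z))), ""


def platform_harmonize(
    dosages: DosageMatrix,
    platform: np.ndarray,
    pcs: np.ndarray,
    p_remove: float = 5e-08,
) -> tuple[DosageMatrix, QCReport]:
    """Remove variants associated with genotyping platform.

    Per variant, logistic regression of the platform indicator on dosage
    plus the PCs; variants with dosage-coefficient Wald p below
    ``p_remove`` are removed.  With more than two platforms the test is
    applied to successive merges (platform 0 vs 1, merged vs 2, ...).
    Separated fits are removed with reason ``separation``.
    """
    platform = np.asarray(platform)
    if len(platform) != dosages.n_individuals:
        raise InvalidConfigError("platform vector length mismatch")
    groups = sorted(pd.unique(platform).tolist())
    if len(groups) < 2:
        warnings.warn("single platform: harmonization is a no-op", stacklevel=2)
        report = QCReport(
            variants=pd.DataFrame(
                {
                    "id": dosages.variants["id"],
                    "platform_p": np.ones(dosages.n_variants),
                    "pass": np.ones(dosages.n_variants, dtype=bool),
                    "reason": np.full(dosages.n_variants, "", dtype=object),
                }
            )
        )
        return dosages, report

    m = dosages.n_variants
    min_p = np.ones(m)
    reason = np.full(m, "", dtype=object)
    merged = platform == groups[0]
    for g in groups[1:]:
        in_g = platform == g
        rows = np.flatnonzero(merged | in_g)
        y = in_g[rows].astype(float)
        pc_block = pcs[rows]
        pc_block = pc_block[:, np.std(pc_block, axis=0) > 0]
        covars = np.column_stack([np.ones(len(rows)), pc_block])
        beta_cov, _, _ = _logistic_irls(covars, y)
        for j in range(m):
            if reason[j] == "separation":
                continue
            p, flag = _platform_assoc_p(
                dosages.dosages[rows, j], y, covars, beta_cov
            )
            if flag:
                reason[j] = flag
            min_p[j] = min(min_p[j], p)
        merged = merged | in_g

    fail = (min_p < p_remove) | (reason == "separation")
    reason[fail & (reason == "")] = "platform_association"
    keep = ~fail
    report = QCReport(
        variants=pd.DataFrame(
            {
                "id": dosages.variants["id"],
                "platform_p": min_p,
                "pass": keep,
                "reason": reason,
            }
        )
    )
    if not keep.any():
        raise EmptyPanelError("platform harmonization removed every variant")
    return dosages.subset_variants(keep), report
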