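"""Synthetic cohort generator with known ground truth.

Generates independent-variant genotype dosages, sparse per-trait scoring
files (with configurable allele swaps and strand flips), covariates,
platform labels, an optional platform batch artefact, and a binary outcome
from a logistic model on the standardized true component scores.

All randomness derives from one master seed; each stage uses a
deterministic child stream whose derivation is recorded in the truth dict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from metaprs.dosage import COMPLEMENT, DosageMatrix
from metaprs.exceptions import InvalidConfigError
from metaprs import scoring as _scoring

#: component traits: disease, inflammation markers, lipids
DEFAULT_TRAITS = (
    "T2D",
    "IL-1ra",
    "IL-6",
    "IL-8",
    "TNF-R1",
    "CRP",
    "LDL-C",
    "HDL-C",
    "TG",
)

COVARIATE_NAMES = ("age", "age2", "sex", "bmi", "sbp", "smoking", "statin", "art")

# stage tags -> child-stream index appended to the master seed
_STAGES = {
    "genotypes": 1,
    "scoring": 2,
    "covariates": 3,
    "phenotype": 4,
    "batch": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the master seed."""
    return np.random.default_rng([int(seed), _STAGES[stage]])


@dataclass
class SimConfig:
    """Generative parameters for a synthetic cohort."""

    n_individuals: int = 1000
    n_variants: int = 500
    n_traits: int = 9
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    dosage_noise_sd: float = 0.0
    ambiguous_fraction: float = 0.0
    n_platforms: int = 2
    n_ancestries: int = 1
    ancestry_freq_shift: float = 0.0
    batch_variant_fraction: float = 0.0
    batch_delta: float = 0.4
    trait_variant_fraction: float = 0.3
    swap_fraction: float = 0.0
    flip_fraction: float = 0.0
    weight_sd: float = 1.0
    trait_effects: tuple[float, ...] = ()
    covariate_effects: dict[str, float] = field(default_factory=dict)
    intercept: float = float(logit(0.2))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traits < 1:
            raise InvalidConfigError("n_traits must be >= 1")
        self.trait_names = tuple(self.trait_names)[: self.n_traits]
        if len(self.trait_names) < self.n_traits:
            extra = [
                f"trait{i}" for i in range(len(self.trait_names), self.n_traits)
            ]
            self.trait_names = self.trait_names + tuple(extra)
        if not self.trait_effects:
            self.trait_effects = (0.0,) * self.n_traits
        self.trait_effects = tuple(float(g) for g in self.trait_effects)
        if len(self.trait_effects) != self.n_traits:
            raise InvalidConfigError("trait_effects length must equal n_traits")
        unknown = set(self.covariate_effects) - set(COVARIATE_NAMES)
        if unknown:
            raise InvalidConfigError(f"unknown covariate effects: {unknown}")

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise InvalidConfigError("n_individuals must be >= 1")
        if self.n_variants < 1:
            raise InvalidConfigError("n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie in (0, 0.5]")
        for name in (
            "missing_rate",
            "ambiguous_fraction",
            "batch_variant_fraction",
            "trait_variant_fraction",
            "swap_fraction",
            "flip_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.n_platforms < 1:
            raise InvalidConfigError("n_platforms must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_names"] = list(self.trait_names)
        d["trait_effects"] = list(self.trait_effects)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class SyntheticCohort:
    """A complete simulated dataset plus its generative truth."""

    dosages: DosageMatrix
    scoring_files: list[_scoring.ScoringFile]
    covariates: pd.DataFrame
    outcome: np.ndarray
    platform: np.ndarray
    truth: dict

    def __post_init__(self) -> None:
        n = self.dosages.n_individuals
        if not (
            len(self.covariates) == len(self.outcome) == len(self.platform) == n
        ):
            raise InvalidConfigError("cohort component row counts disagree")
        if not np.isin(self.outcome, (0, 1)).all():
            raise InvalidConfigError("outcome must be binary 0/1")


_NONAMBIG_PAIRS = [
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if r != a and COMPLEMENT[r] != a
]
_AMBIG_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def simulate_genotypes(config: SimConfig) -> DosageMatrix:
    """Independent variants: dosage ~ Binomial(2, p_v) (+ optional noise,
    clipped to [0,2]); per-variant alt frequency uniform on ``maf_range``."""
    config.validate()
    rng = stage_rng(config.seed, "genotypes")
    n, m = config.n_individuals, config.n_variants
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    ancestry = rng.integers(0, config.n_ancestries, size=n)
    if config.n_ancestries > 1 and config.ancestry_freq_shift > 0:
        shift = rng.uniform(
            -config.ancestry_freq_shift, config.ancestry_freq_shift, size=m
        )
        p_strat = np.clip(p[None, :] + shift[None, :] * np.arange(
            config.n_ancestries
        )[:, None], 0.01, 0.99)
        dosages = rng.binomial(2, p_strat[ancestry, :]).astype(float)
    else:
        dosages = rng.binomial(2, np.broadcast_to(p, (n, m))).astype(float)

    if config.dosage_noise_sd > 0:
        dosages = np.clip(
            dosages + rng.normal(0.0, config.dosage_noise_sd, size=(n, m)),
            0.0,
            2.0,
        )
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = np.nan

    n_ambig = int(round(config.ambiguous_fraction * m))
    ambig_idx = rng.choice(m, size=n_ambig, replace=False) if n_ambig else []
    ambig_set = set(np.asarray(ambig_idx).tolist())
    refs, alts = [], []
    for j in range(m):
        pairs = _AMBIG_PAIRS if j in ambig_set else _NONAMBIG_PAIRS
        r, a = pairs[rng.integers(0, len(pairs))]
        refs.append(r)
        alts.append(a)
    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1:07d}" for j in range(m)],
            "chrom": [str(1 + (j % 22)) for j in range(m)],
            "pos": [10_000 + 100 * j for j in range(m)],
            "ref": refs,
            "alt": alts,
        }
    )
    samples = [f"S{i:06d}" for i in range(n)]
    dm = DosageMatrix(dosages, variants, samples)
    dm.variants.attrs["true_freqs"] = p
    dm.variants.attrs["ancestry"] = ancestry
    return dm


def simulate_scoring_files(
    config: SimConfig, dosages: DosageMatrix
) -> list[_scoring.ScoringFile]:
    """Sparse zero-mean weight vectors per trait, written with a
    ``swap_fraction`` of effect/other alleles swapped and a
    ``flip_fraction`` strand-complemented to exercise harmonization."""
    config.validate()
    rng = stage_rng(config.seed, "scoring")
    m = dosages.n_variants
    m_k = max(1, int(round(config.trait_variant_fraction * m)))
    files = []
    var = dosages.variants
    for trait in config.trait_names:
        idx = np.sort(rng.choice(m, size=m_k, replace=False))
        w_alt = rng.normal(0.0, config.weight_sd, size=m_k)
        swap = rng.random(m_k) < config.swap_fraction
        flip = rng.random(m_k) < config.flip_fraction
        eff, oth, weights = [], [], []
        for j, sw, fl, w in zip(idx, swap, flip, w_alt):
            ea, oa, wt = var["alt"][j], var["ref"][j], w
            if sw:
                # written against the other allele: weight sign flips
                ea, oa, wt = oa, ea, -wt
            if fl:
                ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
            eff.append(ea)
            oth.append(oa)
            weights.append(wt)
        records = pd.DataFrame(
            {
                "rsID": var["id"].to_numpy()[idx],
                "chr_name": var["chrom"].to_numpy()[idx],
                "chr_position": var["pos"].to_numpy()[idx],
                "effect_allele": eff,
                "other_allele": oth,
                "effect_weight": np.asarray(weights, dtype=float),
            }
        )
        files.append(_scoring.ScoringFile(trait_name=trait, records=records))
    return files


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    config.validate()
    rng = stage_rng(config.seed, "covariates")
    n = config.n_individuals
    df = pd.DataFrame(
        {
            "age": rng.normal(50.0, 10.0, size=n).round(1),
            "sex": rng.integers(0, 2, size=n),
            "bmi": rng.normal(28.0, 5.0, size=n).clip(15, 60).round(1),
            "sbp": rng.normal(125.0, 15.0, size=n).clip(80, 220).round(1),
            "smoking": (rng.random(n) < 0.25).astype(int),
            "statin": (rng.random(n) < 0.20).astype(int),
            "art": (rng.random(n) < 0.50).astype(int),
            "platform": rng.integers(0, config.n_platforms, size=n),
        },
        index=[f"S{i:06d}" for i in range(n)],
    )
    df.index.name = "sample_id"
    return df


def _covariate_terms(config: SimConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Linear predictor contribution of covariates; continuous covariates
    are centered at their generative means so the intercept stays the
    baseline log-odds."""
    eff = config.covariate_effects
    lp = np.zeros(len(covariates))
    age_c = covariates["age"].to_numpy() - 50.0
    centered = {
        "age": age_c,
        "age2": age_c**2,
        "sex": covariates["sex"].to_numpy(),
        "bmi": covariates["bmi"].to_numpy() - 28.0,
        "sbp": covariates["sbp"].to_numpy() - 125.0,
        "smoking": covariates["smoking"].to_numpy(),
        "statin": covariates["statin"].to_numpy(),
        "art": covariates["art"].to_numpy(),
    }
    for name, beta in eff.items():
        lp += float(beta) * centered[name]
    return lp


def true_score_matrix(
    config: SimConfig,
    dosages: DosageMatrix,
    scoring_files: list[_scoring.ScoringFile],
) -> pd.DataFrame:
    """In-sample-standardized true component scores Z*_k."""
    cols = {}
    for sf in scoring_files:
        hmap = _scoring.harmonize(sf, dosages)
        raw, _ = _scoring.compute_prs(dosages, sf, hmap)
        z, _, _ = _scoring.standardize(raw)
        cols[sf.trait_name] = z
    return pd.DataFrame(cols, index=list(dosages.samples))


def simulate_phenotype(
    config: SimConfig,
    z_true: pd.DataFrame,
    covariates: pd.DataFrame,
) -> np.ndarray:
    """Bernoulli outcome with P(Y=1) = expit(alpha + sum_k gamma_k Z*_k +
    covariate terms)."""
    config.validate()
    rng = stage_rng(config.seed, "phenotype")
    lp = np.full(len(z_true), float(config.intercept))
    for gamma, trait in zip(config.trait_effects, config.trait_names):
        lp += gamma * z_true[trait].to_numpy()
    lp += _covariate_terms(config, covariates)
    if not np.all(np.isfinite(lp)):
        raise InvalidConfigError("non-finite linear predictor in phenotype model")
    return (rng.random(len(lp)) < expit(lp)).astype(int)


def inject_platform_batch_effect(
    dosages: DosageMatrix,
    platform: np.ndarray,
    config: SimConfig,
) -> tuple[DosageMatrix, np.ndarray]:
    """Shift the alt-allele frequency of a ``batch_variant_fraction`` of
    variants by ``batch_delta`` on platform 0 only (dosages redrawn there;
    the missingness pattern is preserved).  Returns (new matrix, affected
    variant indices)."""
    config.validate()
    n_affected = int(round(config.batch_variant_fraction * dosages.n_variants))
    if n_affected == 0:
        return dosages, np.array([], dtype=int)
    rng = stage_rng(config.seed, "batch")
    affected = np.sort(
        rng.choice(dosages.n_variants, size=n_affected, replace=False)
    )
    out = dosages.copy()
    rows = np.flatnonzero(np.asarray(platform) == 0)
    p = np.nanmean(dosages.dosages[:, affected], axis=0) / 2.0
    p_shift = np.clip(p + config.batch_delta, 0.01, 0.99)
    block = out.dosages[np.ix_(rows, affected)]
    redrawn = rng.binomial(
        2, np.broadcast_to(p_shift, block.shape)
    ).astype(float)
    redrawn[np.isnan(block)] = np.nan
    out.dosages[np.ix_(rows, affected)] = redrawn
    return out, affected


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Run every generative stage and bundle the results with the truth."""
    config.validate()
    dosages = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    platform = covariates["platform"].to_numpy()
    scoring_files = simulate_scoring_files(config, dosages)
    z_true = true_score_matrix(config, dosages, scoring_files)
    outcome = simulate_phenotype(config, z_true, covariates)
    dosages, affected = inject_platform_batch_effect(dosages, platform, config)
    truth = {
        "config": config.to_dict(),
        "stage_seeds": {k: [config.seed, v] for k, v in _STAGES.items()},
        "batch_affected_variants": dosages.variants["id"]
        .to_numpy()[affected]
        .tolist(),
        "prevalence": float(np.mean(outcome)),
    }
    return SyntheticCohort(
        dosages=dosages,
        scoring_files=scoring_files,
        covariates=covariates,
        outcome=outcome,
        platform=platform,
        truth=truth,
    )
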