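"""End-to-end orchestration on synthetic data: simulate -> QC/harmonize ->
score -> 70/30 split -> train meta models -> apply frozen models to the
validation cohort -> association tables -> discrimination report."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from metaprs import discrimination as disc
from metaprs import epi, meta, qc
from metaprs.exceptions import InvalidConfigError
from metaprs.scoring import score_matrix, standardize
from metaprs.synthetic import SimConfig, simulate_cohort


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    qc_preset: str = "cnics"
    enet: meta.ElasticNetConfig = field(default_factory=meta.ElasticNetConfig)
    split_fraction: float = 0.70
    split_seed: int = 0
    n_pcs: int = 10
    n_boot: int = 200
    eval_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "qc_preset": self.qc_preset,
            "enet": {
                "l1_grid": list(self.enet.l1_grid),
                "path_length": self.enet.path_length,
                "lambda_min_ratio": self.enet.lambda_min_ratio,
                "n_folds": self.enet.n_folds,
                "fold_seed": self.enet.fold_seed,
            },
            "split_fraction": self.split_fraction,
            "split_seed": self.split_seed,
            "n_pcs": self.n_pcs,
            "n_boot": self.n_boot,
            "eval_seed": self.eval_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = SimConfig(**d.get("sim", {}))
        enet = meta.ElasticNetConfig(**{
            k: tuple(v) if k == "l1_grid" else v
            for k, v in d.get("enet", {}).items()
        })
        return cls(
            sim=sim,
            qc_preset=d.get("qc_preset", "cnics"),
            enet=enet,
            split_fraction=d.get("split_fraction", 0.70),
            split_seed=d.get("split_seed", 0),
            n_pcs=d.get("n_pcs", 10),
            n_boot=d.get("n_boot", 200),
            eval_seed=d.get("eval_seed", 0),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def split_cohort(
    n_or_ids, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive random split with round(fraction * n) training
    rows; deterministic per seed."""
    if not (0.0 < fraction < 1.0):
        raise InvalidConfigError("split fraction must lie in (0, 1)")
    if np.isscalar(n_or_ids):
        ids = np.arange(int(n_or_ids))
    else:
        ids = np.asarray(n_or_ids)
    n = len(ids)
    n_train = int(round(fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(ids[perm[:n_train]]), np.sort(ids[perm[n_train:]])


def _adjustment_frame(
    covariates: pd.DataFrame, pcs: np.ndarray, n_platforms: int
) -> pd.DataFrame:
    """Association-model covariates: centered age, its square, sex, PCs,
    platform indicators and clinical terms."""
    age_c = covariates["age"] - covariates["age"].mean()
    out = pd.DataFrame(
        {"age": age_c, "age2": age_c**2, "sex": covariates["sex"]},
        index=covariates.index,
    )
    for k in range(pcs.shape[1]):
        out[f"pc{k + 1}"] = pcs[:, k]
    if n_platforms >= 2:
        plat = covariates["platform"].to_numpy()
        levels = sorted(pd.unique(plat).tolist())[1:]
        if len(levels) == 1:
            out["platform"] = (plat == levels[0]).astype(float)
        else:
            for lv in levels:
                out[f"platform_{lv}"] = (plat == lv).astype(float)
    for c in ("art", "statin", "bmi", "sbp", "smoking"):
        out[c] = covariates[c]
    return out


def _association_table(
    outcome: np.ndarray,
    scores: dict[str, np.ndarray],
    covars: pd.DataFrame,
) -> pd.DataFrame:
    """Quintile (Q3 reference) and per-SD odds ratios per score."""
    rows = []
    for name, s in scores.items():
        for coding in ("quintile", "per_sd"):
            ests = epi.fit_or_model(outcome, s, covars, coding=coding)
            for est in ests:
                rows.append(
                    {
                        "score": name,
                        "unit": est.term,
                        "odds_ratio": est.odds_ratio,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "p_value": est.p_value,
                        "n": est.n,
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write artifacts; returns a result dict with the
    fitted models, tables and report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    t_start = time.time()

    def stage(name):
        log.append({"stage": name, "t": round(time.time() - t_start, 3)})

    (outdir / "config.json").write_text(
        json.dumps(
            {"hash": config.config_hash(), **config.to_dict()},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    stage("simulate")
    cohort = simulate_cohort(config.sim)
    thresholds = qc.PRESETS[config.qc_preset]

    stage("variant_qc")
    dm, var_report = qc.variant_qc(cohort.dosages, thresholds)
    stage("sample_qc")
    dm, samp_report = qc.sample_qc(dm, thresholds)
    kept = [cohort.dosages.samples.index(s) for s in dm.samples]
    covariates = cohort.covariates.iloc[kept]
    outcome = cohort.outcome[kept]
    platform = cohort.platform[kept]

    stage("pcs")
    pcs = qc.compute_pcs(dm, config.n_pcs)
    stage("platform_harmonize")
    if config.sim.n_platforms >= 2:
        dm, plat_report = qc.platform_harmonize(
            dm, platform, pcs, thresholds.platform_p_remove
        )
    else:
        plat_report = qc.QCReport()
    var_report.variants.to_csv(
        outdir / "qc_variants.tsv", sep="\t", index=False, float_format="%.6g"
    )
    samp_report.samples.to_csv(
        outdir / "qc_samples.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if plat_report.variants is not None:
        plat_report.variants.to_csv(
            outdir / "qc_platform.tsv", sep="\t", index=False, float_format="%.6g"
        )

    stage("split")
    train_idx, val_idx = split_cohort(
        dm.n_individuals, config.split_fraction, config.split_seed
    )
    dm_train = dm.subset_samples(train_idx)
    dm_val = dm.subset_samples(val_idx)

    stage("score")
    z_train = score_matrix(dm_train, cohort.scoring_files)
    z_val = score_matrix(dm_val, cohort.scoring_files)

    stage("train_meta")
    cov_train = _adjustment_frame(
        covariates.iloc[train_idx], pcs[train_idx], 1
    )
    enet_covars = cov_train[
        ["age", "age2", "sex"] + [f"pc{k + 1}" for k in range(config.n_pcs)]
    ]
    y_train = outcome[train_idx]
    models = {}
    for preset, traits in meta.PRESET_TRAITS.items():
        model = meta.fit_component_weights(
            z_train, y_train, enet_covars, config.enet, traits=traits
        )
        models[preset] = model
        model.save(outdir / f"model_{preset}.json")

    stage("apply_meta")
    y_val = outcome[val_idx]
    raw_scores = {
        "score_t2d": z_val.column("T2D"),
        "score_meta_inflammation": meta.apply_metaprs(z_val, models["inflammation"]),
        "score_meta_lipids": meta.apply_metaprs(z_val, models["lipids"]),
    }
    std_scores = {k: standardize(v)[0] for k, v in raw_scores.items()}

    stage("associate")
    cov_val = _adjustment_frame(
        covariates.iloc[val_idx], pcs[val_idx], config.sim.n_platforms
    )
    base_cols = [
        c
        for c in cov_val.columns
        if c in ("age", "age2", "sex") or c.startswith(("pc", "platform"))
    ]
    table2 = _association_table(y_val, std_scores, cov_val[base_cols])
    table2.to_csv(outdir / "table2.tsv", sep="\t", index=False, float_format="%.6g")

    stage("evaluate")
    data = cov_val.copy()
    data["outcome"] = y_val
    for k, v in std_scores.items():
        data[k] = v
    platform_cols = tuple(c for c in cov_val.columns if c.startswith("platform"))
    specs = _specs_with_platform(config.n_pcs, platform_cols)
    battery = epi.run_model_battery(data, specs)
    report = disc.build_report(battery, n_boot=config.n_boot, seed=config.eval_seed)
    report.to_tsv(outdir / "table3.tsv")
    report.delong.to_csv(outdir / "delong.tsv", sep="\t", float_format="%.6g")
    (outdir / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )

    stage("done")
    (outdir / "log.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seeds": {
                    "sim": config.sim.seed,
                    "split": config.split_seed,
                    "folds": config.enet.fold_seed,
                    "eval": config.eval_seed,
                },
                "n_train": int(len(train_idx)),
                "n_validation": int(len(val_idx)),
                "stages": log,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return {
        "models": models,
        "table2": table2,
        "report": report,
        "battery": battery,
        "train_idx": train_idx,
        "val_idx": val_idx,
        "qc": {
            "variants": var_report,
            "samples": samp_report,
            "platform": plat_report,
        },
    }


def _specs_with_platform(
    n_pcs: int, platform_cols: tuple[str, ...]
) -> list[epi.ModelSpec]:
    pcs = tuple(f"pc{i + 1}" for i in range(n_pcs))
    base = epi.BASE_COVARIATES + pcs + platform_cols
    m2 = base + epi.CLINICAL_COVARIATES
    return [
        epi.ModelSpec(1, base),
        epi.ModelSpec(2, m2),
        epi.ModelSpec(3, m2, score="score_t2d"),
        epi.ModelSpec(4, m2, score="score_meta_inflammation"),
        epi.ModelSpec(5, m2, score="score_meta_lipids"),
    ]
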