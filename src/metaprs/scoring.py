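"""Component PRS computation: scoring-file parsing, allele harmonization
against a genotype panel, dosage-weighted scoring, and standardization.

A raw score is the sum over harmonized scoring records of the variant
weight times the effect-allele dosage; missing dosages are mean-imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from metaprs.dosage import COMPLEMENT, DosageMatrix, is_ambiguous
from metaprs.exceptions import ParseError, ScoreError

MANDATORY_COLUMNS = (
    "rsID",
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
)

#: harmonization actions; swap actions apply the weight to ``2 - dosage``
ACTIONS = (
    "direct",
    "allele_swap",
    "strand_complement",
    "complement_then_swap",
    "dropped",
)


@dataclass
class ScoringFile:
    """Ordered variant weights for one component trait."""

    trait_name: str
    records: pd.DataFrame  # rsID, chr_name, chr_position, effect_allele,
    # other_allele, effect_weight

    def __post_init__(self) -> None:
        for col in MANDATORY_COLUMNS:
            if col not in self.records.columns:
                raise ParseError(f"scoring file missing column {col!r}")
        w = np.asarray(self.records["effect_weight"], dtype=float)
        if not np.all(np.isfinite(w)):
            raise ParseError("non-finite effect weight")
        keys = self.records["chr_name"].astype(str) + ":" + self.records[
            "chr_position"
        ].astype(str)
        dup = keys[keys.duplicated()]
        if len(dup):
            raise ParseError(
                f"duplicate variant keys in scoring file: {sorted(set(dup))}"
            )
        self.records = self.records.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class HarmonizationMap:
    """Per-record match of a scoring file against a genotype panel.

    ``variant_index`` is the panel column for each record (-1 when dropped)
    and ``action`` one of :data:`ACTIONS`.  Swap actions mean the file's
    effect allele is the panel's reference allele, so the weight applies to
    ``2 - dosage``.
    """

    trait_name: str
    variant_index: np.ndarray
    action: np.ndarray  # of str
    drop_reason: np.ndarray  # of str, "" when kept

    def __post_init__(self) -> None:
        bad = set(self.action) - set(ACTIONS)
        if bad:
            raise ValueError(f"unknown harmonization actions: {bad}")

    @property
    def n_used(self) -> int:
        return int(np.sum(self.action != "dropped"))

    def summary(self) -> dict[str, int]:
        vals, counts = np.unique(self.action, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def parse_scoring_file(path: str | Path, trait_name: str | None = None) -> ScoringFile:
    """Read a PGS-Catalog-style scoring file.

    ``#``-prefixed lines are header metadata (a ``#trait_name=`` entry
    supplies the trait label); the first non-comment line is a tab-separated
    header naming the columns, tolerated in any order.
    """
    path = Path(path)
    meta_trait = None
    with open(path) as fh:
        header_lines = []
        pos = 0
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
                stripped = line.lstrip("#").strip()
                if stripped.startswith("trait_name="):
                    meta_trait = stripped.split("=", 1)[1]
                pos += len(line)
            else:
                break
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"{path}: missing mandatory column {col!r}")
    try:
        weights = pd.to_numeric(table["effect_weight"], errors="raise")
    except (ValueError, TypeError):
        numeric = pd.to_numeric(table["effect_weight"], errors="coerce")
        bad_line = int(numeric.index[numeric.isna()][0]) + 2  # header + 1-based
        raise ParseError(
            f"{path}: non-numeric effect_weight on data line {bad_line}"
        ) from None
    records = pd.DataFrame(
        {
            "rsID": table["rsID"],
            "chr_name": table["chr_name"].astype(str),
            "chr_position": pd.to_numeric(table["chr_position"]).astype(int),
            "effect_allele": table["effect_allele"].str.upper(),
            "other_allele": table["other_allele"].str.upper(),
            "effect_weight": weights.astype(float),
        }
    )
    name = trait_name or meta_trait or path.stem
    return ScoringFile(trait_name=name, records=records)


def write_scoring_file(scoring: ScoringFile, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("### PGS CATALOG SCORING FILE\n")
        fh.write(f"#trait_name={scoring.trait_name}\n")
        fh.write("\t".join(MANDATORY_COLUMNS) + "\n")
        for rec in scoring.records.itertuples(index=False):
            fh.write(
                f"{rec.rsID}\t{rec.chr_name}\t{rec.chr_position}\t"
                f"{rec.effect_allele}\t{rec.other_allele}\t"
                f"{rec.effect_weight!r}\n"
            )


def harmonize(scoring: ScoringFile, panel: pd.DataFrame | DosageMatrix) -> HarmonizationMap:
    """Match scoring records to panel variants by chromosome + position.

    Resolution order per record: direct (effect/other == alt/ref),
    allele_swap (effect/other == ref/alt), strand_complement,
    complement_then_swap.  Strand-ambiguous (A/T, C/G) records and records
    without a positional match are dropped.
    """
    if isinstance(panel, DosageMatrix):
        panel = panel.variants
    key_to_idx: dict[tuple[str, int], int] = {}
    for idx, (chrom, pos) in enumerate(zip(panel["chrom"], panel["pos"])):
        key_to_idx.setdefault((str(chrom), int(pos)), idx)

    n = scoring.n_records
    variant_index = np.full(n, -1, dtype=int)
    action = np.full(n, "dropped", dtype=object)
    drop_reason = np.full(n, "", dtype=object)

    ref = panel["ref"].to_numpy()
    alt = panel["alt"].to_numpy()
    for i, rec in enumerate(scoring.records.itertuples(index=False)):
        ea, oa = rec.effect_allele, rec.other_allele
        if ea not in COMPLEMENT or oa not in COMPLEMENT:
            drop_reason[i] = "non_acgt_allele"
            continue
        if is_ambiguous(ea, oa):
            drop_reason[i] = "ambiguous_strand"
            continue
        j = key_to_idx.get((str(rec.chr_name), int(rec.chr_position)))
        if j is None:
            drop_reason[i] = "unmatched_position"
            continue
        r, a = ref[j], alt[j]
        cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
        if (ea, oa) == (a, r):
            act = "direct"
        elif (ea, oa) == (r, a):
            act = "allele_swap"
        elif (cea, coa) == (a, r):
            act = "strand_complement"
        elif (cea, coa) == (r, a):
            act = "complement_then_swap"
        else:
            drop_reason[i] = "allele_mismatch"
            continue
        variant_index[i] = j
        action[i] = act
    return HarmonizationMap(
        trait_name=scoring.trait_name,
        variant_index=variant_index,
        action=action,
        drop_reason=drop_reason,
    )


def compute_prs(
    dosages: DosageMatrix,
    scoring: ScoringFile,
    hmap: HarmonizationMap,
    missing_policy: str = "mean",
) -> tuple[np.ndarray, int]:
    """Weighted dosage sum per individual.

    Swap actions apply the weight to ``2 - dosage``.  Missing dosages are
    imputed with twice the alt-allele frequency (``missing_policy="mean"``)
    or the record is omitted per individual with renormalization of the
    total by the fraction of weight mass observed (``"omit"``).

    Returns (scores, number of contributing variants).
    """
    if missing_policy not in ("mean", "omit"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    used = hmap.action != "dropped"
    if not np.any(used):
        raise ScoreError(
            f"no scoring records usable for trait {scoring.trait_name!r}"
        )
    idx = hmap.variant_index[used]
    weights = scoring.records["effect_weight"].to_numpy()[used]
    swap = np.isin(hmap.action[used], ("allele_swap", "complement_then_swap"))

    d = dosages.dosages[:, idx]
    p = np.nanmean(d, axis=0) / 2.0
    p = np.where(np.isfinite(p), p, 0.0)
    miss = np.isnan(d)
    if missing_policy == "mean":
        d = np.where(miss, 2.0 * p, d)
        eff = np.where(swap, 2.0 - d, d)
        scores = eff @ weights
    else:
        d = np.where(miss, 0.0, d)
        eff = np.where(swap, 2.0 - d, d)
        eff = np.where(miss, 0.0, eff)
        scores = eff @ weights
        absw = np.abs(weights)
        seen = (~miss) @ absw
        total = absw.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(seen > 0, scores * total / seen, 0.0)
    return scores, int(used.sum())


@dataclass
class StandardizedScoreMatrix:
    """Individuals x traits of zero-mean unit-SD component scores."""

    z: pd.DataFrame  # one column per trait
    means: dict[str, float]
    sds: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def traits(self) -> list[str]:
        return list(self.z.columns)

    def column(self, trait: str) -> np.ndarray:
        return self.z[trait].to_numpy()


def standardize(
    scores: np.ndarray,
    reference: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float, float]:
    """Z = (score - mean) / SD; sample (n-1) SD convention.

    ``reference`` supplies (mean, SD) from another cohort; otherwise the
    moments are computed in-sample.  Zero SD raises :class:`ScoreError`.
    """
    scores = np.asarray(scores, dtype=float)
    if reference is not None:
        mean, sd = float(reference[0]), float(reference[1])
    else:
        mean = float(np.mean(scores))
        sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    if sd <= 0:
        raise ScoreError("cannot standardize: zero standard deviation")
    return (scores - mean) / sd, mean, sd


def score_matrix(
    dosages: DosageMatrix,
    scoring_files: list[ScoringFile],
    reference: dict[str, tuple[float, float]] | None = None,
    missing_policy: str = "mean",
) -> StandardizedScoreMatrix:
    """Compute and standardize all component scores against one panel."""
    cols, means, sds, prov = {}, {}, {}, {}
    for sf in scoring_files:
        hmap = harmonize(sf, dosages)
        raw, _ = compute_prs(dosages, sf, hmap, missing_policy=missing_policy)
        ref = reference.get(sf.trait_name) if reference else None
        z, m, s = standardize(raw, ref)
        cols[sf.trait_name] = z
        means[sf.trait_name] = m
        sds[sf.trait_name] = s
        prov[sf.trait_name] = "reference" if ref is not None else "in-sample"
    return StandardizedScoreMatrix(
        z=pd.DataFrame(cols, index=list(dosages.samples)),
        means=means,
        sds=sds,
        provenance=prov,
    )
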