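"""Readers and writers for the plain-text interchange formats: VCF with a
per-sample DS (dosage) field, TSV dosage matrices, covariate tables and
truth files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from metaprs.dosage import DosageMatrix
from metaprs.exceptions import ParseError
from metaprs.scoring import write_scoring_file

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed alternate allele dosage">
"""


def write_vcf(dm: DosageMatrix, path: str | Path) -> None:
    """Uncompressed VCF with dosages in a DS FORMAT field."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(dm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dm.samples)
            + "\n"
        )
        d = dm.dosages
        for j, rec in enumerate(dm.variants.itertuples(index=False)):
            vals = [
                "." if np.isnan(x) else f"{x:.4g}" for x in d[:, j]
            ]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t.\tDS\t" + "\t".join(vals) + "\n"
            )


def read_vcf(path: str | Path) -> DosageMatrix:
    """Read dosages from the DS FORMAT field of a VCF."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows = []
        meta = []
        for rec in vf:
            if "DS" not in rec.format:
                raise ParseError(f"{path}: record {rec.id} lacks a DS field")
            vals = []
            for s in samples:
                v = rec.samples[s].get("DS")
                vals.append(np.nan if v is None else float(v))
            rows.append(vals)
            alt = rec.alts[0] if rec.alts else "."
            if rec.alts and len(rec.alts) > 1:
                alt = ",".join(rec.alts)
            meta.append(
                {
                    "id": rec.id or f"{rec.chrom}:{rec.pos}",
                    "chrom": str(rec.chrom),
                    "pos": int(rec.pos),
                    "ref": rec.ref,
                    "alt": alt,
                }
            )
    if not rows:
        raise ParseError(f"{path}: no variant records")
    return DosageMatrix(
        np.asarray(rows, dtype=float).T, pd.DataFrame(meta), samples
    )


def write_dosage_tsv(dm: DosageMatrix, path: str | Path) -> None:
    """Variants as rows: id, chrom, pos, ref, alt, then one column per
    sample; missing dosages written as NA."""
    table = dm.variants.copy()
    for i, s in enumerate(dm.samples):
        table[s] = dm.dosages[i, :]
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_dosage_tsv(path: str | Path) -> DosageMatrix:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    for c in meta_cols:
        if c not in table.columns:
            raise ParseError(f"{path}: missing column {c!r}")
    samples = [c for c in table.columns if c not in meta_cols]
    if not samples:
        raise ParseError(f"{path}: no sample columns")
    dosages = table[samples].to_numpy(dtype=float).T
    return DosageMatrix(dosages, table[meta_cols], samples)


def write_covariates(
    covariates: pd.DataFrame, outcome: np.ndarray | None, path: str | Path
) -> None:
    out = covariates.copy()
    if outcome is not None:
        out["outcome"] = np.asarray(outcome, dtype=int)
    out.to_csv(path, sep="\t", na_rep="NA")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort(cohort, directory: str | Path) -> None:
    """Serialize a synthetic cohort: VCF + dosage TSV + scoring files +
    covariate/outcome table + truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_vcf(cohort.dosages, directory / "genotypes.vcf")
    write_dosage_tsv(cohort.dosages, directory / "dosages.tsv")
    for sf in cohort.scoring_files:
        safe = sf.trait_name.replace("/", "_")
        write_scoring_file(sf, directory / f"score_{safe}.txt")
    write_covariates(cohort.covariates, cohort.outcome, directory / "covariates.tsv")
    with open(directory / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
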