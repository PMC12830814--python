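"""Dosage matrix container shared by the simulation, QC and scoring stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_ambiguous(ref: str, alt: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved from alleles alone."""
    return COMPLEMENT.get(ref) == alt


@dataclass
class DosageMatrix:
    """Individuals x variants matrix of imputed allelic dosages in [0, 2].

    Missing entries are stored as NaN.  ``variants`` carries one row per
    column of ``dosages`` with columns ``id, chrom, pos, ref, alt``;
    dosages count copies of ``alt``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage "
                f"matrix has {self.dosages.shape[1]} columns"
            )
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variant table missing column {col!r}")
        if not self.samples:
            self.samples = [f"S{i:06d}" for i in range(self.dosages.shape[0])]
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list length does not match dosage rows")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def variant_call_rates(self) -> np.ndarray:
        return 1.0 - np.mean(self.missing_mask, axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - np.mean(self.missing_mask, axis=1)

    def alt_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per variant from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def mafs(self) -> np.ndarray:
        """Minor allele frequency: alt frequency folded to <= 0.5."""
        p = self.alt_freqs()
        return np.minimum(p, 1.0 - p)

    def hard_calls(self, max_distance: float = 0.1) -> np.ndarray:
        """Round dosages to genotypes; entries farther than ``max_distance``
        from an integer become missing (-1).  Used by HWE and pi-hat only."""
        rounded = np.round(self.dosages)
        ok = np.abs(self.dosages - rounded) <= max_distance
        calls = np.where(ok & ~np.isnan(self.dosages), rounded, -1.0)
        return calls.astype(np.int8)

    def subset_variants(self, index) -> "DosageMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return DosageMatrix(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            list(self.samples),
        )

    def subset_samples(self, index) -> "DosageMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return DosageMatrix(
            self.dosages[index, :],
            self.variants.copy(),
            [self.samples[i] for i in index],
        )

    def copy(self) -> "DosageMatrix":
        return DosageMatrix(
            self.dosages.copy(), self.variants.copy(), list(self.samples)
        )
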