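"""Shared in-memory containers.

Coordinates are 0-based half-open internally; TSV inputs/outputs use 1-based
positions for point features (SNPs, cytosines) and BED-like 0-based half-open
intervals for bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Context classes for methylation bins. CG windows are split by the absence
#: or presence of CHG methylation anywhere in the same window (gene-body-like
#: vs TE-like methylation).
CONTEXT_CLASSES = ("CG_only", "CG_in_C", "CHG", "CHH")

#: Columns identifying a bin in a bin table; remaining columns are accessions.
BIN_META_COLUMNS = ["chrom", "start", "end", "context_class"]


@dataclass
class GenotypeMatrix:
    """Haploid-coded biallelic genotypes for a panel of inbred accessions.

    ``matrix`` is individuals x SNPs with entries in {0, 1} (accessions are
    homozygous, so one allele per individual suffices).
    """

    matrix: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 0-based
    accessions: list[str]
    snp_ids: list[str] = field(default_factory=list)
    subpop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
        n, m = self.matrix.shape
        if len(self.accessions) != n:
            raise ValueError("accession count does not match matrix rows")
        if len(self.pos) != m or len(self.chrom) != m:
            raise ValueError("SNP coordinate arrays do not match matrix columns")
        if not self.snp_ids:
            self.snp_ids = [f"snp_{c}_{p + 1}" for c, p in zip(self.chrom, self.pos)]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNP columns, keeping accession metadata."""
        index = np.asarray(index)
        return GenotypeMatrix(
            matrix=self.matrix[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            accessions=list(self.accessions),
            snp_ids=[self.snp_ids[i] for i in np.atleast_1d(index)],
            subpop=self.subpop,
        )


@dataclass
class TraitVector:
    """One quantitative trait measured on every accession."""

    trait_id: str
    values: np.ndarray
    accessions: list[str]
    transform_state: str = "raw"  # raw | anscombe | inverse_normal | standardized

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trait values must be 1-D")
        if len(self.values) != len(self.accessions):
            raise ValueError("trait length does not match accession count")
        if np.isnan(self.values).any():
            raise ValueError(f"trait {self.trait_id} contains missing values")


def validate_bin_table(bins: pd.DataFrame) -> list[str]:
    """Check a bin table's schema and return its accession columns."""
    missing = [c for c in BIN_META_COLUMNS if c not in bins.columns]
    if missing:
        raise ValueError(f"bin table lacks columns: {missing}")
    acc = [c for c in bins.columns if c not in BIN_META_COLUMNS]
    if not acc:
        raise ValueError("bin table has no accession columns")
    return acc


def bin_levels(bins: pd.DataFrame) -> np.ndarray:
    """Per-accession level matrix (bins x accessions) from a bin table."""
    acc = validate_bin_table(bins)
    return bins[acc].to_numpy(dtype=float)


def check_same_accessions(*sequences: Sequence[str]) -> list[str]:
    """Assert that all inputs share one accession ordering; return it."""
    ref = list(sequences[0])
    for s in sequences[1:]:
        if list(s) != ref:
            raise ValueError(
                "accession sets/orders differ between inputs; "
                f"offending set: {list(s)[:5]}... vs {ref[:5]}..."
            )
    return ref
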