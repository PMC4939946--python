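"""Filtering and transformation of genotypes, methylomes and expression.

Methylation is quantified as the average per-cytosine methylation level
(mc/total) over all eligible cytosines of one context in 200-bp windows,
computed separately as mCG/CG, mCHG/CHG and mCHH/CHH. CG windows are split
into gene-body-like (CG_only) and TE-like (CG_in_C) classes by the absence
or presence of CHG methylation anywhere in the same window, so the four
context classes are mutually exclusive.

Filters: SNPs at minor allele frequency >= 0.05; expression genes at mean
Anscombe-transformed level >= 3 and raw coefficient of variation >= 0.05;
methylation bins at CV >= 0.05 and a five-furthest-outlier score <= 75.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from epiqtl.datatypes import BIN_META_COLUMNS, GenotypeMatrix

_H = set("ACT")


def classify_cytosine_context(triplet: str) -> str:
    """CG / CHG / CHH from the trinucleotide on the cytosine's strand."""
    t = triplet.upper()
    if len(t) != 3 or t[0] != "C":
        raise ValueError(f"context triplet must start with C, got {triplet!r}")
    if t[1] == "G":
        return "CG"
    if t[2] == "G":
        return "CHG"
    if t[1] in _H and t[2] in _H:
        return "CHH"
    raise ValueError(f"invalid context triplet {triplet!r}")


def bin_methylation_levels(
    records: pd.DataFrame,
    window: int = 200,
    step: int = 100,
    accessions: list[str] | None = None,
    require_complete: bool = True,
) -> pd.DataFrame:
    """Average per-cytosine levels into overlapping windows, per context.

    ``records`` is long-format with columns accession, chrom, pos (1-based),
    strand, context (trinucleotide), mc_count, total_count. Window starts are
    multiples of ``step``; a cytosine contributes to every window covering
    it. Sites with total_count = 0 are ineligible. Windows with no eligible
    cytosines of a context emit no bin for that context; if
    ``require_complete``, bins missing any accession are dropped.

    Returns a bin table: chrom, start, end, context_class, one level column
    per accession, sorted by position then context class.
    """
    req = {"accession", "chrom", "pos", "context", "mc_count", "total_count"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"cytosine table lacks columns: {sorted(missing)}")
    df = records.loc[records["total_count"] > 0].copy()
    if not len(df):
        return pd.DataFrame(columns=BIN_META_COLUMNS)
    df["ratio"] = df["mc_count"] / df["total_count"]
    df["ctx3"] = [classify_cytosine_context(t) for t in df["context"]]
    pos0 = df["pos"].to_numpy(dtype=np.int64) - 1

    frames = []
    n_offsets = -(-window // step)  # windows covering any one site
    base = (pos0 // step) * step
    for j in range(n_offsets):
        start = base - j * step
        ok = (start >= 0) & (pos0 - start < window)
        sub = df.loc[ok, ["chrom", "ctx3", "accession", "ratio"]].copy()
        sub["start"] = start[ok]
        frames.append(sub)
    allw = pd.concat(frames, ignore_index=True)

    levels = (
        allw.groupby(["chrom", "start", "ctx3", "accession"], sort=False)["ratio"]
        .mean()
        .unstack("accession")
    )
    if accessions is None:
        accessions = sorted(records["accession"].unique())
    levels = levels.reindex(columns=accessions)
    if require_complete:
        levels = levels.dropna(axis=0, how="any")
    if not len(levels):
        return pd.DataFrame(columns=BIN_META_COLUMNS + list(accessions))

    out = levels.reset_index()
    # CG windows split by presence of any CHG methylation in the same window
    chg = allw[(allw["ctx3"] == "CHG") & (allw["ratio"] > 0)]
    chg_windows = set(zip(chg["chrom"], chg["start"]))
    ctx_class = []
    for _, row in out.iterrows():
        if row["ctx3"] == "CG":
            in_c = (row["chrom"], row["start"]) in chg_windows
            ctx_class.append("CG_in_C" if in_c else "CG_only")
        else:
            ctx_class.append(row["ctx3"])
    out["context_class"] = ctx_class
    out["end"] = out["start"] + window
    out = out[BIN_META_COLUMNS + list(accessions)]
    return out.sort_values(["chrom", "start", "context_class"], kind="mergesort").reset_index(
        drop=True
    )


def filter_snps_maf(genotypes: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency >= threshold (0/1 coding)."""
    g = genotypes.matrix
    if not np.isin(g, (0, 1)).all():
        raise ValueError("genotypes must be haploid-coded 0/1")
    f = g.mean(axis=0)
    keep = np.minimum(f, 1.0 - f) >= threshold
    return genotypes.take_snps(np.flatnonzero(keep))


def anscombe(x: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform for counts, a(x) = 2*sqrt(x + 3/8)."""
    return 2.0 * np.sqrt(np.asarray(x, dtype=float) + 0.375)


def filter_expression(
    expr: pd.DataFrame, mean_threshold: float = 3.0, cv_threshold: float = 0.05
) -> pd.DataFrame:
    """Drop weakly/invariantly expressed genes from an rpkm table.

    Keeps genes whose mean Anscombe-transformed expression is >= 3 and whose
    raw-scale coefficient of variation is >= 0.05. Rows are genes, columns
    accessions.
    """
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("rpkm expression values must be nonnegative")
    mean_a = anscombe(values).mean(axis=1)
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mu > 0, sd / mu, 0.0)
    keep = (mean_a >= mean_threshold) & (cv >= cv_threshold)
    return expr.loc[keep]


def five_furthest_score(values: np.ndarray, n_extreme: int = 5) -> float:
    """Sum of squared z-scores of the n furthest values after standardizing.

    A quantitative analogue of the minor-allele-frequency filter: near-binary
    vectors dominated by a few extreme accessions score high.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance vector cannot be standardized")
    z = (x - x.mean()) / sd
    z2 = np.sort(z**2)
    return float(z2[-n_extreme:].sum())


def filter_methylation_bins(
    bins: pd.DataFrame,
    cv_threshold: float = 0.05,
    outlier_threshold: float = 75.0,
    n_extreme: int = 5,
) -> pd.DataFrame:
    """Drop near-constant and outlier-dominated bins.

    A bin is kept iff its raw-level CV is >= cv_threshold and, after
    standardizing to mean 0 / variance 1, the sum of squared z-scores of its
    ``n_extreme`` furthest values is <= outlier_threshold.
    """
    acc = [c for c in bins.columns if c not in BIN_META_COLUMNS]
    levels = bins[acc].to_numpy(dtype=float)
    keep = np.zeros(len(bins), dtype=bool)
    for i, row in enumerate(levels):
        mu = row.mean()
        sd = row.std(ddof=1)
        if sd == 0 or mu <= 0 or sd / mu < cv_threshold:
            continue
        keep[i] = five_furthest_score(row, n_extreme) <= outlier_threshold
    return bins.loc[keep].reset_index(drop=True)


def inverse_normal_transform(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based mapping onto normal quantiles (Blom offset c = 3/8).

    A value with rank r among n maps to Phi^-1((r - c) / (n + 1 - 2c)); ties
    get the mean of their ranks. Only the order information survives.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("all values tied; inverse normal transform undefined")
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - c) / (len(x) + 1.0 - 2.0 * c))


class InverseNormalTransformer:
    """Stateless row-wise inverse-normal transform for trait tables."""

    def __init__(self, c: float = 3.0 / 8.0):
        self.c = c

    def fit(self, X, y=None):  # noqa: D102 - sklearn-style no-op
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy().astype(float)
        for i in range(len(out)):
            out.iloc[i] = inverse_normal_transform(out.iloc[i].to_numpy(), c=self.c)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def transform_trait_table(
    table: pd.DataFrame, mode: str = "inverse_normal"
) -> pd.DataFrame:
    """Apply the configured trait transform row-wise (traits x accessions)."""
    if mode == "untransformed":
        return table.copy()
    if mode == "inverse_normal":
        return InverseNormalTransformer().transform(table)
    raise ValueError(f"unknown transform mode {mode!r}")
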