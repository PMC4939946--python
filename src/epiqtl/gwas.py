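"""Mixed-model association scans with SNPs or methylation bins as fixed effects.

The scan model is Y ~ N(mu + X beta, K sigma_s^2 + I sigma_e^2). Following
the EMMAX approximation, the variance ratio delta = sigma_s^2 / sigma_e^2 is
estimated once under the null model (no candidate fixed effect); phenotype
and candidates are then rotated by (Lambda*delta + I)^(-1/2) Q', where
Q Lambda Q' is the spectral decomposition of K, after which ordinary
least-squares F-tests apply. Forward stepwise selection repeatedly adds the
top marginal variant as a cofactor while it passes a Bonferroni threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh

from epiqtl.lmm import KinshipMatrix, MixedModelFit, fit_mixed_model

_COLLINEAR_TOL = 1e-10


@dataclass
class RotationCache:
    """Spectral rotation of one kinship at a null-model variance ratio."""

    Q: np.ndarray
    eigenvalues: np.ndarray
    delta: float
    rotation: np.ndarray  # (Lambda*delta + I)^(-1/2) Q'
    null_fit: MixedModelFit


@dataclass
class StepwiseResult:
    """Ordered cofactors selected by forward stepwise scanning."""

    cofactors: list[dict] = field(default_factory=list)
    final_fit: MixedModelFit | None = None
    threshold: float = float("nan")
    n_candidates: int = 0

    @property
    def cofactor_ids(self) -> list[str]:
        return [c["variant_id"] for c in self.cofactors]


def build_rotation(
    y: np.ndarray,
    K: KinshipMatrix,
    X: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> RotationCache:
    """Fit the null mixed model and build the EMMAX whitening rotation.

    ``X`` are null-model fixed effects (an intercept if None); candidates are
    NOT part of the null. The rotated residual covariance is spherical under
    the null, so candidate tests reduce to OLS F-tests.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate trait: all values equal")
    if eig is None:
        w, Q = eigh(K.matrix)
    else:
        w, Q = eig
    w = np.clip(w, 0.0, None)
    null_fit = fit_mixed_model(y, X, kinships=(K,), criterion="ML", eig=(w, Q))
    s2e = null_fit.variance_components["residual"]
    s2g = null_fit.variance_components[K.role]
    delta = s2g / s2e if s2e > 0 else 0.0
    rotation = (Q / np.sqrt(w * delta + 1.0)).T
    return RotationCache(Q=Q, eigenvalues=w, delta=delta, rotation=rotation,
                         null_fit=null_fit)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M on the column span of Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def marginal_scan(
    y: np.ndarray,
    candidates: np.ndarray,
    cache: RotationCache,
    variant_ids: list[str] | None = None,
    positions: np.ndarray | None = None,
    chroms: np.ndarray | None = None,
    variant_type: str | np.ndarray = "snp",
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-variant F-tests in the rotated (whitened) regression.

    ``candidates`` is accessions x variants; one null-model delta (from
    ``cache``) is reused for every candidate. ``covariates`` are additional
    fixed effects (unrotated), e.g. stepwise cofactors. Constant candidates
    get p = 1 with a warning. Returns a DataFrame with F, p per variant.
    """
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(candidates, dtype=float))
    if C.shape[0] != len(y):
        raise ValueError("candidate matrix rows must match accession count")
    n, m = C.shape
    R = cache.rotation
    Zcols = [np.ones((n, 1))]
    if covariates is not None:
        Zcols.append(np.atleast_2d(np.asarray(covariates, dtype=float)))
    Z = R @ np.hstack(Zcols)
    yr = _residualize((R @ y)[:, None], Z)[:, 0]
    Cr = _residualize(R @ C, Z)

    q = Z.shape[1]
    dof = n - q - 1
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom for the scan")
    xtx = np.einsum("ij,ij->j", Cr, Cr)
    xty = Cr.T @ yr
    yty = float(yr @ yr)
    const = xtx <= _COLLINEAR_TOL * n
    if const.any():
        warnings.warn(f"{int(const.sum())} constant/collinear candidate(s): p set to 1")
    safe_xtx = np.where(const, 1.0, xtx)
    b = xty / safe_xtx
    rss = np.maximum(yty - b * xty, 0.0)
    denom = np.where(rss <= 0, np.nan, rss / dof)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(const, 0.0, (b**2) * safe_xtx / denom)
    F = np.nan_to_num(F, nan=np.inf, posinf=np.inf)
    p = np.where(const, 1.0, stats.f.sf(F, 1, dof))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "variant_id": variant_ids if variant_ids is not None else
            [f"v{j}" for j in range(m)],
            "variant_type": variant_type if not isinstance(variant_type, str)
            else [variant_type] * m,
            "chrom": chroms if chroms is not None else [""] * m,
            "pos": positions if positions is not None else np.arange(m),
            "F": F,
            "p": p,
        }
    )
    return out


def stepwise_scan(
    y: np.ndarray,
    K: KinshipMatrix,
    snp_candidates: np.ndarray | None = None,
    meth_candidates: np.ndarray | None = None,
    snp_meta: pd.DataFrame | None = None,
    meth_meta: pd.DataFrame | None = None,
    bonferroni_alpha: float = 0.05,
    bonferroni_n: int | None = None,
    refit_delta: bool = True,
    max_steps: int = 50,
) -> StepwiseResult:
    """Forward stepwise mixed-model scan over SNP and methylation candidates.

    At each step the minimum-p variant (ties broken by lowest genomic
    coordinate) is added as a fixed cofactor while its p-value stays below
    bonferroni_alpha / n_candidates. By default delta is re-estimated after
    each inclusion (set ``refit_delta=False`` for the strict one-delta
    approximation). ``*_meta`` frames carry variant_id / chrom / pos columns.
    """
    blocks, metas, types = [], [], []
    if snp_candidates is not None and np.size(snp_candidates):
        blocks.append(np.atleast_2d(np.asarray(snp_candidates, dtype=float)))
        metas.append(snp_meta)
        types.append("snp")
    if meth_candidates is not None and np.size(meth_candidates):
        blocks.append(np.atleast_2d(np.asarray(meth_candidates, dtype=float)))
        metas.append(meth_meta)
        types.append("meth_bin")
    if not blocks:
        raise ValueError("no candidates supplied")
    C = np.hstack(blocks)
    n, m = C.shape
    ids, chroms, poss, vtypes = [], [], [], []
    for block, meta, vt in zip(blocks, metas, types):
        k = block.shape[1]
        if meta is not None:
            ids += list(meta["variant_id"])
            chroms += [str(c) for c in meta["chrom"]]
            poss += [int(p) for p in meta["pos"]]
        else:
            ids += [f"{vt}_{j}" for j in range(k)]
            chroms += [""] * k
            poss += list(range(k))
        vtypes += [vt] * k

    n_cand = bonferroni_n if bonferroni_n is not None else m
    threshold = bonferroni_alpha / n_cand
    selected: list[int] = []
    cofactors: list[dict] = []
    cache = build_rotation(y, K)

    for _ in range(max_steps):
        cov = C[:, selected] if selected else None
        if refit_delta and selected:
            cache = build_rotation(y, K, X=np.hstack([np.ones((n, 1)), cov]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = marginal_scan(
                y, C, cache,
                variant_ids=ids,
                positions=np.asarray(poss),
                chroms=np.asarray(chroms, dtype=object),
                variant_type=np.asarray(vtypes, dtype=object),
                covariates=cov,
            )
        res.loc[res.index.isin(selected), "p"] = 1.0  # already in the model
        order = np.lexsort((res["pos"].to_numpy(), res["p"].to_numpy()))
        top = int(order[0])
        if res["p"].iloc[top] >= threshold:
            break
        selected.append(top)
        cofactors.append(
            {
                "variant_id": res["variant_id"].iloc[top],
                "variant_type": res["variant_type"].iloc[top],
                "chrom": res["chrom"].iloc[top],
                "pos": int(res["pos"].iloc[top]),
                "p_entry": float(res["p"].iloc[top]),
                "column": top,
            }
        )

    Xfinal = np.hstack([np.ones((n, 1)), C[:, selected]]) if selected else None
    final_fit = fit_mixed_model(y, Xfinal, kinships=(K,), criterion="ML")
    return StepwiseResult(cofactors=cofactors, final_fit=final_fit,
                          threshold=threshold, n_candidates=n_cand)


# ------------------------------------------------------------ cis/trans FDR


def cis_distance(pos: int, gene_start: int, gene_end: int) -> int:
    """bp distance from a point variant to a 0-based half-open gene interval."""
    if gene_start <= pos < gene_end:
        return 0
    return gene_start - pos if pos < gene_start else pos - (gene_end - 1)


def label_cis(
    results: pd.DataFrame, gene: dict | pd.Series, cis_window: int = 20000
) -> pd.DataFrame:
    """Add a cis_flag column: strictly less than ``cis_window`` bp from the gene."""
    out = results.copy()
    same = out["chrom"].astype(str) == str(gene["chrom"])
    d = np.array(
        [cis_distance(int(p), int(gene["start"]), int(gene["end"])) for p in out["pos"]]
    )
    out["cis_flag"] = same.to_numpy() & (d < cis_window)
    return out


def cis_trans_fdr_bound(
    cis_hits: int, cis_tests: int, trans_hits: int, trans_tests: int
) -> float:
    """Conservative FDR upper bound for cis associations.

    Assumes every trans hit is a false positive, so the per-test false rate is
    trans_hits / trans_tests; the expected number of false cis hits is that
    rate times cis_tests, and the bound is the ratio to observed cis hits.
    """
    if cis_tests <= 0 or trans_tests <= 0:
        raise ValueError("test counts must be positive")
    if cis_hits < 0 or trans_hits < 0:
        raise ValueError("hit counts must be nonnegative")
    if cis_hits == 0:
        raise ValueError("FDR bound undefined: no cis hits")
    if trans_hits == 0:
        return 0.0
    return (trans_hits / trans_tests) * cis_tests / cis_hits
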