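"""Genome-wide methylation background test and nested cis variance models.

Two analyses live here. First, the genome-wide test asks whether a
methylation similarity matrix K_M explains trait variance beyond the SNP
kinship K_S, by a boundary-corrected likelihood-ratio test of

    Y ~ N(mu, K_S sigma_S^2 + K_M sigma_M^2 + I sigma_e^2)   vs.
    Y ~ N(mu, K_S sigma_S^2 + I sigma_e^2).

Second, the nested cis models quantify methylation effects on top of SNP
effects for one gene: stage 1 selects stepwise cis-SNP cofactors under a
K_S + K_l (global + local kinship) random structure; stage 2 adds stepwise
cis methylation-bin cofactors to the same random structure, with a
Bonferroni threshold over methylation bins only. A global methylation
kinship is deliberately not included in these models. The fitted model is
then decomposed into cis-genetic, trans-genetic, cis-methylation and
residual variance fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from epiqtl.lmm import (
    KinshipMatrix,
    LRTResult,
    MixedModelFit,
    fit_mixed_model,
    likelihood_ratio_test,
)

_COLLINEAR_TOL = 1e-10


@dataclass
class GenomewideMethylationTest:
    fit_full: MixedModelFit
    fit_null: MixedModelFit
    lrt: LRTResult


@dataclass
class NestedCisResult:
    """Stage-1 (genetics) and stage-2 (genetics + methylation) fits."""

    genetics_fit: MixedModelFit
    full_fit: MixedModelFit
    snp_cofactors: list[dict] = field(default_factory=list)
    meth_cofactors: list[dict] = field(default_factory=list)
    snp_columns: np.ndarray | None = None
    meth_columns: np.ndarray | None = None
    has_local_kinship: bool = True


@dataclass
class VariancePartition:
    """Trait-variance fractions, normalized to sum to one."""

    cis_genetic: float
    trans_genetic: float
    cis_methylation: float
    residual: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cis_genetic": self.cis_genetic,
            "trans_genetic": self.trans_genetic,
            "cis_methylation": self.cis_methylation,
            "residual": self.residual,
        }


def test_genomewide_methylation_effect(
    y: np.ndarray,
    K_S: KinshipMatrix,
    K_M: KinshipMatrix,
    reverse: bool = False,
) -> GenomewideMethylationTest:
    """LRT for a genome-wide methylation variance component beyond SNPs.

    With ``reverse=True`` the roles swap: does the SNP kinship add anything
    on top of the methylation similarity?
    """
    base, extra = (K_M, K_S) if reverse else (K_S, K_M)
    fit_full = fit_mixed_model(y, kinships=(base, extra), criterion="ML")
    fit_null = fit_mixed_model(y, kinships=(base,), criterion="ML")
    return GenomewideMethylationTest(
        fit_full=fit_full, fit_null=fit_null,
        lrt=likelihood_ratio_test(fit_full, fit_null),
    )


# ------------------------------------------------- nested cis (two stages)


def _whitening_from_fit(fit: MixedModelFit) -> np.ndarray:
    """V^(-1/2) at a fit's variance-component ratios (for rotated OLS scans)."""
    n = fit.n
    s2e = fit.variance_components["residual"]
    V = np.eye(n)
    for K in fit.kinships:
        s2 = fit.variance_components.get(K.role, 0.0)
        if s2 > 0 and s2e > 0:
            V = V + (s2 / s2e) * K.matrix
    w, Q = eigh(V)
    w = np.clip(w, 1e-12, None)
    return (Q / np.sqrt(w)) @ Q.T


def _rotated_f_scan(y, C, W, covariates):
    """OLS F-tests of each column of C after whitening with W."""
    n = len(y)
    Zcols = [np.ones((n, 1))]
    if covariates is not None and covariates.size:
        Zcols.append(covariates)
    Z = W @ np.hstack(Zcols)
    coef, *_ = np.linalg.lstsq(Z, np.column_stack([W @ y, W @ C]), rcond=None)
    resid = np.column_stack([W @ y, W @ C]) - Z @ coef
    yr, Cr = resid[:, 0], resid[:, 1:]
    dof = n - Z.shape[1] - 1
    xtx = np.einsum("ij,ij->j", Cr, Cr)
    xty = Cr.T @ yr
    yty = float(yr @ yr)
    const = xtx <= _COLLINEAR_TOL * n
    safe = np.where(const, 1.0, xtx)
    b = xty / safe
    rss = np.maximum(yty - b * xty, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(const, 0.0, (b**2) * safe / (rss / dof))
    from scipy import stats

    p = np.where(const, 1.0, stats.f.sf(F, 1, dof))
    return F, np.clip(p, np.finfo(float).tiny, 1.0)


def _forward_select(y, C, meta_pos, kinships, alpha, n_tests, preselected,
                    max_steps=25):
    """Stepwise cofactor selection under an arbitrary kinship set."""
    selected: list[int] = []
    cofactors: list[dict] = []
    threshold = alpha / max(n_tests, 1)
    n = len(y)
    for _ in range(max_steps):
        cov_cols = [c for c in (preselected, C[:, selected] if selected else None)
                    if c is not None and c.size]
        cov = np.hstack(cov_cols) if cov_cols else None
        Xnull = np.hstack([np.ones((n, 1)), cov]) if cov is not None else None
        fit = fit_mixed_model(y, Xnull, kinships=kinships, criterion="ML")
        W = _whitening_from_fit(fit)
        F, p = _rotated_f_scan(y, C, W, cov)
        p = p.copy()
        p[selected] = 1.0
        order = np.lexsort((meta_pos, p))
        top = int(order[0])
        if p[top] >= threshold:
            break
        selected.append(top)
        cofactors.append({"column": top, "p_entry": float(p[top]),
                          "pos": int(meta_pos[top])})
    return selected, cofactors


def fit_nested_cis_models(
    y: np.ndarray,
    cis_snps: np.ndarray | None,
    cis_meth_bins: np.ndarray | None,
    K_S: KinshipMatrix,
    K_l: KinshipMatrix | None,
    snp_positions: np.ndarray | None = None,
    meth_positions: np.ndarray | None = None,
    alpha: float = 0.05,
) -> NestedCisResult:
    """Two-stage nested cis models for one expression trait.

    Stage 1 ("genetics"): stepwise cis-SNP cofactors X_S under the
    K_S + K_l random structure, Bonferroni over the SNP candidates.
    Stage 2 ("genetics + methylation"): stepwise methylation cofactors X_M
    added to the stage-1 fixed part, same random structure, Bonferroni over
    the methylation bins only. If ``K_l`` is None (empty cis window) the
    local component is omitted with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K_l is None:
        warnings.warn("no cis SNPs for local kinship: K_l omitted from the model")
        kinships: tuple[KinshipMatrix, ...] = (K_S,)
    else:
        kinships = (K_S, K_l)

    snp_sel: list[int] = []
    snp_cof: list[dict] = []
    if cis_snps is not None and np.size(cis_snps):
        cis_snps = np.atleast_2d(np.asarray(cis_snps, dtype=float))
        pos_s = (np.asarray(snp_positions) if snp_positions is not None
                 else np.arange(cis_snps.shape[1]))
        snp_sel, snp_cof = _forward_select(
            y, cis_snps, pos_s, kinships, alpha, cis_snps.shape[1], None
        )
    Xs = cis_snps[:, snp_sel] if snp_sel else np.empty((n, 0))
    X1 = np.hstack([np.ones((n, 1)), Xs])
    genetics_fit = fit_mixed_model(y, X1, kinships=kinships, criterion="ML")

    meth_sel: list[int] = []
    meth_cof: list[dict] = []
    if cis_meth_bins is not None and np.size(cis_meth_bins):
        cis_meth_bins = np.atleast_2d(np.asarray(cis_meth_bins, dtype=float))
        pos_m = (np.asarray(meth_positions) if meth_positions is not None
                 else np.arange(cis_meth_bins.shape[1]))
        meth_sel, meth_cof = _forward_select(
            y, cis_meth_bins, pos_m, kinships, alpha, cis_meth_bins.shape[1],
            Xs if Xs.size else None,
        )
    Xm = cis_meth_bins[:, meth_sel] if meth_sel else np.empty((n, 0))
    X2 = np.hstack([X1, Xm])
    full_fit = fit_mixed_model(y, X2, kinships=kinships, criterion="ML")
    if full_fit.log_likelihood < genetics_fit.log_likelihood:
        # ML over a superset of fixed effects cannot be worse; keep monotone
        full_fit = genetics_fit

    return NestedCisResult(
        genetics_fit=genetics_fit,
        full_fit=full_fit,
        snp_cofactors=snp_cof,
        meth_cofactors=meth_cof,
        snp_columns=Xs if Xs.size else None,
        meth_columns=Xm if Xm.size else None,
        has_local_kinship=K_l is not None,
    )


def partition_variance(result: NestedCisResult) -> VariancePartition:
    """Decompose the stage-2 fit into variance fractions.

    Fixed-effect blocks are attributed by the sample variance of each fitted
    sub-predictor, with covariance between sub-predictors split equally
    (row-sum allocation); random components contribute sigma^2 times the mean
    diagonal of their kinship; the local kinship and SNP cofactors count as
    cis-genetic, the global kinship as trans-genetic. Fractions are clipped
    at zero and normalized to sum to one.
    """
    fit = result.full_fit
    if not fit.converged:
        raise ValueError("cannot partition variance of a non-converged fit")
    n = fit.n

    # fixed-part sub-predictors (intercept excluded: no variance)
    blocks: list[tuple[str, np.ndarray]] = []
    j = 1
    n_snp = result.snp_columns.shape[1] if result.snp_columns is not None else 0
    n_meth = result.meth_columns.shape[1] if result.meth_columns is not None else 0
    if fit.X.shape[1] != 1 + n_snp + n_meth:
        # stage-2 fell back to the stage-1 fit: no methylation columns
        n_meth = fit.X.shape[1] - 1 - n_snp
    if n_snp:
        blocks.append(("cis_genetic", fit.X[:, j:j + n_snp] @ fit.beta[j:j + n_snp]))
        j += n_snp
    if n_meth:
        blocks.append(("cis_methylation", fit.X[:, j:j + n_meth] @ fit.beta[j:j + n_meth]))

    contrib = {"cis_genetic": 0.0, "trans_genetic": 0.0,
               "cis_methylation": 0.0, "residual": 0.0}
    if blocks:
        P = np.column_stack([b for _, b in blocks])
        Cov = np.atleast_2d(np.cov(P.T, ddof=1)) if P.shape[1] > 1 else np.array(
            [[float(np.var(P[:, 0], ddof=1))]]
        )
        for i, (label, _) in enumerate(blocks):
            contrib[label] += float(Cov[i].sum())  # own variance + split covariance

    for K in fit.kinships:
        s2 = fit.variance_components.get(K.role, 0.0)
        label = "cis_genetic" if K.role == "local_cis" else "trans_genetic"
        contrib[label] += s2 * float(np.diag(K.matrix).mean())
    contrib["residual"] = fit.variance_components["residual"]

    vals = {k: max(v, 0.0) for k, v in contrib.items()}
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("degenerate fit: total attributed variance is zero")
    return VariancePartition(**{k: v / total for k, v in vals.items()})
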