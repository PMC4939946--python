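"""Kinship construction and linear mixed-model fitting.

Models are of the form

    Y ~ N(X beta, sum_i K_i sigma_i^2 + I sigma_e^2)

with zero to three kinship (similarity) matrices: a global SNP kinship K_S, a
methylation similarity K_M computed the same way from bin levels, and a local
cis kinship K_l from SNPs near one gene. Fitting profiles out beta and the
overall scale; with a single kinship the variance ratio is optimized in 1-D
on the spectral decomposition (EMMA-style), with several kinships the
log-likelihood is maximized numerically over variance-component ratios with
multiple restarts, and every proper subset of components (including the
no-kinship OLS boundary) is also evaluated so that adding a component can
never decrease the maximized ML log-likelihood.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, eigh, solve_triangular

_PSD_TOL = 1e-8
#: variance ratios sigma_i^2 / sigma_e^2 are searched within [1e-6, 1e6];
#: outside this range the profile likelihood can diverge when a kinship null
#: direction lies in the fixed-effect column space (EMMA bounds it the same way)
_LOG_RATIO_BOUND = np.log(1e6)
_LOG_DELTA_GRID = np.linspace(-_LOG_RATIO_BOUND, _LOG_RATIO_BOUND, 61)


class EmptyCisWindowError(ValueError):
    """No informative SNPs in the requested cis window; drop the K_l term."""


@dataclass
class KinshipMatrix:
    """Accession x accession similarity matrix with a role tag."""

    role: str  # global_snp | methylation | local_cis (free-form allowed)
    matrix: np.ndarray
    accessions: list[str] | None = None

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be a square matrix")
        if not np.isfinite(K).all():
            raise ValueError("kinship contains non-finite entries")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        K = (K + K.T) / 2.0
        wmin = eigh(K, eigvals_only=True, subset_by_index=[0, 0])[0]
        if wmin < -_PSD_TOL * max(np.trace(K) / K.shape[0], 1.0):
            raise ValueError(f"kinship is not positive semidefinite (min eig {wmin:.3g})")
        self.matrix = K

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MixedModelFit:
    """Result of one (restricted) maximum-likelihood mixed-model fit."""

    beta: np.ndarray
    variance_components: dict[str, float]  # kinship role -> sigma^2, + "residual"
    log_likelihood: float
    criterion: str
    converged: bool
    n: int
    kinship_roles: tuple[str, ...]
    X: np.ndarray | None = None
    kinships: tuple[KinshipMatrix, ...] = field(default=(), repr=False)
    n_eff: int = 0  # dimensions used in the likelihood after aliasing projection

    @property
    def n_params(self) -> int:
        """Free parameters: fixed effects + variance components (incl. residual)."""
        return len(self.beta) + len(self.variance_components)

    def genetic_fraction(self, role: str) -> float:
        """Fraction of model-implied variance from one kinship component."""
        total = 0.0
        for r, s2 in self.variance_components.items():
            if r == "residual":
                total += s2
            else:
                K = self.kinships[self.kinship_roles.index(r)].matrix
                total += s2 * float(np.diag(K).mean())
        if total <= 0:
            return 0.0
        K = self.kinships[self.kinship_roles.index(role)].matrix
        return self.variance_components[role] * float(np.diag(K).mean()) / total


# ------------------------------------------------------------------ kinship


def compute_kinship(
    values: np.ndarray | pd.DataFrame,
    role: str = "global_snp",
    accessions: list[str] | None = None,
) -> KinshipMatrix:
    """Variant-based similarity matrix K = Z'Z / m over standardized variants.

    ``values`` is variants x accessions (SNP dosages or methylation bin
    levels). Each variant row is standardized to mean 0, variance 1;
    zero-variance rows are dropped. K is rescaled so its mean diagonal is 1
    (likelihood-ratio tests and variance ratios are invariant to this).
    """
    if isinstance(values, pd.DataFrame):
        if accessions is None:
            accessions = list(values.columns)
        values = values.to_numpy(dtype=float)
    Z = np.asarray(values, dtype=float)
    if Z.ndim != 2:
        raise ValueError("expected a 2-D variants x accessions array")
    sd = Z.std(axis=1)
    informative = sd > 0
    if not informative.any():
        raise ValueError("no informative variants: all rows are constant")
    Z = Z[informative]
    Z = (Z - Z.mean(axis=1, keepdims=True)) / sd[informative][:, None]
    K = Z.T @ Z / Z.shape[0]
    K /= np.diag(K).mean()
    return KinshipMatrix(role=role, matrix=K, accessions=accessions)


def compute_local_kinship(
    genotypes,
    gene: dict | pd.Series,
    window_bp: int = 50000,
    role: str = "local_cis",
) -> KinshipMatrix:
    """Kinship from SNPs within ``window_bp`` of the gene's transcribed interval."""
    chrom = str(gene["chrom"])
    start, end = int(gene["start"]), int(gene["end"])
    sel = (
        (genotypes.chrom.astype(str) == chrom)
        & (genotypes.pos >= start - window_bp)
        & (genotypes.pos < end + window_bp)
    )
    if not sel.any():
        raise EmptyCisWindowError(
            f"no SNPs within {window_bp} bp of {gene.get('gene_id', 'gene')}"
        )
    sub = genotypes.matrix[:, sel].T.astype(float)
    try:
        return compute_kinship(sub, role=role, accessions=list(genotypes.accessions))
    except ValueError as err:
        raise EmptyCisWindowError(str(err)) from err


# ------------------------------------------------------------- model fitting


def _profile_gaussian(
    yt: np.ndarray, Xt: np.ndarray, d: np.ndarray, logdet: float, criterion: str
):
    """Profile beta and the scale out of N(X beta, sigma^2 * diag-like V).

    ``yt``/``Xt`` live in coordinates where V is diagonal with entries ``d``
    (spectral path), or are pre-whitened with d = 1 (generic path, where
    ``logdet`` carries log|V|).
    """
    n, p = Xt.shape
    sqd = np.sqrt(d)
    A = Xt / sqd[:, None]
    b = yt / sqd
    beta, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    p = int(rank)  # effective design rank (projection can zero out columns)
    r = b - A @ beta
    rss = float(r @ r)
    vary = float(np.var(yt)) + 1e-30
    rss = max(rss, 1e-12 * vary)  # guard exact fits; keeps logL finite
    if criterion == "ML":
        s2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)
    else:  # REML
        dof = n - p
        s2 = rss / dof
        sign, logdet_xx = np.linalg.slogdet(A.T @ A)
        ll = -0.5 * (dof * math.log(2 * math.pi * s2) + logdet + logdet_xx + dof)
    return ll, beta, s2


def _fit_no_kinship(y, X, criterion):
    d = np.ones(len(y))
    ll, beta, s2 = _profile_gaussian(y, X, d, 0.0, criterion)
    return ll, beta, s2, {}


def _fit_one_kinship_spectral(y, X, K: KinshipMatrix, criterion, eig=None):
    """1-D profile over the variance ratio delta = sigma_g^2 / sigma_e^2."""
    if eig is None:
        w, Q = eigh(K.matrix)
    else:
        w, Q = eig
    w = np.clip(w, 0.0, None)
    yt = Q.T @ y
    Xt = Q.T @ X

    def negll(log_delta: float) -> float:
        delta = math.exp(log_delta)
        d = w * delta + 1.0
        ll, _, _ = _profile_gaussian(yt, Xt, d, float(np.log(d).sum()), criterion)
        return -ll

    grid_vals = np.array([negll(ld) for ld in _LOG_DELTA_GRID])
    i = int(np.argmin(grid_vals))
    lo = _LOG_DELTA_GRID[max(i - 1, 0)]
    hi = _LOG_DELTA_GRID[min(i + 1, len(_LOG_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    log_delta = float(res.x) if res.fun <= grid_vals[i] else float(_LOG_DELTA_GRID[i])
    delta = math.exp(log_delta)
    d = w * delta + 1.0
    ll, beta, s2 = _profile_gaussian(yt, Xt, d, float(np.log(d).sum()), criterion)
    # boundary delta -> 0 (no genetic variance)
    ll0, beta0, s20, _ = _fit_no_kinship(y, X, criterion)
    if ll0 >= ll:
        return ll0, beta0, s20, {K.role: 0.0}
    return ll, beta, s2, {K.role: delta * s2}


def _fit_multi_kinship(y, X, kinships: tuple[KinshipMatrix, ...], criterion,
                       restarts=(0.1, 1.0, 10.0)):
    """Numerical ML/REML over log variance ratios for >= 2 kinships."""
    n = len(y)
    Ks = [k.matrix for k in kinships]
    ones = np.ones(n)

    def whiten(theta):
        V = np.eye(n)
        for t, K in zip(theta, Ks):
            V = V + t * K
        c, _ = cho_factor(V, lower=True)
        L = np.tril(c)
        logdet = 2.0 * float(np.log(np.diag(c)).sum())
        yt = solve_triangular(L, y, lower=True)
        Xt = solve_triangular(L, X, lower=True)
        return yt, Xt, logdet

    def negll(log_theta: np.ndarray) -> float:
        theta = np.exp(np.clip(log_theta, -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND))
        try:
            yt, Xt, logdet = whiten(theta)
        except np.linalg.LinAlgError:
            return np.inf
        ll, _, _ = _profile_gaussian(yt, Xt, ones, logdet, criterion)
        return -ll

    best = None
    converged = True
    for r in restarts:
        x0 = np.full(len(Ks), math.log(r))
        res = optimize.minimize(
            negll, x0, method="Nelder-Mead",
            options={"fatol": 1e-9, "xatol": 1e-7, "maxiter": 400 * len(Ks)},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        converged = False
    theta = np.exp(np.clip(best.x, -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND))
    yt, Xt, logdet = whiten(theta)
    ll, beta, s2 = _profile_gaussian(yt, Xt, ones, logdet, criterion)
    comps = {k.role: float(t * s2) for k, t in zip(kinships, theta)}
    return ll, beta, s2, comps, converged


def _aliased_projection(kinships, X):
    """Orthonormal basis of the quotient space used for likelihood evaluation.

    Directions annihilated by every kinship AND lying inside span(X) carry no
    information about the variance ratios, but make the profiled ML criterion
    diverge logarithmically (the fixed effect absorbs them exactly while the
    residual variance is pooled over all n dimensions). A column-standardized
    kinship always has the ones vector in its null space, so any model with
    an intercept hits this. Such directions are projected out; the returned
    basis C (n x n_eff) spans their orthogonal complement, or None when no
    direction is aliased.
    """
    Ksum = sum(K.matrix for K in kinships)
    w, U = eigh(Ksum)
    scale = max(float(w[-1]), 1.0)
    null_mask = w < 1e-9 * scale
    if not null_mask.any():
        return None
    N = U[:, null_mask]
    Qx, _ = np.linalg.qr(X)
    resid = N - Qx @ (Qx.T @ N)
    in_x = np.linalg.norm(resid, axis=0) < 1e-8
    if not in_x.any():
        return None
    return np.hstack([U[:, ~null_mask], N[:, ~in_x]])


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray | None = None,
    kinships: tuple[KinshipMatrix, ...] | list[KinshipMatrix] = (),
    criterion: str = "ML",
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> MixedModelFit:
    """Fit Y ~ N(X beta, sum_i K_i sigma_i^2 + I sigma_e^2) by ML or REML.

    ``X`` defaults to an intercept; pass a design WITHOUT adding your own
    all-ones column unless you want only those columns (an intercept column is
    prepended automatically when ``X`` is None, otherwise X is used as given).
    ``eig`` optionally caches the eigendecomposition of the single kinship.

    All proper subsets of the kinship list are also fitted and the best
    log-likelihood returned, so nested fits are monotone in the component set.
    Exactly aliased directions (kinship null space inside span(X)) are
    projected out of the likelihood; ``fit.n_eff`` records the dimension
    actually used, and beta is recovered by full-data GLS at the fitted
    variance ratios.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            raise ValueError("design and trait dimensions disagree")
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    kinships = tuple(kinships)
    for K in kinships:
        if K.n != n:
            raise ValueError("kinship dimension does not match trait length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")

    C = _aliased_projection(kinships, X) if kinships else None
    if C is not None:
        y_w = C.T @ y
        X_w = C.T @ X
        # columns absorbed entirely by the projected-out directions reduce to
        # numerical noise; drop them so lstsq does not treat noise as signal
        col_scale = np.linalg.norm(X, axis=0) + 1.0
        X_w = X_w[:, np.linalg.norm(X_w, axis=0) > 1e-9 * col_scale]
        kin_w = tuple(
            KinshipMatrix(role=K.role, matrix=C.T @ K.matrix @ C) for K in kinships
        )
        eig = None  # cache refers to the unprojected kinship
    else:
        y_w, X_w, kin_w = y, X, kinships

    candidates = []  # (ll, beta, s2, comps, converged)
    ll, beta, s2, _ = _fit_no_kinship(y_w, X_w, criterion)
    candidates.append((ll, beta, s2, {K.role: 0.0 for K in kin_w}, True))
    for r in range(1, len(kin_w) + 1):
        for subset in itertools.combinations(range(len(kin_w)), r):
            sub = tuple(kin_w[i] for i in subset)
            if r == 1:
                use_eig = eig if (len(kin_w) == 1 and subset == (0,)) else None
                ll, beta, s2, comps = _fit_one_kinship_spectral(
                    y_w, X_w, sub[0], criterion, eig=use_eig
                )
                conv = True
            else:
                ll, beta, s2, comps, conv = _fit_multi_kinship(y_w, X_w, sub, criterion)
            full_comps = {K.role: comps.get(K.role, 0.0) for K in kin_w}
            candidates.append((ll, beta, s2, full_comps, conv))

    ll, beta, s2, comps, conv = max(candidates, key=lambda c: c[0])
    if C is not None:
        # GLS beta on the full data at the fitted variance ratios
        V = np.eye(n)
        if s2 > 0:
            for K in kinships:
                V = V + (comps.get(K.role, 0.0) / s2) * K.matrix
        c, _ = cho_factor(V, lower=True)
        L = np.tril(c)
        A = solve_triangular(L, X, lower=True)
        b = solve_triangular(L, y, lower=True)
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    comps = dict(comps)
    comps["residual"] = float(s2)
    return MixedModelFit(
        beta=np.asarray(beta, dtype=float),
        variance_components=comps,
        log_likelihood=float(ll),
        criterion=criterion,
        converged=bool(conv),
        n=n,
        kinship_roles=tuple(K.role for K in kinships),
        X=X,
        kinships=kinships,
        n_eff=len(y_w),
    )


# ----------------------------------------------------------------------- LRT


@dataclass
class LRTResult:
    statistic: float
    p_value: float
    df: int


def likelihood_ratio_test(fit_full: MixedModelFit, fit_null: MixedModelFit) -> LRTResult:
    """Boundary-corrected LRT for extra variance component(s).

    Under the null the statistic for one extra component follows the
    0.5*chi2_0 + 0.5*chi2_1 mixture (the component variance sits on the
    boundary of its parameter space); for df extra components the
    0.5*(chi2_{df-1} + chi2_df) mixture is used.
    """
    if fit_full.criterion != "ML" or fit_null.criterion != "ML":
        raise ValueError("likelihood ratio tests require ML fits (not REML)")
    if fit_full.n != fit_null.n or len(fit_full.beta) != len(fit_null.beta):
        raise ValueError("models do not appear to be fitted on the same data/design")
    if fit_full.n_eff != fit_null.n_eff:
        raise ValueError(
            "fits use different quotient-space dimensions; log-likelihoods "
            "are not comparable"
        )
    if not set(fit_null.kinship_roles) <= set(fit_full.kinship_roles):
        raise ValueError("null model components are not a subset of the full model's")
    df = len(fit_full.kinship_roles) - len(fit_null.kinship_roles)
    if df < 0:
        raise ValueError("full model must have at least the null's variance components")
    stat = 2.0 * (fit_full.log_likelihood - fit_null.log_likelihood)
    if df == 0:
        # identical model structure: the test is vacuous
        return LRTResult(statistic=max(stat, 0.0), p_value=1.0, df=0)
    if stat < -1e-6:
        raise ValueError(
            "full-model log-likelihood is below the null's: arguments swapped?"
        )
    stat = max(stat, 0.0)
    if stat == 0.0:
        p = 1.0
    elif df == 1:
        p = 0.5 * stats.chi2.sf(stat, 1)  # 0.5*chi2_0 + 0.5*chi2_1 mixture
    else:
        p = 0.5 * (stats.chi2.sf(stat, df - 1) + stats.chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), p_value=float(min(max(p, 0.0), 1.0)), df=df)
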