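"""BIC-based selection among causal genotype/methylation/expression models.

Four causal structures relate genotype (G, fixed-effect SNPs X plus a
polygenic random effect with kinship K_S), a methylation bin (M) and an
expression trait (E):

  Model I   L = p(e|m) p(m|g) p(g)      (G -> M -> E)
  Model II  L = p(m|e) p(e|g) p(g)      (G -> E -> M)
  Model III L = p(e|g) p(m|g) p(g)      (independent control)
  Model IV  L = p(e|m,g) p(m|g) p(g) = p(m|e,g) p(e|g) p(g)   (full model)

Trait-on-trait conditionals are ordinary least-squares Gaussian regressions;
genotype conditionals are ML mixed models with the K_S random term. p(g) is
identical across models and dropped. Models are compared with
BIC = -2 logL + k ln(n), and the winner is called only when it beats the
runner-up by at least 3 BIC units; otherwise the gene is labelled ambiguous.
Model IV is evaluated under both factorizations and the larger maximized
likelihood is used, which makes it nest Models I-III exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from epiqtl.gwas import build_rotation, cis_distance, marginal_scan
from epiqtl.lmm import KinshipMatrix, fit_mixed_model

MODELS = ("I", "II", "III", "IV")


@dataclass
class CausalInput:
    """One expression/methylation pair prepared for causal analysis."""

    gene_id: str
    e: np.ndarray
    m: np.ndarray
    X: np.ndarray | None  # shared large-effect SNP cofactors, accessions x q
    r2: float = float("nan")
    bin_id: str = ""
    shared_snps: list[str] = field(default_factory=list)


@dataclass
class CausalFit:
    """Per-gene likelihoods, parameter counts, BICs and the assigned label."""

    loglik: dict[str, float]
    k: dict[str, int]
    bic: dict[str, float]
    label: str
    gene_id: str = ""


def _ols_loglik(yv: np.ndarray, X: np.ndarray) -> float:
    """Gaussian ML log-likelihood of an OLS regression at the LS fit."""
    n = len(yv)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    r = yv - X @ beta
    rss = float(r @ r)
    rss = max(rss, 1e-12 * (float(np.var(yv)) + 1e-30))
    s2 = rss / n
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


class KinshipWorkspace:
    """Shared contrast-space reduction of one kinship for causal fits.

    Every component likelihood (trait-on-trait least squares and
    genotype-conditional mixed models) must be evaluated on the same sample
    space for the BICs to be comparable. When the kinship annihilates the
    ones vector (the standard variant-standardized construction), the grand
    mean carries no information and makes the profiled ML criteria
    inconsistent between components, so all traits and designs are reduced
    to the (n-1)-dimensional contrast space first; intercepts are absorbed
    exactly and dropped from the designs (but still counted in k).
    """

    def __init__(self, K_S: KinshipMatrix):
        from epiqtl.lmm import _aliased_projection

        n = K_S.n
        self.n = n
        self.C = _aliased_projection((K_S,), np.ones((n, 1)))
        if self.C is None:
            self.K = K_S
        else:
            self.K = KinshipMatrix(role=K_S.role, matrix=self.C.T @ K_S.matrix @ self.C)
        w, Q = eigh(self.K.matrix)
        self.eig = (np.clip(w, 0.0, None), Q)
        self.n_c = self.K.n

    def reduce(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return v if self.C is None else self.C.T @ v

    def design(self, *blocks) -> np.ndarray:
        """Stack design columns, prepending an intercept when not absorbed."""
        cols = [] if self.C is not None else [np.ones((self.n, 1))]
        for b in blocks:
            if b is None:
                continue
            b = np.atleast_2d(np.asarray(b, dtype=float))
            if b.shape[0] != self.n:
                b = b.T
            cols.append(self.reduce(b))
        if not cols:
            return np.empty((self.n_c, 0))
        return np.hstack(cols)

    def mm_loglik(self, yv: np.ndarray, X: np.ndarray) -> float:
        fit = fit_mixed_model(yv, X, kinships=(self.K,), criterion="ML",
                              eig=self.eig)
        return fit.log_likelihood


def model_loglikelihood(
    model: str,
    inp: CausalInput,
    K_S: KinshipMatrix,
    workspace: KinshipWorkspace | None = None,
) -> tuple[float, int]:
    """Maximized log-likelihood and free-parameter count of one causal model.

    The constant p(g) factor is omitted (identical across models, so BIC
    differences are unaffected). Parameter counts use the nominal
    parameterization: per Gaussian component one intercept, one slope per
    regressor, one residual variance, plus a kinship variance for the
    genotype-conditional components.
    """
    if model not in MODELS:
        raise ValueError(f"unknown causal model {model!r}")
    ws = workspace if workspace is not None else KinshipWorkspace(K_S)
    e = ws.reduce(np.asarray(inp.e, float))
    m = ws.reduce(np.asarray(inp.m, float))
    q = 0 if inp.X is None else np.atleast_2d(np.asarray(inp.X)).shape[1]
    Xg = ws.design(inp.X)  # genotype cofactors (+ intercept if not absorbed)
    k_g = q + 3  # p(.|g): intercept + q slopes + sigma_S^2 + sigma_e^2

    if model == "I":
        ll = _ols_loglik(e, np.hstack([ws.design(), m[:, None]]))  # p(e|m)
        return ll + ws.mm_loglik(m, Xg), 3 + k_g
    if model == "II":
        ll = _ols_loglik(m, np.hstack([ws.design(), e[:, None]]))
        return ll + ws.mm_loglik(e, Xg), 3 + k_g
    if model == "III":
        return ws.mm_loglik(e, Xg) + ws.mm_loglik(m, Xg), 2 * k_g
    # Model IV: both factorizations of the full model; the larger maximized
    # likelihood is used, so Model IV nests Models I-III exactly
    fact1 = ws.mm_loglik(e, np.hstack([Xg, m[:, None]])) + ws.mm_loglik(m, Xg)
    fact2 = ws.mm_loglik(m, np.hstack([Xg, e[:, None]])) + ws.mm_loglik(e, Xg)
    return max(fact1, fact2), 2 * q + 7


def compute_bic(loglik: float, k: int, n: int = 135) -> float:
    """Bayesian Information Criterion, -2 logL + k ln(n)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if n < 2:
        raise ValueError("n must be >= 2")
    return -2.0 * loglik + k * math.log(n)


def classify_causal_model(bic: dict[str, float], gap: float = 3.0) -> str:
    """argmin-BIC label, or 'ambiguous' if the runner-up is within ``gap``."""
    if set(bic) != set(MODELS):
        raise ValueError(f"need BIC values for all of {MODELS}")
    ordered = sorted(MODELS, key=lambda mdl: bic[mdl])
    if bic[ordered[1]] - bic[ordered[0]] < gap:
        return "ambiguous"
    return ordered[0]


def fit_causal_models(
    inp: CausalInput,
    K_S: KinshipMatrix,
    workspace: KinshipWorkspace | None = None,
    gap: float = 3.0,
    n: int | None = None,
) -> CausalFit:
    """Likelihoods, BICs and label for all four models on one pair."""
    ws = workspace if workspace is not None else KinshipWorkspace(K_S)
    n_eff = n if n is not None else len(inp.e)
    loglik, kpar, bic = {}, {}, {}
    for mdl in MODELS:
        ll, k = model_loglikelihood(mdl, inp, K_S, workspace=ws)
        loglik[mdl], kpar[mdl] = ll, k
        bic[mdl] = compute_bic(ll, k, n_eff)
    return CausalFit(loglik=loglik, k=kpar, bic=bic,
                     label=classify_causal_model(bic, gap=gap),
                     gene_id=inp.gene_id)


# --------------------------------------------------------- pair preselection


def _greedy_prune(C: np.ndarray, order: np.ndarray, r2_max: float = 0.9,
                  cap: int = 5) -> list[int]:
    """Keep up to ``cap`` columns in priority order, dropping near-duplicates."""
    kept: list[int] = []
    for j in order:
        x = C[:, j]
        if np.std(x) == 0:
            continue
        dup = False
        for i in kept:
            r = np.corrcoef(x, C[:, i])[0, 1]
            if r * r > r2_max:
                dup = True
                break
        if not dup:
            kept.append(int(j))
        if len(kept) >= cap:
            break
    return kept


def select_causal_pairs(
    expression: pd.DataFrame,
    bins: pd.DataFrame,
    annotation: pd.DataFrame,
    genotypes,
    K_S: KinshipMatrix,
    r2_threshold: float = 0.2,
    tss_window: int = 2000,
    cis_window: int = 50000,
    cis_p_threshold: float = 1e-5,
    alpha: float = 0.05,
    kinship_fraction: float = 0.05,
) -> list[CausalInput]:
    """Build the causal testing pool of expression/methylation pairs.

    Per gene: correlate expression with every methylation bin inside the gene
    or within ``tss_window`` bp of the TSS; if the best bin reaches
    r^2 > ``r2_threshold`` the pair is a candidate. A candidate is retained
    if the two traits share an associated SNP (Bonferroni threshold for trans
    SNPs, defined as > ``cis_window`` bp away; ``cis_p_threshold`` for cis
    SNPs) or if either trait's kinship component explains at least
    ``kinship_fraction`` of its variance. Shared significant SNPs become the
    fixed-effect cofactors X (LD-pruned, up to five).
    """
    from epiqtl.datatypes import BIN_META_COLUMNS

    acc = [c for c in bins.columns if c not in BIN_META_COLUMNS]
    w, Q = eigh(K_S.matrix)
    eig = (np.clip(w, 0.0, None), Q)
    G = genotypes.matrix.astype(float)
    bonferroni_p = alpha / max(genotypes.n_snps, 1)
    pairs: list[CausalInput] = []

    for _, gene in annotation.iterrows():
        gid = gene["gene_id"]
        if gid not in expression.index:
            continue
        e = expression.loc[gid, acc].to_numpy(dtype=float)
        tss = int(gene["start"]) if gene["strand"] == "+" else int(gene["end"]) - 1
        same_chrom = bins["chrom"].astype(str) == str(gene["chrom"])
        mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2.0
        in_gene = (mid >= int(gene["start"])) & (mid < int(gene["end"]))
        near_tss = np.abs(mid - tss) <= tss_window
        cand = bins.loc[same_chrom.to_numpy() & (in_gene | near_tss)]
        if not len(cand):
            continue
        levels = cand[acc].to_numpy(dtype=float)
        sd = levels.std(axis=1)
        ok = sd > 0
        if not ok.any() or e.std() == 0:
            continue
        zc = (levels[ok] - levels[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
        ze = (e - e.mean()) / e.std()
        r = zc @ ze / len(e)
        best = int(np.argmax(r**2))
        if r[best] ** 2 <= r2_threshold:
            continue
        row = cand.iloc[np.flatnonzero(ok)[best]]
        m = row[acc].to_numpy(dtype=float)
        bin_id = f"{row['chrom']}:{int(row['start'])}-{int(row['end'])}"

        # shared associated SNPs at the cis/trans thresholds
        cache_e = build_rotation(e, K_S, eig=eig)
        cache_m = build_rotation(m, K_S, eig=eig)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_e = marginal_scan(e, G, cache_e, positions=genotypes.pos,
                                  chroms=genotypes.chrom,
                                  variant_ids=genotypes.snp_ids)
            res_m = marginal_scan(m, G, cache_m, positions=genotypes.pos,
                                  chroms=genotypes.chrom,
                                  variant_ids=genotypes.snp_ids)
        d = np.array([
            cis_distance(int(p), int(gene["start"]), int(gene["end"]))
            if str(c) == str(gene["chrom"]) else np.iinfo(np.int64).max
            for p, c in zip(genotypes.pos, genotypes.chrom)
        ])
        is_cis = d <= cis_window
        thr = np.where(is_cis, cis_p_threshold, bonferroni_p)
        shared = (res_e["p"].to_numpy() < thr) & (res_m["p"].to_numpy() < thr)

        keep = False
        if shared.any():
            keep = True
        else:
            fe = fit_mixed_model(e, kinships=(K_S,), criterion="ML", eig=eig)
            fm = fit_mixed_model(m, kinships=(K_S,), criterion="ML", eig=eig)
            if (fe.genetic_fraction(K_S.role) >= kinship_fraction
                    or fm.genetic_fraction(K_S.role) >= kinship_fraction):
                keep = True
        if not keep:
            continue

        X = None
        shared_ids: list[str] = []
        if shared.any():
            idx = np.flatnonzero(shared)
            worst_p = np.maximum(res_e["p"].to_numpy()[idx], res_m["p"].to_numpy()[idx])
            pruned = _greedy_prune(G[:, idx], np.argsort(worst_p))
            cols = idx[pruned]
            if len(cols):
                X = G[:, cols]
                shared_ids = [genotypes.snp_ids[c] for c in cols]
        pairs.append(CausalInput(gene_id=gid, e=e, m=m, X=X,
                                 r2=float(r[best] ** 2), bin_id=bin_id,
                                 shared_snps=shared_ids))
    return pairs


# ------------------------------------------------------------ recovery study


def run_causal_simulation_study(
    genotypes,
    configs: list,
    n_reps: int = 100,
    seed: int = 0,
    use_true_snp: bool = True,
) -> pd.DataFrame:
    """Confusion matrix (true model x assigned label) over simulated pairs.

    For each config and replicate, a trait pair is simulated, the
    large-effect SNP (when present) enters as the fixed cofactor X, all four
    models are fitted and the BIC label recorded. Deterministic given seed.
    """
    from epiqtl.lmm import compute_kinship
    from epiqtl.simulate import TraitSimConfig, simulate_trait_pair

    K_S = compute_kinship(genotypes.matrix.T.astype(float), role="global_snp")
    ws = KinshipWorkspace(K_S)
    rng = np.random.default_rng(seed)
    labels = list(MODELS) + ["ambiguous"]
    counts = {cfg.model: {lab: 0 for lab in labels} for cfg in configs}

    for cfg in configs:
        for rep in range(n_reps):
            rep_seed = int(rng.integers(2**31 - 1))
            rc = TraitSimConfig(**{**cfg.__dict__, "seed": rep_seed})
            pair = simulate_trait_pair(genotypes, rc)
            X = None
            if use_true_snp and rc.n_large_effects:
                x = genotypes.matrix[:, pair.truth["large_idx"]].astype(float)
                if x.std() > 0:
                    X = x[:, None]
            inp = CausalInput(gene_id=f"{cfg.model}_{rep}", e=pair.e, m=pair.m, X=X)
            fit = fit_causal_models(inp, K_S, workspace=ws,
                                    n=genotypes.n_individuals)
            counts[cfg.model][fit.label] += 1

    out = pd.DataFrame(counts).T.reindex(columns=labels).fillna(0).astype(int)
    out.index.name = "true_model"
    return out
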