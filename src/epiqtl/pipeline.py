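"""End-to-end orchestration: bundle -> filters -> kinships -> scans -> causal.

Every stage writes a TSV under the output directory and the run is sealed
with a JSON manifest (config, seed, package version, config hash), so that
identical config + seed reproduces identical outputs and each stage can be
re-run from the intermediate files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from epiqtl import io as eio
from epiqtl.datatypes import BIN_META_COLUMNS, check_same_accessions
from epiqtl.gwas import (
    build_rotation,
    cis_distance,
    cis_trans_fdr_bound,
    label_cis,
    marginal_scan,
    stepwise_scan,
)
from epiqtl.lmm import EmptyCisWindowError, compute_kinship, compute_local_kinship
from epiqtl.preprocess import (
    bin_methylation_levels,
    filter_expression,
    filter_methylation_bins,
    filter_snps_maf,
    transform_trait_table,
)
from epiqtl.causal import fit_causal_models, select_causal_pairs
from epiqtl.varpart import (
    fit_nested_cis_models,
    partition_variance,
    test_genomewide_methylation_effect,
)

logger = logging.getLogger("epiqtl")


@dataclass
class RunConfig:
    """All thresholds and window sizes of a pipeline run."""

    genotypes: str = ""
    methylation: str = ""
    expression: str = ""
    annotation: str = ""
    out_dir: str = "epiqtl_run"
    bin_window: int = 200
    bin_step: int = 100
    cis_window_fdr: int = 20000  # cis/trans FDR labelling
    cis_window_scan: int = 50000  # candidate sets, local kinship
    tss_window_causal: int = 2000
    maf_threshold: float = 0.05
    cv_threshold: float = 0.05
    outlier_threshold: float = 75.0
    anscombe_mean_threshold: float = 3.0
    r2_threshold: float = 0.2
    cis_p_threshold: float = 1e-5
    bic_gap: float = 3.0
    alpha: float = 0.05
    transform: str = "inverse_normal"  # or "untransformed"
    relax_expression_filter: bool = False  # keep low/no-expression genes too
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_window", "bin_step", "cis_window_fdr", "cis_window_scan",
                     "maf_threshold", "cv_threshold", "outlier_threshold",
                     "anscombe_mean_threshold", "r2_threshold", "cis_p_threshold",
                     "bic_gap", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.transform not in ("inverse_normal", "untransformed"):
            raise ValueError("transform must be inverse_normal or untransformed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class _StageTimer:
    """Logs per-stage wall time to the package logger."""

    def __init__(self) -> None:
        self.t0 = time.time()

    def done(self, name: str) -> None:
        logger.info("stage %-24s %6.2fs", name, time.time() - self.t0)
        self.t0 = time.time()


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write per-stage TSVs plus a manifest.

    Returns a dict of in-memory results keyed by stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timer = _StageTimer()

    # ---- load
    genotypes = eio.read_genotypes_tsv(config.genotypes) \
        if not str(config.genotypes).endswith(".vcf") \
        else eio.read_genotypes_vcf(config.genotypes)
    cyto = eio.read_cytosine_tsv(config.methylation)
    expr_raw = eio.read_expression_tsv(config.expression)
    annotation = eio.read_annotation_gff3(config.annotation)
    accessions = check_same_accessions(genotypes.accessions, expr_raw.columns)
    timer.done("load")

    # ---- preprocess
    genotypes = filter_snps_maf(genotypes, config.maf_threshold)
    if genotypes.n_snps == 0:
        raise ValueError("no SNPs survive the MAF filter")
    if config.relax_expression_filter:
        expr = expr_raw.loc[expr_raw.std(axis=1) > 0]
    else:
        expr = filter_expression(expr_raw, config.anscombe_mean_threshold,
                                 config.cv_threshold)
    bins = bin_methylation_levels(cyto, window=config.bin_window,
                                  step=config.bin_step, accessions=accessions)
    bins = filter_methylation_bins(bins, config.cv_threshold,
                                   config.outlier_threshold)
    eio.write_bins_tsv(bins, out_dir / "bins.filtered.tsv")
    expr.to_csv(out_dir / "expression.filtered.tsv", sep="\t")

    expr_t = transform_trait_table(expr, config.transform)
    bin_levels = bins[accessions].to_numpy(dtype=float)
    bins_t = bins.copy()
    bins_t[accessions] = transform_trait_table(
        pd.DataFrame(bin_levels, columns=accessions), config.transform
    ).to_numpy()

    # ---- kinships
    K_S = compute_kinship(genotypes.matrix.T.astype(float), role="global_snp",
                          accessions=accessions)
    timer.done("preprocess")
    eio.write_kinship_tsv(K_S.matrix, accessions, out_dir / "kinship_snp.tsv")
    K_M = None
    if len(bins) >= 2:
        K_M = compute_kinship(bin_levels, role="methylation", accessions=accessions)
        eio.write_kinship_tsv(K_M.matrix, accessions, out_dir / "kinship_meth.tsv")
    results["kinships"] = {"K_S": K_S, "K_M": K_M}

    # ---- genome-wide methylation background test per expression trait
    gw_rows = []
    if K_M is not None:
        for gid in expr_t.index:
            y = expr_t.loc[gid].to_numpy(dtype=float)
            test = test_genomewide_methylation_effect(y, K_S, K_M)
            gw_rows.append({"gene_id": gid, "lrt_stat": test.lrt.statistic,
                            "lrt_p": test.lrt.p_value,
                            "sigma2_M": test.fit_full.variance_components.get(
                                "methylation", 0.0)})
    gw = pd.DataFrame(gw_rows)
    gw.to_csv(out_dir / "genomewide_methylation_test.tsv", sep="\t", index=False)
    results["genomewide"] = gw
    timer.done("genomewide_methylation")

    # ---- per-gene scans, nested cis models, partitions
    scan_rows, part_rows = [], []
    cis_counts = {"cis_hits": 0, "cis_tests": 0, "trans_hits": 0, "trans_tests": 0}
    bin_mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    for _, gene in annotation.iterrows():
        gid = gene["gene_id"]
        if gid not in expr_t.index:
            continue
        y = expr_t.loc[gid].to_numpy(dtype=float)
        cache = build_rotation(y, K_S)
        scan = marginal_scan(y, genotypes.matrix.astype(float), cache,
                             variant_ids=genotypes.snp_ids,
                             positions=genotypes.pos, chroms=genotypes.chrom,
                             variant_type="snp")
        if len(bins):
            mscan = marginal_scan(
                y, bins_t[accessions].to_numpy(dtype=float).T, cache,
                variant_ids=[f"bin:{c}:{s}-{e}:{x}" for c, s, e, x in
                             zip(bins["chrom"], bins["start"], bins["end"],
                                 bins["context_class"])],
                positions=bin_mid, chroms=bins["chrom"].to_numpy(),
                variant_type="meth_bin")
            scan = pd.concat([scan, mscan], ignore_index=True)
        scan = label_cis(scan, gene, config.cis_window_fdr)
        scan.insert(0, "trait_id", gid)
        scan_rows.append(scan)
        sig = scan["p"] < config.alpha / len(scan)
        cis_counts["cis_hits"] += int((sig & scan["cis_flag"]).sum())
        cis_counts["trans_hits"] += int((sig & ~scan["cis_flag"]).sum())
        cis_counts["cis_tests"] += int(scan["cis_flag"].sum())
        cis_counts["trans_tests"] += int((~scan["cis_flag"]).sum())

        # nested cis models
        d_snp = np.array([cis_distance(int(p), int(gene["start"]), int(gene["end"]))
                          if str(c) == str(gene["chrom"]) else np.iinfo(np.int64).max
                          for p, c in zip(genotypes.pos, genotypes.chrom)])
        cis_snp_idx = np.flatnonzero(d_snp < config.cis_window_scan)
        d_bin = np.array([cis_distance(int(p), int(gene["start"]), int(gene["end"]))
                          if str(c) == str(gene["chrom"]) else np.iinfo(np.int64).max
                          for p, c in zip(bin_mid, bins["chrom"])]) \
            if len(bins) else np.array([], dtype=int)
        cis_bin_idx = np.flatnonzero(d_bin < config.cis_window_scan)
        try:
            K_l = compute_local_kinship(genotypes, gene, config.cis_window_scan)
        except EmptyCisWindowError:
            K_l = None
        nested = fit_nested_cis_models(
            y,
            genotypes.matrix[:, cis_snp_idx].astype(float) if len(cis_snp_idx) else None,
            bins_t[accessions].to_numpy(dtype=float).T[:, cis_bin_idx]
            if len(cis_bin_idx) else None,
            K_S, K_l,
            snp_positions=genotypes.pos[cis_snp_idx],
            meth_positions=bin_mid[cis_bin_idx] if len(cis_bin_idx) else None,
            alpha=config.alpha,
        )
        part = partition_variance(nested)
        part_rows.append({"gene_id": gid, **part.as_dict(),
                          "n_snp_cofactors": len(nested.snp_cofactors),
                          "n_meth_cofactors": len(nested.meth_cofactors),
                          "logL_genetics": nested.genetics_fit.log_likelihood,
                          "logL_full": nested.full_fit.log_likelihood})

    scans = pd.concat(scan_rows, ignore_index=True) if scan_rows else pd.DataFrame()
    scans.to_csv(out_dir / "association_scans.tsv", sep="\t", index=False)
    parts = pd.DataFrame(part_rows)
    parts.to_csv(out_dir / "variance_partition.tsv", sep="\t", index=False)
    results["scans"] = scans
    results["partitions"] = parts
    try:
        results["cis_fdr_bound"] = cis_trans_fdr_bound(**cis_counts)
    except ValueError:
        results["cis_fdr_bound"] = None
    results["cis_counts"] = cis_counts
    timer.done("scans_and_partitions")

    # ---- causal analysis
    causal_rows = []
    if len(bins):
        pairs = select_causal_pairs(
            expr_t, bins_t, annotation, genotypes, K_S,
            r2_threshold=config.r2_threshold,
            tss_window=config.tss_window_causal,
            cis_window=config.cis_window_scan,
            cis_p_threshold=config.cis_p_threshold,
            alpha=config.alpha,
        )
        for pair in pairs:
            fit = fit_causal_models(pair, K_S, gap=config.bic_gap)
            causal_rows.append({
                "gene_id": pair.gene_id, "bin_id": pair.bin_id, "r2": pair.r2,
                **{f"logL_{mdl}": fit.loglik[mdl] for mdl in fit.loglik},
                **{f"k_{mdl}": fit.k[mdl] for mdl in fit.k},
                **{f"BIC_{mdl}": fit.bic[mdl] for mdl in fit.bic},
                "label": fit.label,
            })
    causal = pd.DataFrame(causal_rows)
    causal.to_csv(out_dir / "causal_calls.tsv", sep="\t", index=False)
    results["causal"] = causal
    timer.done("causal")

    # ---- manifest + summary
    import epiqtl

    manifest = {
        "package_version": epiqtl.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_accessions": len(accessions),
        "n_snps_after_maf": genotypes.n_snps,
        "n_genes_after_filter": int(len(expr)),
        "n_bins_after_filter": int(len(bins)),
        "cis_counts": cis_counts,
        "cis_fdr_bound": results["cis_fdr_bound"],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results


# ----------------------------------------------- positional r profiles


def summarize_correlation_profiles(
    expression: pd.DataFrame,
    bins: pd.DataFrame,
    annotation: pd.DataFrame,
    n_upstream: int = 5,
    n_body: int = 10,
    n_downstream: int = 5,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Pearson r between expression and cis bins on a normalized gene axis.

    Positions are mapped strand-aware onto ``n_upstream`` flank slots before
    the TSS, ``n_body`` slots across the gene body, and ``n_downstream``
    slots past the TTS. Zero-variance traits/bins are excluded (counted in
    the returned frame's complement). Returns one row per (gene, bin) with
    the slot index, context class and r.
    """
    acc = [c for c in bins.columns if c not in BIN_META_COLUMNS]
    rows = []
    mid_all = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2.0
    n_slots = n_upstream + n_body + n_downstream
    for _, gene in annotation.iterrows():
        gid = gene["gene_id"]
        if gid not in expression.index:
            continue
        e = expression.loc[gid, acc].to_numpy(dtype=float)
        if e.std() == 0:
            continue
        gstart, gend = int(gene["start"]), int(gene["end"])
        plus = gene["strand"] != "-"
        same = bins["chrom"].astype(str) == str(gene["chrom"])
        lo, hi = gstart - flank_bp, gend + flank_bp
        sel = same.to_numpy() & (mid_all >= lo) & (mid_all < hi)
        for i in np.flatnonzero(sel):
            mid = mid_all[i]
            # signed position relative to the gene, flipped for minus strand
            if mid < gstart:
                frac = (mid - gstart) / flank_bp  # in [-1, 0)
            elif mid >= gend:
                frac = 1.0 + (mid - gend) / flank_bp  # in [1, 2)
            else:
                frac = (mid - gstart) / max(gend - gstart, 1)  # [0, 1)
            if not plus:
                frac = 1.0 - frac
            if frac < 0:
                slot = int(n_upstream + frac * n_upstream)
                slot = max(slot, 0)
            elif frac < 1:
                slot = n_upstream + int(frac * n_body)
            else:
                slot = n_upstream + n_body + min(int((frac - 1.0) * n_downstream),
                                                 n_downstream - 1)
            levels = bins.iloc[i][acc].to_numpy(dtype=float)
            if levels.std() == 0:
                continue
            r = float(np.corrcoef(levels, e)[0, 1])
            rows.append({"gene_id": gid, "chrom": bins.iloc[i]["chrom"],
                         "bin_start": int(bins.iloc[i]["start"]),
                         "context_class": bins.iloc[i]["context_class"],
                         "slot": min(slot, n_slots - 1), "r": r})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "bin_start",
                                       "context_class", "slot", "r"])
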