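"""Synthetic genotype, methylome, and expression generators.

The generators emulate the statistical structure of a structured panel of
inbred A. thaliana accessions: haploid-coded biallelic SNPs under a
Balding-Nichols subpopulation model, 200-bp methylation bins in four context
classes partly driven by cis SNPs, and expression traits generated under
four causal structures linking genotype (G), methylation (M) and
expression (E):

  Model I   G -> M -> E (methylation mediates all genetic effects)
  Model II  G -> E -> M
  Model III G -> M and G -> E independently
  Model IV  Model III plus a direct link between the traits

Each trait is a sum of an optional large-effect SNP, a polygenic background
of many small SNP effects, and Gaussian noise, with components rescaled to
requested variance fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from epiqtl.datatypes import CONTEXT_CLASSES, GenotypeMatrix

_SNP_SPACING = 1000  # bp between simulated SNPs on the single chromosome


@dataclass
class PopulationConfig:
    """Structured-panel genotype simulation settings.

    divergence is the Balding-Nichols F_ST-like parameter in [0, 1]; at 0 all
    subpopulations share the ancestral allele frequencies.
    """

    n_individuals: int = 135
    n_snps: int = 1000
    n_subpops: int = 3
    divergence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")


@dataclass
class TraitSimConfig:
    """Settings for one simulated methylation/expression trait pair.

    h2_large and h2_poly are the variance fractions of the large-effect SNP
    and the polygenic background in the upstream trait; link_strength is the
    variance fraction the downstream trait inherits from the upstream trait
    (Models I/II/IV). shared_small_fraction splits the polygenic background
    into SNP effects shared by both traits vs private to each (Models III/IV).
    """

    model: str = "I"
    n_large_effects: int = 1
    n_small_effects: int = 10000
    h2_large: float = 0.3
    h2_poly: float = 0.3
    link_strength: float = 0.5
    shared_small_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in {"I", "II", "III", "IV"}:
            raise ValueError(f"unknown causal model label: {self.model!r}")
        if self.n_large_effects not in (0, 1):
            raise ValueError("n_large_effects must be 0 or 1")
        for name in ("h2_large", "h2_poly", "link_strength", "shared_small_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.h2_large + self.h2_poly > 1.0 + 1e-12:
            raise ValueError("h2_large + h2_poly must not exceed 1")


@dataclass
class SimulatedBins:
    """Bin table plus per-bin ground truth from simulate_methylation_bins."""

    bins: pd.DataFrame
    causal_snp: np.ndarray  # SNP column index driving each bin, -1 if none
    preclip_levels: np.ndarray  # bins x accessions, before [0,1] clipping


@dataclass
class TraitPair:
    """Simulated (methylation, expression) pair with generating ground truth."""

    m: np.ndarray
    e: np.ndarray
    truth: dict = field(default_factory=dict)


def simulate_structured_genotypes(config: PopulationConfig) -> GenotypeMatrix:
    """Draw haploid 0/1 genotypes under a Balding-Nichols subpopulation model.

    Ancestral allele frequencies are uniform on [0.05, 0.95]; each
    subpopulation draws its own frequency from the Beta distribution with
    mean p and "divergence" F, then individuals draw alleles independently.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    p_anc = rng.uniform(0.05, 0.95, size=m)
    subpop = np.arange(n) % config.n_subpops
    F = config.divergence
    if F > 0 and config.n_subpops > 1:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        freqs = rng.beta(a, b, size=(config.n_subpops, m))
    else:
        freqs = np.broadcast_to(p_anc, (config.n_subpops, m)).copy()
    geno = (rng.random((n, m)) < freqs[subpop, :]).astype(np.int8)
    pos = np.arange(m, dtype=np.int64) * _SNP_SPACING
    chrom = np.repeat("1", m)
    return GenotypeMatrix(
        matrix=geno,
        chrom=chrom,
        pos=pos,
        accessions=[f"acc{i:04d}" for i in range(n)],
        subpop=subpop,
    )


def _base_level(context_class: str, rng: np.random.Generator) -> float:
    # typical plant methylation baselines: CG bins intermediate-to-high,
    # CHG intermediate, CHH low
    lo, hi = {
        "CG_only": (0.3, 0.8),
        "CG_in_C": (0.3, 0.8),
        "CHG": (0.1, 0.5),
        "CHH": (0.05, 0.3),
    }[context_class]
    return float(rng.uniform(lo, hi))


def simulate_methylation_bins(
    genotypes: GenotypeMatrix,
    n_bins: int,
    cis_fraction: float = 0.5,
    effect_size: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
    region_offset: int = 0,
) -> SimulatedBins:
    """Simulate 200-bp methylation bins, a fraction of them driven by a SNP.

    A cis bin's level is an affine function of a nearby SNP plus Gaussian
    noise; all levels are clipped to [0, 1] afterwards (they are
    proportions). ``region_offset`` shifts bin coordinates, e.g. to place
    background bins away from simulated genes.
    """
    if genotypes.n_snps == 0 or genotypes.n_individuals == 0:
        raise ValueError("genotypes must be nonempty")
    if not 0.0 <= cis_fraction <= 1.0:
        raise ValueError("cis_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    n_cis = int(round(cis_fraction * n_bins))
    is_cis = np.zeros(n_bins, dtype=bool)
    if n_cis:
        is_cis[rng.choice(n_bins, size=n_cis, replace=False)] = True

    rows = []
    causal = np.full(n_bins, -1, dtype=np.int64)
    preclip = np.empty((n_bins, n), dtype=float)
    for i in range(n_bins):
        ctx = CONTEXT_CLASSES[i % 4]
        snp_idx = int(rng.integers(genotypes.n_snps))
        # window containing (or near) the designated SNP
        start = max(0, int(genotypes.pos[snp_idx]) - 100) + region_offset
        base = _base_level(ctx, rng)
        level = np.full(n, base)
        if is_cis[i]:
            g = genotypes.matrix[:, snp_idx].astype(float)
            level = level + effect_size * (g - g.mean())
            causal[i] = snp_idx
        if noise_sd > 0:
            level = level + rng.normal(0.0, noise_sd, size=n)
        preclip[i] = level
        rows.append(
            {
                "chrom": str(genotypes.chrom[snp_idx]),
                "start": start,
                "end": start + 200,
                "context_class": ctx,
                **dict(zip(genotypes.accessions, np.clip(level, 0.0, 1.0))),
            }
        )
    bins = pd.DataFrame(rows)
    return SimulatedBins(bins=bins, causal_snp=causal, preclip_levels=preclip)


def _scaled(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center x and rescale to an exact sample variance target."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    sd = x.std()
    if sd == 0 or target_var == 0:
        return np.zeros_like(x)
    return x / sd * np.sqrt(target_var)


def simulate_trait_pair(genotypes: GenotypeMatrix, config: TraitSimConfig) -> TraitPair:
    """Generate one (M, E) trait pair under causal Model I, II, III or IV.

    Each upstream trait is the sum of 0-1 large-effect SNP, a polygenic
    background of ``n_small_effects`` i.i.d. per-SNP effects, and Gaussian
    noise, with components rescaled so their sample variances match the
    requested fractions. Model IV consumes randomness on the same path as
    Model III, so link_strength=0 reproduces Model III exactly.
    """
    if config.n_small_effects > genotypes.n_snps:
        raise ValueError("n_small_effects exceeds the number of available SNPs")
    rng = np.random.default_rng(config.seed)
    n = genotypes.n_individuals
    G = genotypes.matrix.astype(float)

    freq = G.mean(axis=0)
    common = np.flatnonzero(np.minimum(freq, 1 - freq) >= 0.1)
    # large effect on a common SNP so the requested variance is achievable
    large_idx = int(rng.choice(common)) if len(common) else int(rng.integers(genotypes.n_snps))
    small_idx = rng.choice(genotypes.n_snps, size=config.n_small_effects, replace=False)
    Z = G[:, small_idx]
    Z = Z - Z.mean(axis=0)

    h2l = config.h2_large if config.n_large_effects else 0.0
    h2p = config.h2_poly
    h2e = max(0.0, 1.0 - h2l - h2p)
    ls = config.link_strength

    def large_component() -> np.ndarray:
        return _scaled(G[:, large_idx], h2l)

    truth: dict = {
        "model": config.model,
        "large_idx": large_idx,
        "small_idx": small_idx.tolist(),
        "h2_large": h2l,
        "h2_poly": h2p,
        "h2_noise": h2e,
        "link_strength": ls,
    }

    if config.model in ("I", "II"):
        large = large_component()
        poly = _scaled(Z @ rng.normal(size=config.n_small_effects), h2p)
        noise = _scaled(rng.normal(size=n), h2e)
        raw = large + poly + noise
        sd_raw = raw.std() if raw.std() > 0 else 1.0
        upstream = _scaled(raw, 1.0)
        pre = _scaled(upstream, ls) + _scaled(rng.normal(size=n), 1.0 - ls)
        downstream = _scaled(pre, 1.0)
        truth["components_upstream"] = {
            "large": large / sd_raw,
            "poly": poly / sd_raw,
            "noise": noise / sd_raw,
        }
        if config.model == "I":
            m, e = upstream, downstream
        else:
            e, m = upstream, downstream
    else:  # III or IV: shared architecture with optional M->E link (IV)
        n_shared = int(round(config.shared_small_fraction * config.n_small_effects))
        u_shared = rng.normal(size=config.n_small_effects)
        u_priv_m = rng.normal(size=config.n_small_effects)
        u_priv_e = rng.normal(size=config.n_small_effects)
        shared_mask = np.zeros(config.n_small_effects, dtype=bool)
        shared_mask[:n_shared] = True
        h2p_shared = h2p * config.shared_small_fraction
        h2p_priv = h2p - h2p_shared
        shared_poly = _scaled(Z[:, shared_mask] @ u_shared[shared_mask], h2p_shared)
        large = large_component()
        poly_m = shared_poly + _scaled(Z[:, ~shared_mask] @ u_priv_m[~shared_mask], h2p_priv)
        poly_e = shared_poly + _scaled(Z[:, ~shared_mask] @ u_priv_e[~shared_mask], h2p_priv)
        noise_m = _scaled(rng.normal(size=n), h2e)
        noise_e_raw = rng.normal(size=n)
        m_raw = large + poly_m + noise_m
        sd_raw = m_raw.std() if m_raw.std() > 0 else 1.0
        m = _scaled(m_raw, 1.0)
        e_raw = large + poly_e + _scaled(noise_e_raw, h2e)
        if config.model == "III":
            e = _scaled(e_raw, 1.0)
        else:  # IV: Model-III components shrunk by (1 - link), plus a term
            # in M; the link_strength = 0 path is bit-identical to Model III
            pre = _scaled(e_raw, 1.0 - ls)
            if ls > 0:
                pre = pre + _scaled(m, ls)
                e = _scaled(pre, 1.0)
            else:
                e = pre
        truth["n_shared_small"] = n_shared
        truth["components_upstream"] = {
            "large": large / sd_raw,
            "poly": poly_m / sd_raw,
            "noise": noise_m / sd_raw,
        }
    return TraitPair(m=np.asarray(m), e=np.asarray(e), truth=truth)


# ---------------------------------------------------------------------------
# Study bundle: files on disk that round-trip through the preprocessing module
# ---------------------------------------------------------------------------

_CONTEXT_TRIPLET = {"CG_only": "CGA", "CG_in_C": "CGA", "CHG": "CAG", "CHH": "CTT"}
_GENE_LENGTH = 2000


def _bin_cytosine_rows(chrom, start, context_class, levels, accessions):
    """Five same-context cytosines per bin; counts encode the bin level."""
    triplet = _CONTEXT_TRIPLET[context_class]
    rows = []
    offsets = (10, 50, 90, 130, 170)
    for off in offsets:
        pos1 = start + off + 1  # 1-based in the file
        for acc, level in zip(accessions, levels):
            total = 1000
            mc = int(round(float(level) * total))
            rows.append((acc, chrom, pos1, "+", triplet, mc, total))
    if context_class == "CG_in_C":
        # one methylated CHG site marks the window as TE-like context
        for acc in accessions:
            rows.append((acc, chrom, start + 191, "+", "CAG", 500, 1000))
    return rows


def generate_study_bundle(
    pop_config: PopulationConfig,
    trait_configs: list[TraitSimConfig],
    out_dir: str | Path,
    n_background_bins: int = 20,
    expression_scale: float = 0.4,
    expression_mean_log: float = 2.0,
) -> dict[str, Path]:
    """Write a self-consistent synthetic study to ``out_dir``.

    Produces genotype TSV and VCF, a long-format per-cytosine methylation
    TSV, an rpkm-like expression TSV (one gene per trait config, raw scale =
    exp(mean_log + scale * latent E)), a GFF3 gene annotation, and a
    ground-truth JSON. Bin levels written as cytosine counts round-trip
    through preprocessing up to count rounding (1/1000).
    """
    from epiqtl import io as eio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_structured_genotypes(pop_config)
    accessions = genotypes.accessions
    genome_end = int(genotypes.pos[-1]) + _SNP_SPACING

    # each gene is anchored at its trait's large-effect SNP so the panel has
    # genuine cis structure (the SNP falls inside the transcribed interval)
    genes = []
    cyto_rows: list[tuple] = []
    expr_rows = {}
    truth: dict = {"pop_config": asdict(pop_config), "genes": {}}
    for gi, tc in enumerate(trait_configs):
        gene_id = f"gene{gi:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        pair = simulate_trait_pair(genotypes, tc)
        gstart = max(0, int(genotypes.pos[pair.truth["large_idx"]]) - 500)
        genes.append((gene_id, "1", gstart, gstart + _GENE_LENGTH, strand))
        # paired methylation bin sits inside the gene, near the TSS
        tss = gstart if strand == "+" else gstart + _GENE_LENGTH
        bstart = gstart + 200
        level = np.clip(0.5 + 0.15 * pair.m, 0.001, 0.999)
        ctx = "CG_only"
        cyto_rows.extend(_bin_cytosine_rows("1", bstart, ctx, level, accessions))
        raw_expr = np.exp(expression_mean_log + expression_scale * pair.e)
        expr_rows[gene_id] = raw_expr
        truth["genes"][gene_id] = {
            "model": tc.model,
            "config": asdict(tc),
            "tss": tss,
            "strand": strand,
            "bin": {"chrom": "1", "start": bstart, "end": bstart + 200,
                    "context_class": ctx, "levels": [round(float(x), 6) for x in level]},
            "large_idx": pair.truth["large_idx"],
            "latent_m": [round(float(x), 6) for x in pair.m],
            "latent_e": [round(float(x), 6) for x in pair.e],
        }

    background = simulate_methylation_bins(
        genotypes,
        n_bins=n_background_bins,
        cis_fraction=0.5,
        effect_size=0.3,
        noise_sd=0.05,
        seed=pop_config.seed + 1,
    )
    for _, row in background.bins.iterrows():
        levels = np.clip(row[accessions].to_numpy(dtype=float), 0.001, 0.999)
        cyto_rows.extend(
            _bin_cytosine_rows(row["chrom"], int(row["start"]), row["context_class"],
                               levels, accessions)
        )

    paths = {
        "genotypes_tsv": out_dir / "genotypes.tsv",
        "genotypes_vcf": out_dir / "genotypes.vcf",
        "methylation": out_dir / "methylation.tsv",
        "expression": out_dir / "expression.tsv",
        "annotation": out_dir / "annotation.gff3",
        "truth": out_dir / "truth.json",
    }
    eio.write_genotypes_tsv(genotypes, paths["genotypes_tsv"])
    eio.write_genotypes_vcf(genotypes, paths["genotypes_vcf"])
    cyto = pd.DataFrame(
        cyto_rows,
        columns=["accession", "chrom", "pos", "strand", "context", "mc_count", "total_count"],
    ).sort_values(["chrom", "pos", "accession"], kind="mergesort")
    eio.write_cytosine_tsv(cyto, paths["methylation"])
    expr = pd.DataFrame(expr_rows, index=accessions).T
    expr.index.name = "gene_id"
    eio.write_expression_tsv(expr, paths["expression"])
    ann = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    eio.write_annotation_gff3(ann, paths["annotation"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
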