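# Methods

This note documents the models, the numerical choices, and the synthetic
study design behind `epiqtl`, and states what the test suite does and does
not demonstrate about real data.

## Data model and preprocessing

The unit of analysis is a panel of n inbred accessions (default n = 135).
Because accessions are effectively homozygous, genotypes are haploid-coded
0/1. SNPs with minor allele frequency below 0.05 are removed: with n ≈ 135
there is little power for rarer variants and parametric regression is
outlier-sensitive.

Methylation is quantified per cytosine as mc/total reads and averaged over
all eligible cytosines of one sequence context within 200-bp windows
(window starts on a 100-bp grid by default, so windows overlap; both are
configurable). Levels are computed separately as mCG/CG, mCHG/CHG and
mCHH/CHH. CG windows are split into CG-only (gene-body-like) and CG-in-C
(TE-like) classes by the absence or presence of any CHG methylation in the
same window anywhere in the sample; the sample-level rule was chosen so
that each bin carries exactly one context class. Sites with zero coverage
are ineligible; a window without eligible sites emits no bin.

Filters: bins and expression traits need a coefficient of variation of at
least 0.05 (computed on the untransformed scale; the CV of near-constant
traits is meaningless after rank transforms). Expression additionally needs
a mean Anscombe-transformed level a(x) = 2·sqrt(x + 3/8) of at least 3 —
the Poisson-stabilizing form of the transform is used, as appropriate for
count-derived rpkm. Methylation bins are further screened by a quantitative
analogue of the MAF filter: standardize to mean 0, variance 1 (sample
standard deviation, ddof = 1) and sum the squared z-scores of the five
furthest accessions; a bin scoring above 75 is dominated by a handful of
outliers and is dropped. A vector of 134 zeros and a single one scores
about 134 and is removed; standard-normal vectors score roughly 20–35 and
over 99% survive.

Before association testing, traits are mapped onto normal quantiles
(rank r of n → Φ⁻¹((r − c)/(n + 1 − 2c)) with the Blom offset c = 3/8,
ties averaged), keeping only rank information. An untransformed mode is
exposed because rank transforms can dampen effects in the causal analysis.

## Mixed models

All models have the form Y ~ N(Xβ, Σᵢ Kᵢσᵢ² + Iσ_ε²) with zero to three
kinship components: the global SNP kinship K_S, the methylation similarity
K_M built the same way from bin levels, and the local cis kinship K_l built
from SNPs within a window of one gene (50 kb of the transcribed interval by
default for scans and local kinships; the cis/trans FDR labelling uses a
strict < 20 kb rule; causal-pair bins come from within the gene or 2 kb of
the TSS). Kinships are variant-standardized (each variant to mean 0,
variance 1), K = ZᵀZ/m, rescaled to mean diagonal 1 — tests and variance
ratios are invariant to this scaling.

Fitting profiles out β and the overall scale. With one kinship the variance
ratio δ = σ²/σ_ε² is optimized in 1-D on the spectral decomposition of K
(61-point log-grid on [10⁻⁶, 10⁶] plus bounded refinement, and the δ = 0
boundary checked explicitly). With two or three kinships the
log-likelihood is maximized numerically over log variance ratios
(Nelder–Mead, restarts from ratios 0.1, 1 and 10, ratios bounded to
[10⁻⁶, 10⁶]); every proper subset of the component list is also fitted and
the best log-likelihood kept, so adding a component can never appear to
decrease the maximized ML log-likelihood.

**Aliased directions.** A variant-standardized kinship annihilates the ones
vector exactly, and every model here carries an intercept. In that
configuration the profiled ML criterion is unbounded: the fixed effect
absorbs the null direction exactly while the pooled residual variance still
counts its dimension, so the criterion grows like ½·log δ without limit and
ratio estimates pile onto the search bound. The likelihood is therefore
computed on the quotient space: directions lying in the kinship null space
*and* inside the fixed-effect column span are projected out (this is the
identifiable part of the model; projecting the whole fixed-effect span
would give REML). β is recovered afterwards by full-data GLS at the fitted
ratios, and `fit.n_eff` records the dimension used. For full-rank kinships
nothing is projected and the reported log-likelihood equals the dense
multivariate-normal density at the fitted parameters to numerical
precision. Likelihood-ratio tests refuse to compare fits with different
quotient dimensions.

The LRT for one extra variance component uses the boundary-corrected null
0.5·χ²₀ + 0.5·χ²₁ (the component variance sits on the edge of its
parameter space). With a methylation similarity built from partly
cis-SNP-driven bins — the realistic case, where K_M correlates strongly
with K_S — the test is conservative (empirical size ≈ 3–5% at nominal 5%).

## Association scans

Marginal scans follow the EMMAX approximation: δ is estimated once for the
null model, phenotype and candidates are rotated by (Λδ + I)^(−1/2)Qᵀ, and
each candidate is tested by an ordinary F-test (df = n − q − 1) after
residualizing on the rotated intercept and covariates. δ is interpreted as
the variance *ratio* σ_S²/σ_ε², which is what makes (Λδ + I) the correct
null covariance. With K = I the procedure is exactly ordinary least
squares. Constant candidates get p = 1 with a warning.

Forward stepwise selection adds the minimum-p variant (ties broken by
lowest genomic coordinate) as a fixed cofactor while its p-value stays
below α/(number of candidates), with α = 0.05. By default δ is re-estimated
after each inclusion (a conservative refinement); the strict one-δ
behaviour is available via `refit_delta=False`, and marginal scans always
use one δ. The Bonferroni denominator is the candidate count of the current
scan and is configurable, since genome-scale thresholds only reproduce at
genome scale.

The cis FDR bound assumes every trans hit (≥ 20 kb from the gene) is a
false positive: bound = (trans hits / trans tests) × cis tests / cis hits.
It is 0 with no trans hits and undefined (an error) with no cis hits.

A note on detection power at this sample size: a candidate explaining 5% of
trait variance at n = 135 has an expected p-value near 10⁻², which ~10 of
1,000 null candidates beat by chance, so such an effect typically ranks
around 10th in a 1,000-candidate scan; ranking first reliably requires
roughly 15% explained variance.

## Nested cis models and variance partitioning

For one expression trait, stage 1 ("genetics") selects stepwise cis-SNP
cofactors under the K_S + K_l random structure; stage 2 ("genetics +
methylation") adds stepwise cis methylation-bin cofactors to the same
random structure, with the Bonferroni threshold over methylation bins only.
A global methylation kinship is deliberately excluded here, as the
genome-wide test shows it explains nothing beyond K_S in most cases. An
empty cis window drops K_l with a warning.

The stage-2 fit is decomposed into variance fractions: each fixed-effect
block contributes the sample variance of its fitted sub-predictor, with
covariance between blocks split equally (row-sum allocation, clipped at
zero); each random component contributes σ²·(mean diagonal of its K); SNP
cofactors and σ_l² count as cis-genetic, σ_S² as trans-genetic. Fractions
are normalized to sum to one. The methylation fraction is exactly 0
whenever stage 2 adds no cofactors.

Under a strongly structured kinship these ML components are
high-variance: for a pure-noise trait the spurious genetic share has a long
right tail (median residual share > 0.95, but individual replicates can
attribute half the variance to kinship), and for a 30/30/40
cis/polygenic/noise trait the per-replicate σ_S estimate piles on its zero
boundary often enough to pull the trans *median* below the truth while the
*mean* over 200 replicates recovers all three components within ±0.07.
Recovery statements in the tests are therefore about means.

## Causal model selection

For each gene, the most correlated methylation bin (within the gene or
2 kb of the TSS) with r² > 0.2 forms a candidate pair; the pair enters the
testing pool if the two traits share an associated SNP (Bonferroni for
trans SNPs, p < 10⁻⁵ for cis SNPs, cis defined as ≤ 50 kb here) or if
either trait's kinship component explains ≥ 5% of its variance (the
retention clause is an OR; shared significant SNPs, LD-pruned at r² > 0.9
and capped at five, become the fixed cofactors X).

Four models are compared through their maximized likelihoods,

    I:   L = p(e|m) p(m|g) p(g)        II:  L = p(m|e) p(e|g) p(g)
    III: L = p(e|g) p(m|g) p(g)        IV:  L = p(e|m,g) p(m|g) p(g)
                                          = p(m|e,g) p(e|g) p(g)

with trait-on-trait conditionals fitted by least squares and
genotype-conditionals by ML mixed models with the K_S random term; p(g) is
identical across models and dropped. Model IV is evaluated under both
factorizations and the larger maximized likelihood used — the two families
are not identical once each conditional is maximized separately, and the
max makes Model IV nest Models I–III exactly. BIC = −2 ln L + k ln n with
explicit parameter counts (per Gaussian component: intercept + slopes + one
residual variance, + one kinship variance where present). The winner is
called only with a BIC margin ≥ 3, else "ambiguous".

All component likelihoods are evaluated on the same contrast space (the
complement of the intercept-aliased kinship null direction, see above);
mixing spaces between the least-squares and mixed-model components would
make the BICs incomparable and break the invariance of BIC differences
under affine trait rescaling.

## Synthetic study design

Genotypes follow a Balding–Nichols model: ancestral frequencies uniform on
[0.05, 0.95], subpopulation frequencies Beta-distributed around them with
divergence parameter F (default 0.2, three subpopulations — "strong"
structure comparable to a regional plant panel), haploid draws per
individual. SNPs sit on one chromosome at 1-kb spacing.

Trait pairs: the upstream trait is the sum of 0–1 large-effect SNP
(variance fraction h2_large, default 0.3, drawn from SNPs with MAF ≥ 0.1),
a polygenic background of n_small i.i.d. effects on standardized dosages
(h2_poly, default 0.3; standardized dosages match the kinship construction
so the background is exactly a K_S term), and Gaussian noise; components
are rescaled to their exact sample-variance targets and the trait is
standardized. Models I/II chain the second trait on the first with variance
fraction link_strength (default 0.5). Models III/IV share the large effect
and a fraction of the small effects between the traits
(shared_small_fraction), Model IV adding a direct trait-on-trait term on
the same random path, so link_strength = 0 reproduces Model III
bit-for-bit.

shared_small_fraction defaults to 0.25. The choice matters: the *realized*
shared polygenic background induces a correlation between M and E given G
that Model III's conditional-independence likelihood cannot represent (the
kinship term models variatedness, not the realization), and at a 0.5 shared
fraction that correlation (~0.2) exceeds what the 3-unit BIC gap can
absorb, flipping Model III data into IV/ambiguous calls. At 0.25 the
induced correlation stays below the BIC resolution while the architecture
still mixes shared and private effects. Under the default settings the
recovery study reproduces the expected qualitative pattern: Models I and II
are recovered ~95% of the time, Model III 50–60%, and Model IV — whose
extra link is nearly unidentifiable from III at these effect sizes —
under 20%.

Methylation bins are proportions in [0, 1] (clipped after noise): a
configurable fraction receives a linear effect of a nearby SNP. The study
bundle writes genotypes (TSV and haploid GT-only VCF), long-format
per-cytosine counts (five same-context cytosines per bin, counts encoding
the level to 1/1000), rpkm-like expression (exp-transformed latent traits),
GFF3 gene models anchored at each trait's large-effect SNP (giving genuine
cis structure), and a ground-truth JSON. Identical seeds give byte-identical
bundles.

What the generator does *not* emulate: read-level bisulfite noise and
conversion errors, realistic LD decay within the cis window, chromosome-
scale genomes, missing data, and environment-driven methylation variation.
Passing tests demonstrate the statistical machinery is correct and
calibrated under the stated generative assumptions, not that those
assumptions hold in any particular real panel.

## Numerical conventions and limitations

- Coordinates 0-based half-open internally; 1-based point positions in
  TSVs; BED-like bins. A variant exactly 20,000 bp from a gene is trans.
- Variance ratios searched in [10⁻⁶, 10⁶]; relative log-likelihood
  tolerance ~10⁻⁸ (spectral path), Nelder–Mead fatol 10⁻⁹ (generic path).
- Residual sums of squares floored at 10⁻¹²·var(y) so exact fits keep a
  finite log-likelihood; component variances then report as 0.
- Ties in stepwise selection break by lowest genomic coordinate; exact
  duplicate cofactors are never re-selected (their conditional p is 1).
- Problem sizes in the test-suite simulations (panel of 135 × 2,000 SNPs,
  hundreds of replicates per calibration check, 2-kb genes at 20-kb
  spacing) were chosen as the smallest designs whose Monte-Carlo error is
  comfortably below the tested tolerances.
- The pipeline's per-gene loop is quadratic in accessions per fit
  (Cholesky/eigendecompositions at n ≈ 135 cost ~1 ms); genome-scale scans
  are feasible but the package is optimized for clarity over throughput.
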