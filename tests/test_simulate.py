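"""Generators: population structure, cis-driven bins, causal trait pairs."""

import json

import numpy as np
import pytest

from epiqtl.datatypes import BIN_META_COLUMNS
from epiqtl.lmm import compute_kinship
from epiqtl.simulate import (
    PopulationConfig,
    TraitSimConfig,
    generate_study_bundle,
    simulate_methylation_bins,
    simulate_structured_genotypes,
    simulate_trait_pair,
)


def _kinship_block_means(geno):
    K = compute_kinship(geno.matrix.T.astype(float)).matrix
    same = geno.subpop[:, None] == geno.subpop[None, :]
    off = ~np.eye(len(K), dtype=bool)
    return K[same & off].mean(), K[~same].mean()


class TestStructuredGenotypes:
    def test_divergence_creates_kinship_block_structure(self):
        geno = simulate_structured_genotypes(
            PopulationConfig(n_individuals=100, n_snps=500, n_subpops=2,
                             divergence=0.5, seed=3)
        )
        within, between = _kinship_block_means(geno)
        assert within > between

    def test_no_divergence_gives_exchangeable_individuals(self):
        # averaged over replicates, within- and between-subpop kinship agree
        diffs = []
        for rep in range(50):
            geno = simulate_structured_genotypes(
                PopulationConfig(n_individuals=60, n_snps=200, n_subpops=2,
                                 divergence=0.0, seed=rep)
            )
            within, between = _kinship_block_means(geno)
            diffs.append(within - between)
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 1e-3

    def test_seeded_reproducibility(self):
        cfg = PopulationConfig(n_individuals=30, n_snps=100, seed=11)
        a = simulate_structured_genotypes(cfg)
        b = simulate_structured_genotypes(cfg)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.matrix.min() >= 0 and a.matrix.max() <= 1

    @pytest.mark.parametrize(
        "kwargs", [{"n_individuals": 1}, {"n_snps": 0}, {"divergence": 1.5}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PopulationConfig(**kwargs)


class TestMethylationBins:
    def test_null_effect_gives_null_correlations(self, panel):
        sim = simulate_methylation_bins(panel, n_bins=500, cis_fraction=1.0,
                                        effect_size=0.0, noise_sd=0.1, seed=4)
        acc = [c for c in sim.bins.columns if c not in BIN_META_COLUMNS]
        levels = sim.bins[acc].to_numpy(float)
        rs = []
        for i in range(len(sim.bins)):
            gcol = panel.matrix[:, sim.causal_snp[i]].astype(float)
            if gcol.std() == 0 or levels[i].std() == 0:
                continue
            rs.append(abs(np.corrcoef(levels[i], gcol)[0, 1]))
        # |r| with the designated SNP should look like noise: the 95th
        # percentile stays below the r that would give r^2 = 0.2 at n = 135
        assert np.quantile(rs, 0.95) < np.sqrt(0.2)

    def test_noiseless_bins_are_affine_in_causal_snp(self, small_panel):
        sim = simulate_methylation_bins(small_panel, n_bins=20, cis_fraction=1.0,
                                        effect_size=0.2, noise_sd=0.0, seed=4)
        for i in range(20):
            g = small_panel.matrix[:, sim.causal_snp[i]].astype(float)
            if g.std() == 0:
                continue
            r = np.corrcoef(sim.preclip_levels[i], g)[0, 1]
            assert abs(abs(r) - 1.0) < 1e-12

    def test_seeded_reproducibility_and_range(self, small_panel):
        a = simulate_methylation_bins(small_panel, n_bins=10, seed=9)
        b = simulate_methylation_bins(small_panel, n_bins=10, seed=9)
        acc = [c for c in a.bins.columns if c not in BIN_META_COLUMNS]
        assert a.bins.equals(b.bins)
        levels = a.bins[acc].to_numpy(float)
        assert levels.min() >= 0.0 and levels.max() <= 1.0

    def test_cis_fraction_validated(self, small_panel):
        with pytest.raises(ValueError):
            simulate_methylation_bins(small_panel, n_bins=5, cis_fraction=1.5)


class TestTraitPair:
    def test_noiseless_chain_model_one(self, small_panel):
        cfg = TraitSimConfig(model="I", n_small_effects=300, h2_large=0.3,
                             h2_poly=0.7, link_strength=1.0, seed=2)
        pair = simulate_trait_pair(small_panel, cfg)
        # h2_noise = 0 and full link: E equals M elementwise
        np.testing.assert_allclose(pair.e, pair.m, atol=1e-10)

    def test_model_three_without_sharing_gives_null_correlation(self, panel):
        rs = []
        for rep in range(200):
            cfg = TraitSimConfig(model="III", n_large_effects=0,
                                 n_small_effects=500, h2_poly=0.4,
                                 shared_small_fraction=0.0, seed=rep)
            pair = simulate_trait_pair(panel, cfg)
            rs.append(np.corrcoef(pair.m, pair.e)[0, 1])
        # null sampling band for a correlation at n = 135
        assert abs(np.mean(rs)) < 3.0 / np.sqrt(135 * len(rs)) + 0.02

    def test_large_effect_variance_fraction(self, panel):
        fracs = []
        for rep in range(200):
            cfg = TraitSimConfig(model="I", n_small_effects=500, h2_large=0.4,
                                 h2_poly=0.3, seed=rep)
            pair = simulate_trait_pair(panel, cfg)
            comp = pair.truth["components_upstream"]
            fracs.append(np.var(comp["large"]) / np.var(pair.m))
        assert abs(np.mean(fracs) - 0.40) < 0.05

    def test_model_four_with_zero_link_equals_model_three(self, small_panel):
        kw = dict(n_small_effects=300, h2_large=0.2, h2_poly=0.4, seed=8)
        p3 = simulate_trait_pair(small_panel, TraitSimConfig(model="III", link_strength=0.0, **kw))
        p4 = simulate_trait_pair(small_panel, TraitSimConfig(model="IV", link_strength=0.0, **kw))
        np.testing.assert_array_equal(p3.m, p4.m)
        np.testing.assert_array_equal(p3.e, p4.e)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            TraitSimConfig(model="V")

    def test_too_many_small_effects_rejected(self, small_panel):
        cfg = TraitSimConfig(model="I", n_small_effects=10**6)
        with pytest.raises(ValueError):
            simulate_trait_pair(small_panel, cfg)


class TestStudyBundle:
    def test_all_files_exist_and_parse(self, tiny_bundle):
        from epiqtl import io as eio

        paths = tiny_bundle["paths"]
        for p in paths.values():
            assert p.exists()
        g = eio.read_genotypes_tsv(paths["genotypes_tsv"])
        gv = eio.read_genotypes_vcf(paths["genotypes_vcf"])
        assert np.array_equal(g.matrix, gv.matrix)
        assert len(eio.read_annotation_gff3(paths["annotation"])) == 6
        assert eio.read_expression_tsv(paths["expression"]).shape == (6, 30)
        json.load(open(paths["truth"]))

    def test_bin_levels_roundtrip_through_preprocessing(self, tiny_bundle):
        from epiqtl import io as eio
        from epiqtl.preprocess import bin_methylation_levels

        paths = tiny_bundle["paths"]
        g = eio.read_genotypes_tsv(paths["genotypes_tsv"])
        truth = json.load(open(paths["truth"]))
        bins = bin_methylation_levels(
            eio.read_cytosine_tsv(paths["methylation"]), accessions=g.accessions
        )
        for gid, info in truth["genes"].items():
            b = bins[(bins["start"] == info["bin"]["start"])
                     & (bins["context_class"] == info["bin"]["context_class"])]
            assert len(b) == 1, gid
            got = b[g.accessions].to_numpy(float)[0]
            # methylated/total read counts quantize levels to 1/1000
            np.testing.assert_allclose(got, info["bin"]["levels"], atol=6e-4)

    def test_bundle_is_deterministic(self, tiny_bundle, tmp_path):
        paths2 = generate_study_bundle(
            tiny_bundle["pop"], tiny_bundle["traits"], tmp_path, n_background_bins=10
        )
        for key, p in tiny_bundle["paths"].items():
            assert p.read_bytes() == paths2[key].read_bytes(), key
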