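from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from locusdissect import synthetic_data as sd


class TestSimConfigValidation:
    def test_block_sizes_must_sum_to_n_variants(self):
        with pytest.raises(ValueError, match="sum"):
            sd.SimConfig(n_variants=10, ld_block_sizes=(4, 4), causal_variant_index=0)

    def test_degenerate_latent_correlation_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sd.SimConfig(within_block_r=1.0)

    def test_maf_range_bounds(self):
        with pytest.raises(ValueError, match="maf_range"):
            sd.SimConfig(maf_range=(0.0, 0.4))
        with pytest.raises(ValueError, match="maf_range"):
            sd.SimConfig(maf_range=(0.1, 0.6))

    def test_out_of_range_indices(self):
        with pytest.raises(ValueError, match="causal_variant_index"):
            sd.SimConfig(causal_variant_index=36)
        with pytest.raises(ValueError, match="target_gene_index"):
            sd.SimConfig(target_gene_index=60)


class TestSimulateGenotypes:
    def test_same_seed_is_bit_identical(self, small_cfg):
        g1, b1 = sd.simulate_genotypes(small_cfg)
        g2, b2 = sd.simulate_genotypes(small_cfg)
        assert g1.equals(g2)
        assert b1 == b2

    def test_dosages_and_maf_in_range(self, small_cfg):
        g, _ = sd.simulate_genotypes(small_cfg, 2_000)
        vals = g.to_numpy()
        assert set(np.unique(vals)) <= {0, 1, 2}
        maf = vals.mean(axis=0) / 2
        lo, hi = small_cfg.maf_range
        assert (maf > lo - 0.05).all() and (maf < hi + 0.05).all()

    def test_independent_blocks_have_near_zero_ld(self):
        cfg = sd.SimConfig(
            n_variants=8, ld_block_sizes=(1,) * 8, within_block_r=0.0,
            causal_variant_index=0, seed=4,
        )
        n = 4_000
        g, _ = sd.simulate_genotypes(cfg, n)
        corr = np.corrcoef(g.to_numpy(dtype=float), rowvar=False)
        off = np.abs(corr[np.triu_indices(8, k=1)])
        assert off.mean() < 3 / np.sqrt(n)

    def test_high_ld_pair_reaches_target_r2(self):
        # oracle band from the same Gaussian-threshold construction run at
        # 10x n over 30 seeds: r^2 in [0.80, 0.82] around the 0.81 implied
        # by a realized dosage correlation of 0.9
        cfg = sd.SimConfig(
            n_variants=2, ld_block_sizes=(2,), within_block_r=0.9,
            causal_variant_index=0, seed=21,
        )
        g, _ = sd.simulate_genotypes(cfg, 5_000)
        r2 = np.corrcoef(g.iloc[:, 0], g.iloc[:, 1])[0, 1] ** 2
        assert 0.75 <= r2 <= 0.95

    def test_block_structure_matches_map(self, small_cfg):
        _, block_map = sd.simulate_genotypes(small_cfg)
        assert block_map == [0] * 4 + [1] * 4 + [2] * 4


class TestSimulateExpression:
    def test_null_eqtl_gives_null_association(self, small_cfg):
        for seed in range(5):
            cfg = replace(small_cfg, eqtl_beta=0.0, seed=seed)
            rng = np.random.default_rng(seed)
            g, _ = sd.simulate_genotypes(cfg, 500, rng)
            expr, truth = sd.simulate_expression(g, cfg, rng)
            x = g[truth.causal_variant].to_numpy(float)
            y = expr["AOR"].loc[truth.target_gene].to_numpy()
            r, _ = stats.pearsonr(x, y)
            t = r * np.sqrt(498) / np.sqrt(1 - r * r)
            assert abs(t) < 4

    def test_planted_slope_within_ols_sampling_band(self, small_cfg):
        rng = np.random.default_rng(9)
        g, _ = sd.simulate_genotypes(small_cfg, 500, rng)
        expr, truth = sd.simulate_expression(g, small_cfg, rng)
        x = g[truth.causal_variant].to_numpy(float)
        y = expr["AOR"].loc[truth.target_gene].to_numpy()
        slope, _, _, _, se = stats.linregress(x, y)
        assert abs(slope - small_cfg.eqtl_beta) < 3 * se

    def test_eqtl_confined_to_arterial_tissues(self, small_cfg):
        rng = np.random.default_rng(10)
        g, _ = sd.simulate_genotypes(small_cfg, 500, rng)
        expr, truth = sd.simulate_expression(g, small_cfg, rng)
        assert truth.eqtl_beta["AOR"] == small_cfg.eqtl_beta
        assert truth.eqtl_beta["LIV"] == 0.0
        x = g[truth.causal_variant].to_numpy(float)
        y = expr["LIV"].loc[truth.target_gene].to_numpy()
        r, _ = stats.pearsonr(x, y)
        t = r * np.sqrt(498) / np.sqrt(1 - r * r)
        assert abs(t) < 4

    def test_module_structure_within_versus_between(self, small_cfg):
        cfg = replace(small_cfg, module_loading=0.8)
        rng = np.random.default_rng(11)
        g, _ = sd.simulate_genotypes(cfg, 400, rng)
        expr, truth = sd.simulate_expression(g, cfg, rng)
        X = expr["SKLM"]
        mods = truth.module_assignments
        m1 = [g_ for g_, m in mods.items() if m == "factor1"]
        m2 = [g_ for g_, m in mods.items() if m == "factor2"]
        corr = np.corrcoef(X.loc[m1 + m2].to_numpy())
        k = len(m1)
        within = np.abs(np.concatenate([corr[:k, :k][np.triu_indices(k, 1)], corr[k:, k:][np.triu_indices(len(m2), 1)]]))
        between = np.abs(corr[:k, k:]).ravel()
        assert within.mean() > between.mean()

    def test_target_gene_index_out_of_range(self, small_cfg):
        with pytest.raises(ValueError):
            replace(small_cfg, target_gene_index=100)


class TestSimulateOutcomeAndTraits:
    def test_mismatched_sample_ids_error(self, small_cfg):
        rng = np.random.default_rng(3)
        g, _ = sd.simulate_genotypes(small_cfg, 100, rng)
        expr, _ = sd.simulate_expression(g, small_cfg, rng)
        bad = {t: df.iloc[:, ::-1] for t, df in expr.items()}
        with pytest.raises(ValueError, match="sample ids"):
            sd.simulate_outcome_and_traits(g, bad, small_cfg, rng)

    def test_planted_trait_correlation_in_fisher_band(self, small_cfg):
        rng = np.random.default_rng(8)
        g, _ = sd.simulate_genotypes(small_cfg, 500, rng)
        expr, truth = sd.simulate_expression(g, small_cfg, rng)
        _, traits = sd.simulate_outcome_and_traits(g, expr, small_cfg, rng)
        x = expr["AOR"].loc[truth.target_gene]
        r = np.corrcoef(x, traits["cad_severity"])[0, 1]
        # 99.9% Fisher-z interval around atanh(0.3) at n = 500
        assert 0.164 <= r <= 0.423

    def test_outcome_is_binary_and_mediated(self, small_cfg):
        rng = np.random.default_rng(8)
        g, _ = sd.simulate_genotypes(small_cfg, 500, rng)
        expr, _ = sd.simulate_expression(g, small_cfg, rng)
        outcome, _ = sd.simulate_outcome_and_traits(g, expr, small_cfg, rng)
        assert set(outcome.unique()) <= {0, 1}

    def test_truth_mediation_identity(self, small_cfg):
        rng = np.random.default_rng(2)
        g, _ = sd.simulate_genotypes(small_cfg, 100, rng)
        _, truth = sd.simulate_expression(g, small_cfg, rng)
        assert truth.disease_beta == pytest.approx(truth.eqtl_beta["AOR"] * truth.mediated_beta)
        assert all(truth.eqtl_beta[t] == 0 for t in ("LIV", "SKLM"))


class TestSimulateAccessibility:
    def _setup(self, cfg):
        variants, genes_df, peaks = sd.make_locus_annotation(cfg)
        causal_pos = int(variants.iloc[cfg.causal_variant_index]["pos"])
        return variants, genes_df, peaks, causal_pos

    def test_planted_coupling_in_fisher_band(self, small_cfg):
        _, genes_df, peaks, causal_pos = self._setup(small_cfg)
        acc, expr, truth = sd.simulate_accessibility(
            small_cfg, peaks, genes_df, causal_pos, np.random.default_rng(4)
        )
        r = np.corrcoef(acc.loc[truth["linked_peak"]], expr.loc[truth["target_gene"]])[0, 1]
        # 99% Fisher-z interval around atanh(0.6) over 100 groups
        assert 0.41 <= r <= 0.74

    def test_null_coupling_stays_small(self, small_cfg):
        cfg = replace(small_cfg, access_r=0.0)
        _, genes_df, peaks, causal_pos = self._setup(cfg)
        ok = 0
        for seed in range(20):
            acc, expr, truth = sd.simulate_accessibility(
                cfg, peaks, genes_df, causal_pos, np.random.default_rng(seed)
            )
            r = np.corrcoef(acc.loc[truth["linked_peak"]], expr.loc[truth["target_gene"]])[0, 1]
            ok += abs(r) < 0.26
        assert ok >= 19

    def test_variant_at_peak_end_not_contained(self, small_cfg):
        _, genes_df, peaks, _ = self._setup(small_cfg)
        peak = peaks[0]
        # half-open [start, end): the 1-based position end+1 maps to the
        # 0-based point end, which is outside
        assert not peak.contains_position(peak.end + 1)
        assert peak.contains_position(peak.end)
        with pytest.raises(ValueError, match="no peak contains"):
            sd.simulate_accessibility(small_cfg, peaks, genes_df, 999_999_999)


class TestStudyBundle:
    def test_full_study_is_deterministic(self, small_cfg):
        b1 = sd.simulate_study(small_cfg)
        b2 = sd.simulate_study(small_cfg)
        assert b1.genotypes_gwas.equals(b2.genotypes_gwas)
        assert b1.expression["AOR"].equals(b2.expression["AOR"])
        assert b1.outcome.equals(b2.outcome)
        assert b1.accessibility.equals(b2.accessibility)

    def test_cohorts_share_variants_but_not_samples(self, small_cfg):
        b = sd.simulate_study(small_cfg)
        assert list(b.genotypes_eqtl.columns) == list(b.genotypes_gwas.columns)
        assert set(b.genotypes_eqtl.index).isdisjoint(b.genotypes_gwas.index)

    def test_decoy_gene_hosts_snps_target_does_not(self, small_cfg):
        from locusdissect.locus_catalog import annotate_snp

        b = sd.simulate_study(small_cfg)
        target = b.truth.target_gene
        labels = []
        for _, row in b.variants.iterrows():
            from locusdissect.locus_catalog import VariantRecord

            rec = VariantRecord(row["rsid"], row["chrom"], int(row["pos"]), "A", "G", 0.1, 0.01, 1e-5)
            labels.append(annotate_snp(rec, b.features))
        genes_hit = {g for g, kind in labels if kind != "intergenic"}
        assert target not in genes_hit
        assert len(genes_hit) == 1  # the decoy only
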