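"""GWAS harmonization, fixed-effect pooling, inflation factor, loci."""

import numpy as np
import pandas as pd
import pytest

from gbsig.meta import (
    fixed_effect_meta,
    genomic_lambda,
    harmonize_variants,
    qq_manhattan_tables,
    significant_loci,
)
from gbsig.synthetic import GwasSimConfig, gen_gwas_pair


def gwas_row(snp="rs1", chrom=1, bp=1000, ea="A", nea="G", eaf=0.3, beta=0.1, se=0.05, p=0.04, n=1000):
    return {
        "SNP": snp, "CHR": chrom, "BP": bp, "EA": ea, "NEA": nea,
        "EAF": eaf, "BETA": beta, "SE": se, "P": p, "N": n,
    }


def frame(*rows):
    return pd.DataFrame(list(rows))


class TestHarmonization:
    def test_identical_alleles_pass_through(self):
        s1 = frame(gwas_row())
        s2 = frame(gwas_row(beta=0.2))
        aligned, drops = harmonize_variants(s1, s2)
        assert drops.empty
        assert aligned["BETA_2"].iloc[0] == pytest.approx(0.2)

    def test_swapped_alleles_flip_sign_and_eaf(self):
        s1 = frame(gwas_row(ea="A", nea="G", eaf=0.3))
        s2 = frame(gwas_row(ea="G", nea="A", eaf=0.7, beta=-0.2))
        aligned, _ = harmonize_variants(s1, s2)
        assert aligned["BETA_2"].iloc[0] == pytest.approx(0.2)
        assert aligned["EAF_2"].iloc[0] == pytest.approx(0.3)

    def test_ambiguous_palindromic_dropped(self):
        s1 = frame(gwas_row(ea="A", nea="T", eaf=0.50))
        s2 = frame(gwas_row(ea="A", nea="T", eaf=0.50, beta=0.3))
        aligned, drops = harmonize_variants(s1, s2, how="inner")
        assert aligned.empty
        assert list(drops["reason"]) == ["palindromic_ambiguous"]

    def test_mismatched_alleles_dropped_with_reason(self):
        s1 = frame(gwas_row(ea="A", nea="G"))
        s2 = frame(gwas_row(ea="A", nea="C", beta=0.3))
        aligned, drops = harmonize_variants(s1, s2, how="inner")
        assert aligned.empty
        assert list(drops["reason"]) == ["allele_mismatch"]

    def test_strand_flip_recognized(self):
        # study 2 reports the complementary strand of the same variant
        s1 = frame(gwas_row(ea="A", nea="G", beta=0.1))
        s2 = frame(gwas_row(ea="T", nea="C", beta=0.25))
        aligned, drops = harmonize_variants(s1, s2)
        assert drops.empty
        assert aligned["BETA_2"].iloc[0] == pytest.approx(0.25)

    def test_no_swaps_is_identity_on_betas(self):
        cfg = GwasSimConfig(n_snps=200, swap_rate=0.0, palindromic_rate=0.0, seed=8)
        s1, s2 = gen_gwas_pair(cfg)
        aligned, drops = harmonize_variants(s1, s2)
        assert drops.empty
        assert np.allclose(aligned["BETA_2"], s2["BETA"])


class TestFixedEffectMeta:
    def test_equal_studies_halve_the_variance(self):
        s1 = frame(gwas_row(beta=0.3, se=0.1))
        s2 = frame(gwas_row(beta=0.3, se=0.1))
        pooled = fixed_effect_meta(harmonize_variants(s1, s2)[0])
        assert pooled["BETA"].iloc[0] == pytest.approx(0.3)
        assert pooled["SE"].iloc[0] == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_computed_inverse_variance_weights(self):
        s1 = frame(gwas_row(beta=0.2, se=0.1))
        s2 = frame(gwas_row(beta=0.4, se=0.2))
        pooled = fixed_effect_meta(harmonize_variants(s1, s2)[0])
        # weights 100 and 25: beta = (0.2*100 + 0.4*25)/125 = 0.24
        assert pooled["BETA"].iloc[0] == pytest.approx(0.24, abs=1e-12)
        assert pooled["SE"].iloc[0] == pytest.approx(1 / np.sqrt(125), abs=1e-12)

    def test_single_study_passthrough_flagged(self):
        s1 = frame(gwas_row(snp="rs1"), gwas_row(snp="rs2", beta=0.5))
        s2 = frame(gwas_row(snp="rs1", beta=0.1))
        pooled = fixed_effect_meta(harmonize_variants(s1, s2)[0]).set_index("SNP")
        assert pooled.loc["rs2", "n_studies"] == 1
        assert pooled.loc["rs2", "BETA"] == pytest.approx(0.5)
        assert pooled.loc["rs1", "n_studies"] == 2

    def test_pooled_variance_never_exceeds_smallest(self):
        rng = np.random.default_rng(0)
        rows1, rows2 = [], []
        for i in range(50):
            rows1.append(gwas_row(snp=f"rs{i}", se=float(rng.uniform(0.05, 0.5))))
            rows2.append(gwas_row(snp=f"rs{i}", se=float(rng.uniform(0.05, 0.5))))
        pooled = fixed_effect_meta(harmonize_variants(frame(*rows1), frame(*rows2))[0])
        se1 = frame(*rows1).set_index("SNP")["SE"]
        se2 = frame(*rows2).set_index("SNP")["SE"]
        merged = pooled.set_index("SNP")
        assert (merged["SE"] <= np.minimum(se1, se2)[merged.index] + 1e-12).all()

    def test_pooled_p_recomputable_from_beta_se(self):
        from scipy import stats

        s1 = frame(gwas_row(beta=0.2, se=0.05))
        s2 = frame(gwas_row(beta=0.1, se=0.08))
        pooled = fixed_effect_meta(harmonize_variants(s1, s2)[0])
        z = pooled["BETA"].iloc[0] / pooled["SE"].iloc[0]
        assert pooled["P"].iloc[0] == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)


class TestGenomicLambda:
    def test_half_p_values_give_unit_lambda(self):
        res = genomic_lambda(np.full(1000, 0.5))
        assert res.value == pytest.approx(1.0, abs=1e-9)
        assert not res.low_confidence

    def test_uniform_null_lambda_near_one(self, rng):
        res = genomic_lambda(rng.uniform(size=10_000))
        assert 0.95 <= res.value <= 1.05

    def test_smaller_p_values_inflate_lambda(self, rng):
        p = rng.uniform(size=5000)
        assert genomic_lambda(p / 2).value > genomic_lambda(p).value

    def test_few_values_flagged_low_confidence(self):
        with pytest.warns(UserWarning, match="unstable"):
            res = genomic_lambda(np.full(50, 0.5))
        assert res.low_confidence


class TestSignificantLoci:
    def meta_frame(self, hits):
        rows = [
            {"SNP": f"rs{i}", "CHR": c, "BP": bp, "BETA": 1.0, "SE": 0.1, "P": p}
            for i, (c, bp, p) in enumerate(hits)
        ]
        return pd.DataFrame(rows)

    def test_single_hit_single_locus(self):
        loci = significant_loci(self.meta_frame([(1, 500_000, 1e-9)]))
        assert len(loci) == 1
        assert loci["lead_snp"].iloc[0] == "rs0"

    def test_window_rule_merges_and_splits(self):
        near = significant_loci(self.meta_frame([(1, 1_000_000, 1e-9), (1, 1_100_000, 1e-10)]))
        assert len(near) == 1
        assert near["lead_snp"].iloc[0] == "rs1"  # smaller p leads
        far = significant_loci(self.meta_frame([(1, 1_000_000, 1e-9), (1, 1_600_000, 1e-10)]))
        assert len(far) == 2

    def test_chromosomes_never_merge(self):
        loci = significant_loci(self.meta_frame([(1, 100, 1e-9), (2, 200, 1e-9)]))
        assert len(loci) == 2

    def test_planted_loci_recovered_from_simulated_pair(self):
        # four isolated strong effects among nulls
        cfg = GwasSimConfig(
            n_snps=2000, frac_nonnull=0.0, seed=12, palindromic_rate=0.0, swap_rate=0.0
        )
        s1, s2 = gen_gwas_pair(cfg)
        for k, (chrom, bp) in enumerate([(1, 10**7), (3, 5 * 10**7), (7, 9 * 10**7), (11, 2 * 10**7)]):
            for df in (s1, s2):
                df.loc[k, ["CHR", "BP"]] = (chrom, bp)
                df.loc[k, "BETA"] = 8 * df.loc[k, "SE"]
        pooled = fixed_effect_meta(harmonize_variants(s1, s2)[0])
        loci = significant_loci(pooled)
        assert len(loci) == 4


class TestPlotTables:
    def test_qq_expected_column_follows_rank_rule(self):
        meta = pd.DataFrame(
            {"SNP": ["a", "b", "c"], "CHR": [1, 1, 1], "BP": [1, 2, 3], "P": [0.5, 0.05, 0.005]}
        )
        qq, _ = qq_manhattan_tables(meta)
        expected = -np.log10((np.arange(1, 4) - 0.5) / 3)
        assert np.allclose(qq["expected"], expected)
        assert np.allclose(qq["observed"], -np.log10([0.005, 0.05, 0.5]))

    def test_empty_input_empty_tables(self):
        qq, man = qq_manhattan_tables(pd.DataFrame(columns=["SNP", "CHR", "BP", "P"]))
        assert qq.empty and man.empty

    def test_manhattan_cumulative_positions_monotone_within_chromosome(self):
        meta = pd.DataFrame(
            {
                "SNP": ["a", "b", "c", "d"],
                "CHR": [1, 1, 2, 2],
                "BP": [10, 20, 5, 15],
                "P": [0.1, 0.2, 0.3, 0.4],
            }
        )
        _, man = qq_manhattan_tables(meta)
        assert man["cum_pos"].is_monotonic_increasing
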