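"""MR estimators, sensitivity statistics, FDR, verdict and the scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gbsig.errors import NoInstrumentsError, UsageError
from gbsig.mr import (
    GeneLocus,
    HarmonizedInstrumentSet,
    Instrument,
    MethodEstimate,
    MRResult,
    Panel,
    SensitivityStats,
    estimate_effects,
    fdr_adjust,
    harmonize_exposure_outcome,
    heterogeneity_and_pleiotropy,
    overlap_summary,
    proteome_scan,
    robustness_verdict,
    run_mr,
    select_instruments,
)
from gbsig.synthetic import PqtlSimConfig, gen_pqtl_study


def make_set(bx, sx, by, sy, protein="P1") -> HarmonizedInstrumentSet:
    instruments = tuple(
        Instrument(
            snp=f"rs{i}",
            beta_exp=float(x), se_exp=float(s1), p_exp=1e-10,
            beta_out=float(y), se_out=float(s2), p_out=0.5,
            distance_bp=0.0, ea="A", nea="G",
        )
        for i, (x, s1, y, s2) in enumerate(zip(bx, sx, by, sy))
    )
    return HarmonizedInstrumentSet(protein=protein, locus=None, instruments=instruments)


def sim_set(config: PqtlSimConfig) -> HarmonizedInstrumentSet:
    exp, out, _ = gen_pqtl_study(config)
    return make_set(exp["BETA"], exp["SE"], out["BETA"], out["SE"])


class TestInstrumentSelection:
    def exposure_frame(self):
        return pd.DataFrame(
            {
                "SNP": ["cis_strong", "trans_strong", "cis_weakp"],
                "CHR": [1, 5, 1],
                "BP": [10_500_000, 10_500_000, 10_400_000],
                "EA": ["A", "A", "A"],
                "NEA": ["G", "G", "G"],
                "EAF": [0.3, 0.3, 0.3],
                "BETA": [0.5, 0.6, 0.1],
                "SE": [0.05, 0.05, 0.02],
                "P": [1e-9, 1e-10, 1e-5],
                "N": [35_000] * 3,
            }
        )

    def locus(self):
        return GeneLocus(1, 10_000_000, 10_050_000, "GENE1")

    def test_each_filter_fires(self):
        hset = select_instruments(self.exposure_frame(), self.locus())
        assert [i.snp for i in hset.instruments] == ["cis_strong"]

    def test_greedy_ld_pruning_keeps_smallest_p(self):
        df = self.exposure_frame().copy()
        df.loc[2, ["P", "BETA", "SE"]] = (1e-10, 0.5, 0.05)  # now significant
        ld = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]],
            index=["cis_strong", "cis_weakp"],
            columns=["cis_strong", "cis_weakp"],
        )
        hset = select_instruments(df, self.locus(), ld=ld)
        assert [i.snp for i in hset.instruments] == ["cis_weakp"]  # p=1e-10 beats 1e-9

    def test_weak_instrument_excluded_by_f(self):
        df = self.exposure_frame().copy()
        # F = (0.1/0.05)^2 = 4 < 10 even though p passes
        df.loc[0, ["BETA", "SE", "P"]] = (0.1, 0.05, 1e-9)
        with pytest.raises(NoInstrumentsError):
            select_instruments(df.iloc[[0]], self.locus())

    def test_no_survivors_raises(self):
        with pytest.raises(NoInstrumentsError):
            select_instruments(self.exposure_frame().iloc[[1]], self.locus(), protein="P")


class TestHarmonizeExposureOutcome:
    def outcome_frame(self, ea="A", nea="G", beta=0.1):
        return pd.DataFrame(
            {
                "SNP": ["rs0"], "CHR": [1], "BP": [100], "EA": [ea], "NEA": [nea],
                "EAF": [0.3], "BETA": [beta], "SE": [0.05], "P": [0.04], "N": [1000],
            }
        )

    def hset(self):
        return make_set([0.5], [0.05], [np.nan], [np.nan])

    def test_same_alleles_identity(self):
        h = harmonize_exposure_outcome(self.hset(), self.outcome_frame())
        assert h.instruments[0].beta_out == pytest.approx(0.1)

    def test_swapped_alleles_flip_outcome_sign(self):
        h = harmonize_exposure_outcome(self.hset(), self.outcome_frame(ea="G", nea="A"))
        assert h.instruments[0].beta_out == pytest.approx(-0.1)

    def test_missing_snp_decrements_count(self):
        out = self.outcome_frame()
        out["SNP"] = ["rs_other"]
        h = harmonize_exposure_outcome(self.hset(), out)
        assert len(h) == 0


class TestEstimators:
    def test_single_snp_wald_ratio(self):
        h = make_set([0.5], [0.05], [0.1], [0.02])
        est = estimate_effects(h)
        assert set(est) == {"wald"}
        assert est["wald"].beta == pytest.approx(0.2)
        assert est["wald"].se == pytest.approx(0.02 / 0.5)

    def test_ivw_with_one_instrument_equals_wald(self):
        bx, sy = [0.5], [0.02]
        h = make_set(bx, [0.05], [0.1], sy)
        wald = estimate_effects(h)["wald"]
        ivw = estimate_effects(make_set(bx * 2, [0.05] * 2, [0.1] * 2, sy * 2))["ivw"]
        # two identical instruments leave the estimate at the Wald ratio
        assert ivw.beta == pytest.approx(wald.beta)

    def test_degenerate_agreement_across_all_estimators(self):
        bx = np.array([0.2, 0.4, 0.5, 0.8, 1.0])
        h = make_set(bx, bx * 0.1, 0.2 * bx, np.full(5, 0.05))
        est = estimate_effects(h, seed=1)
        for method in ("ivw", "egger", "weighted_median", "weighted_mode", "simple_mode"):
            assert est[method].beta == pytest.approx(0.2, abs=1e-6), method

    def test_zero_exposure_beta_is_an_error(self):
        h = make_set([0.0], [0.05], [0.1], [0.02])
        with pytest.raises(UsageError):
            estimate_effects(h)

    def test_or_and_ci_consistent_with_beta(self):
        e = MethodEstimate("ivw", beta=0.3, se=0.1, p=0.01, n_snp=5)
        assert e.odds_ratio == pytest.approx(np.exp(0.3))
        lo, hi = e.ci
        assert lo == pytest.approx(np.exp(0.3 - 1.96 * 0.1))
        assert hi == pytest.approx(np.exp(0.3 + 1.96 * 0.1))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_ivw_invariant_under_per_snp_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        bx = rng.uniform(0.1, 0.5, n)
        by = rng.normal(0.3 * bx, 0.05)
        sy = np.full(n, 0.05)
        flip = rng.random(n) < 0.5
        sign = np.where(flip, -1.0, 1.0)
        a = estimate_effects(make_set(bx, bx * 0.1, by, sy))["ivw"]
        b = estimate_effects(make_set(bx * sign, bx * 0.1, by * sign, sy))["ivw"]
        assert b.beta == pytest.approx(a.beta, rel=1e-12)


class TestSensitivity:
    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.2, 0.4, 0.8])
        h = make_set(bx, bx * 0.1, 0.2 * bx, np.full(3, 0.05))
        est = estimate_effects(h, seed=0)
        sens = heterogeneity_and_pleiotropy(h, est)
        assert sens.q_ivw == pytest.approx(0.0, abs=1e-20)
        assert sens.q_ivw_p == pytest.approx(1.0)

    def test_two_instruments_q_df_one_no_egger(self):
        h = make_set([0.3, 0.5], [0.03, 0.05], [0.1, 0.12], [0.05, 0.05])
        est = estimate_effects(h, seed=0)
        sens = heterogeneity_and_pleiotropy(h, est)
        assert sens.q_ivw_df == 1
        assert sens.egger_intercept is None

    def test_directional_pleiotropy_detected(self):
        # positive mean direct effects shift the Egger intercept upward
        intercepts = []
        detected = 0
        reps = 40
        for rep in range(reps):
            cfg = PqtlSimConfig(
                n_instruments=50, beta_causal=0.0, pleiotropy="directional",
                pleiotropy_scale=0.05, seed=1000 + rep,
            )
            h = sim_set(cfg)
            est = estimate_effects(h, methods=["ivw", "egger"], seed=rep)
            sens = heterogeneity_and_pleiotropy(h, est)
            intercepts.append(sens.egger_intercept)
            detected += sens.egger_intercept_p < 0.05
        assert np.mean(intercepts) > 0
        assert detected / reps > 0.5


class TestFdr:
    def test_hand_applied_bh_with_cumulative_minimum(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.73])[0] == pytest.approx(0.73)

    def test_out_of_range_rejected(self):
        with pytest.raises(UsageError):
            fdr_adjust([0.5, 0.0])
        with pytest.raises(UsageError):
            fdr_adjust([1.5])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_definition(self, p_list):
        p = np.array(p_list)
        # independent step-up oracle straight from the definition
        n = len(p)
        order = np.argsort(p)
        scaled = p[order] * n / np.arange(1, n + 1)
        oracle_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        oracle = np.empty(n)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        assert np.allclose(fdr_adjust(p), oracle, atol=1e-12)


class TestVerdict:
    def result(self, q_p=0.2, icept_p=0.5, directions=(1, 1, 1, 1)):
        estimates = {"ivw": MethodEstimate("ivw", 0.3, 0.1, 0.01, 5)}
        for name, sign in zip(("egger", "weighted_median", "weighted_mode", "simple_mode"), directions):
            estimates[name] = MethodEstimate(name, 0.2 * sign, 0.1, 0.1, 5)
        sens = SensitivityStats(q_ivw=1.0, q_ivw_df=4, q_ivw_p=q_p, egger_intercept=0.0,
                                egger_intercept_se=0.01, egger_intercept_p=icept_p)
        return MRResult(protein="P", estimates=estimates, sensitivity=sens)

    def test_clean_result_passes(self):
        ok, reasons = robustness_verdict(self.result())
        assert ok and reasons == []

    def test_heterogeneity_fails_with_reason(self):
        ok, reasons = robustness_verdict(self.result(q_p=0.01))
        assert not ok and "heterogeneity" in reasons

    def test_pleiotropy_fails_with_reason(self):
        ok, reasons = robustness_verdict(self.result(icept_p=0.01))
        assert not ok and "pleiotropy" in reasons

    def test_direction_clause_needs_two_agreeing_estimators(self):
        ok, reasons = robustness_verdict(self.result(directions=(-1, -1, -1, -1)))
        assert not ok and "direction" in reasons
        ok2, _ = robustness_verdict(self.result(directions=(-1, 1, 1, -1)))
        assert ok2

    def test_small_set_requires_all_available_to_agree(self):
        estimates = {"wald": MethodEstimate("wald", 0.3, 0.1, 0.01, 1)}
        r = MRResult(protein="P", estimates=estimates, sensitivity=SensitivityStats())
        ok, _ = robustness_verdict(r)
        assert ok  # nothing to contradict: clauses vacuous


class TestParameterRecovery:
    def test_ivw_recovers_causal_effect(self):
        # mean IVW estimate over replicates sits on the true effect
        reps = 100
        estimates = []
        for rep in range(reps):
            h = sim_set(PqtlSimConfig(n_instruments=50, beta_causal=0.3, seed=rep))
            estimates.append(estimate_effects(h, methods=["ivw"])["ivw"].beta)
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.015)

    def test_type_i_error_near_nominal_at_null(self):
        reps = 300
        rejections = 0
        for rep in range(reps):
            h = sim_set(PqtlSimConfig(n_instruments=50, beta_causal=0.0, seed=10_000 + rep))
            est = estimate_effects(h, methods=["ivw"])["ivw"]
            rejections += est.p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


class TestScan:
    def panels(self, n_proteins=6, n_causal=2, seed=0):
        panels, outcomes = [], {}
        for i in range(n_proteins):
            cfg = PqtlSimConfig(
                n_instruments=12,
                beta_causal=0.5 if i < n_causal else 0.0,
                gene_chrom=1 + i,
                seed=seed + i,
            )
            exp, out, _ = gen_pqtl_study(cfg)
            name = f"P{i + 1}"
            panels.append(
                Panel(
                    protein=name,
                    dataset="deCODE" if i % 2 == 0 else "UKB",
                    exposure=exp,
                    locus=GeneLocus(cfg.gene_chrom, cfg.gene_start, cfg.gene_end, name),
                )
            )
            outcomes[name] = out
        return panels, outcomes

    def test_causal_proteins_found_nulls_not(self):
        panels, outcomes = self.panels()
        results = []
        for p in panels:
            results.append(run_mr(p, outcomes[p.protein], seed=1))
        adj = fdr_adjust([r.primary.p for r in results])
        sig = {r.protein for r, q in zip(results, adj) if q < 0.05 and r.verdict}
        assert {"P1", "P2"} <= sig
        assert len(sig) <= 3  # at most one false positive slips through

    def test_overlap_summary_set_arithmetic(self):
        a = {f"A{i}" for i in range(13)} | {f"S{i}" for i in range(6)}
        b = {f"B{i}" for i in range(54)} | {f"S{i}" for i in range(6)}
        s = overlap_summary(a, b, "deCODE", "UKB")
        assert s["n_deCODE"] == 19
        assert s["n_UKB"] == 60
        assert s["n_shared"] == 6
        assert s["n_union"] == 73

    def test_proteome_scan_shared_outcome(self):
        # all panels scanned against one outcome built from a null protein
        panels, outcomes = self.panels(n_proteins=4, n_causal=0, seed=50)
        results, summary = proteome_scan(panels, outcomes["P3"], seed=2)
        assert len(results) == 4
        assert summary["n_union"] == len(
            set().union(*(set(v) for v in summary["per_dataset"].values()))
        )
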