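"""Two-sample MR: harmonization, estimator battery, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from dietcausal import GwasSummarySet, GwasTruth, MRConfig, generate_gwas_pair, run_mr
from dietcausal.mr import (
    MRModel,
    build_adjusted_instrument,
    harmonize,
    instrument_strength,
    ivw,
    leave_one_out,
    mr_egger,
    mr_presso,
    mr_raps,
    select_instruments,
    wald_ratio,
    weighted_median,
)


def _summary_set(rows, trait=""):
    defaults = {"CHR": 1, "POS": 1000, "EAF": 0.3, "N": 10000}
    table = pd.DataFrame(rows)
    for k, v in defaults.items():
        if k not in table.columns:
            table[k] = v
    return GwasSummarySet(table, trait=trait)


def _variant(snp, ea, oa, beta, se=0.05, p=1e-8, **kw):
    return {"SNP": snp, "EA": ea, "OA": oa, "BETA": beta, "SE": se, "P": p, **kw}


class TestContainers:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _summary_set([_variant("rs1", "A", "G", 0.1), _variant("rs1", "A", "G", 0.2)])

    def test_bad_alleles_rejected(self):
        with pytest.raises(ValueError):
            _summary_set([_variant("rs1", "A", "X", 0.1)])

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            _summary_set([_variant("rs1", "A", "G", 0.1, se=0.0)])

    def test_tsv_roundtrip(self, tmp_path):
        s = _summary_set([_variant("rs1", "A", "G", 0.1)])
        path = tmp_path / "x.tsv"
        s.to_tsv(path)
        back = GwasSummarySet.from_tsv(path)
        pd.testing.assert_frame_equal(back.table, s.table)


class TestSelectInstruments:
    def _ld(self, snps, r2):
        mat = np.full((len(snps), len(snps)), r2, float)
        np.fill_diagonal(mat, 1.0)
        return pd.DataFrame(mat, index=snps, columns=snps)

    def test_single_variant_below_threshold_retained(self):
        s = _summary_set([_variant("rs1", "A", "G", 0.1, p=1e-7)])
        assert len(select_instruments(s, 5e-6)) == 1

    def test_greedy_clump_keeps_lowest_p(self):
        s = _summary_set(
            [
                _variant("rs1", "A", "G", 0.1, p=1e-8, POS=100_000),
                _variant("rs2", "A", "G", 0.1, p=1e-7, POS=110_000),
            ]
        )
        out = select_instruments(s, 5e-6, ld=self._ld(["rs1", "rs2"], 0.5))
        assert out.table["SNP"].tolist() == ["rs1"]

    def test_low_ld_pair_both_kept(self):
        s = _summary_set(
            [
                _variant("rs1", "A", "G", 0.1, p=1e-8, POS=100_000),
                _variant("rs2", "A", "G", 0.1, p=1e-7, POS=110_000),
            ]
        )
        out = select_instruments(s, 5e-6, ld=self._ld(["rs1", "rs2"], 0.1))
        assert sorted(out.table["SNP"]) == ["rs1", "rs2"]

    def test_distant_pair_not_clumped(self):
        s = _summary_set(
            [
                _variant("rs1", "A", "G", 0.1, p=1e-8, POS=100_000),
                _variant("rs2", "A", "G", 0.1, p=1e-7, POS=2_000_000),
            ]
        )
        out = select_instruments(s, 5e-6, ld=self._ld(["rs1", "rs2"], 0.9))
        assert len(out) == 2

    def test_missing_ld_entries_rejected(self):
        s = _summary_set([_variant("rs1", "A", "G", 0.1), _variant("rs2", "A", "G", 0.1)])
        with pytest.raises(ValueError, match="missing"):
            select_instruments(s, 1.0, ld=self._ld(["rs1"], 0.5))

    def test_p_filter(self):
        s = _summary_set([_variant("rs1", "A", "G", 0.1, p=1e-3)])
        assert len(select_instruments(s, 5e-6)) == 0


class TestAdjustedInstrument:
    def test_disjoint_union(self):
        a = _summary_set([_variant(f"rs{i}", "A", "G", 0.1) for i in range(3)])
        b = _summary_set([_variant(f"rs{i}", "A", "G", 0.1) for i in range(10, 12)])
        out = build_adjusted_instrument(a, b)
        assert len(out) == 5

    def test_overlap_removed(self):
        a = _summary_set([_variant(f"rs{i}", "A", "G", 0.1) for i in range(4)])
        b = _summary_set([_variant(f"rs{i}", "A", "G", 0.1) for i in range(3, 6)])
        out = build_adjusted_instrument(a, b)
        assert len(out) == 5
        assert "rs3" not in set(out.table["SNP"])

    def test_identical_sets_rejected(self):
        a = _summary_set([_variant("rs1", "A", "G", 0.1)])
        with pytest.raises(ValueError, match="overlap"):
            build_adjusted_instrument(a, a)


class TestHarmonize:
    def test_aligned_variant_kept(self):
        e = _summary_set([_variant("rs1", "A", "G", 0.1)])
        o = _summary_set([_variant("rs1", "A", "G", -0.05)])
        h = harmonize(e, o)
        row = h.table.iloc[0]
        assert row["action"] == "kept" and row["beta_outcome"] == -0.05

    def test_swapped_alleles_flipped(self):
        e = _summary_set([_variant("rs1", "A", "G", 0.1)])
        o = _summary_set([_variant("rs1", "G", "A", -0.05)])
        row = harmonize(e, o).table.iloc[0]
        assert row["action"] == "flipped"
        assert row["beta_outcome"] == pytest.approx(0.05)

    def test_strand_flip_resolved(self):
        e = _summary_set([_variant("rs1", "A", "G", 0.1)])
        o = _summary_set([_variant("rs1", "T", "C", 0.07)])
        row = harmonize(e, o).table.iloc[0]
        assert row["action"] == "kept" and row["beta_outcome"] == 0.07

    def test_strand_flip_swapped_resolved(self):
        e = _summary_set([_variant("rs1", "A", "G", 0.1)])
        o = _summary_set([_variant("rs1", "C", "T", 0.07)])
        row = harmonize(e, o).table.iloc[0]
        assert row["action"] == "flipped"
        assert row["beta_outcome"] == pytest.approx(-0.07)

    def test_palindromic_removed(self):
        e = _summary_set([_variant("rs1", "A", "T", 0.1)])
        o = _summary_set([_variant("rs1", "A", "T", 0.05)])
        h = harmonize(e, o)
        assert h.table.iloc[0]["action"] == "removed_palindromic"
        assert h.n_retained == 0

    def test_missing_variant_removed(self):
        e = _summary_set([_variant("rs1", "A", "G", 0.1)])
        o = _summary_set([_variant("rs2", "A", "G", 0.05)])
        assert harmonize(e, o).table.iloc[0]["action"] == "removed_missing"

    def test_mismatched_alleles_removed(self):
        e = _summary_set([_variant("rs1", "A", "G", 0.1)])
        o = _summary_set([_variant("rs1", "A", "C", 0.05)])
        assert harmonize(e, o).table.iloc[0]["action"] == "removed_mismatch"

    def test_involution_safe(self):
        rng = np.random.default_rng(0)
        truth = GwasTruth(k_snps=20, theta=0.2, seed=5)
        e, o = generate_gwas_pair(truth)
        h1 = harmonize(e, o)
        # re-harmonizing the already-aligned survivors changes nothing
        keep = h1.retained["SNP"]
        e2, o2 = e.subset(keep), o.subset(keep)
        h2 = harmonize(e2, o2)
        r1 = h1.retained.reset_index(drop=True)
        r2 = h2.retained.reset_index(drop=True)
        pd.testing.assert_frame_equal(r1, r2)

    def test_wald_columns_present_for_retained(self):
        e = _summary_set([_variant("rs1", "A", "G", 0.2)])
        o = _summary_set([_variant("rs1", "A", "G", 0.1, se=0.02)])
        row = harmonize(e, o).retained.iloc[0]
        assert row["wald_ratio"] == pytest.approx(0.5)
        assert row["wald_se"] == pytest.approx(0.1)


class TestWaldRatio:
    def test_unit_denominator(self):
        est = wald_ratio(([1.0], [0.1], [0.5], [0.1]))
        assert (est.estimate, est.se) == (0.5, 0.1)

    def test_formula(self):
        est = wald_ratio(([0.2], [0.01], [0.1], [0.02]))
        assert est.estimate == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(([0.0], [0.1], [0.5], [0.1]))


class TestIvw:
    def test_k1_equals_wald_exactly(self):
        args = ([0.2], [0.01], [0.1], [0.02])
        w, i = wald_ratio(args), ivw(args)
        assert i.estimate == w.estimate
        assert i.se == w.se

    def test_consistent_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = ivw((bx, 0.01 * np.ones(3), 0.3 * bx, 0.01 * np.ones(3)))
        assert est.estimate == pytest.approx(0.3, abs=1e-14)
        assert est.q_statistic == pytest.approx(0.0, abs=1e-18)

    def test_k3_closed_form_oracle(self):
        bx = [0.1, 0.2, 0.15]
        by = [0.05, 0.09, 0.08]
        sy = [0.01, 0.01, 0.01]
        est = ivw((bx, [0.01] * 3, by, sy))
        # independent brute-force computation of the weighted quotient
        num = den = 0.0
        for x, y, s in zip(bx, by, sy):
            num += (y * x) / s**2
            den += (x * x) / s**2
        assert est.estimate == pytest.approx(num / den, abs=1e-12)

    def test_sign_flip_invariance(self, strong_instruments):
        bx, sx, by, sy = strong_instruments.arrays()
        base = ivw((bx, sx, by, sy)).estimate
        flip = np.where(np.arange(len(bx)) % 2 == 0, -1.0, 1.0)
        flipped = ivw((bx * flip, sx, by * flip, sy)).estimate
        assert flipped == pytest.approx(base, abs=1e-14)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.2, 30)
        by = 0.2 * bx + rng.normal(0, 0.05, 30)  # heterogeneous
        sy = np.full(30, 0.01)
        est = ivw((bx, 0.01 * np.ones(30), by, sy))
        fixed_se = 1 / np.sqrt(np.sum((bx / sy) ** 2))
        assert est.se >= fixed_se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ivw(([], [], [], []))


class TestEgger:
    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))

    def test_agrees_with_ivw_without_pleiotropy(self, strong_instruments):
        e, i = mr_egger(strong_instruments), ivw(strong_instruments)
        assert e.estimate == pytest.approx(i.estimate, abs=3 * e.se)
        assert abs(e.extra["intercept"]) < 3 * e.extra["intercept_se"]

    def test_matches_weighted_least_squares_oracle(self, strong_instruments):
        import statsmodels.api as sm

        bx, sx, by, sy = strong_instruments.arrays()
        flip = np.sign(bx)
        x, y = bx * flip, by * flip
        fit = sm.WLS(y, sm.add_constant(x), weights=1 / sy**2).fit()
        est = mr_egger(strong_instruments)
        assert est.estimate == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(fit.params[0], abs=1e-10)

    def test_directional_pleiotropy_intercept_recovery(self):
        rng = np.random.default_rng(3)
        intercepts = []
        for s in range(20):
            truth = GwasTruth(
                k_snps=100, theta=0.2, gamma=rng.uniform(0.05, 0.15, 100),
                pleiotropy_mode="directional", mu_alpha=0.05,
                palindromic_fraction=0.0, seed=100 + s,
            )
            e, o = generate_gwas_pair(truth)
            h = harmonize(select_instruments(e, 1.0), o)
            intercepts.append(mr_egger(h).extra["intercept"])
        assert np.mean(intercepts) == pytest.approx(0.05, abs=0.01)


class TestWeightedMedian:
    def test_equal_weights_odd_k_gives_middle_ratio(self):
        bx = np.ones(5)
        by = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        est = weighted_median((bx, 0.01 * np.ones(5), by, 0.01 * np.ones(5)),
                              bootstrap_draws=10, seed=0)
        assert est.estimate == pytest.approx(0.3)

    def test_majority_valid_recovers_truth(self):
        k = 50
        bx = np.full(k, 0.1)
        by = np.full(k, 0.03)          # 60% valid: ratio 0.3
        by[:20] = 0.1                  # 40% invalid: ratio 1.0
        est = weighted_median(
            (bx, np.full(k, 1e-4), by, np.full(k, 1e-4)), bootstrap_draws=10, seed=0
        )
        assert est.estimate == pytest.approx(0.3, abs=0.05)

    def test_seeded_bootstrap_se_reproducible(self, strong_instruments):
        e1 = weighted_median(strong_instruments, bootstrap_draws=50, seed=7)
        e2 = weighted_median(strong_instruments, bootstrap_draws=50, seed=7)
        assert e1.se == e2.se

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            weighted_median(([0.1], [0.01], [0.05], [0.01]))


class TestRaps:
    def test_recovery_without_pleiotropy(self, strong_instruments):
        est = mr_raps(strong_instruments)
        assert est.estimate == pytest.approx(0.2, abs=0.03)
        assert est.extra["overdispersion"] == pytest.approx(0.0, abs=1e-3)

    def test_balanced_pleiotropy_detected_as_overdispersion(self):
        rng = np.random.default_rng(5)
        tau2 = []
        for s in range(10):
            truth = GwasTruth(
                k_snps=100, theta=0.2, gamma=rng.uniform(0.05, 0.15, 100),
                pleiotropy_mode="balanced", alpha_sd=0.02,
                palindromic_fraction=0.0, seed=200 + s,
            )
            e, o = generate_gwas_pair(truth)
            h = harmonize(select_instruments(e, 1.0), o)
            tau2.append(mr_raps(h).extra["overdispersion"])
        assert np.mean(tau2) > 1e-5

    def test_huber_loss_runs_and_agrees_on_clean_data(self, strong_instruments):
        sq = mr_raps(strong_instruments, loss="squared")
        hu = mr_raps(strong_instruments, loss="huber")
        assert hu.estimate == pytest.approx(sq.estimate, abs=0.02)

    def test_invalid_loss_rejected(self, strong_instruments):
        with pytest.raises(ValueError):
            mr_raps(strong_instruments, loss="cauchy")

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            mr_raps(([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))


class TestPresso:
    def _planted(self, seed=0, shift=10.0):
        rng = np.random.default_rng(seed)
        k = 20
        bx = rng.uniform(0.05, 0.15, k)
        sx = np.full(k, 0.005)
        sy = np.full(k, 0.01)
        by = 0.2 * bx + rng.normal(0, sy)
        by[7] += shift * sy[7]
        return bx, sx, by, sy

    def test_planted_outlier_flagged(self):
        res = mr_presso(self._planted(), n_sim=500, seed=1)
        assert 7 in res.outlier_indices
        assert res.global_p < 0.05
        assert res.corrected is not None

    def test_corrected_estimate_less_biased(self):
        bx, sx, by, sy = self._planted(seed=3)
        res = mr_presso((bx, sx, by, sy), n_sim=500, seed=1)
        uncorrected = ivw((bx, sx, by, sy)).estimate
        assert abs(res.corrected.estimate - 0.2) < abs(uncorrected - 0.2)

    def test_clean_data_large_global_p(self):
        rng = np.random.default_rng(9)
        k = 20
        bx = rng.uniform(0.05, 0.15, k)
        by = 0.2 * bx + rng.normal(0, 0.01, k)
        res = mr_presso((bx, np.full(k, 0.005), by, np.full(k, 0.01)), n_sim=500, seed=4)
        assert res.global_p > 0.05
        assert res.outlier_indices == []

    def test_seeded_determinism(self):
        a = mr_presso(self._planted(), n_sim=200, seed=11)
        b = mr_presso(self._planted(), n_sim=200, seed=11)
        assert a.global_p == b.global_p
        assert np.array_equal(a.outlier_p, b.outlier_p)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            mr_presso(([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.01] * 3), n_sim=200)

    def test_small_nsim_rejected(self):
        with pytest.raises(ValueError):
            mr_presso(self._planted(), n_sim=50)


class TestInstrumentStrength:
    def test_formula(self):
        f, med = instrument_strength(([0.1], [0.02], [0.0], [1.0]))
        assert f[0] == pytest.approx(25.0)
        assert med == pytest.approx(25.0)

    def test_zero_beta(self):
        f, _ = instrument_strength(([0.0], [0.02], [0.0], [1.0]))
        assert f[0] == 0.0

    def test_median_summary(self):
        bx = np.array([2.0, np.sqrt(5), 10.0])
        f, med = instrument_strength((bx, np.ones(3), np.zeros(3), np.ones(3)))
        assert med == pytest.approx(5.0)


class TestLeaveOneOut:
    def test_identical_instruments_all_equal_full(self):
        k = 5
        bx = np.full(k, 0.1)
        by = np.full(k, 0.03)
        loo = leave_one_out((bx, np.full(k, 0.01), by, np.full(k, 0.01)))
        np.testing.assert_allclose(loo["estimate"], 0.3, atol=1e-14)
        assert not loo["influential"].any()

    def test_dominant_outlier_flagged(self):
        bx = np.array([0.1, 0.1, 0.1, 0.1, 0.1])
        by = np.array([0.03, 0.03, 0.03, 0.03, 0.2])
        loo = leave_one_out((bx, np.full(5, 0.005), by, np.full(5, 0.002)))
        assert loo.loc[4, "influential"]

    def test_k2_boundary(self):
        loo = leave_one_out(([0.1, 0.2], [0.01] * 2, [0.03, 0.08], [0.01] * 2))
        assert len(loo) == 2
        # each row is the remaining single-variant Wald ratio
        assert loo.loc[0, "estimate"] == pytest.approx(0.08 / 0.2)
        assert loo.loc[1, "estimate"] == pytest.approx(0.3)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            leave_one_out(([0.1], [0.01], [0.05], [0.01]))


class TestRunMr:
    def test_binary_outcome_or_recovery(self):
        rng = np.random.default_rng(21)
        truth = GwasTruth(
            k_snps=60, theta=-0.75, gamma=rng.uniform(0.05, 0.15, 60),
            palindromic_fraction=0.1, n_exposure=5 * 10**6, n_outcome=5 * 10**6,
            seed=77,
        )
        e, o = generate_gwas_pair(truth)
        res = run_mr(e, o, MRConfig(p_threshold=1.0, binary_outcome=True, seed=1))
        or_est, lo, hi = res.odds_ratio("ivw")
        assert or_est == pytest.approx(np.exp(-0.75), rel=0.05)
        assert lo < or_est < hi

    def test_single_variant_bundle(self):
        e = _summary_set([_variant("rs1", "A", "G", 0.2, p=1e-9)])
        o = _summary_set([_variant("rs1", "A", "G", 0.1, se=0.02)])
        res = MRModel.from_summary_stats(e, o, MRConfig()).fit()
        assert "wald_ratio" in res.estimates
        assert "mr_egger" in res.skipped
        assert "weighted_median" in res.skipped
        assert "mr_presso" in res.skipped
        assert res.estimates["ivw"].estimate == res.estimates["wald_ratio"].estimate

    def test_null_theta_not_significant(self):
        truth = GwasTruth(k_snps=40, theta=0.0, seed=31, gamma_sd=0.08)
        e, o = generate_gwas_pair(truth)
        res = run_mr(e, o, MRConfig(p_threshold=1.0, seed=2))
        assert res.verdict == "not significant"

    def test_true_effect_significant(self, strong_instruments):
        res = MRModel(strong_instruments, MRConfig(seed=3)).fit()
        assert res.verdict == "significant"
        assert res.f_median > 30

    def test_no_surviving_instruments_rejected(self):
        e = _summary_set([_variant("rs1", "A", "T", 0.2, p=1e-9)])  # palindromic
        o = _summary_set([_variant("rs1", "A", "T", 0.1)])
        with pytest.raises(ValueError):
            MRModel.from_summary_stats(e, o, MRConfig())
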