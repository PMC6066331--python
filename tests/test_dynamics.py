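"""Expression-dynamics analyses: profiles, regression, half-lives, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirdyn import dynamics, simulate
from mirdyn.dynamics import (
    FilterThresholds,
    aggregate_pri_density,
    build_regression_points,
    cluster_change_anova,
    compare_coefficients_by_5p_nt,
    estimate_half_life,
    filter_regression_genes,
    fit_kinetic_regression,
    fit_per_gene,
    kmeans_elbow,
    kmeans_profiles,
    pooled_prediction_r2,
    predict_change_rates,
    prediction_error_rates,
    zscore_profiles,
)

from conftest import UNIFORM_2H, time_course


class TestZScore:
    def test_hand_computed_values(self):
        z = zscore_profiles(time_course([[1, 2, 3]]))
        np.testing.assert_allclose(
            z.iloc[0].to_numpy(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_constant_row_dropped_not_nan(self):
        z = zscore_profiles(time_course([[5, 5, 5], [1, 2, 3]]))
        assert list(z.index) == ["g1"] and not z.isna().any().any()

    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        z = zscore_profiles(time_course(rng.random((20, 8))))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            zscore_profiles(time_course([[1.0]]))


class TestKMeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0.0, 0.05, size=(10, 8))
        blob2 = rng.normal(5.0, 0.05, size=(10, 8))
        mat = time_course(np.vstack([blob1, blob2]))
        res = kmeans_profiles(mat, k=2, seed=0)
        labels = res.assignments.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k1_wss_is_total_sum_of_squares(self):
        rng = np.random.default_rng(2)
        vals = rng.random((12, 8))
        res = kmeans_profiles(time_course(vals), k=1, seed=0)
        tss = ((vals - vals.mean(axis=0)) ** 2).sum()
        assert res.wss == pytest.approx(tss)

    def test_duplicate_rows_same_cluster(self):
        rng = np.random.default_rng(3)
        row = rng.random(8)
        vals = np.vstack([row, row, rng.random(8) + 10, rng.random(8) + 10])
        res = kmeans_profiles(time_course(vals), k=2, seed=0)
        assert res.assignments.iloc[0] == res.assignments.iloc[1]

    def test_k_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            kmeans_profiles(time_course(np.random.default_rng(0).random((3, 8))), k=4)

    def test_elbow_wss_not_increasing_in_k(self):
        rng = np.random.default_rng(4)
        mat = time_course(rng.random((30, 8)))
        wss = kmeans_elbow(mat, ks=[1, 2, 3, 4, 5], restarts=5, seed=0)
        assert (wss.diff().dropna() <= 1e-9).all()


class TestFilters:
    def make(self, mature_rows, pri_rows):
        return time_course(mature_rows), time_course(pri_rows)

    def test_maternal_share_rule(self):
        # 40% of summed RPTS in the first window -> excluded
        m = [40.0, 10, 10, 10, 10, 10, 5, 5]
        other = [12.5] * 8
        mature, pri = self.make([m, other], [[2.0] * 8] * 2)
        rep = filter_regression_genes(mature, pri)
        assert "g0" in rep.removed["maternal_share"] and "g1" in rep.kept

    def test_mature_level_rule_strict(self):
        base = [0.0] * 8
        four = base.copy()
        four[2:6] = [10.1] * 4          # above 10 RPTS in only 4 windows -> out
        five = base.copy()
        five[2:7] = [10.1] * 5          # in 5 windows -> kept
        mature, pri = self.make([four, five], [[2.0] * 8] * 2)
        rep = filter_regression_genes(mature, pri)
        assert "g0" in rep.removed["mature_level"] and "g1" in rep.kept

    def test_exactly_10_rpts_does_not_count(self):
        row = [0.0] * 8
        row[2:7] = [10.0] * 5           # exactly 10 is not "> 10"
        mature, pri = self.make([row], [[2.0] * 8])
        rep = filter_regression_genes(mature, pri)
        assert "g0" in rep.removed["mature_level"]

    def test_multimapper_rule(self):
        good = [20.0] * 8
        mature, pri = self.make([good, good], [[2.0] * 8] * 2)
        mm = pd.Series({"g0": 0.25, "g1": 0.20})
        rep = filter_regression_genes(mature, pri, multimapper_fraction=mm)
        assert "g0" in rep.removed["multimapper"] and "g1" in rep.kept

    def test_pri_density_rule(self):
        good = [20.0] * 8
        mature, pri = self.make([good, good], [[0.5] * 8, [1.5] + [0.0] * 7])
        rep = filter_regression_genes(mature, pri)
        assert "g0" in rep.removed["pri_density"] and "g1" in rep.kept

    def test_mismatched_grids_rejected(self):
        mature = time_course([[1.0] * 8])
        pri = time_course([[1.0] * 6])
        with pytest.raises(ValueError):
            filter_regression_genes(mature, pri)


class TestAggregation:
    def test_mean_of_tiling_windows(self):
        fine = time_course([[3.0, 6.0, 9.0]], labels=["h12-14", "h14-16", "h16-18"])
        out = aggregate_pri_density(fine, [(12, 18)])
        assert out.at["g0", "h12-18"] == 6.0

    def test_identity_on_matching_grid(self):
        fine = time_course([[1.0, 2.0]], labels=["h00-02", "h02-04"])
        out = aggregate_pri_density(fine, [(0, 2), (2, 4)])
        pd.testing.assert_frame_equal(out, fine)

    def test_study_grid_from_twelve_fine_windows(self):
        labels = [f"h{2*i:02d}-{2*i+2:02d}" for i in range(12)]
        fine = time_course([list(range(1, 13))], labels=labels)
        targets = [(2 * i, 2 * i + 2) for i in range(6)] + [(12, 18), (18, 24)]
        out = aggregate_pri_density(fine, targets)
        assert list(out.columns) == [
            "h00-02", "h02-04", "h04-06", "h06-08", "h08-10", "h10-12", "h12-18", "h18-24",
        ]
        assert out.at["g0", "h12-18"] == 8.0 and out.at["g0", "h18-24"] == 11.0

    def test_untiled_target_rejected(self):
        fine = time_course([[1.0, 2.0]], labels=["h00-02", "h02-04"])
        with pytest.raises(ValueError):
            aggregate_pri_density(fine, [(0, 6)])


class TestRegressionPoints:
    def test_toy_three_window_series(self):
        labels = ["h00-02", "h02-04", "h04-06"]
        mature = time_course([[10.0, 14.0, 14.0]], labels=labels)
        pri = time_course([[0.0, 2.0, 0.0]], labels=labels)
        pts = build_regression_points(mature, pri)
        assert len(pts) == 2
        assert tuple(pts.loc[0, ["x", "y", "z"]]) == (10.0, 2.0, 4.0)
        assert tuple(pts.loc[1, ["x", "y", "z"]]) == (14.0, 0.0, 0.0)

    def test_constant_profile_zero_z(self):
        mature = time_course([[7.0] * 8])
        pri = time_course([[1.0] * 8])
        assert (build_regression_points(mature, pri)["z"] == 0).all()

    def test_eight_windows_give_seven_points_per_gene(self):
        rng = np.random.default_rng(0)
        mature = time_course(rng.random((3, 8)))
        pri = time_course(rng.random((3, 8)))
        pts = build_regression_points(mature, pri)
        assert pts.groupby("gene").size().eq(7).all()

    def test_per_hour_divides_by_midpoint_gap(self):
        mature = time_course([[0.0] * 6 + [12.0, 12.0]])
        pri = time_course([[0.0] * 8])
        raw = build_regression_points(mature, pri)
        rate = build_regression_points(mature, pri, per_hour=True)
        # pair 5: h10-12 (mid 11) -> h12-18 (mid 15): gap 4 h
        assert raw.loc[raw["pair"] == 5, "z"].iloc[0] == 12.0
        assert rate.loc[rate["pair"] == 5, "z"].iloc[0] == 3.0


class TestKineticFit:
    def test_noiseless_plane_recovered(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(30) * 100, rng.random(30) * 10
        z = -0.1 * x + 2.0 * y + 0.0
        pts = pd.DataFrame({"gene": "g", "x": x, "y": y, "z": z})
        fit = fit_kinetic_regression(pts, scope="global")
        assert fit.a == pytest.approx(-0.1, abs=1e-12)
        assert fit.b == pytest.approx(2.0, abs=1e-12)
        assert fit.c == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        x, y = rng.random(40), rng.random(40)
        z = rng.random(40)
        pts = pd.DataFrame({"gene": "g", "x": x, "y": y, "z": z})
        fit = fit_kinetic_regression(pts, scope="global")
        X = np.column_stack([x, y, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        np.testing.assert_allclose([fit.a, fit.b, fit.c], beta, atol=1e-9)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x, y, z = rng.random(25), rng.random(25), rng.random(25)
        pts = pd.DataFrame({"gene": "g", "x": x, "y": y, "z": z})
        fit = fit_kinetic_regression(pts, scope="global")
        res = sm.OLS(z, sm.add_constant(np.column_stack([x, y]))).fit()
        np.testing.assert_allclose([fit.c, fit.a, fit.b], res.params, atol=1e-10)
        assert fit.r2 == pytest.approx(res.rsquared)

    def test_underdetermined_rejected(self):
        pts = pd.DataFrame({"gene": "g", "x": [1, 2], "y": [1, 2], "z": [1, 2]})
        with pytest.raises(ValueError):
            fit_kinetic_regression(pts, scope="global")

    def test_rank_deficient_flagged(self):
        pts = pd.DataFrame({"gene": "g", "x": [1.0] * 5, "y": [2.0] * 5, "z": [0.5] * 5})
        fits = fit_per_gene(pts)
        assert not fits.loc["g", "ok"]

    def test_recovers_generator_parameters_noiseless(self):
        cfg = simulate.random_kinetics_config(
            n_genes=20, seed=10, kinetics="euler", window_bounds=UNIFORM_2H
        )
        tk = simulate.simulate_time_course(cfg)
        pts = build_regression_points(tk.mature_frame(), tk.pri_frame(), per_hour=True)
        fits = fit_per_gene(pts)
        np.testing.assert_allclose(fits["Coef_mature_Level"].to_numpy(), -cfg.a, atol=1e-9)
        np.testing.assert_allclose(fits["Coef_Updensity"].to_numpy(), cfg.b, atol=1e-9)
        assert pooled_prediction_r2(fits, pts) == pytest.approx(1.0, abs=1e-9)

    def test_fitted_degradation_sign_under_noise(self):
        cfg = simulate.random_kinetics_config(
            n_genes=50, seed=0, kinetics="euler", window_bounds=UNIFORM_2H
        )
        tk = simulate.simulate_time_course(cfg)
        counts = simulate.simulate_counts(tk, cfg)
        from mirdyn.quant import rpts_normalize

        rpts = [rpts_normalize(df) for df in counts.values()]
        mean_rpts = sum(rpts) / len(rpts)
        rep = filter_regression_genes(mean_rpts, tk.pri_frame())
        pts = build_regression_points(
            mean_rpts.loc[rep.kept], tk.pri_frame().reindex(rep.kept), per_hour=True
        )
        fits = fit_per_gene(pts)
        assert (fits["Coef_mature_Level"] < 0).mean() >= 0.95


class TestErrorRates:
    def _points(self, z, width):
        return pd.DataFrame(
            {
                "gene": ["g"], "pair": [0], "window1": ["h00-02"], "window2": ["h02-04"],
                "z": [z], "gap_h": [width], "window2_width_h": [width],
            }
        )

    def test_perfect_prediction_zero_error(self):
        pts = self._points(z=3.0, width=2.0)
        mature = time_course([[50.0, 100.0]], genes=["g"], labels=["h00-02", "h02-04"])
        out = prediction_error_rates(pts, pd.Series([3.0]), mature)
        assert out["error_rate_pct"].iloc[0] == 0.0

    def test_formula_worked_example(self):
        # (predicted - observed) = 1, window 2 h, level 100 RPTS -> 2%
        pts = self._points(z=0.0, width=2.0)
        mature = time_course([[50.0, 100.0]], genes=["g"], labels=["h00-02", "h02-04"])
        out = prediction_error_rates(pts, pd.Series([1.0]), mature)
        assert out["error_rate_pct"].iloc[0] == pytest.approx(2.0)

    def test_sign_preserved_and_six_hour_window(self):
        pts = self._points(z=5.0, width=6.0)
        mature = time_course([[50.0, 60.0]], genes=["g"], labels=["h00-02", "h02-04"])
        out = prediction_error_rates(pts, pd.Series([0.0]), mature)
        assert out["error_rate_pct"].iloc[0] == pytest.approx(-50.0)

    def test_low_level_points_flagged(self):
        pts = self._points(z=1.0, width=2.0)
        mature = time_course([[50.0, 5.0]], genes=["g"], labels=["h00-02", "h02-04"])
        out = prediction_error_rates(pts, pd.Series([1.0]), mature, min_level=10.0)
        assert bool(out["excluded"].iloc[0])


class TestHalfLife:
    def test_exact_halving(self):
        est = estimate_half_life([100, 50, 25, 12.5], [0, 2, 4, 6])
        assert est.half_life == pytest.approx(2.0, abs=1e-12)
        assert est.r2 == pytest.approx(1.0)

    def test_constant_levels_infinite_half_life(self):
        est = estimate_half_life([10, 10, 10], [0, 2, 4])
        assert est.decay_rate == 0.0 and est.half_life == np.inf

    def test_scale_invariance(self):
        lv = np.array([80.0, 37.0, 21.0, 9.0])
        t = np.array([1.0, 3.0, 5.0, 7.0])
        assert estimate_half_life(lv, t).half_life == pytest.approx(
            estimate_half_life(lv * 137.0, t).half_life
        )

    def test_nonpositive_levels_dropped(self):
        with_zero = estimate_half_life([100, 0.0, 25, 12.5], [0, 2, 4, 6])
        without = estimate_half_life([100, 25, 12.5], [0, 4, 6])
        assert with_zero.half_life == pytest.approx(without.half_life)
        assert with_zero.n_points == 3

    def test_too_few_points_flagged(self):
        est = estimate_half_life([10.0, 0.0], [0, 2])
        assert not est.ok

    def test_window_range_restricts_fit(self):
        # decay only holds after t=4; restricting the range recovers it exactly
        t = np.array([0, 2, 4, 6, 8, 10], dtype=float)
        lv = np.array([5.0, 5.0, 100.0, 50.0, 25.0, 12.5])
        est = estimate_half_life(lv, t, window_range=(4, 10))
        assert est.half_life == pytest.approx(2.0, abs=1e-12)

    def test_noisy_median_recovery(self):
        """Median of 500 lognormal-noise replicates within 5% of a 3 h truth."""
        rng = np.random.default_rng(99)
        mids = np.array([1, 3, 5, 7, 9, 11, 15, 21], dtype=float)
        lam = np.log(2) / 3.0
        sigma = np.sqrt(np.log(1 + 0.1**2))
        halves = [
            estimate_half_life(
                100 * np.exp(-lam * mids) * rng.lognormal(-sigma**2 / 2, sigma, size=8), mids
            ).half_life
            for _ in range(500)
        ]
        assert abs(np.median(halves) - 3.0) / 3.0 < 0.05


class TestFivePrime:
    def _fits(self, coefs):
        return pd.DataFrame(
            {"Coef_mature_Level": coefs, "ok": True},
            index=pd.Index([f"g{i}" for i in range(len(coefs))], name="gene"),
        )

    def test_identical_groups_d_zero(self):
        fits = self._fits([0.1, 0.2, 0.1, 0.2])
        nt = pd.Series(["U", "U", "A", "A"], index=fits.index)
        comp = compare_coefficients_by_5p_nt(fits, nt)
        assert comp.ks.statistic == 0.0

    def test_complete_separation_d_one(self):
        fits = self._fits([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        nt = pd.Series(["U", "U", "U", "A", "C", "G"], index=fits.index)
        comp = compare_coefficients_by_5p_nt(fits, nt)
        assert comp.ks.statistic == 1.0 and comp.mean_u > comp.mean_other

    def test_d_matches_scipy_one_sided(self):
        rng = np.random.default_rng(12)
        u = rng.normal(1.0, 1.0, size=20)
        other = rng.normal(0.0, 1.0, size=20)
        fits = self._fits(np.concatenate([u, other]))
        nt = pd.Series(["U"] * 20 + ["A"] * 20, index=fits.index)
        comp = compare_coefficients_by_5p_nt(fits, nt)
        # our "U stochastically greater" D equals scipy's 'less' convention
        ref = stats.ks_2samp(u, other, alternative="less")
        assert comp.ks.statistic == pytest.approx(ref.statistic)

    def test_empty_group_rejected(self):
        fits = self._fits([0.1, 0.2])
        nt = pd.Series(["U", "U"], index=fits.index)
        with pytest.raises(ValueError):
            compare_coefficients_by_5p_nt(fits, nt)


class TestClusterAnova:
    def _reps(self, gene_values):
        """gene_values: gene -> list of per-replicate 3-window profiles."""
        labels = ["h00-02", "h02-04", "h04-06"]
        reps = {}
        n_rep = len(next(iter(gene_values.values())))
        for r in range(n_rep):
            rows = {g: v[r] for g, v in gene_values.items()}
            reps[f"rep{r+1}"] = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
        return reps

    def test_identical_members_f_zero_p_one(self):
        prof = [[0, 1, 2], [0, 1, 2], [0, 1, 2]]
        reps = self._reps({"g1": prof, "g2": prof})
        res = cluster_change_anova(reps, {"g1": "c", "g2": "c"})
        assert (res["F"] == 0).all() and (res["p"] == 1).all()

    def test_matches_textbook_anova_oracle(self):
        reps = self._reps(
            {
                "g1": [[0, 1.0, 0], [0, 1.2, 0], [0, 0.8, 0]],
                "g2": [[0, 3.0, 0], [0, 3.3, 0], [0, 2.7, 0]],
            }
        )
        res = cluster_change_anova(reps, {"g1": "c", "g2": "c"})
        row = res[res["window_pair"] == "h00-02->h02-04"].iloc[0]
        a = np.array([1.0, 1.2, 0.8])
        b = np.array([3.0, 3.3, 2.7])
        grand = np.concatenate([a, b]).mean()
        ss_between = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oracle = (ss_between / 1) / (ss_within / 4)
        assert row["F"] == pytest.approx(f_oracle)
        assert row["p"] == pytest.approx(stats.f.sf(f_oracle, 1, 4))

    def test_bh_adjustment_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_and_not_below_raw(self):
        rng = np.random.default_rng(8)
        from statsmodels.stats.multitest import multipletests

        p = np.sort(rng.random(20))
        adj = multipletests(p, method="fdr_bh")[1]
        assert (adj >= p - 1e-15).all()
        assert (np.diff(adj) >= -1e-15).all()

    def test_single_member_cluster_skipped(self):
        prof = [[0, 1, 2], [0, 1, 2]]
        reps = self._reps({"g1": prof})
        res = cluster_change_anova(reps, {"g1": "solo"})
        assert res.empty

    def test_single_replicate_rejected(self):
        labels = ["h00-02", "h02-04"]
        reps = {"rep1": pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=labels)}
        with pytest.raises(ValueError):
            cluster_change_anova(reps, {"g1": "c"})
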