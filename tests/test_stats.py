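"""Statistical battery: effort modulation, outlier screen, correlations,
multiple-testing, dependent correlations, ANOVAs and the power calculation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rebl import stats, task
from rebl.stats import (
    bh_adjust,
    block_order_anova,
    correlation_power,
    effort_modulation,
    filter_outliers,
    one_sample_t_one_tailed,
    pearson_filon_z,
    power_min_n,
    rating_anova,
    spearman_partial,
)
from rebl.task import ADVANTAGEOUS, EFFORT, REWARD, SessionData, TaskConfig, TrialRecord


def build_session(speed_high=4.0, speed_low=3.5, n_low=6, trials_per_block=25):
    """Session where the first n_low reward-block trials are low-reward."""
    cfg = TaskConfig(trials_per_block=trials_per_block)
    trials = []
    for i in range(trials_per_block):
        low = i < n_low
        trials.append(
            TrialRecord(REWARD, i, ADVANTAGEOUS, 0 if low else 1,
                        "low" if low else "high", "high", 60,
                        press_speed=speed_low if low else speed_high)
        )
    for i in range(trials_per_block):
        high_eff = i % 2 == 0
        trials.append(
            TrialRecord(EFFORT, i, ADVANTAGEOUS, 0 if high_eff else 1,
                        "high", "high" if high_eff else "low",
                        60 if high_eff else 35, press_speed=speed_high)
        )
    return SessionData("p0", cfg, trials)


class TestEffortModulation:
    def test_constant_speeds_give_zero(self):
        em = effort_modulation(build_session(4.0, 4.0))
        assert em.diff == pytest.approx(0.0)

    def test_constructed_means(self):
        em = effort_modulation(build_session(4.0, 3.5))
        assert em.speed_high == pytest.approx(4.0)
        assert em.speed_low == pytest.approx(3.5)
        assert em.diff == pytest.approx(0.5)

    def test_effort_block_high_effort_trials_count_as_high_reward(self):
        em = effort_modulation(build_session(4.0, 3.5, n_low=6))
        # 19 reward-block high-reward + 13 effort-block high-effort trials
        assert em.n_high == 19 + 13

    def test_no_low_reward_trials_flagged(self):
        em = effort_modulation(build_session(n_low=0))
        assert em.diff is None and em.outlier_flag

    def test_missing_speeds_rejected(self, agent_session):
        with pytest.raises(ValueError, match="press speeds"):
            effort_modulation(agent_session)


class TestFilterOutliers:
    def test_hand_example(self):
        """(0,0,0,0,0,100): mean 16.67, sample SD 40.82; |100-16.67| >= 2 SD."""
        retained, removed = filter_outliers([0, 0, 0, 0, 0, 100], k=2)
        assert list(removed) == [5]
        assert list(retained) == [0, 0, 0, 0, 0]

    def test_identical_values_keep_everything(self):
        retained, removed = filter_outliers([7.0] * 10, k=2)
        assert removed.size == 0 and retained.size == 10

    def test_normal_tail_mass(self):
        """About 4.6% of a standard normal sample lies beyond 2 SD."""
        x = np.random.default_rng(8).standard_normal(10_000)
        _, removed = filter_outliers(x, k=2)
        assert 0.04 < removed.size / x.size < 0.052

    def test_single_pass_not_iterated(self):
        """The screen uses the full-sample mean/SD once; a value that would
        only become an outlier after removal is retained."""
        x = np.array([0, 0, 0, 0, 0, 50, 100.0])
        retained, removed = filter_outliers(x, k=2)
        assert 50.0 in retained

    def test_input_guards(self):
        with pytest.raises(ValueError):
            filter_outliers([1.0, 2.0], k=2)
        with pytest.raises(ValueError):
            filter_outliers([1.0, 2.0, 3.0], k=0)


class TestOneSampleT:
    def test_null_centre(self):
        t, df, p = one_sample_t_one_tailed([-1.0, 1.0, -2.0, 2.0], mu0=0.0)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_hand_computation(self):
        t, df, p = one_sample_t_one_tailed([1, 1, 1, 1, 2], mu0=0.0)
        assert t == pytest.approx(6.0)
        assert df == 4

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t_one_tailed([1.0, 1.0, 1.0])

    def test_type_one_error_calibration(self):
        """Under the null the one-tailed test rejects at ~alpha (10,000 reps, n=145)."""
        rng = np.random.default_rng(99)
        reps, n, alpha = 10_000, 145, 0.05
        rejections = sum(
            one_sample_t_one_tailed(rng.standard_normal(n))[2] < alpha
            for _ in range(reps)
        )
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3 * se


class TestSpearmanPartial:
    def test_monotone_invariance(self):
        x = np.linspace(1, 10, 40)
        res = spearman_partial(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_matches_plain_spearman_without_covariates(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        res = spearman_partial(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_agrees_with_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(4)
        z = rng.standard_normal(80)
        x = z + rng.standard_normal(80)
        y = z + rng.standard_normal(80)
        res = spearman_partial(x, y, covariates=[z])
        ref = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y",
            covar="z", method="spearman",
        )
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref[p_col].iloc[0]), rel=1e-6)

    def test_conditional_independence_partials_out(self):
        """x and y driven only by z: partial rho ~ 0 on average."""
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(300):
            z = rng.standard_normal(100)
            x = z + rng.standard_normal(100)
            y = z + rng.standard_normal(100)
            vals.append(spearman_partial(x, y, covariates=[z]).rho)
        assert abs(np.mean(vals)) < 0.03
        assert sps.spearmanr(x, y).statistic > 0.2  # marginally correlated

    def test_confounded_null_mildly_anticonservative(self):
        """Under conditional independence with a strong shared driver the
        rank-based partial test inflates type-I error slightly (a known
        property of Pearson-on-ranks partialling); the inflation stays
        bounded."""
        rng = np.random.default_rng(20)
        n, reps, alpha = 155, 2000, 0.05
        rej = 0
        for _ in range(reps):
            z = rng.standard_normal(n)
            x = z + rng.standard_normal(n)
            y = z + rng.standard_normal(n)
            rej += stats.spearman_partial(x, y, covariates=[z]).p < alpha
        assert 0.04 < rej / reps < 0.09

    def test_null_calibration_under_permutation(self):
        """Permuted y: rejection rate ~ alpha (10,000 reps)."""
        rng = np.random.default_rng(6)
        n, reps, alpha = 60, 10_000, 0.05
        x = rng.standard_normal(n)
        rej = 0
        for _ in range(reps):
            y = rng.permutation(n).astype(float)
            rej += spearman_partial(x, y).p < alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rej / reps - alpha) < 3 * se

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_partial([1.0] * 10, list(range(10)))


def brute_force_bh(p, q):
    """Step-up definition evaluated literally."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBhAdjust:
    def test_single_test_unchanged(self):
        p_adj, reject = bh_adjust([0.03], q=0.05)
        assert p_adj == pytest.approx([0.03])
        assert reject.tolist() == [True]

    def test_uniform_small_ps_all_rejected(self):
        _, reject = bh_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        p_adj, reject = bh_adjust([1.0] * 5, q=0.05)
        assert not reject.any()

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = rng.integers(1, 9)
            p = rng.uniform(0, 1, m)
            _, reject = bh_adjust(p, q=0.05)
            assert np.array_equal(reject, brute_force_bh(p, 0.05))

    def test_adjusted_monotone_in_raw_order(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        p_adj, _ = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPearsonFilon:
    def test_equal_correlations_give_zero(self):
        res = pearson_filon_z(0.4, 0.4, 0.3, 155)
        assert res.z == 0.0 and res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = pearson_filon_z(0.5, 0.2, 0.3, 100)
        b = pearson_filon_z(0.2, 0.5, 0.3, 100)
        assert a.z == pytest.approx(-b.z)

    def test_monotone_in_correlation_gap(self):
        zs = [abs(pearson_filon_z(0.1 + d, 0.1, 0.2, 155).z) for d in np.linspace(0.05, 0.5, 8)]
        assert np.all(np.diff(zs) > 0)

    def test_input_guards(self):
        with pytest.raises(ValueError):
            pearson_filon_z(1.2, 0.1, 0.1, 100)
        with pytest.raises(ValueError):
            pearson_filon_z(0.1, 0.1, 0.1, 3)
        with pytest.raises(ValueError, match="positive semidefinite"):
            pearson_filon_z(0.9, -0.9, 0.9, 100)

    def test_null_calibration(self):
        """True rho_jk = rho_jh: rejection rate near alpha (10,000 reps, n=155)."""
        rng = np.random.default_rng(17)
        n, reps, alpha = 155, 10_000, 0.05
        C = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.2], [0.3, 0.2, 1.0]])
        L = np.linalg.cholesky(C)
        rej = 0
        for _ in range(reps):
            X = rng.standard_normal((n, 3)) @ L.T
            R = np.corrcoef(X, rowvar=False)
            rej += pearson_filon_z(R[0, 1], R[0, 2], R[1, 2], n).p < alpha
        assert 0.03 < rej / reps < 0.07


def make_rating_table(n, effect=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n):
        for rt in ("liking", "wanting", "effort_willingness"):
            for time in ("pre", "post"):
                rows.append(
                    {
                        "participant_id": f"p{i}",
                        "rating_type": rt,
                        "time": time,
                        "diff": rng.standard_normal()
                        + (effect if rt == "liking" else 0.0),
                    }
                )
    return pd.DataFrame(rows)


class TestRatingAnova:
    def test_error_df_at_study_size(self):
        table = rating_anova(make_rating_table(155))
        assert set(table["df2"]) == {924.0}  # 930 observations - 6 cells
        assert dict(zip(table["effect"], table["df1"])) == {
            "rating_type": 2.0, "time": 1.0, "rating_type:time": 2.0,
        }

    def test_null_calibration(self):
        rng = np.random.default_rng(23)
        alpha, reps = 0.05, 300
        rej = sum(
            (rating_anova(make_rating_table(20, rng=rng))["p"] < alpha).any()
            for _ in range(reps)
        ) / reps
        # three tests per table: familywise null rate ~ 1 - 0.95^3 = 0.143
        se = np.sqrt(0.143 * 0.857 / reps)
        assert abs(rej - 0.143) < 3.5 * se

    def test_detects_planted_type_effect(self):
        table = rating_anova(make_rating_table(155, effect=1.0))
        assert table.set_index("effect").loc["rating_type", "p"] < 0.001

    def test_constant_dv_rejected(self):
        df = make_rating_table(10)
        df["diff"] = 1.0
        with pytest.raises(ValueError):
            rating_anova(df)

    def test_missing_cells_rejected(self):
        df = make_rating_table(10).iloc[1:]
        with pytest.raises(ValueError):
            rating_anova(df)

    def test_within_subject_variant_runs(self):
        table = rating_anova(make_rating_table(12), within_subject=True)
        assert {"rating_type", "time"} <= set(
            e.replace(" * ", ":") for e in table["effect"]
        )


def make_accuracy_table(n, block_effect=0.0, sd=0.05, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n):
        order = "reward_first" if i % 2 == 0 else "effort_first"
        base = 0.7 + sd * rng.standard_normal()
        rows.append({"participant_id": f"p{i}", "block": "reward",
                     "block_order": order, "accuracy": base + block_effect})
        rows.append({"participant_id": f"p{i}", "block": "effort",
                     "block_order": order, "accuracy": base})
    return pd.DataFrame(rows)


class TestBlockOrderAnova:
    def test_within_effect_df_at_study_size(self):
        table = block_order_anova(make_accuracy_table(155))
        row = table.set_index("effect").loc["block"]
        assert (row["df1"], row["df2"]) == (1, 153)

    def test_identical_blocks_give_zero_f(self):
        table = block_order_anova(make_accuracy_table(40, block_effect=0.0, sd=0.05))
        # accuracy identical across blocks per participant by construction
        assert table.set_index("effect").loc["block", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_planted_block_difference_detected(self):
        """A 0.1 block effect against 0.05 between-subject SD is essentially
        always significant at N=155."""
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(50):
            df = make_accuracy_table(155, block_effect=0.1, sd=0.05, rng=rng)
            df["accuracy"] += 0.05 * rng.standard_normal(len(df))  # trial noise
            table = block_order_anova(df)
            hits += table.set_index("effect").loc["block", "p"] < 0.05
        assert hits >= 48

    def test_single_order_rejected(self):
        df = make_accuracy_table(20)
        df["block_order"] = "reward_first"
        with pytest.raises(ValueError):
            block_order_anova(df)


class TestPower:
    def test_study_sample_size(self):
        assert power_min_n(0.3, 0.80, 0.05) == 84

    def test_fisher_approximation_differs(self):
        assert power_min_n(0.3, 0.80, 0.05, method="fisher") == 85

    def test_monotone_in_effect_size(self):
        assert power_min_n(0.5, 0.80, 0.05) < power_min_n(0.3, 0.80, 0.05)

    def test_minimality_contract(self):
        n = power_min_n(0.3, 0.80, 0.05)
        assert correlation_power(0.3, n) >= 0.80
        assert correlation_power(0.3, n - 1) < 0.80

    def test_density_normalises(self):
        from scipy import integrate

        pdf = lambda r: np.exp(stats._log_pdf_r(r, 0.4, 60))
        total, _ = integrate.quad(pdf, -1, 1, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            power_min_n(0.0)
        with pytest.raises(ValueError):
            power_min_n(0.3, power=1.2)
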