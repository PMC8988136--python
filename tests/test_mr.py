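"""Estimator battery: oracle equivalences, symmetries and calibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import mrlab
from mrlab.mr import (
    egger,
    ivw,
    leave_one_out,
    mr_power_binary,
    presso,
    raps,
    steiger,
    wald_ratio,
    weighted_median,
)
from mrlab.simulate import simulate_mr_instruments
from mrlab.sumstats import HarmonizedSet


def hset(beta_exp, se_exp, beta_out, se_out, n_exp=1e5, n_out=1e5):
    J = len(beta_exp)
    t = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(J)],
            "beta_exp": beta_exp, "se_exp": se_exp,
            "f_exp": 0.3, "f_out": 0.3,
            "beta_out": beta_out, "se_out": se_out,
            "n_exp": n_exp, "n_out": n_out,
            "z_exp": np.asarray(beta_exp) / np.asarray(se_exp),
            "z_out": np.asarray(beta_out) / np.asarray(se_out),
            "flipped": False,
        }
    )
    return HarmonizedSet(table=t, exclusions=pd.DataFrame(columns=["variant_id", "reason"]))


def random_hset(rng, J=8):
    bx = rng.uniform(0.05, 0.3, J) * rng.choice([-1, 1], J)
    sx = rng.uniform(0.005, 0.02, J)
    by = rng.normal(0.5 * bx, 0.05)
    sy = rng.uniform(0.01, 0.05, J)
    return hset(bx, sx, by, sy)


class TestIVW:
    def test_constant_ratios_recovered_exactly(self):
        h = hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.10, 0.15], [0.01] * 3)
        est = ivw(h)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-12)
        assert est.q_stat == pytest.approx(0.0, abs=1e-10)

    def test_equals_wls_through_origin_oracle(self, rng):
        for _ in range(20):
            h = random_hset(rng)
            est = ivw(h)
            t = h.table
            fit = sm.WLS(
                t["beta_out"], t["beta_exp"], weights=1.0 / t["se_out"] ** 2
            ).fit()
            assert est.beta_hat == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_antisymmetric_ratios_cancel(self):
        h = hset([0.1, 0.1], [0.01] * 2, [0.1, -0.1], [0.01] * 2)
        assert ivw(h).beta_hat == pytest.approx(0.0, abs=1e-12)

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            h = random_hset(rng)
            assert ivw(h).se >= ivw(h, random_effects=False).se - 1e-15

    def test_or_matches_exp_beta(self, rng):
        est = ivw(random_hset(rng))
        assert est.or_hat == pytest.approx(np.exp(est.beta_hat), rel=1e-12)
        assert est.ci_low <= est.beta_hat <= est.ci_high

    def test_single_instrument_refused(self):
        h = hset([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(ValueError):
            ivw(h)
        assert wald_ratio(h).beta_hat == pytest.approx(0.5)


class TestWeightedMedian:
    def test_identical_ratios(self):
        h = hset([0.1] * 3, [0.01] * 3, [0.07] * 3, [0.01] * 3)
        assert weighted_median(h).beta_hat == pytest.approx(0.7, abs=1e-9)

    def test_equal_weight_median(self):
        h = hset([0.1] * 3, [0.01] * 3, [0.01, 0.02, 0.09], [0.01] * 3)
        assert weighted_median(h).beta_hat == pytest.approx(0.2, abs=1e-9)

    def test_matches_grid_inversion_oracle(self, rng):
        for _ in range(10):
            h = random_hset(rng)
            t = h.table
            theta = (t["beta_out"] / t["beta_exp"]).to_numpy()
            w = (np.abs(t["beta_exp"]) / t["se_out"]).to_numpy() ** 2
            order = np.argsort(theta)
            th, ww = theta[order], w[order]
            s = (np.cumsum(ww) - ww / 2) / ww.sum()
            # invert the piecewise-linear CDF on a dense grid
            grid = np.linspace(th[0], th[-1], 200001)
            cdf = np.interp(grid, th, s)
            oracle = grid[np.argmin(np.abs(cdf - 0.5))]
            assert weighted_median(h).beta_hat == pytest.approx(oracle, abs=1e-4)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_estimate_within_ratio_range(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hset(rng, J=6)
        theta = h.table["beta_out"] / h.table["beta_exp"]
        est = weighted_median(h, boot_reps=100)
        assert theta.min() - 1e-12 <= est.beta_hat <= theta.max() + 1e-12

    def test_bootstrap_se_reproducible(self, rng):
        h = random_hset(rng)
        assert weighted_median(h, seed=5).se == weighted_median(h, seed=5).se


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = hset(bx, [0.01] * 4, 0.5 * bx, [0.01] * 4)
        est = egger(h)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_relation_recovers_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = hset(bx, [0.01] * 4, 0.02 + 0.5 * bx, [0.01] * 4)
        est = egger(h)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-10)

    def test_orientation_invariance_under_allele_recoding(self, rng):
        h = random_hset(rng)
        est1 = egger(h)
        t = h.table.copy()
        t.loc[2, ["beta_exp", "beta_out"]] *= -1  # recode one variant's alleles
        est2 = egger(HarmonizedSet(table=t, exclusions=h.exclusions))
        assert est2.beta_hat == pytest.approx(est1.beta_hat, rel=1e-10)
        assert est2.egger_intercept == pytest.approx(est1.egger_intercept, rel=1e-10)

    def test_degenerate_design_rejected(self):
        h = hset([0.2] * 4, [0.01] * 4, [0.1] * 4, [0.01] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            egger(h)

    def test_intercept_test_calibrated_under_null(self):
        # no directional pleiotropy: intercept rejection rate ~ alpha
        reject = 0
        n_sims = 1000
        for seed in range(n_sims):
            h = simulate_mr_instruments(0.6, n_instruments=30, seed=seed)
            if egger(h).egger_intercept_p < 0.05:
                reject += 1
        rate = reject / n_sims
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < ci + 0.01  # max(1,.) SE truncation is conservative


class TestRAPS:
    def test_reduces_to_ivw_when_exposure_error_vanishes(self, rng):
        for _ in range(5):
            h = random_hset(rng)
            h.table["se_exp"] = 1e-12
            assert raps(h, loss="plain").beta_hat == pytest.approx(
                ivw(h).beta_hat, abs=1e-6
            )

    def test_exact_proportionality_recovers_ratio(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = hset(bx, [0.01] * 3, 0.7 * bx, [0.01] * 3)
        assert raps(h).beta_hat == pytest.approx(0.7, abs=1e-6)

    def test_parameter_recovery_at_design_effect(self):
        # 50 strong instruments, true effect 0.6: mean estimate unbiased
        ests = [
            raps(simulate_mr_instruments(0.6, n_instruments=50, seed=s),
                 overdispersion=True).beta_hat
            for s in range(20)
        ]
        assert abs(np.mean(ests) - 0.6) < 0.05

    def test_huber_loss_close_to_plain_on_clean_data(self, rng):
        h = random_hset(rng)
        assert raps(h, loss="huber").beta_hat == pytest.approx(
            raps(h, loss="plain").beta_hat, abs=0.05
        )

    def test_overdispersion_nonnegative(self, rng):
        h = random_hset(rng)
        est = raps(h, overdispersion=True)
        assert est.tau2 >= 0.0


class TestPRESSO:
    def test_clean_data_corrected_equals_raw(self):
        h = simulate_mr_instruments(0.6, n_instruments=10, seed=42)
        est = presso(h, n_sim=1000, seed=1)
        assert est.outliers == []
        assert est.beta_hat == pytest.approx(est.raw_beta, abs=1e-12)
        assert 0.0 < est.global_p <= 1.0

    def test_planted_outlier_detected(self):
        flagged = 0
        for seed in range(20):
            h = simulate_mr_instruments(
                0.6, n_instruments=20, seed=seed,
                outlier_index=3, outlier_offset_se=10.0,
            )
            est = presso(h, n_sim=2000, seed=seed + 1)
            flagged += "iv0004" in est.outliers
        assert flagged >= 19  # >= 95% detection

    def test_reproducible_under_seed(self):
        h = simulate_mr_instruments(0.6, n_instruments=10, seed=0)
        a = presso(h, n_sim=500, seed=9)
        b = presso(h, n_sim=500, seed=9)
        assert a.global_p == b.global_p and a.outliers == b.outliers

    def test_too_few_instruments_rejected(self):
        h = simulate_mr_instruments(0.6, n_instruments=3, seed=0)
        with pytest.raises(ValueError):
            presso(h, n_sim=500)


class TestSteiger:
    def test_strong_exposure_null_outcome(self):
        h = hset([0.1] * 5, [0.005] * 5, [0.001] * 5, [0.02] * 5)
        direction, p = steiger(h)
        assert direction is True and p < 1e-10

    def test_tie_breaks_false(self):
        h = hset([0.1] * 3, [0.01] * 3, [0.1] * 3, [0.01] * 3)
        direction, p = steiger(h)
        assert direction is False
        assert p == pytest.approx(1.0)

    def test_antisymmetry_under_swap(self):
        h = hset([0.1] * 5, [0.005] * 5, [0.01] * 5, [0.02] * 5)
        d1, p1 = steiger(h)
        t = h.table.rename(
            columns={
                "beta_exp": "beta_out", "beta_out": "beta_exp",
                "se_exp": "se_out", "se_out": "se_exp",
                "f_exp": "f_out", "f_out": "f_exp",
                "n_exp": "n_out", "n_out": "n_exp",
                "z_exp": "z_out", "z_out": "z_exp",
            }
        )
        d2, p2 = steiger(HarmonizedSet(table=t, exclusions=h.exclusions))
        assert d1 != d2
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestLeaveOneOut:
    def test_homogeneous_rows_equal_full_estimate(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = hset(bx, [0.01] * 4, 0.5 * bx, [0.01] * 4)
        table = leave_one_out(h)
        assert len(table) == 4
        np.testing.assert_allclose(table["beta_hat"], 0.5, atol=1e-10)
        assert not table["ci_excludes_full"].any()

    def test_excluding_outlier_moves_toward_truth(self):
        h = simulate_mr_instruments(
            0.6, n_instruments=20, seed=5, outlier_index=0, outlier_offset_se=15.0
        )
        table = leave_one_out(h)
        full = ivw(h).beta_hat
        without = table.loc[table["variant_id"] == "iv0001", "beta_hat"].iloc[0]
        assert abs(without - 0.6) < abs(full - 0.6)


class TestPower:
    def test_null_or_gives_alpha(self):
        assert mr_power_binary(1e5, 0.2, 0.05, 1.0, alpha=0.05) == pytest.approx(0.05)

    def test_study_design_point_exceeds_99pct(self):
        power = mr_power_binary(159208, 26676 / 159208, 0.041, 1.86, alpha=0.05)
        assert power >= 0.99

    def test_monotone_in_n_and_effect(self):
        base = mr_power_binary(5000, 0.2, 0.02, 1.3)
        assert mr_power_binary(10000, 0.2, 0.02, 1.3) > base
        assert mr_power_binary(5000, 0.2, 0.02, 1.6) > base
        assert mr_power_binary(5000, 0.2, 0.02, 1 / 1.3) == pytest.approx(base)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mr_power_binary(1000, 0.0, 0.05, 1.5)
        with pytest.raises(ValueError):
            mr_power_binary(1000, 0.2, 1.5, 1.5)


class TestBatteryCoherence:
    def test_estimators_agree_at_design_effect(self):
        # all five estimators should land near each other on clean data
        h = simulate_mr_instruments(0.6, n_instruments=50, seed=4)
        ests = [
            ivw(h), weighted_median(h), egger(h),
            raps(h, overdispersion=True), presso(h, n_sim=500, seed=4),
        ]
        for a in ests:
            for b in ests:
                joint_se = np.hypot(a.se, b.se)
                assert abs(a.beta_hat - b.beta_hat) < 3 * joint_se

    def test_battery_table_shape_and_bonferroni_gate(self):
        h = simulate_mr_instruments(0.6, n_instruments=30, seed=8)
        table = mrlab.mr_battery(h, seed=1)
        assert set(table["method"]) == {
            "IVW", "Weighted median", "MR-Egger", "MR-RAPS",
            "MR-PRESSO (outlier-corrected)",
        }
        ivw_row = table.loc[table["method"] == "IVW"].iloc[0]
        assert ivw_row["significant"] == (ivw_row["pvalue"] < 0.05 / 6)

    def test_single_instrument_falls_back_to_wald(self):
        h = simulate_mr_instruments(0.6, n_instruments=1, seed=3)
        table = mrlab.mr_battery(h)
        assert list(table["method"]) == ["Wald ratio"]
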