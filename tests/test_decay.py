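"""Decay fitting: exact recovery, half-life transforms, nested-model F test,
ROUT outlier elimination, CI coverage, and plateau-constraint logic."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from argokit.decay import (
    INF_RATE_TOL,
    extra_ss_f_test,
    fit_one_phase,
    fit_two_phase,
    profile_ci_rate,
    rout_outliers,
)

LN2 = math.log(2.0)


def one_phase_curve(t, y0, k, b):
    return b + (y0 - b) * np.exp(-k * t)


def two_phase_curve(t, y0, f, kf, ks, b):
    return b + (y0 - b) * (f * np.exp(-kf * t) + (1 - f) * np.exp(-ks * t))


class TestOnePhase:
    def test_noiseless_exact_recovery_with_fixed_plateau(self):
        t = np.arange(0.0, 6.0)
        y = one_phase_curve(t, 1.0, 0.5, 0.1)
        fit = fit_one_phase(t, y, plateau=0.1)
        assert fit.params["k"] == pytest.approx(0.5, abs=1e-8)
        assert fit.params["y0"] == pytest.approx(1.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.plateau_constrained and fit.df == t.size - 2

    def test_noiseless_exact_recovery_with_free_plateau(self):
        t = np.linspace(0.0, 8.0, 12)
        y = one_phase_curve(t, 1.0, 0.7, 0.08)
        fit = fit_one_phase(t, y, plateau=None)
        assert fit.params["plateau"] == pytest.approx(0.08, abs=1e-6)
        assert not fit.plateau_constrained and fit.df == t.size - 3

    def test_fast_pool_rate_gives_point_nine_day_half_life(self):
        """k = 0.7535/d transforms to a half-life of 0.92 d ('about 0.9')."""
        t = np.linspace(0.0, 5.0, 10)
        y = one_phase_curve(t, 1.0, 0.7535, 0.0)
        fit = fit_one_phase(t, y, plateau=0.0)
        h = fit.half_lives["half_life"].value
        assert h == pytest.approx(LN2 / 0.7535, rel=1e-6)
        assert round(h, 1) == 0.9

    def test_half_life_times_rate_is_ln2(self):
        rng = np.random.default_rng(0)
        t = np.repeat(np.arange(6.0), 5)
        y = one_phase_curve(t, 1.0, 0.4, 0.1) + rng.normal(0, 0.03, t.size)
        fit = fit_one_phase(t, y, plateau=0.1)
        assert fit.half_lives["half_life"].value * fit.params["k"] == pytest.approx(LN2)

    def test_flat_data_reports_infinite_half_life(self):
        t = np.arange(8.0)
        y = np.ones_like(t)
        fit = fit_one_phase(t, y, plateau=0.1)
        assert fit.params["k"] < INF_RATE_TOL
        assert fit.half_lives["half_life"].is_infinite
        assert math.isinf(fit.half_lives["half_life"].ci95[1])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_one_phase([0, 1], [1, 0.5], plateau=0.0)
        with pytest.raises(ValueError):
            fit_one_phase([0, 1, 2], [1.0, 0.7, 0.5], plateau=None)

    def test_ci_covers_truth_at_nominal_rate(self):
        """95% Wald t-intervals on k cover the generating rate in 93-97%
        of simulated datasets at moderate noise."""
        rng = np.random.default_rng(7)
        k_true, b = 0.3, 0.07
        t = np.repeat(np.arange(6.0), 15)
        covered = 0
        n_sim = 600
        for _ in range(n_sim):
            y = one_phase_curve(t, 1.0, k_true, b) * rng.lognormal(
                -0.5 * 0.15**2, 0.15, t.size
            )
            fit = fit_one_phase(t, y, plateau=b)
            lo, hi = fit.ci95["k"]
            covered += lo <= k_true <= hi
        assert 0.93 <= covered / n_sim <= 0.97

    def test_parameters_converge_to_truth_as_noise_shrinks(self):
        rng = np.random.default_rng(1)
        t = np.repeat(np.arange(6.0), 10)
        errs = []
        for sd in (0.2, 0.05, 0.01):
            y = one_phase_curve(t, 1.0, 0.5, 0.1) + rng.normal(0, sd, t.size)
            fit = fit_one_phase(t, y, plateau=0.1)
            errs.append(abs(fit.params["k"] - 0.5))
        assert errs[0] > errs[-1]
        assert errs[-1] < 0.01

    def test_profile_ci_brackets_wald_estimate(self):
        rng = np.random.default_rng(3)
        t = np.repeat(np.arange(6.0), 8)
        y = one_phase_curve(t, 1.0, 0.4, 0.1) + rng.normal(0, 0.05, t.size)
        fit = fit_one_phase(t, y, plateau=0.1)
        lo, hi = profile_ci_rate(fit)
        assert lo < fit.params["k"] < hi


class TestTwoPhase:
    def test_noiseless_exact_recovery(self):
        """Self-consistency at the biphasic best-fit values (39% fast pool
        at 0.7535/d, inert remainder)."""
        t = np.linspace(0.0, 5.0, 30)
        y = two_phase_curve(t, 1.0, 0.39, 0.7535, 0.0, 0.05)
        fit = fit_two_phase(t, y, plateau=0.05)
        assert fit.params["f_fast"] == pytest.approx(0.39, abs=1e-6)
        assert fit.params["k_fast"] == pytest.approx(0.7535, abs=1e-6)
        assert fit.params["k_slow"] == pytest.approx(0.0, abs=1e-6)
        assert fit.half_lives["slow"].is_infinite  # "essentially infinite"

    def test_single_pool_data_collapses_to_one_phase(self):
        """f_fast -> 1 on one-phase data: SS identical to the one-phase fit."""
        t = np.linspace(0.0, 6.0, 20)
        y = one_phase_curve(t, 1.0, 0.5, 0.1)
        one = fit_one_phase(t, y, plateau=0.1)
        two = fit_two_phase(t, y, plateau=0.1)
        assert two.ss_residual == pytest.approx(one.ss_residual, abs=1e-10)
        assert two.degenerate in ("rates_collapsed", "boundary_fraction")

    def test_rate_ordering_enforced(self):
        t = np.linspace(0.0, 5.0, 25)
        y = two_phase_curve(t, 1.0, 0.6, 2.0, 0.1, 0.0)
        fit = fit_two_phase(t, y, plateau=0.0)
        assert fit.params["k_fast"] >= fit.params["k_slow"]
        assert fit.params["f_fast"] == pytest.approx(0.6, abs=1e-4)


class TestExtraSSFTest:
    def test_identical_ss_gives_f_zero_p_one(self):
        t = np.linspace(0.0, 6.0, 20)
        y = one_phase_curve(t, 1.0, 0.5, 0.1)
        one = fit_one_phase(t, y, plateau=0.1)
        two = fit_two_phase(t, y, plateau=0.1)
        F, p = extra_ss_f_test(one, two)
        assert F == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_closed_form_arithmetic_example(self):
        """SS 10 vs 5 with df 20 vs 18: F = (5/2)/(5/18) = 9.0."""

        class Stub:
            def __init__(self, model, ss, df, n):
                self.model, self.ss_residual, self.df, self.n_points = model, ss, df, n

        F, p = extra_ss_f_test(Stub("one_phase", 10.0, 20, 22), Stub("two_phase", 5.0, 18, 22))
        assert F == pytest.approx(9.0)
        assert p == pytest.approx(float(sps.f.sf(9.0, 2, 18)), rel=1e-12)
        assert p == pytest.approx(0.00187, abs=2e-4)

    def test_non_nested_models_rejected(self):
        t = np.linspace(0.0, 6.0, 20)
        y = one_phase_curve(t, 1.0, 0.5, 0.1)
        one = fit_one_phase(t, y, plateau=0.1)
        with pytest.raises(ValueError, match="nested"):
            extra_ss_f_test(one, one)

    def test_type_i_error_controlled_at_alpha(self):
        """One-phase truth, 400 replicates: two-phase favored at most ~5% of
        the time at alpha = 0.05. The observed rate runs below nominal
        (~2%): under the null the extra two-phase parameters are not
        identifiable (any f with equal rates gives the same curve), a
        regularity violation that makes the extra-SS F test conservative."""
        rng = np.random.default_rng(11)
        t = np.repeat(np.arange(6.0), 15)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            y = one_phase_curve(t, 1.0, 0.3, 0.07) + rng.normal(0, 0.1, t.size)
            one = fit_one_phase(t, y, plateau=0.07)
            two = fit_two_phase(t, y, plateau=0.07)
            _, p = extra_ss_f_test(one, two)
            rejections += p < 0.05
        rate = rejections / n_sim
        assert rate <= 0.08
        assert rate >= 0.001  # sanity: the test is not degenerate


class TestRout:
    def test_planted_gross_outlier_is_flagged(self):
        rng = np.random.default_rng(5)
        t = np.repeat(np.arange(6.0), 10)
        y = one_phase_curve(t, 1.0, 0.4, 0.1) + rng.normal(0, 0.03, t.size)
        y[17] += 10 * 0.03 * 10  # gross outlier, ~100x residual SD
        mask, fit = rout_outliers(t, y, "one_phase", Q=0.05, plateau=0.1)
        assert not mask[17]
        assert fit.params["k"] == pytest.approx(0.4, abs=0.05)
        assert fit.q_used == 0.05 and fit.outlier_mask is mask

    def test_false_flag_rate_on_clean_data_is_small(self):
        """Clean Gaussian data at Q = 1%: only a small fraction of datasets
        get any point flagged."""
        rng = np.random.default_rng(9)
        t = np.repeat(np.arange(6.0), 8)
        any_flag = 0
        n_sim = 150
        for _ in range(n_sim):
            y = one_phase_curve(t, 1.0, 0.4, 0.1) + rng.normal(0, 0.05, t.size)
            mask, _ = rout_outliers(t, y, "one_phase", Q=0.01, plateau=0.1)
            any_flag += not mask.all()
        assert any_flag / n_sim <= 0.10

    def test_q_bounds_enforced(self):
        t = np.arange(8.0)
        y = one_phase_curve(t, 1.0, 0.4, 0.1)
        with pytest.raises(ValueError):
            rout_outliers(t, y, "one_phase", Q=0.2, plateau=0.1)
        with pytest.raises(ValueError):
            rout_outliers(t, y, "one_phase", Q=0.0, plateau=0.1)


class TestPlateauConstraintLogic:
    """Free-plateau CI vs measured background: the discriminator between
    exhaustive one-phase turnover and a retained (inert) pool."""

    @staticmethod
    def _simulate_and_fit(curve_fn, args, rng, n_rep=40):
        t = np.repeat(np.arange(7.0), 15)
        hits = []
        for _ in range(n_rep):
            y = curve_fn(t, *args) * rng.lognormal(-0.5 * 0.12**2, 0.12, t.size)
            fit = fit_one_phase(t, y, plateau=None)
            hits.append(fit.ci95["plateau"])
        return np.array(hits)

    def test_one_phase_truth_plateau_ci_overlaps_background(self):
        rng = np.random.default_rng(21)
        b_true = 0.08
        cis = self._simulate_and_fit(one_phase_curve, (1.0, 0.5, b_true), rng)
        frac_overlap = np.mean((cis[:, 0] <= b_true) & (b_true <= cis[:, 1]))
        assert frac_overlap >= 0.8

    def test_two_pool_truth_plateau_sits_above_background(self):
        rng = np.random.default_rng(22)
        b_true = 0.08
        cis = self._simulate_and_fit(
            two_phase_curve, (1.0, 0.39, 0.7535, 0.0, b_true), rng
        )
        frac_above = np.mean(cis[:, 0] > b_true)
        assert frac_above >= 0.8


class TestRatiometricAdvantage:
    def test_gfp_only_fits_are_noisier_than_ratiometric(self):
        """Growth-enabled A0 cohorts: fitting raw GFP means gives lower R^2
        and wider half-life CIs than fitting normalized ratios, because
        animal-to-animal brightness scatter cancels only in the ratio."""
        from argokit.synthetic import (
            CohortDesign,
            KineticsModel,
            SyntheticConfig,
        )
        from argokit.synthetic import simulate_ratio_cohort
        from argokit.turnover import normalize_to_control, summarize_neurons

        cfg = SyntheticConfig(
            kinetics=KineticsModel(k=LN2 / 3.0),
            design=CohortDesign(
                pulse_age=0.0,
                chase_times=tuple(float(x) for x in range(6)),
                n_animals_per_timepoint=15,
                pulse_delay_h=0.0,
            ),
        )
        r2_ratio, r2_gfp, w_ratio, w_gfp = [], [], [], []
        for seed in range(10):
            table = simulate_ratio_cohort(cfg, seed=seed)
            neurons = normalize_to_control(summarize_neurons(table))
            pulsed = table[table.treatment == "pulsed"]
            pn = neurons[neurons.treatment == "pulsed"]
            t = pn["age_days"].to_numpy(dtype=float)
            fit_r = fit_one_phase(t, pn["normalized_ratio"].to_numpy(), plateau=None)
            gfp = pulsed.groupby("animal_id").agg(
                t=("age_days", "first"), g=("mean_gfp", "mean")
            )
            g_norm = gfp["g"] / gfp["g"][gfp["t"] == 0.0].mean()
            fit_g = fit_one_phase(gfp["t"].to_numpy(), g_norm.to_numpy(), plateau=None)
            r2_ratio.append(fit_r.r_squared)
            r2_gfp.append(fit_g.r_squared)
            w_ratio.append(np.diff(fit_r.half_lives["half_life"].ci95)[0])
            w_gfp.append(np.diff(fit_g.half_lives["half_life"].ci95)[0])
        assert np.median(r2_ratio) > np.median(r2_gfp)
        assert np.median(w_gfp) > np.median(w_ratio)

    def test_gfp_decays_slower_than_ratio_under_growth(self):
        """With the pulse during synapse growth, the ratio half-life is
        shorter than the GFP-only half-life (growth dilutes the ratio)."""
        from argokit.synthetic import CohortDesign, KineticsModel, NoiseModel, SyntheticConfig
        from argokit.synthetic import simulate_ratio_cohort
        from argokit.turnover import normalize_to_control, summarize_neurons

        cfg = SyntheticConfig(
            kinetics=KineticsModel(k=LN2 / 3.0),
            design=CohortDesign(
                pulse_age=0.0,
                chase_times=tuple(float(x) for x in range(6)),
                n_animals_per_timepoint=6,
                pulse_delay_h=0.0,
            ),
            noise=NoiseModel.off(),
        )
        table = simulate_ratio_cohort(cfg, seed=0)
        neurons = normalize_to_control(summarize_neurons(table))
        pn = neurons[neurons.treatment == "pulsed"]
        t = pn["age_days"].to_numpy(dtype=float)
        fit_r = fit_one_phase(t, pn["normalized_ratio"].to_numpy(), plateau=None)
        pulsed = table[table.treatment == "pulsed"]
        gfp = pulsed.groupby("animal_id").agg(
            t=("age_days", "first"), g=("mean_gfp", "mean")
        )
        g_norm = gfp["g"] / gfp["g"][gfp["t"] == 0.0].mean()
        fit_g = fit_one_phase(gfp["t"].to_numpy(), g_norm.to_numpy(), plateau=None)
        assert (
            fit_r.half_lives["half_life"].value < fit_g.half_lives["half_life"].value
        )
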