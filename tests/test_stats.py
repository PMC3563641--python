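"""Noise generation, lack-of-fit ANOVA, variance-ratio test, KL histogram."""

import numpy as np
import pytest

import modeldiscrim as md
from modeldiscrim.stats import Dataset, NoiseModel, lack_of_fit_test, variance_ratio_test


def flat_design(n, dt=1.0, x0=None):
    return md.ExperimentalDesign(x0=x0 or {"S": 1.0}, intervals=np.full(n, dt))


class TestGenerateData:
    def test_zero_sigma_reproduces_trajectory(self, decay_model):
        design = flat_design(4)
        traj = md.simulate(decay_model, {"k": 0.5}, design)
        data = md.generate_data(decay_model, {"k": 0.5}, design, NoiseModel(sigma=0.0), 3, seed=1)
        for ds in data:
            np.testing.assert_array_equal(ds.values, traj.values)

    def test_additive_noise_law(self, decay_model):
        # Monte-Carlo: sample SD of additive noise at sigma = 0.1
        design = flat_design(1)
        data = md.generate_data(
            decay_model, {"k": 0.0}, design, NoiseModel("additive", 0.1), 10_000, seed=2
        )
        draws = np.array([ds.values[0, 0] for ds in data])
        assert 0.097 <= draws.std(ddof=1) <= 0.103

    def test_relative_noise_law(self):
        # eta = 10, sigma = 0.05: SD of y = eta (1 + eps) is ~0.5
        const = md.KineticModel(
            name="const10", species=("X",), parameters=(),
            rhs=lambda x, p, u, t: np.zeros(1), observed=("X",),
        )
        design = flat_design(1, x0={"X": 10.0})
        data = md.generate_data(const, {}, design, NoiseModel("relative", 0.05), 10_000, seed=3)
        draws = np.array([ds.values[0, 0] for ds in data])
        assert 0.47 <= draws.std(ddof=1) <= 0.53

    def test_seeded_generation_is_reproducible(self, decay_model):
        design = flat_design(3)
        a = md.generate_data(decay_model, {"k": 0.5}, design, NoiseModel("additive", 0.2), 2, seed=9)
        b = md.generate_data(decay_model, {"k": 0.5}, design, NoiseModel("additive", 0.2), 2, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_clipping_is_counted(self, decay_model):
        design = flat_design(2)
        data = md.generate_data(
            decay_model, {"k": 5.0}, design, NoiseModel("additive", 1.0), 20, seed=4
        )
        assert any(ds.meta["clipped"] > 0 for ds in data)
        assert all(ds.values.min() >= 0 for ds in data)


class TestLackOfFit:
    def test_curve_through_replicate_means_gives_zero_F(self, decay_model):
        design = flat_design(4)
        traj = md.simulate(decay_model, {"k": 0.5}, design)
        # construct replicates whose mean IS the model curve
        delta = 0.01 * np.ones_like(traj.values)
        reps = [
            Dataset(times=traj.times, species=traj.species, values=traj.values + delta, design=design),
            Dataset(times=traj.times, species=traj.species, values=traj.values - delta, design=design),
        ]
        res = lack_of_fit_test(decay_model, {"k": 0.5}, reps, alpha=0.05, n_params=0)
        assert res.f_statistic["S"] == pytest.approx(0.0, abs=1e-20)
        assert not res.any_rejected

    def test_hand_computed_anova_table(self):
        """Tiny worked case: 3 times, 2 replicates, trivial constant model."""
        const = md.KineticModel(
            name="const0", species=("X",), parameters=(),
            rhs=lambda x, p, u, t: np.zeros(1), observed=("X",),
        )
        design = flat_design(3, x0={"X": 1.0})
        y1 = np.array([[1.2, 0.8, 1.1]])
        y2 = np.array([[0.8, 1.2, 0.7]])
        reps = [
            Dataset(times=design.times, species=("X",), values=y1, design=design),
            Dataset(times=design.times, species=("X",), values=y2, design=design),
        ]
        # hand ANOVA: eta = 1; means (1.0, 1.0, 0.9); SS_lof = 2*(0+0+0.01)=0.02
        # SS_pure = (0.2²+0.2²)+(0.2²+0.2²)+(0.2²+0.2²) = 0.24
        # df_lof = 3, df_pure = 3 -> F = (0.02/3)/(0.24/3) = 1/12
        res = lack_of_fit_test(const, {}, reps, alpha=0.05, n_params=0)
        assert res.ss_lof["X"] == pytest.approx(0.02)
        assert res.ss_pure["X"] == pytest.approx(0.24)
        assert res.df_lof == 3 and res.df_pure == 3
        assert res.f_statistic["X"] == pytest.approx(0.02 / 0.24)

    def test_type_one_error_matches_alpha(self, decay_model):
        """Under the null (data generated by the tested curve) the rejection
        rate over 500 simulations stays within 2 Monte-Carlo SEs of alpha."""
        design = flat_design(5)
        traj = md.simulate(decay_model, {"k": 0.3}, design)
        sigma, alpha, n_sim = 0.05, 0.05, 500
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(n_sim):
            reps = [
                Dataset(
                    times=traj.times, species=traj.species,
                    values=traj.values + rng.normal(0, sigma, traj.values.shape),
                    design=design,
                )
                for _ in range(3)
            ]
            res = lack_of_fit_test(decay_model, {"k": 0.3}, reps, alpha=alpha, n_params=0)
            rejections += res.reject["S"]
        rate = rejections / n_sim
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert alpha - 2 * se <= rate <= alpha + 2 * se

    def test_single_replicate_rejected(self, decay_model):
        design = flat_design(3)
        traj = md.simulate(decay_model, {"k": 0.3}, design)
        ds = Dataset(times=traj.times, species=traj.species, values=traj.values, design=design)
        with pytest.raises(ValueError, match="replicates"):
            lack_of_fit_test(decay_model, {"k": 0.3}, [ds])


class TestVarianceRatio:
    def test_identical_residuals_not_rejected(self, rng):
        r = rng.normal(size=30)
        ratio, crit, reject = variance_ratio_test(r, r.copy())
        assert ratio == pytest.approx(1.0)
        assert not reject

    def test_sd_one_vs_two_gives_ratio_four(self, rng):
        a = np.array([-1.0, 1.0, -1.0, 1.0])
        b = 2.0 * a
        ratio, _, _ = variance_ratio_test(a, b)
        assert ratio == pytest.approx(4.0)

    def test_critical_value_matches_published_f_table(self):
        # F table: upper 5% points F(5,5)=5.05, F(10,10)=2.98
        _, crit55, _ = variance_ratio_test(np.ones(5) + np.arange(5) * 0.1,
                                           np.ones(5) - np.arange(5) * 0.1, alpha=0.05)
        assert crit55 == pytest.approx(5.05, abs=0.01)
        _, crit1010, _ = variance_ratio_test(np.arange(10.0), np.arange(10.0) * 2, alpha=0.05)
        assert crit1010 == pytest.approx(2.98, abs=0.01)

    def test_zero_denominator_variance_rejects(self):
        ratio, _, reject = variance_ratio_test([1.0, -1.0, 1.0], [0.5, 0.5, 0.5])
        assert np.isinf(ratio) and reject

    def test_sd_ratio_mode_is_square_root(self, rng):
        a, b = rng.normal(size=40), 2 * rng.normal(size=40)
        var_ratio, _, _ = variance_ratio_test(a, b)
        sd_ratio, _, _ = variance_ratio_test(a, b, use_sd_ratio=True)
        assert sd_ratio == pytest.approx(np.sqrt(var_ratio))


class TestHistogram:
    @staticmethod
    def toy_objective():
        def J(design, pA, pB):
            return (float(pA["t"]) - 0.5) ** 2 + 1.0

        return J

    def test_single_draw_degenerate_box(self):
        J = self.toy_objective()
        design = md.ExperimentalDesign(x0={}, intervals=[1.0])
        box = md.ParameterBox({"t": 0.2}, {"t": 0.2})
        hist = md.kl_histogram(J, design, (box, None), ({"t": 0.2}, {}), n_draws=1, n_bins=10)
        assert hist.counts.sum() == 1
        assert hist.min_objective == pytest.approx(J(design, {"t": 0.2}, {}))

    def test_counts_sum_to_draws(self):
        J = self.toy_objective()
        design = md.ExperimentalDesign(x0={}, intervals=[1.0])
        box = md.ParameterBox({"t": 0.0}, {"t": 1.0})
        hist = md.kl_histogram(J, design, (box, None), ({"t": 0.5}, {}), n_draws=500, n_bins=100, seed=3)
        assert hist.counts.sum() == 500
        assert len(hist.bin_edges) == 101
        widths = np.diff(hist.bin_edges)
        np.testing.assert_allclose(widths, widths[0], rtol=1e-9)

    def test_failed_draws_are_counted_and_excluded(self):
        calls = {"n": 0}

        def J(design, pA, pB):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise md.IntegrationError("stiff", (0.0, 1.0))
            return 1.0

        design = md.ExperimentalDesign(x0={}, intervals=[1.0])
        box = md.ParameterBox({"t": 0.0}, {"t": 1.0})
        hist = md.kl_histogram(J, design, (box, None), ({"t": 0.5}, {}), n_draws=30, n_bins=5)
        assert hist.failures == 10
        assert hist.counts.sum() == 20
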