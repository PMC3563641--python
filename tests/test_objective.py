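"""Discrimination criterion: steps, weights, KL terms and their properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import modeldiscrim as md
from modeldiscrim.objective import ObjectiveConfig, VarianceModel


def traj(values, times=None, species=("A",)):
    values = np.atleast_2d(np.asarray(values, float))
    times = np.asarray(times if times is not None else np.arange(1, values.shape[1] + 1), float)
    return md.TrajectorySet(times=times, species=species, values=values)


def wide_design(n=3, dt=100.0):
    return md.ExperimentalDesign(x0={}, intervals=np.full(n, dt))


class TestSmoothStep:
    def test_half_at_center(self):
        cfg = md.StepFunctionConfig(width=2.0, center=1.0, steepness=10.0)
        assert md.smooth_step(1.0, cfg) == pytest.approx(0.5)

    def test_saturation(self):
        cfg = md.StepFunctionConfig(width=1.0, center=0.0, steepness=10.0)
        assert md.smooth_step(10.0, cfg) > 1 - 1e-8
        assert md.smooth_step(-10.0, cfg) < 1e-8

    def test_close_to_heaviside_outside_width(self):
        cfg = md.StepFunctionConfig(width=1.0, center=0.0, steepness=5.0)
        for x in np.linspace(-5, 5, 101):
            if abs(x) > 1.0:
                heaviside = 1.0 if x > 0 else 0.0
                assert abs(md.smooth_step(x, cfg) - heaviside) < 0.01

    def test_heaviside_limit_in_steepness(self):
        cfg5 = md.StepFunctionConfig(width=1.0, center=0.0, steepness=5.0)
        cfg500 = md.StepFunctionConfig(width=1.0, center=0.0, steepness=500.0)
        x = 0.05
        assert abs(md.smooth_step(x, cfg500) - 1.0) < abs(md.smooth_step(x, cfg5) - 1.0)
        assert md.smooth_step(x, cfg500) > 1 - 1e-10

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.floats(-50, 50),
        y=st.floats(-50, 50),
        steep=st.floats(0.1, 30),
        width=st.floats(0.1, 10),
        center=st.floats(-5, 5),
    )
    def test_monotone_and_bounded(self, x, y, steep, width, center):
        cfg = md.StepFunctionConfig(width=width, center=center, steepness=steep)
        fx, fy = md.smooth_step(x, cfg), md.smooth_step(y, cfg)
        assert 0.0 <= fx <= 1.0
        if x <= y:
            assert fx <= fy + 1e-12


class TestMeasurementWeight:
    def test_clean_point_has_weight_one(self, exact_objective_config):
        cfg = exact_objective_config
        w = md.measurement_weight(100.0, 0.0, cfg.dt_step, cfg.pert_step)
        assert w == pytest.approx(1.0, abs=1e-12)

    def test_vanishing_interval_disables_measurement(self, exact_objective_config):
        cfg = exact_objective_config
        w = md.measurement_weight(0.0, 0.0, cfg.dt_step, cfg.pert_step)
        assert w < 1e-8

    def test_perturbed_point_is_suppressed(self, exact_objective_config):
        cfg = exact_objective_config
        w = md.measurement_weight(100.0, 1.0, cfg.dt_step, cfg.pert_step)
        assert w < 1e-8

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            md.measurement_weight(-1.0, 0.0)


class TestDiscriminationObjective:
    def test_identical_trajectories_give_zero(self, exact_objective_config):
        t = traj([1.0, 2.0, 3.0])
        assert md.discrimination_objective(t, t, wide_design(), exact_objective_config) == 0.0

    def test_hand_computed_homoscedastic_sum(self, exact_objective_config):
        # three points differing by 2, sigma = 1, weights 1: 3 * 4 / 2 = 6
        t1, t2 = traj([1, 1, 1]), traj([3, 3, 3])
        J = md.discrimination_objective(t1, t2, wide_design(), exact_objective_config)
        assert J == pytest.approx(6.0, abs=1e-12)

    def test_reduces_to_scaled_ssq(self, exact_objective_config, rng):
        sigma = 0.7
        cfg = ObjectiveConfig(
            variance=VarianceModel(sigma=sigma),
            dt_step=exact_objective_config.dt_step,
            pert_step=exact_objective_config.pert_step,
        )
        a, b = rng.normal(size=(2, 5))
        J = md.discrimination_objective(traj(a, np.arange(1, 6)), traj(b, np.arange(1, 6)),
                                        wide_design(5), cfg)
        assert J == pytest.approx(((a - b) ** 2).sum() / (2 * sigma**2), rel=1e-12)

    def test_per_model_zero_for_identical_gaussians(self, exact_objective_config):
        cfg = ObjectiveConfig(
            variance=VarianceModel(kind="per_model", var1=lambda t: 0.5 + 0 * t,
                                   var2=lambda t: 0.5 + 0 * t),
            dt_step=exact_objective_config.dt_step,
            pert_step=exact_objective_config.pert_step,
        )
        t = traj([1.0, 2.0, 3.0])
        assert md.discrimination_objective(t, t, wide_design(), cfg) == pytest.approx(0.0)

    def test_per_model_directed_asymmetry(self, exact_objective_config):
        # unequal variances make the directed criterion order-dependent
        cfg = ObjectiveConfig(
            variance=VarianceModel(kind="per_model", var1=lambda t: 1.0 + 0 * t,
                                   var2=lambda t: 4.0 + 0 * t),
            dt_step=exact_objective_config.dt_step,
            pert_step=exact_objective_config.pert_step,
        )
        rev = ObjectiveConfig(
            variance=VarianceModel(kind="per_model", var1=lambda t: 4.0 + 0 * t,
                                   var2=lambda t: 1.0 + 0 * t),
            dt_step=cfg.dt_step,
            pert_step=cfg.pert_step,
        )
        t1, t2 = traj([1, 1, 1]), traj([2, 2, 2])
        fwd = md.discrimination_objective(t1, t2, wide_design(), cfg)
        bwd = md.discrimination_objective(t2, t1, wide_design(), rev)
        assert fwd != pytest.approx(bwd)

    def test_quadratic_scaling_in_response_difference(self, exact_objective_config):
        base = md.discrimination_objective(
            traj([0, 0, 0]), traj([1, 1, 1]), wide_design(), exact_objective_config
        )
        scaled = md.discrimination_objective(
            traj([0, 0, 0]), traj([3, 3, 3]), wide_design(), exact_objective_config
        )
        assert scaled == pytest.approx(9 * base, rel=1e-12)

    def test_weights_suppress_perturbed_point(self, exact_objective_config):
        design = md.ExperimentalDesign(
            x0={}, intervals=[100.0, 100.0, 100.0], perturbations={2: {"A": 1.0}}
        )
        J = md.discrimination_objective(traj([1, 1, 1]), traj([3, 3, 3]), design,
                                        exact_objective_config)
        assert J == pytest.approx(4.0, abs=1e-6)  # middle point dropped

    def test_time_grid_mismatch_rejected(self, exact_objective_config):
        with pytest.raises(ValueError):
            md.discrimination_objective(
                traj([1, 2, 3], [1, 2, 3]), traj([1, 2, 3], [1, 2, 4]),
                wide_design(), exact_objective_config
            )

    def test_species_are_matched_by_label(self, exact_objective_config):
        tAB = md.TrajectorySet(times=[1, 2], species=("A", "B"), values=[[1, 1], [5, 5]])
        tBA = md.TrajectorySet(times=[1, 2], species=("B", "A"), values=[[5, 5], [1, 1]])
        design = wide_design(2)
        assert md.discrimination_objective(tAB, tBA, design, exact_objective_config) == 0.0

    def test_finite_difference_gradient_exists(self, exact_objective_config, decay_model):
        # J is differentiable in the parameters: FD gradient is finite
        design = md.ExperimentalDesign(x0={"S": 1.0}, intervals=[2.0, 2.0])
        J = md.make_pair_objective(decay_model, decay_model, exact_objective_config)

        def f(k):
            return J(design, {"k": k}, {"k": 1.0})

        g = (f(0.5 + 1e-6) - f(0.5 - 1e-6)) / 2e-6
        assert np.isfinite(g) and abs(g) > 0


class TestSymmetricObjective:
    def test_zero_for_identical_models(self, exact_objective_config):
        t = traj([1, 2, 3])
        assert md.symmetric_objective(t, t, wide_design(), exact_objective_config) == 0.0

    def test_swap_invariance(self, exact_objective_config):
        cfg = ObjectiveConfig(
            variance=VarianceModel(kind="per_model", var1=lambda t: 1.0 + 0 * t,
                                   var2=lambda t: 2.0 + 0 * t),
            dt_step=exact_objective_config.dt_step,
            pert_step=exact_objective_config.pert_step,
        )
        swapped = ObjectiveConfig(
            variance=VarianceModel(kind="per_model", var1=cfg.variance.var2,
                                   var2=cfg.variance.var1),
            dt_step=cfg.dt_step,
            pert_step=cfg.pert_step,
        )
        t1, t2 = traj([1, 1, 1]), traj([2, 3, 2])
        ab = md.symmetric_objective(t1, t2, wide_design(), cfg)
        ba = md.symmetric_objective(t2, t1, wide_design(), swapped)
        assert ab == pytest.approx(ba, rel=1e-12)

    def test_homoscedastic_doubles_directed_value(self, exact_objective_config):
        t1, t2 = traj([1, 1, 1]), traj([2, 2, 2])
        J = md.discrimination_objective(t1, t2, wide_design(), exact_objective_config)
        Jsym = md.symmetric_objective(t1, t2, wide_design(), exact_objective_config)
        assert Jsym == pytest.approx(2 * J, rel=1e-12)
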