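"""Penalties, objective semantics and the multi-start machinery."""

import numpy as np
import pytest

from bioen import estimation
from bioen.estimation import (ParameterSpec, exhaustion_constraint,
                              feasibility_penalty, multistart_fit, objective,
                              posthoc_adjust, table2_spec)
from bioen.simulator import simulate
from bioen.synthetic import generate_trial


def single_start(spec: ParameterSpec) -> ParameterSpec:
    return ParameterSpec(
        initials={k: [v[0]] for k, v in spec.initials.items()},
        bounds=spec.bounds, fixed=spec.fixed)


def data_driven_spec(trial):
    mr_ae_max0 = float(np.max(np.convolve(
        trial.y, np.ones(31) / 31.0, mode="valid")))
    mr_rest0 = float(np.clip(np.mean(trial.y[:15]), 70.0, 220.0))
    return table2_spec(mr_rest_init=mr_rest0, mr_lt_init=0.58 * mr_ae_max0,
                       mr_ae_max_init=mr_ae_max0,
                       ve_max=float(trial.u2.max()))


class TestFeasibilityPenalty:
    def test_interior_point_is_unpenalized(self):
        f = feasibility_penalty(np.array([0.5]), np.array([0.5]))
        assert f[0] == 1.0

    def test_grows_monotonically_without_bound(self):
        x = np.linspace(0.96, 1.4, 100)
        f = feasibility_penalty(x, np.zeros_like(x))
        assert np.all(np.diff(f) > 0.0)
        assert f[-1] > 100.0

    def test_continuous_at_onset(self):
        below = feasibility_penalty(np.array([0.95]), np.array([0.0]))[0]
        above = feasibility_penalty(np.array([0.9500001]), np.array([0.0]))[0]
        assert above == pytest.approx(below, abs=1e-4)

    def test_disabled_switch(self):
        f = feasibility_penalty(np.array([1.5]), np.array([1.5]),
                                enabled=False)
        assert f[0] == 1.0


class TestExhaustionConstraint:
    def test_zero_when_satisfied(self):
        t = np.arange(0.0, 500.0, 2.0)
        x4 = np.full(t.size, 0.9)
        assert exhaustion_constraint(t, x4, 400.0) == 0.0

    def test_quadratic_in_shortfall(self):
        t = np.arange(0.0, 500.0, 2.0)
        p1 = exhaustion_constraint(t, np.full(t.size, 0.80), 400.0)
        p2 = exhaustion_constraint(t, np.full(t.size, 0.75), 400.0)
        assert p1 > 0.0
        assert p2 / p1 == pytest.approx((0.10 / 0.05) ** 2, rel=1e-9)

    def test_window_clipped_at_trace_start(self):
        t = np.arange(0.0, 100.0, 2.0)
        p = exhaustion_constraint(t, np.full(t.size, 0.80), 60.0)
        assert p > 0.0  # clipped window [0, 60] still evaluated


class TestObjective:
    def test_self_consistency_noiseless(self, subject1, synth_config):
        from dataclasses import replace

        quiet = replace(synth_config, noise_sd=0.0)
        trial, truth, t_ex = generate_trial(subject1, config=quiet, seed=5,
                                            apply_trims=False)
        params = subject1.params.with_updates(VE_max=synth_config.ve_max)
        obj = objective(params, trial, penalties=False)
        assert obj < 1e-12
        # on the trimmed series the rest-state carryover of the removed
        # first 100 s leaves only a negligible residual
        trimmed, _, _ = generate_trial(subject1, config=quiet, seed=5)
        assert objective(params, trimmed, penalties=False) < 5.0

    def test_matches_noise_floor(self, subject1, fit_trial1, synth_config):
        trial, truth, t_ex = fit_trial1
        params = subject1.params.with_updates(VE_max=synth_config.ve_max)
        obj = objective(params, trial, penalties=False)
        assert obj == pytest.approx(synth_config.noise_sd ** 2, rel=0.10)

    def test_doubling_noise_quadruples_objective(self, subject1,
                                                 synth_config):
        from dataclasses import replace

        objs = {}
        for sd in (30.0, 60.0):
            cfg = replace(synth_config, noise_sd=sd)
            trial, _, _ = generate_trial(subject1, config=cfg, seed=9,
                                         apply_trims=False)
            params = subject1.params.with_updates(VE_max=cfg.ve_max)
            objs[sd] = objective(params, trial, penalties=False)
        # identical seeded noise draws scale exactly with sd
        assert objs[60.0] / objs[30.0] == pytest.approx(4.0, rel=1e-9)


class TestSpec:
    def test_table_start_cardinality(self):
        assert len(table2_spec().start_points()) == 64

    def test_single_initials_give_one_start(self):
        assert len(single_start(table2_spec()).start_points()) == 1

    def test_initials_outside_bounds_rejected(self):
        spec = table2_spec()
        bad = dict(spec.initials)
        bad["tau_ae"] = [5.0]
        with pytest.raises(ValueError):
            ParameterSpec(initials=bad, bounds=spec.bounds, fixed=spec.fixed)


@pytest.fixture(scope="module")
def fitted(fit_trial1):
    trial, _, t_ex = fit_trial1
    spec = single_start(data_driven_spec(trial))
    fit = multistart_fit(spec, trial, t_exhaust=t_ex)
    return spec, trial, t_ex, fit


class TestFit:
    def test_objective_is_minimum_over_starts(self, fitted):
        _, _, _, fit = fitted
        assert fit.objective == pytest.approx(min(fit.start_objectives))

    def test_fit_improves_on_initial_point(self, fitted):
        spec, trial, t_ex, fit = fitted
        theta0 = spec.start_points()[0]
        obj0 = objective(theta0, trial, t_exhaust=t_ex, fixed=spec.fixed)
        assert fit.objective <= obj0

    def test_parameters_respect_bounds(self, fitted):
        spec, _, _, fit = fitted
        d = fit.params.to_dict()
        for name, (lo, hi) in spec.bounds.items():
            assert lo - 1e-9 <= d[name] <= hi + 1e-9

    def test_posthoc_rescale_normalizes_alactic_peak(self, fitted):
        _, trial, _, fit = fitted
        adjusted = posthoc_adjust(fit, trial)
        sim = simulate(trial, adjusted)
        assert sim.x1.max() == pytest.approx(1.0, abs=1e-6)
        assert adjusted.demand.VE_max == float(trial.u2.max())
        assert adjusted.E_al_max == pytest.approx(
            estimation.E_AL_MAX_INITIAL * fit.max_x1)

    def test_degenerate_protocol_without_alactic_engagement(self, subject1):
        from conftest import constant_trial

        trial = constant_trial(n=201, y=143.0)
        fitlike = type("F", (), {})()
        fitlike.params = subject1.params
        with pytest.raises(ValueError):
            posthoc_adjust(fitlike, trial)
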