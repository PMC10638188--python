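"""Grey-box individualization of the model parameters.

Fourteen parameters are estimated by bounded trust-region least squares on
the residual between measured and modeled MR_ae, from every combination of
the per-parameter initial values (two initials for six parameters: 64
starts). Two constants stay fixed (VE_max from the fitting trial, K = 0.8)
and the alactic capacity E_al,max is excluded from the optimizer and rescaled
afterwards to the initial value times the achieved maximum of x1, which makes
the re-simulated maximum of x1 exactly 1 on the fitting trial.

Feasibility of the normalized states is enforced softly: a multiplicative
barrier on modeled MR_ae grows exponentially once max(x1, x4) passes 0.95,
and an additive penalty forces the muscle-lactate proxy x4 above 0.85 over
the last 100 s before exhaustion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .simulator import ModelParams, simulate, SimResult
from .series import TrialSeries

__all__ = [
    "ParameterSpec", "FitResult", "table2_spec",
    "feasibility_penalty", "exhaustion_constraint",
    "objective", "multistart_fit", "posthoc_adjust",
]

#: Barrier activation level and e-folding width for the feasibility penalty.
PENALTY_ONSET = 0.95
PENALTY_WIDTH = 0.02

#: Weight of the exhaustion shortfall penalty (W²): a shortfall of 0.05
#: contributes 1e4 W², dominating a typical fit MSE of a few thousand W².
EXHAUSTION_WEIGHT = 4.0e6
EXHAUSTION_WINDOW = 100.0  # s before exhaustion
EXHAUSTION_FLOOR = 0.85

#: Default alactic capacity before the post-hoc rescale, J.
E_AL_MAX_INITIAL = 21000.0

_ESTIMABLE = (
    "tau_ae", "MR_rest", "MR_lt", "MR_ae_max", "A_f", "B_f", "A_ve",
    "B_ve", "A_acc", "B_acc", "A_red", "eta_al", "V_m", "tau_la",
)


@dataclass
class ParameterSpec:
    """Resolved (absolute) initials and bounds of the estimable parameters.

    ``initials[name]`` holds one or two start values; ``bounds[name]`` the
    absolute (lower, upper) box. ``fixed`` holds the non-estimated constants
    (VE_max, K) and the pre-rescale alactic capacity.
    """

    initials: dict[str, list[float]]
    bounds: dict[str, tuple[float, float]]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(_ESTIMABLE) - set(self.initials)
        if missing:
            raise ValueError(f"missing initials for {sorted(missing)}")
        for name in _ESTIMABLE:
            lo, hi = self.bounds[name]
            for v in self.initials[name]:
                if not lo <= v <= hi:
                    raise ValueError(
                        f"initial {v} of {name} outside [{lo}, {hi}]")

    def start_points(self) -> list[dict[str, float]]:
        """Cartesian product of the per-parameter initial-value lists."""
        names = list(_ESTIMABLE)
        combos = itertools.product(*(self.initials[n] for n in names))
        return [dict(zip(names, c)) for c in combos]


def table2_spec(mr_rest_init: float = 135.0, mr_lt_init: float = 960.0,
                mr_ae_max_init: float = 1674.0, ve_max: float = 197.0,
                e_al_max_init: float = E_AL_MAX_INITIAL) -> ParameterSpec:
    """Standard estimation spec: initials and allowed ranges.

    The three metabolic-rate anchors are individual (taken from the fitting
    and incremental trials); percentage-form bounds are resolved here, once,
    into absolute values. A_ve/A_acc forms are percentages of the MR_ae_max
    initial; A_red and V_m forms are percentages of the V_m initial (mean of
    its two start values). Yields 2^6 = 64 start combinations.
    """
    M = mr_ae_max_init
    vm_inits = [38800.0, 41200.0]
    vm_ref = float(np.mean(vm_inits))
    spec = ParameterSpec(
        initials={
            "tau_ae": [25.0],
            "MR_rest": [mr_rest_init],
            "MR_lt": [mr_lt_init],
            "MR_ae_max": [mr_ae_max_init],
            "A_f": [143.0, 158.0],
            "B_f": [2.8],
            "A_ve": [0.088 * M],
            "B_ve": [0.9],
            "A_acc": [0.038 * M, 0.042 * M],
            "B_acc": [1.0],
            "A_red": [0.0048 * vm_ref, 0.0053 * vm_ref],
            "eta_al": [0.40, 0.45],
            "V_m": vm_inits,
            "tau_la": [11.9, 13.1],
        },
        bounds={
            "tau_ae": (10.0, 100.0),
            "MR_rest": (70.0, 220.0),
            "MR_lt": (0.70 * mr_lt_init, 1.30 * mr_lt_init),
            "MR_ae_max": (1.00 * mr_ae_max_init, 1.05 * mr_ae_max_init),
            "A_f": (50.0, 250.0),
            "B_f": (2.2, 3.5),
            "A_ve": (0.05 * M, 0.15 * M),
            "B_ve": (0.0, 1.0),
            "A_acc": (0.0, 0.15 * M),
            "B_acc": (0.0, 1.0),
            "A_red": (0.003 * vm_ref, 0.007 * vm_ref),
            "eta_al": (0.40, 0.50),
            "V_m": (0.50 * vm_ref, 1.50 * vm_ref),
            "tau_la": (10.0, 15.0),
        },
        fixed={"VE_max": ve_max, "K": 0.8, "E_al_max": e_al_max_init},
    )
    return spec


def feasibility_penalty(x1: np.ndarray, x4: np.ndarray,
                        enabled: bool = True) -> np.ndarray:
    """Multiplicative barrier factor (>= 1) per node.

    1 while both normalized states stay below 0.95; beyond that the factor
    grows as ``1 + exp((max(x1,x4) - 1)/0.02) - exp(-0.05/0.02)`` —
    continuous at onset, unbounded as the states approach and pass 1.
    """
    if not enabled:
        return np.ones_like(np.asarray(x1, dtype=float))
    m = np.maximum(x1, x4)
    onset = math.exp((PENALTY_ONSET - 1.0) / PENALTY_WIDTH)
    f = 1.0 + np.exp(
        np.minimum((m - 1.0) / PENALTY_WIDTH, 50.0)) - onset
    return np.where(m > PENALTY_ONSET, f, 1.0)


def exhaustion_constraint(t: np.ndarray, x4: np.ndarray,
                          t_exhaust: float,
                          weight: float = EXHAUSTION_WEIGHT) -> float:
    """Additive penalty forcing x4 >= 0.85 over the 100 s before exhaustion.

    Zero when satisfied; otherwise ``weight`` times the window mean of the
    squared shortfall. The window is clipped to the trace start.
    """
    s = _exhaustion_shortfall(t, x4, t_exhaust)
    if s.size == 0:
        return 0.0
    return float(weight * np.mean(s * s))


def _exhaustion_shortfall(t, x4, t_exhaust):
    m = (t >= t_exhaust - EXHAUSTION_WINDOW) & (t <= t_exhaust + 1e-9)
    return np.maximum(0.0, EXHAUSTION_FLOOR - x4[m])


def _residuals(theta: dict[str, float], fixed: dict[str, float],
               trial: TrialSeries, t_exhaust: float | None,
               penalties: bool) -> np.ndarray:
    params = ModelParams.from_dict({**theta, **fixed})
    sim = simulate(trial, params)
    factor = feasibility_penalty(sim.x1, sim.x4, enabled=penalties)
    n = trial.t.size
    res = (trial.y - sim.y * factor) / math.sqrt(n)
    if penalties and t_exhaust is not None:
        s = _exhaustion_shortfall(trial.t, sim.x4, t_exhaust)
        if s.size:
            res = np.concatenate(
                [res, math.sqrt(EXHAUSTION_WEIGHT / s.size) * s])
    return res


def objective(params_or_theta, trial: TrialSeries,
              t_exhaust: float | None = None, fixed: dict | None = None,
              penalties: bool = True) -> float:
    """Penalized mean-squared-error objective (W²).

    Mean over nodes of the squared penalized residual plus the exhaustion
    penalty. A failed simulation maps to a large finite value so multi-start
    optimization continues.
    """
    if isinstance(params_or_theta, ModelParams):
        theta = params_or_theta.to_dict()
        fixed = {}
    else:
        theta = dict(params_or_theta)
        fixed = dict(fixed or {})
    try:
        r = _residuals(theta, fixed, trial, t_exhaust, penalties)
    except FloatingPointError:
        return 1.0e12
    return float(np.dot(r, r))


@dataclass
class FitResult:
    """Outcome of the multi-start estimation."""

    params: ModelParams            # best parameters (before post-hoc adjust)
    objective: float               # penalized MSE of the best start, W²
    start_objectives: list[float]  # one per start combination
    start_thetas: list[dict]       # starting values per combination
    max_x1: float                  # on the fitting trial at the optimum
    max_x4: float
    n_starts: int
    exhaustion_penalty: float


def multistart_fit(spec: ParameterSpec, trial: TrialSeries,
                   t_exhaust: float | None = None,
                   max_nfev: int = 400, penalties: bool = True,
                   verbose: bool = False) -> FitResult:
    """Bounded least squares from every initial-value combination.

    Deterministic given the trial and spec. Each start runs a trust-region
    reflective least-squares fit (ftol = xtol = 1e-8, function-evaluation
    budget ``max_nfev``); the argmin over starts is returned.
    """
    if trial.y is None:
        raise ValueError("fitting requires a measured output on the trial")
    names = list(_ESTIMABLE)
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    starts = spec.start_points()
    scale = np.maximum(np.abs(
        [np.mean(spec.initials[n]) for n in names]), 1e-3)
    fixed = dict(spec.fixed)
    n_res = trial.t.size
    if penalties and t_exhaust is not None:
        n_res += int(np.count_nonzero(
            (trial.t >= t_exhaust - EXHAUSTION_WINDOW)
            & (trial.t <= t_exhaust + 1e-9)))

    def fun(x):
        theta = dict(zip(names, x))
        try:
            return _residuals(theta, fixed, trial, t_exhaust, penalties)
        except FloatingPointError:
            return np.full(n_res, 1.0e6)

    best = None
    start_objs: list[float] = []
    for i, theta0 in enumerate(starts):
        x0 = np.array([theta0[n] for n in names])
        sol = least_squares(
            fun, x0, bounds=(lo, hi), method="trf",
            ftol=1e-8, xtol=1e-8, gtol=1e-10,
            x_scale=scale, diff_step=1e-6, max_nfev=max_nfev)
        obj = float(2.0 * sol.cost)  # cost = 0.5 * sum(res^2)
        start_objs.append(obj)
        if verbose:
            print(f"  start {i + 1}/{len(starts)}: objective {obj:.2f} W^2")
        if best is None or obj < best[0]:
            best = (obj, sol.x.copy())
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("all multi-start fits failed")

    theta_best = dict(zip(names, best[1]))
    params = ModelParams.from_dict({**theta_best, **fixed})
    sim = simulate(trial, params)
    exh = (exhaustion_constraint(trial.t, sim.x4, t_exhaust)
           if t_exhaust is not None else 0.0)
    return FitResult(
        params=params, objective=best[0], start_objectives=start_objs,
        start_thetas=starts, max_x1=float(sim.x1.max()),
        max_x4=float(sim.x4.max()), n_starts=len(starts),
        exhaustion_penalty=exh)


def posthoc_adjust(fit: FitResult, trial: TrialSeries,
                   e_al_max_init: float | None = None) -> ModelParams:
    """Post-estimation adjustments of the separately treated constants.

    The alactic capacity becomes its initial value times the maximum x1
    achieved on the fitting trial (so the re-simulated maximum of x1 is
    exactly 1 there), and VE_max becomes the maximum measured ventilation of
    the fitting trial.
    """
    if e_al_max_init is None:
        e_al_max_init = fit.params.E_al_max
    sim = simulate(trial, fit.params)
    max_x1 = float(sim.x1.max())
    if max_x1 <= 0.0:
        raise ValueError("no alactic engagement on the fitting trial; "
                         "cannot rescale the alactic capacity")
    return fit.params.with_updates(
        E_al_max=e_al_max_init * max_x1,
        VE_max=float(trial.u2.max()),
    )
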