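"""Four-state bioenergetic supply ODE and its fixed-step integrator.

The supply side of the model tracks

* ``x1`` — fractional depletion of the alactic (phosphocreatine) store
  (0 full, 1 depleted; may exceed 1 on validation trials),
* ``x2`` — lactic (lactate-accumulating glycolytic) metabolic rate, W,
* ``x3`` — primary aerobic component above rest, W,
* ``x4`` — normalized muscle-lactate proxy (0 none, 1 maximal).

Dynamics, with residual ``r1 = MR_dem - MR_rest - x3 - x2``::

    x1' = r1 / E_al_max          (times eta_al when negative: hysteresis cost)
    x2' = r1 / tau_la - K * x3'  (floored: x2' = 0 when x2 = 0 and x2' < 0)
    x3' = (MR_dem - MR_rest - x3) / tau_ae
                                 (capped: x3' = 0 at x3 = MR_ae_max - MR_rest)
    x4' = (x2 - A_red * Z_dem * x4) / V_m

The alactic store closes the energy balance instantaneously: whenever
``r1 >= 0``, supply ``MR_al + MR_la + MR_ae`` equals demand identically.
During recovery (``r1 < 0``) the alactic term is a sink; only the fraction
``eta_al`` of diverted energy is restored, and MR_al is reported as 0.

Integration is a fixed-step explicit RK4 with substeps aligned to the 0.5 Hz
input grid; the floor/cap conditions are applied inside the derivative
evaluation and as a post-step clamp against truncation overshoot. The forcing
is piecewise constant (power) or piecewise linear (ventilation), which an
adaptive stiff solver's error control handles poorly across the frequent
discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .demand import DemandParams, POWER_NOISE_FLOOR

__all__ = ["ModelParams", "SimResult", "simulate", "energy_contributions"]

#: Default RK4 substep, s (8 substeps per 2 s grid interval).
DEFAULT_SUBSTEP = 0.25

# layout of the packed parameter vector consumed by the jitted core
_PARAM_ORDER = (
    "A_f", "B_f", "A_ve", "B_ve", "A_acc", "B_acc", "VE_max",
    "MR_rest", "MR_lt", "E_al_max", "tau_ae", "tau_la", "K",
    "A_red", "eta_al", "V_m", "MR_ae_max",
)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: demand parameters plus the supply-side constants.

    Attributes
    ----------
    demand : DemandParams
        The nine demand-side parameters.
    E_al_max : float
        Alactic energy capacity, J (Table-2 scale 21.0 corresponds to
        21000 J).
    tau_ae : float
        Time constant of the aerobic system, s (10–100).
    tau_la : float
        Time constant of the lactic system, s (10–15).
    K : float
        Dampening factor coupling lactic response to aerobic rate of change
        (constant 0.8).
    A_red : float
        Maximum amplitude of muscle-lactate reduction, in the same J-scale
        units as ``V_m`` (resolved from its percentage-of-V_m form at load).
    eta_al : float
        Efficiency of alactic recovery, dimensionless in (0, 1].
    V_m : float
        Muscle lactate storage capacity on the J scale (normalizes the x4
        balance).
    MR_ae_max : float
        Ceiling of the aerobic metabolic rate, W.
    """

    demand: DemandParams
    E_al_max: float
    tau_ae: float
    tau_la: float
    K: float
    A_red: float
    eta_al: float
    V_m: float
    MR_ae_max: float

    def __post_init__(self) -> None:
        if not 10.0 <= self.tau_ae <= 100.0:
            raise ValueError("tau_ae must lie in [10, 100] s")
        if not 10.0 <= self.tau_la <= 15.0:
            raise ValueError("tau_la must lie in [10, 15] s")
        if not 0.0 < self.eta_al <= 1.0:
            raise ValueError("eta_al must lie in (0, 1]")
        for name in ("E_al_max", "V_m", "A_red"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if not self.MR_ae_max > self.demand.MR_lt:
            raise ValueError("MR_ae_max must exceed MR_lt")

    def pack(self) -> np.ndarray:
        """Flatten into the vector layout of the jitted integrator core."""
        d = self.demand
        src = {**d.to_dict(), **{
            "E_al_max": self.E_al_max, "tau_ae": self.tau_ae,
            "tau_la": self.tau_la, "K": self.K, "A_red": self.A_red,
            "eta_al": self.eta_al, "V_m": self.V_m,
            "MR_ae_max": self.MR_ae_max,
        }}
        return np.array([src[k] for k in _PARAM_ORDER], dtype=float)

    @classmethod
    def unpack(cls, vec: np.ndarray) -> "ModelParams":
        src = dict(zip(_PARAM_ORDER, (float(v) for v in vec)))
        demand = DemandParams(**{k: src[k] for k in (
            "A_f", "B_f", "A_ve", "B_ve", "A_acc", "B_acc",
            "VE_max", "MR_rest", "MR_lt")})
        return cls(demand=demand, **{k: src[k] for k in (
            "E_al_max", "tau_ae", "tau_la", "K", "A_red", "eta_al",
            "V_m", "MR_ae_max")})

    def to_dict(self) -> dict[str, float]:
        return dict(zip(_PARAM_ORDER, (float(v) for v in self.pack())))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls.unpack(np.array([float(d[k]) for k in _PARAM_ORDER]))

    def with_updates(self, **kwargs) -> "ModelParams":
        """Return a copy with named (demand or supply) parameters replaced."""
        d = self.to_dict()
        d.update(kwargs)
        return self.from_dict(d)


@njit(cache=True)
def _deriv(x1, x2, x3, x4, u1, u2, p):
    """Right-hand side with the floor/cap conditions applied."""
    A_f, B_f, A_ve, B_ve = p[0], p[1], p[2], p[3]
    A_acc, B_acc, VE_max = p[4], p[5], p[6]
    MR_rest, MR_lt, E_al_max = p[7], p[8], p[9]
    tau_ae, tau_la, K = p[10], p[11], p[12]
    A_red, eta_al, V_m = p[13], p[14], p[15]
    MR_ae_max = p[16]

    if abs(u1) < 0.5:  # POWER_NOISE_FLOOR
        mrf = 0.0
    else:
        mrf = A_f + B_f * u1
    r = u2 / VE_max
    mrve = A_ve * (B_ve * r + (1.0 - B_ve) * r * r)
    mracc = A_acc * (B_acc * x4 + (1.0 - B_acc) * x4 * x4)
    mrdem = MR_rest + mrf + mrve + mracc

    cap = MR_ae_max - MR_rest
    dx3 = (mrdem - MR_rest - x3) / tau_ae
    if x3 >= cap and dx3 > 0.0:
        dx3 = 0.0
    r1 = mrdem - MR_rest - x3 - x2
    dx2 = r1 / tau_la - K * dx3
    if x2 <= 0.0 and dx2 < 0.0:
        dx2 = 0.0
    dx1 = r1 / E_al_max
    if dx1 < 0.0:
        dx1 *= eta_al
    z = (MR_lt - mrdem) / (MR_lt - MR_rest)
    if z < 0.0:
        z = 0.0
    elif z > 1.0:
        z = 1.0
    dx4 = (x2 - A_red * z * x4) / V_m
    return dx1, dx2, dx3, dx4


@njit(cache=True)
def _integrate(t, u1, u2, p, x0, n_sub):
    """RK4 over the node grid; returns the state trajectory (n, 4)."""
    n = t.shape[0]
    xs = np.empty((n, 4))
    x1, x2, x3, x4 = x0[0], x0[1], x0[2], x0[3]
    xs[0, 0], xs[0, 1], xs[0, 2], xs[0, 3] = x1, x2, x3, x4
    cap = p[16] - p[7]
    for i in range(n - 1):
        dt_node = t[i + 1] - t[i]
        h = dt_node / n_sub
        pu1 = u1[i]  # power held piecewise constant over the interval
        for k in range(n_sub):
            f0 = k / n_sub
            f1 = (k + 0.5) / n_sub
            f2 = (k + 1.0) / n_sub
            v0 = u2[i] + (u2[i + 1] - u2[i]) * f0
            v1 = u2[i] + (u2[i + 1] - u2[i]) * f1
            v2 = u2[i] + (u2[i + 1] - u2[i]) * f2

            a1, a2, a3, a4 = _deriv(x1, x2, x3, x4, pu1, v0, p)
            b1, b2, b3, b4 = _deriv(
                x1 + 0.5 * h * a1, x2 + 0.5 * h * a2,
                x3 + 0.5 * h * a3, x4 + 0.5 * h * a4, pu1, v1, p)
            c1, c2, c3, c4 = _deriv(
                x1 + 0.5 * h * b1, x2 + 0.5 * h * b2,
                x3 + 0.5 * h * b3, x4 + 0.5 * h * b4, pu1, v1, p)
            d1, d2, d3, d4 = _deriv(
                x1 + h * c1, x2 + h * c2,
                x3 + h * c3, x4 + h * c4, pu1, v2, p)

            x1 += h * (a1 + 2.0 * b1 + 2.0 * c1 + d1) / 6.0
            x2 += h * (a2 + 2.0 * b2 + 2.0 * c2 + d2) / 6.0
            x3 += h * (a3 + 2.0 * b3 + 2.0 * c3 + d3) / 6.0
            x4 += h * (a4 + 2.0 * b4 + 2.0 * c4 + d4) / 6.0
            # clamp truncation overshoot at the hard floor/cap
            if x2 < 0.0:
                x2 = 0.0
            if x3 > cap:
                x3 = cap
            if x4 < 0.0:
                x4 = 0.0
        xs[i + 1, 0], xs[i + 1, 1] = x1, x2
        xs[i + 1, 2], xs[i + 1, 3] = x3, x4
    return xs


@dataclass
class SimResult:
    """Time-resolved states, supply rates and demand components (all W)."""

    t: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    x: np.ndarray  # (n, 4)
    y: np.ndarray  # modeled MR_ae = MR_rest + x3
    MR_al: np.ndarray
    MR_la: np.ndarray
    MR_ae: np.ndarray
    MR_sup: np.ndarray
    MR_dem: np.ndarray
    MR_f: np.ndarray
    MR_ve: np.ndarray
    MR_acc: np.ndarray
    residual: np.ndarray  # raw alactic residual r1 (W); negative in recovery

    @property
    def x1(self) -> np.ndarray:
        return self.x[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.x[:, 1]

    @property
    def x3(self) -> np.ndarray:
        return self.x[:, 2]

    @property
    def x4(self) -> np.ndarray:
        return self.x[:, 3]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "u1": self.u1, "u2": self.u2,
            "x1": self.x1, "x2": self.x2, "x3": self.x3, "x4": self.x4,
            "MR_al": self.MR_al, "MR_la": self.MR_la, "MR_ae": self.MR_ae,
            "MR_dem": self.MR_dem, "MR_f": self.MR_f, "MR_ve": self.MR_ve,
            "MR_acc": self.MR_acc,
        })


def simulate(trial, params: ModelParams, x0=None,
             substep: float = DEFAULT_SUBSTEP) -> SimResult:
    """Integrate the supply ODE over a trial's input grid.

    Parameters
    ----------
    trial : TrialSeries
        Inputs on the uniform 0.5 Hz grid (``y`` is ignored here).
    params : ModelParams
    x0 : sequence of 4 floats, optional
        Initial state; defaults to rest equilibrium (0, 0, 0, 0).
    substep : float
        RK4 substep in seconds; must divide the grid spacing.

    Returns
    -------
    SimResult
        States plus all supply and demand components at every node. MR_al
        follows the supply-side convention: ``max(r1, 0)`` (zero during
        recovery, when the alactic term is a sink).
    """
    x0 = np.zeros(4) if x0 is None else np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("initial state must be finite")
    dt = float(trial.t[1] - trial.t[0])
    n_sub = max(1, int(round(dt / substep)))
    p = params.pack()
    xs = _integrate(trial.t, trial.u1, trial.u2, p, x0, n_sub)
    if not np.all(np.isfinite(xs)):
        bad = int(np.argmax(~np.isfinite(xs).all(axis=1)))
        raise FloatingPointError(
            f"state blew up at t = {trial.t[bad]:.1f} s")

    d = params.demand
    mrf = np.where(np.abs(trial.u1) < POWER_NOISE_FLOOR, 0.0,
                   d.A_f + d.B_f * trial.u1)
    r = trial.u2 / d.VE_max
    mrve = d.A_ve * (d.B_ve * r + (1.0 - d.B_ve) * r * r)
    x4 = xs[:, 3]
    mracc = d.A_acc * (d.B_acc * x4 + (1.0 - d.B_acc) * x4 * x4)
    mrdem = d.MR_rest + mrf + mrve + mracc
    mrae = d.MR_rest + xs[:, 2]
    r1 = mrdem - mrae - xs[:, 1]
    mral = np.maximum(r1, 0.0)
    mrla = xs[:, 1].copy()
    return SimResult(
        t=trial.t, u1=trial.u1, u2=trial.u2, x=xs, y=mrae,
        MR_al=mral, MR_la=mrla, MR_ae=mrae, MR_sup=mral + mrla + mrae,
        MR_dem=mrdem, MR_f=mrf, MR_ve=mrve, MR_acc=mracc, residual=r1,
    )


def energy_contributions(result: SimResult, t_end: float | None = None,
                         skip_initial: float = 100.0):
    """Per-system energy (kJ) and percentage shares up to ``t_end``.

    Trapezoidal integrals of MR_al, MR_la and MR_ae over
    ``[t_start + skip_initial, t_end]``; the initial passive-rest stretch is
    omitted by default. Percentages are of the three-system total and sum
    to 100.
    """
    t0 = result.t[0] + skip_initial
    t_end = float(result.t[-1]) if t_end is None else float(t_end)
    if t_end <= t0 or t_end > result.t[-1] + 1e-9:
        raise ValueError("t_end must lie inside the (skipped) result grid")
    m = (result.t >= t0 - 1e-9) & (result.t <= t_end + 1e-9)
    tt = result.t[m]
    out = {}
    total = 0.0
    for name, trace in (("alactic", result.MR_al), ("lactic", result.MR_la),
                        ("aerobic", result.MR_ae)):
        e = float(np.trapezoid(trace[m], tt)) / 1e3  # kJ
        out[name] = {"kJ": e}
        total += e
    for name in out:
        out[name]["percent"] = 100.0 * out[name]["kJ"] / total
    out["anaerobic"] = {
        "kJ": out["alactic"]["kJ"] + out["lactic"]["kJ"],
        "percent": out["alactic"]["percent"] + out["lactic"]["percent"],
    }
    out["total_kJ"] = total
    return out
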