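"""Metabolic demand model.

Total metabolic demand during ergometer cycling is decomposed into four
components, all in watts:

* ``MR_rest`` — resting metabolic rate excluding ventilation,
* ``MR_f`` — fundamental demand of the cycling work, affine in power,
* ``MR_ve`` — demand of pulmonary ventilation, a linear/quadratic blend of
  minute ventilation normalized by the individual maximum,
* ``MR_acc`` — demand attributed to accumulated muscle metabolites, the same
  blend applied to the normalized muscle-lactate proxy ``x4``.

The demand factor ``Z_dem`` maps total demand onto [0, 1]: 1 at rest,
0 at and above the lactate-threshold metabolic rate, linear in between.
It gates the clearance of accumulated muscle lactate.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "DemandParams",
    "DemandBreakdown",
    "z_dem",
    "mr_f",
    "mr_ve",
    "mr_acc",
    "demand_breakdown",
    "POWER_NOISE_FLOOR",
]

#: Powers below this magnitude (W) count as passive rest: MR_f is defined to
#: vanish at zero power and ergometer traces carry sub-watt sensor noise.
POWER_NOISE_FLOOR = 0.5


@dataclass(frozen=True)
class DemandParams:
    """Parameters of the demand model (Table-2 style naming).

    Attributes
    ----------
    A_f : float
        Y-intercept of the fundamental work demand, W (demand of unloaded
        cycling).
    B_f : float
        Slope of fundamental demand per watt of external power (dimensionless).
    A_ve : float
        Maximum metabolic demand rate due to ventilation, W (value of MR_ve
        at ``u2 == VE_max``).
    B_ve : float
        Linear/quadratic distribution factor of MR_ve, in [0, 1].
    A_acc : float
        Maximum metabolic demand rate due to accumulated metabolites, W.
    B_acc : float
        Linear/quadratic distribution factor of MR_acc, in [0, 1].
    VE_max : float
        Individual maximum minute ventilation, L·min⁻¹ BTPS (constant, taken
        from the fitting trial).
    MR_rest : float
        Resting metabolic rate without ventilation demand, W.
    MR_lt : float
        Metabolic rate at the first lactate threshold, W.
    """

    A_f: float
    B_f: float
    A_ve: float
    B_ve: float
    A_acc: float
    B_acc: float
    VE_max: float
    MR_rest: float
    MR_lt: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.B_ve <= 1.0 and 0.0 <= self.B_acc <= 1.0):
            raise ValueError("B_ve and B_acc must lie in [0, 1]")
        if self.MR_lt <= self.MR_rest:
            raise ValueError("MR_lt must exceed MR_rest")
        for name in ("A_f", "A_ve", "A_acc", "VE_max"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "DemandParams":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})


@dataclass(frozen=True)
class DemandBreakdown:
    """Demand components (W); ``MR_dem`` is their sum including ``MR_rest``."""

    MR_f: float
    MR_ve: float
    MR_acc: float
    MR_rest: float
    MR_dem: float


def z_dem(mr_dem, params: DemandParams):
    """Demand factor gating muscle-lactate clearance.

    Equals 1 for ``mr_dem <= MR_rest``, 0 for ``mr_dem >= MR_lt`` and
    interpolates linearly in between. Accepts scalars or arrays.
    """
    if params.MR_lt <= params.MR_rest:
        raise ValueError("MR_lt must exceed MR_rest")
    z = (params.MR_lt - np.asarray(mr_dem, dtype=float)) / (
        params.MR_lt - params.MR_rest
    )
    out = np.clip(z, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def mr_f(u1, A_f: float, B_f: float):
    """Fundamental work demand ``A_f + B_f * u1``; exactly 0 at passive rest.

    The intercept makes MR_f discontinuous at zero power; any ``|u1|`` below
    :data:`POWER_NOISE_FLOOR` is treated as passive rest.
    """
    u1 = np.asarray(u1, dtype=float)
    if np.any(u1 < -POWER_NOISE_FLOOR):
        raise ValueError("power output must be non-negative")
    out = np.where(np.abs(u1) < POWER_NOISE_FLOOR, 0.0, A_f + B_f * u1)
    return float(out) if out.ndim == 0 else out


def mr_ve(u2, params: DemandParams, literal_quadratic: bool = False):
    """Ventilatory demand as a linear/quadratic blend of minute ventilation.

    Normalized form (default): ``A_ve * (B_ve*r + (1-B_ve)*r**2)`` with
    ``r = u2 / VE_max``, so that ``mr_ve(VE_max) == A_ve``. With
    ``literal_quadratic=True`` the quadratic term uses ``u2**2 / VE_max``
    instead of ``(u2/VE_max)**2`` (for reproduction studies only; it does not
    satisfy the A_ve-as-maximum interpretation). ``u2`` above ``VE_max`` is
    evaluated as-is, not clamped.
    """
    u2 = np.asarray(u2, dtype=float)
    if np.any(u2 < 0.0):
        raise ValueError("minute ventilation must be non-negative")
    r = u2 / params.VE_max
    quad = (u2 * u2 / params.VE_max) if literal_quadratic else r * r
    out = params.A_ve * (params.B_ve * r + (1.0 - params.B_ve) * quad)
    return float(out) if out.ndim == 0 else out


def mr_acc(x4, A_acc: float, B_acc: float):
    """Accumulated-metabolite demand, same blend form as :func:`mr_ve`.

    ``x4`` is the normalized muscle-lactate proxy; values above 1 (possible
    on validation trials) extrapolate the same polynomial.
    """
    x4 = np.asarray(x4, dtype=float)
    if np.any(x4 < 0.0):
        raise ValueError("x4 must be non-negative")
    out = A_acc * (B_acc * x4 + (1.0 - B_acc) * x4 * x4)
    return float(out) if out.ndim == 0 else out


def demand_breakdown(
    u1, u2, x4, params: DemandParams, literal_quadratic: bool = False
) -> DemandBreakdown:
    """Evaluate all demand components and their total at one operating point."""
    f = mr_f(u1, params.A_f, params.B_f)
    ve = mr_ve(u2, params, literal_quadratic=literal_quadratic)
    acc = mr_acc(x4, params.A_acc, params.B_acc)
    total = params.MR_rest + f + ve + acc
    return DemandBreakdown(
        MR_f=f, MR_ve=ve, MR_acc=acc, MR_rest=params.MR_rest, MR_dem=total
    )
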