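"""Incremental-test anchors and intermittent protocol construction.

A submaximal incremental test (stages from 80 W in 20 W steps, blood lactate
sampled each stage) yields the lactate baseline, the first lactate threshold
LT1 (baseline + 0.2 mmol·L⁻¹) and the onset of blood lactate accumulation
OBLA (4 mmol·L⁻¹), both converted to power via a cubic [bLa⁻]–power fit.
A maximal ramp (40 W·min⁻¹) yields P_VO2peak (power extrapolated to peak
oxygen uptake) and P_max (stage power minus 40 W times the unfinished
fraction of the minute). The four anchors define the seven power levels of
the intermittent trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import TrialSeries, GRID_DT

__all__ = [
    "SubjectAnchors", "ProtocolSpec", "Segment",
    "lactate_baseline", "fit_bla_power", "compute_p_vo2peak",
    "compute_p_max", "compute_levels", "build_timeline",
    "P2_LIKE", "P3_LIKE",
]

#: Duplicate-sample typical error of blood lactate, rounded up, mmol·L⁻¹.
LACTATE_TOL = 0.2

#: OBLA blood lactate concentration, mmol·L⁻¹.
OBLA_CONC = 4.0

LEVEL_NAMES = ("PR", "AR", "L1", "L2", "L3", "L4.3", "L4.2")


@dataclass(frozen=True)
class SubjectAnchors:
    """Individual power anchors (W) and lactate reference concentrations."""

    P_LT1: float
    P_OBLA: float
    P_VO2peak: float
    P_max: float
    bla_baseline: float = 1.0
    LT1_conc: float | None = None

    def __post_init__(self) -> None:
        if self.LT1_conc is None:
            object.__setattr__(self, "LT1_conc", self.bla_baseline + LACTATE_TOL)

    @property
    def ordered(self) -> bool:
        return self.P_LT1 < self.P_OBLA < self.P_VO2peak < self.P_max


@dataclass(frozen=True)
class Segment:
    level: str
    duration: float  # s; ignored when open_ended
    open_ended: bool = False

    def __post_init__(self) -> None:
        if not self.open_ended and self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered power-level segments; at most the final one is open-ended."""

    name: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        open_idx = [i for i, s in enumerate(self.segments) if s.open_ended]
        if open_idx and open_idx != [len(self.segments) - 2] and \
                open_idx != [len(self.segments) - 1]:
            raise ValueError(
                "only the final high-intensity segment may be open-ended")
        if len(open_idx) > 1:
            raise ValueError("at most one open-ended segment")

    @property
    def has_open_ended(self) -> bool:
        return any(s.open_ended for s in self.segments)


def lactate_baseline(concs, tol: float = LACTATE_TOL):
    """Blood-lactate baseline and the LT1 concentration.

    The baseline is the running mean of the first two stage concentrations,
    extended one value at a time while the next concentration stays within
    ``tol`` of the current mean. LT1 is ``baseline + tol``.
    """
    concs = np.asarray(concs, dtype=float)
    if concs.size < 2:
        raise ValueError("need at least two lactate values")
    k = 2
    mean = float(concs[:2].mean())
    while k < concs.size and abs(concs[k] - mean) <= tol:
        k += 1
        mean = float(concs[:k].mean())
    return mean, mean + tol


class ThresholdNotReached(ValueError):
    """The lactate–power curve never crosses the requested concentration."""


@dataclass
class LactatePowerFit:
    """Least-squares cubic of blood lactate on power."""

    coeffs: np.ndarray  # numpy polynomial coefficients, highest degree first
    p_min: float
    p_max: float

    def __call__(self, power):
        return np.polyval(self.coeffs, power)

    def power_at_conc(self, target: float) -> float:
        """Smallest real root of conc(P) = target within the observed power
        range extended 10% above (first crossing as power increases)."""
        c = self.coeffs.copy()
        c[-1] -= target
        roots = np.roots(c)
        hi = self.p_max + 0.1 * (self.p_max - self.p_min)
        real = [float(r.real) for r in roots
                if abs(r.imag) < 1e-8 * max(1.0, abs(r.real))
                and self.p_min - 1e-9 <= r.real <= hi + 1e-9]
        if not real:
            raise ThresholdNotReached(
                f"no power in [{self.p_min:.0f}, {hi:.0f}] W reaches "
                f"[bLa-] = {target} mmol/L")
        return min(real)


def fit_bla_power(power, concs) -> LactatePowerFit:
    """Fit stage blood lactate vs power to a third-degree polynomial."""
    power = np.asarray(power, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if power.size < 4:
        raise ValueError("need at least four stages for a cubic fit")
    if np.any(np.diff(power) <= 0):
        raise ValueError("stage powers must be strictly increasing")
    coeffs = np.polyfit(power, concs, 3)
    return LactatePowerFit(coeffs=coeffs, p_min=float(power[0]),
                           p_max=float(power[-1]))


def compute_p_vo2peak(submax_power, submax_vo2, vo2peak: float) -> float:
    """Power at peak oxygen uptake by extrapolating the submaximal
    power–VO2 line (OLS of power on VO2) to ``vo2peak``."""
    p = np.asarray(submax_power, dtype=float)
    v = np.asarray(submax_vo2, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two submaximal stages")
    if vo2peak < v.max():
        import warnings

        warnings.warn("VO2peak below the largest submaximal VO2; "
                      "extrapolation is inconsistent", stacklevel=2)
    slope, intercept = np.polyfit(v, p, 1)
    return float(slope * vo2peak + intercept)


def compute_p_max(last_stage_power: float, seconds_remaining: float,
                  increment: float = 40.0, stage_s: float = 60.0) -> float:
    """Maximum power from the ramp test: stage power at exhaustion minus the
    increment times the unfinished fraction of the stage."""
    if not 0 <= seconds_remaining < stage_s:
        raise ValueError("seconds_remaining must lie in [0, stage length)")
    if last_stage_power < 100:
        raise ValueError("ramp stages start at 100 W")
    return float(last_stage_power - increment * seconds_remaining / stage_s)


def compute_levels(anchors: SubjectAnchors) -> dict[str, float]:
    """Seven intermittent power levels (W) from the four anchors."""
    if not (anchors.P_LT1 <= anchors.P_OBLA <= anchors.P_VO2peak
            <= anchors.P_max):
        raise ValueError("anchors must be ordered "
                         "P_LT1 <= P_OBLA <= P_VO2peak <= P_max")
    a = anchors
    return {
        "L4.2": a.P_VO2peak + 0.50 * (a.P_max - a.P_VO2peak),
        "L4.3": a.P_VO2peak + 0.25 * (a.P_max - a.P_VO2peak),
        "L3": a.P_OBLA + 0.60 * (a.P_VO2peak - a.P_OBLA),
        "L2": a.P_LT1 + 0.60 * (a.P_OBLA - a.P_LT1),
        "L1": 0.85 * a.P_LT1,
        "AR": 0.50 * a.P_LT1,
        "PR": 0.0,
    }


def build_timeline(spec: ProtocolSpec, levels: dict[str, float],
                   exhaustion_time: float | None = None) -> TrialSeries:
    """Piecewise-constant power trace at 0.5 Hz for a protocol.

    ``exhaustion_time`` is the duration (s) of the open-ended segment and is
    required when the spec contains one. Segment boundaries are recorded for
    downstream power smoothing and day-to-day metrics. The ventilation
    channel is returned as zeros (filled by measurement or the synthetic
    generator).
    """
    if spec.has_open_ended and exhaustion_time is None:
        raise ValueError(f"protocol {spec.name} needs an exhaustion time")
    durations = []
    for seg in spec.segments:
        durations.append(exhaustion_time if seg.open_ended else seg.duration)
    total = float(sum(durations))
    n = int(round(total / GRID_DT)) + 1
    t = np.arange(n) * GRID_DT
    u1 = np.zeros(n)
    boundaries = []
    t0 = 0.0
    for seg, dur in zip(spec.segments, durations):
        m = (t >= t0 - 1e-9) & (t < t0 + dur - 1e-9)
        u1[m] = levels[seg.level]
        t0 += dur
        boundaries.append(t0)
    u1[-1] = levels[spec.segments[-1].level]
    return TrialSeries(t=t, u1=u1, u2=np.zeros(n),
                       segment_boundaries=boundaries[:-1])


def _spec(name, *segs):
    return ProtocolSpec(name=name, segments=tuple(
        Segment(level=lv, duration=d, open_ended=(d is None)) if d is not None
        else Segment(level=lv, duration=1.0, open_ended=True)
        for lv, d in segs))


#: Illustrative fitting-style protocol: submaximal steps with active-rest
#: interludes, a supra-maximal block, an open-ended top step and a 180 s
#: concluding period. Segment durations are package defaults, not a
#: reproduction of any measured protocol.
P2_LIKE = _spec(
    "P2-like",
    ("PR", 200.0), ("L1", 300.0), ("AR", 120.0), ("L2", 240.0),
    ("PR", 300.0), ("L3", 90.0), ("AR", 120.0), ("L2", 120.0),
    ("L4.2", None), ("L2", 180.0),
)

#: Validation-style counterpart: the first six periods match the fitting
#: protocol (they feed the day-to-day comparison), then it diverges and the
#: open-ended final level differs.
P3_LIKE = _spec(
    "P3-like",
    ("PR", 200.0), ("L1", 300.0), ("AR", 120.0), ("L2", 240.0),
    ("PR", 300.0), ("L3", 90.0), ("PR", 240.0), ("L4.2", 45.0),
    ("AR", 120.0), ("L4.3", None), ("AR", 180.0),
)
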