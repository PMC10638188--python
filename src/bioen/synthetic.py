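"""Synthetic subjects, incremental tests and intermittent trials.

No measured data ships with the package, so every stage — anchors, power
levels, protocol timelines, ventilation and noisy measured MR_ae — can be
generated with the statistical structure the estimation assumes. The
ventilation generator is wholly synthetic (in a real trial u2 is measured):
a first-order lag toward a Hill-type saturating function of metabolic
demand, bounded by the individual maximum ventilation. Demand and
ventilation form a loop (MR_ve depends on u2, u2 tracks MR_dem), which is
closed by fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demand import DemandParams
from .simulator import ModelParams, simulate, SimResult
from .series import TrialSeries, GRID_DT
from .protocol import (SubjectAnchors, ProtocolSpec, compute_levels,
                       build_timeline, P2_LIKE, P3_LIKE)

__all__ = [
    "SyntheticConfig", "default_params", "generate_subject",
    "generate_trial", "generate_incremental", "SyntheticSubject",
]


def default_params() -> ModelParams:
    """Cohort-mean optimized parameter values used as ground truth."""
    return ModelParams(
        demand=DemandParams(
            A_f=158.0, B_f=2.96, A_ve=182.0, B_ve=0.93,
            A_acc=114.0, B_acc=0.97, VE_max=197.0,
            MR_rest=143.0, MR_lt=952.0),
        E_al_max=16300.0, tau_ae=25.8, tau_la=12.87, K=0.8,
        A_red=0.0048 * 41700.0, eta_al=0.41, V_m=41700.0,
        MR_ae_max=1649.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the generator.

    ``noise_sd`` (W) matches the magnitude of typical fitting-trial
    model-measurement RMSE, so recovery tests run at realistic
    signal-to-noise. The ventilation model parameters (rest level, maximum,
    half-saturation demand, Hill exponent, lag) are synthetic-only plumbing.
    """

    noise_sd: float = 60.0
    ve_rest: float = 12.0       # L/min at seated rest
    ve_max: float = 197.0       # L/min, cohort-style maximum
    ve_half_demand: float = 900.0  # W above rest at half ventilation rise
    ve_hill: float = 2.0
    tau_ve: float = 30.0        # s, ventilation lag
    exhaustion_range: tuple[float, float] = (190.0, 240.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.ve_rest >= self.ve_max:
            raise ValueError("ve_rest must be below ve_max")


@dataclass
class SyntheticSubject:
    anchors: SubjectAnchors
    levels: dict[str, float]
    fitting_spec: ProtocolSpec
    validation_spec: ProtocolSpec
    params: ModelParams


def generate_subject(config: SyntheticConfig | None = None,
                     seed: int = 0) -> SyntheticSubject:
    """Draw one physiologically ordered subject.

    Anchors are drawn as positive power increments around cohort-style means
    (P_LT1 about 200 W, then +60, +80, +80 W), which guarantees the ordering
    P_LT1 < P_OBLA < P_VO2peak < P_max; non-positive increments are redrawn.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)

    def draw_pos(mean, sd, lo):
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if v > lo:
                return v
        raise RuntimeError("rejection sampling failed")  # pragma: no cover

    p_lt1 = draw_pos(195.0, 15.0, 130.0)
    p_obla = p_lt1 + draw_pos(60.0, 10.0, 10.0)
    p_vo2 = p_obla + draw_pos(135.0, 15.0, 20.0)
    p_max = p_vo2 + draw_pos(45.0, 10.0, 10.0)
    baseline = float(np.clip(rng.normal(1.0, 0.15), 0.6, 1.6))
    anchors = SubjectAnchors(P_LT1=p_lt1, P_OBLA=p_obla, P_VO2peak=p_vo2,
                             P_max=p_max, bla_baseline=baseline)
    levels = compute_levels(anchors)
    # Tie the subject's metabolic-rate thresholds to the drawn anchors, as
    # they are derived from that subject's measurements in a real study:
    # MR_lt is the demand at P_LT1 (modest ventilation); MR_ae_max the
    # steady-state demand at the top intermittent level with a mid-range
    # metabolite load (x4 = 0.55) and the generator's own ventilation
    # response. The final push then rides at the aerobic ceiling, and the
    # sustained lactic contribution is driven by the accumulated-metabolite
    # feedback beyond that reference load, pushing x4 toward 1 at
    # exhaustion.
    base = default_params()
    d = base.demand
    mr_lt = d.MR_rest + d.A_f + d.B_f * p_lt1 + 0.25 * d.A_ve
    x4_ref = 0.45
    dem = d.MR_rest + d.A_f + d.B_f * levels["L4.2"]
    for _ in range(30):  # demand-ventilation fixed point at L4.2
        excess = max(dem - d.MR_rest, 0.0)
        sat = excess ** config.ve_hill / (
            excess ** config.ve_hill
            + config.ve_half_demand ** config.ve_hill)
        r = (config.ve_rest
             + (config.ve_max - config.ve_rest) * sat) / config.ve_max
        dem = (d.MR_rest + d.A_f + d.B_f * levels["L4.2"]
               + d.A_ve * (d.B_ve * r + (1 - d.B_ve) * r * r)
               + d.A_acc * (d.B_acc * x4_ref
                            + (1 - d.B_acc) * x4_ref * x4_ref))
    params = base.with_updates(MR_lt=mr_lt, MR_ae_max=dem)
    return SyntheticSubject(
        anchors=anchors, levels=levels, fitting_spec=P2_LIKE,
        validation_spec=P3_LIKE, params=params)


def _ventilation_response(t, mr_dem, config: SyntheticConfig,
                          mr_rest: float) -> np.ndarray:
    """First-order lag toward a saturating (Hill) function of demand."""
    d = np.maximum(mr_dem - mr_rest, 0.0)
    h = config.ve_hill
    sat = d ** h / (d ** h + config.ve_half_demand ** h)
    target = config.ve_rest + (config.ve_max - config.ve_rest) * sat
    u2 = np.empty_like(target)
    u2[0] = config.ve_rest
    dt = float(t[1] - t[0])
    a = dt / config.tau_ve
    for i in range(1, t.size):
        u2[i] = u2[i - 1] + a * (target[i] - u2[i - 1])
    return u2


def generate_trial(subject: SyntheticSubject,
                   params: ModelParams | None = None,
                   config: SyntheticConfig | None = None,
                   seed: int = 0,
                   spec: ProtocolSpec | None = None,
                   exhaustion_time: float | None = None,
                   apply_trims: bool = True):
    """Forward-simulate one intermittent trial with noisy measured output.

    Returns ``(trial, truth, t_exhaust)``: a :class:`TrialSeries` with the
    noisy measured ``y``, the noise-free :class:`SimResult` on the same
    grid, and the exhaustion time (s; end of the open-ended segment, None
    for fully closed protocols). The demand–ventilation loop is
    iterated to a fixed point (tolerance 1 W on MR_dem, at most 5 passes).
    With ``apply_trims`` the first 100 s and last 60 s are removed, as the
    preprocessing pipeline would.
    """
    params = params or subject.params
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    spec = spec or subject.fitting_spec
    if exhaustion_time is None and spec.has_open_ended:
        lo, hi = config.exhaustion_range
        exhaustion_time = float(
            GRID_DT * round(rng.uniform(lo, hi) / GRID_DT))
    timeline = build_timeline(spec, subject.levels, exhaustion_time)
    params = params.with_updates(VE_max=config.ve_max)

    t = timeline.t
    u2 = np.full(t.size, config.ve_rest)
    mr_dem_prev = None
    sim = None
    for _ in range(5):
        trial = TrialSeries(t=t, u1=timeline.u1, u2=u2,
                            segment_boundaries=timeline.segment_boundaries)
        sim = simulate(trial, params)
        if mr_dem_prev is not None and \
                np.max(np.abs(sim.MR_dem - mr_dem_prev)) <= 1.0:
            break
        mr_dem_prev = sim.MR_dem
        u2 = _ventilation_response(t, sim.MR_dem, config,
                                   params.demand.MR_rest)
    else:
        raise RuntimeError(
            "demand-ventilation fixed point did not converge; "
            "check the ventilation configuration")

    y = sim.y + rng.normal(0.0, config.noise_sd, size=t.size) \
        if config.noise_sd > 0 else sim.y.copy()

    # exhaustion occurs at the end of the open-ended segment
    t_exhaust = None
    if spec.has_open_ended:
        idx = [i for i, s in enumerate(spec.segments) if s.open_ended][0]
        bounds = [0.0, *timeline.segment_boundaries, t[-1]]
        t_exhaust = bounds[idx + 1]

    if apply_trims:
        keep = (t >= t[0] + 100.0 - 1e-9) & (t <= t[-1] - 60.0 + 1e-9)
        sb = [b for b in timeline.segment_boundaries
              if t[keep][0] < b < t[keep][-1]]
        trial = TrialSeries(t=t[keep], u1=timeline.u1[keep], u2=u2[keep],
                            y=y[keep], segment_boundaries=sb)
        truth = _mask_result(sim, keep)
    else:
        trial = TrialSeries(t=t, u1=timeline.u1, u2=u2, y=y,
                            segment_boundaries=timeline.segment_boundaries)
        truth = sim
    return trial, truth, t_exhaust


def _mask_result(sim: SimResult, keep: np.ndarray) -> SimResult:
    return SimResult(**{
        name: getattr(sim, name)[keep] if name != "x" else sim.x[keep]
        for name in ("t", "u1", "u2", "x", "y", "MR_al", "MR_la", "MR_ae",
                     "MR_sup", "MR_dem", "MR_f", "MR_ve", "MR_acc",
                     "residual")})


def generate_incremental(subject: SyntheticSubject,
                         config: SyntheticConfig | None = None,
                         seed: int = 0,
                         lactate_noise_sd: float = 0.12):
    """Synthetic submaximal incremental records for round-trip testing.

    Stage powers follow 80 + 20k W. Blood lactate is generated exactly from
    a cubic ``conc(P) = baseline + ((P - 80)/s)**3`` whose scale ``s`` is
    set so the curve crosses 4 mmol·L⁻¹ at the subject's P_OBLA; the implied
    P_LT1 of that curve (generally different from the subject's drawn
    anchor) is returned alongside so threshold recovery can be checked
    against the generating curve. VO2 is linear in power
    (``VO2 = (P + 30)/75`` L·min⁻¹). ``lactate_noise_sd`` is the
    duplicate-sample typical error of the measurement (0.12 mmol·L⁻¹).

    Returns a dict with stage powers, lactate, VO2, and the implied
    anchors/curve.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    baseline = subject.anchors.bla_baseline
    scale = (subject.anchors.P_OBLA - 80.0) / (4.0 - baseline) ** (1.0 / 3.0)
    top = subject.anchors.P_VO2peak
    powers = np.arange(80.0, top + 1e-9, 20.0)
    conc_true = baseline + ((powers - 80.0) / scale) ** 3
    concs = conc_true + rng.normal(0.0, lactate_noise_sd, powers.size)
    vo2_true = (powers + 30.0) / 75.0
    vo2 = vo2_true + rng.normal(0.0, 0.05, powers.size)
    implied_p_lt1 = 80.0 + scale * 0.2 ** (1.0 / 3.0)
    return {
        "power": powers,
        "bla": concs,
        "bla_true": conc_true,
        "vo2": vo2,
        "vo2_true": vo2_true,
        "baseline_true": baseline,
        "implied_P_LT1": implied_p_lt1,
        "implied_P_OBLA": float(subject.anchors.P_OBLA),
    }
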