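"""Breath-by-breath gas-exchange preprocessing.

Raw metabolic-cart records (irregular end-of-breath timestamps with
expiratory minute ventilation and expired O2/CO2 fractions) are converted to
the uniform 0.5 Hz series the model consumes:

1. inspiratory ventilation via the Haldane (nitrogen balance)
   transformation,
2. locally weighted linear smoothing of ventilations and gas fractions
   (centered 40 s time window, tricube weights),
3. autoregressive filling of mouthpiece-removal gaps,
4. oxygen uptake, CO2 output and RQ from the smoothed channels, and the
   aerobic metabolic rate MR_ae = (1.232 RQ + 3.8149) · VO2 · 4184/60,
5. removal of the first 100 s and last 60 s (smoothing edge effects) and
   linear resampling onto the 2 s grid,
6. per-segment mean smoothing of the 1 Hz ergometer power (sharp level
   transitions are preserved at segment boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .series import TrialSeries, GRID_DT

__all__ = [
    "AmbientConditions", "haldane_inspiratory", "mr_ae_from_gas",
    "smooth_lowess", "fill_gaps", "trim_resample", "smooth_power",
    "preprocess_trial",
]

#: Ambient inspired-air fractions (dry atmospheric air).
FIO2 = 0.2093
FICO2 = 0.0004

TRIM_HEAD = 100.0  # s removed at the start
TRIM_TAIL = 60.0   # s removed at the end
LOWESS_WINDOW = 40.0  # s, centered


@dataclass(frozen=True)
class AmbientConditions:
    """Lab conditions for BTPS/STPD gas-volume conversion.

    Defaults are standard lab conditions (the conversion is only needed when
    one of the two ventilation conventions is missing from the raw file).
    """

    pressure_mmHg: float = 760.0
    body_temp_C: float = 37.0

    @property
    def btps_to_stpd(self) -> float:
        ph2o = 47.0  # saturated water vapour pressure at 37 C, mmHg
        return ((self.pressure_mmHg - ph2o) / 760.0
                * 273.15 / (273.15 + self.body_temp_C))


def haldane_inspiratory(ve_exp, fio2: float = FIO2, fico2: float = FICO2,
                        feo2=None, feco2=None):
    """Inspiratory minute ventilation from the nitrogen balance.

    ``VI = VE_exp * (1 - FeO2 - FeCO2) / (1 - FiO2 - FiCO2)``. Inputs may be
    scalars or arrays; ventilations in L·min⁻¹, fractions in (0, 1).
    """
    ve_exp = np.asarray(ve_exp, dtype=float)
    feo2 = np.asarray(feo2, dtype=float)
    feco2 = np.asarray(feco2, dtype=float)
    for name, frac in (("FiO2", fio2), ("FiCO2", fico2)):
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"{name} outside [0, 1)")
    if np.any(feo2 <= 0.0) or np.any(feo2 >= 1.0) or np.any(feco2 < 0.0) \
            or np.any(feco2 >= 1.0):
        raise ValueError("expired fractions must lie in (0, 1)")
    fn2_i = 1.0 - fio2 - fico2
    if fn2_i <= 0.0:
        raise ValueError("inspired nitrogen fraction must be positive")
    out = ve_exp * (1.0 - feo2 - feco2) / fn2_i
    return float(out) if out.ndim == 0 else out


def mr_ae_from_gas(vo2, rq):
    """Aerobic metabolic rate (W) from oxygen uptake and RQ.

    ``MR_ae = (1.232 RQ + 3.8149) * VO2 * 4184/60`` with VO2 in L·min⁻¹ STPD
    and RQ the nonprotein respiratory quotient. The caloric-equivalent line
    is affine in RQ; 4184/60 converts kcal·min⁻¹ to W.
    """
    vo2 = np.asarray(vo2, dtype=float)
    rq = np.asarray(rq, dtype=float)
    if np.any(vo2 < 0.0):
        raise ValueError("VO2 must be non-negative")
    if np.any((rq < 0.7) | (rq > 1.3)):
        warnings.warn("RQ outside the physiological 0.7-1.3 band",
                      stacklevel=2)
    out = (1.232 * rq + 3.8149) * vo2 * 4184.0 / 60.0
    return float(out) if out.ndim == 0 else out


def smooth_lowess(t, values, window: float = LOWESS_WINDOW) -> np.ndarray:
    """Locally weighted linear regression over a centered time window.

    At each timestamp a weighted straight line is fitted to the samples
    within ``window/2`` seconds (tricube weights on time distance, window
    truncated at the record edges) and evaluated there. Exact for constant
    and linear signals. NaN samples are ignored in the fits and smoothed
    values at NaN locations remain NaN (fill gaps afterwards).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 5:
        raise ValueError("need at least five samples")
    if t[-1] - t[0] <= window:
        raise ValueError("record shorter than the smoothing window")
    half = window / 2.0
    out = np.full_like(v, np.nan)
    finite = np.isfinite(v)
    for i in range(t.size):
        if not finite[i]:
            continue
        m = (np.abs(t - t[i]) <= half) & finite
        tt, vv = t[m], v[m]
        d = np.abs(tt - t[i]) / half
        w = (1.0 - np.minimum(d, 1.0) ** 3) ** 3
        w[np.abs(tt - t[i]) < 1e-12] = np.maximum(
            w[np.abs(tt - t[i]) < 1e-12], 1e-6)
        sw = w.sum()
        tm = (w * tt).sum() / sw
        vm = (w * vv).sum() / sw
        dt = tt - tm
        den = (w * dt * dt).sum()
        if den <= 1e-30:
            out[i] = vm
        else:
            slope = (w * dt * (vv - vm)).sum() / den
            out[i] = vm + slope * (t[i] - tm)
    return out


MAX_GAP_S = 30.0  # mouthpiece removals are < 30 s by protocol
_SHORT_GAP_S = 4.0


def fill_gaps(values: np.ndarray, t=None, max_order: int = 16) -> np.ndarray:
    """Fill NaN runs by forward/backward autoregressive extrapolation.

    The AR order is selected by AIC up to ``max_order`` on the flanking
    segments; forecasts from both sides are cross-faded linearly across the
    gap, which keeps the fill continuous at both edges. Gaps shorter than
    4 s (or with too little flanking data) fall back to linear
    interpolation. Gaps longer than 30 s are filled anyway with a warning.
    Returns the input unchanged (same array values) when there are no gaps.
    """
    v = np.asarray(values, dtype=float).copy()
    isnan = ~np.isfinite(v)
    if not isnan.any():
        return v
    t = np.arange(v.size, dtype=float) if t is None else np.asarray(t, float)
    # locate NaN runs
    idx = np.flatnonzero(isnan)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        lo, hi = run[0], run[-1]
        gap_s = t[min(hi + 1, v.size - 1)] - t[max(lo - 1, 0)]
        if gap_s > MAX_GAP_S:
            warnings.warn(f"gap of {gap_s:.0f} s exceeds the {MAX_GAP_S:.0f} s"
                          " protocol limit; filling anyway", stacklevel=2)
        left = v[:lo][np.isfinite(v[:lo])]
        right = v[hi + 1:][np.isfinite(v[hi + 1:])]
        n = run.size
        if gap_s < _SHORT_GAP_S or left.size < 8 or right.size < 8:
            a = left[-1] if left.size else right[0]
            b = right[0] if right.size else left[-1]
            v[lo:hi + 1] = np.linspace(a, b, n + 2)[1:-1]
            continue
        fwd = _ar_forecast(left, n, max_order)
        bwd = _ar_forecast(right[::-1], n, max_order)[::-1]
        w = np.linspace(1.0, 0.0, n + 2)[1:-1]
        v[lo:hi + 1] = w * fwd + (1.0 - w) * bwd
    return v


def _ar_forecast(segment: np.ndarray, n: int, max_order: int) -> np.ndarray:
    """n-step-ahead AR forecast from the tail of ``segment``."""
    seg = segment[-min(segment.size, 300):]
    if np.ptp(seg) < 1e-12:  # constant flank: AR fit is singular
        return np.full(n, seg[-1])
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    order = min(max_order, seg.size // 3)
    try:
        sel = ar_select_order(seg, maxlag=order, ic="aic", old_names=False)
        lags = sel.ar_lags or [1]
        res = AutoReg(seg, lags=lags, old_names=False).fit()
        fc = res.predict(start=seg.size, end=seg.size + n - 1)
        if np.all(np.isfinite(fc)):
            return np.asarray(fc)
    except Exception:  # singular fits on degenerate flanks
        pass
    return np.full(n, seg[-1])


def trim_resample(t, *channels, head: float = TRIM_HEAD,
                  tail: float = TRIM_TAIL):
    """Drop the first ``head`` s and last ``tail`` s, resample to 2 s grid.

    Returns ``(t_grid, ch1_grid, ch2_grid, ...)`` with linear interpolation
    of each channel onto the uniform grid spanning
    ``[t[0] + head, t[-1] - tail]``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    span = t[-1] - t[0]
    if span <= head + tail:
        raise ValueError(f"record of {span:.0f} s is too short to trim "
                         f"{head:.0f}+{tail:.0f} s")
    t0, t1 = t[0] + head, t[-1] - tail
    n = int(np.floor((t1 - t0) / GRID_DT)) + 1
    tg = t0 + np.arange(n) * GRID_DT
    out = [tg]
    for ch in channels:
        out.append(np.interp(tg, t, np.asarray(ch, dtype=float)))
    return tuple(out)


def smooth_power(t, power, segment_boundaries) -> np.ndarray:
    """Replace each protocol segment of the power trace by its mean.

    Boundaries are times (s) of level switches; transitions stay sharp. The
    per-segment mean preserves the work integral of each segment.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(power, dtype=float).copy()
    edges = [t[0] - 1e-9, *sorted(segment_boundaries), t[-1] + 1e-9]
    for a, b in zip(edges[:-1], edges[1:]):
        m = (t >= a) & (t < b)
        if not m.any():
            raise ValueError(f"empty protocol segment [{a:.0f}, {b:.0f}) s")
        p[m] = p[m].mean()
    return p


def preprocess_trial(breath_t, ve_btps, ve_stpd, feo2, feco2,
                     power_t, power, segment_boundaries,
                     ambient: AmbientConditions | None = None) -> TrialSeries:
    """Full pipeline from raw records to a model-ready :class:`TrialSeries`.

    ``breath_*`` are irregular end-of-breath samples; ``power_t``/``power``
    the 1 Hz ergometer trace. Channels with NaNs (mouthpiece removal) are
    smoothed first (NaNs ignored) and then gap-filled.
    """
    ve_btps_s = fill_gaps(smooth_lowess(breath_t, ve_btps), t=breath_t)
    ve_stpd_s = fill_gaps(smooth_lowess(breath_t, ve_stpd), t=breath_t)
    feo2_s = fill_gaps(smooth_lowess(breath_t, feo2), t=breath_t)
    feco2_s = fill_gaps(smooth_lowess(breath_t, feco2), t=breath_t)

    vi_stpd = haldane_inspiratory(ve_stpd_s, feo2=feo2_s, feco2=feco2_s)
    vo2 = FIO2 * vi_stpd - feo2_s * ve_stpd_s
    vco2 = feco2_s * ve_stpd_s - FICO2 * vi_stpd
    rq = vco2 / np.maximum(vo2, 1e-9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # transient RQ excursions at onset
        y = mr_ae_from_gas(np.maximum(vo2, 0.0), rq)

    tg, u2, yg = trim_resample(breath_t, ve_btps_s, y)
    p_sm = smooth_power(power_t, power, segment_boundaries)
    u1 = np.interp(tg, power_t, p_sm)
    bounds = [b for b in segment_boundaries if tg[0] < b < tg[-1]]
    return TrialSeries(t=tg, u1=u1, u2=u2, y=yg, segment_boundaries=bounds)
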