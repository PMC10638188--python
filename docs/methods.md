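# Methods

## The model

`bioen` implements a dynamic bioenergetic supply/demand model of
intermittent ergometer cycling. Energy conservation requires the total
metabolic supply rate to equal the total metabolic demand rate at every
instant; both are expressed in watts.

**Demand** is the sum of four components:

* `MR_rest` — seated-rest metabolism excluding ventilation;
* `MR_f = A_f + B_f·u1` — the fundamental cost of pedalling at power `u1`,
  defined as exactly 0 at zero power (passive rest), which makes the
  component discontinuous at `u1 = 0`; any `|u1| < 0.5 W` is treated as
  passive rest since protocol power is piecewise constant after smoothing
  and ergometer noise sits below that floor;
* `MR_ve = A_ve·(B_ve·r + (1−B_ve)·r²)`, `r = u2/V̇E,max` — the cost of
  pulmonary ventilation, a blend of a linear and a quadratic response in
  minute ventilation normalized by the individual maximum, so that
  `MR_ve(V̇E,max) = A_ve` (the "maximum demand due to ventilation"
  interpretation of `A_ve`). A `literal_quadratic` switch evaluates the
  quadratic term as `u2²/V̇E,max` instead, for comparison with sources that
  print the un-normalized form; it is not the default because it breaks the
  `A_ve`-as-maximum property and is dimensionally inconsistent;
* `MR_acc = A_acc·(B_acc·x4 + (1−B_acc)·x4²)` — extra demand attributed to
  accumulated muscle metabolites, with the normalized muscle-lactate proxy
  `x4` standing in for the metabolite pool.

Inputs above the nominal maxima (`u2 > V̇E,max`, `x4 > 1`) are evaluated
as-is rather than clamped: both occur legitimately when a model fitted on
one trial is applied to a harder one.

**Supply** is a four-state ODE. With residual
`r1 = MR_dem − MR_rest − x3 − x2`:

```
x1' = r1 / E_al,max          x1' < 0 ⇒ x1' ·= η_al
x2' = r1 / τ_la − K·x3'      x2 = 0 and x2' < 0 ⇒ x2' = 0
x3' = (MR_dem − MR_rest − x3) / τ_ae
                             x3 = MR_ae,max − MR_rest and x3' > 0 ⇒ x3' = 0
x4' = (x2 − A_red·Z_dem·x4) / V_m
```

`x3` is the primary aerobic component (modeled aerobic rate
`MR_ae = MR_rest + x3`, a mono-exponential response without time delay);
`x2` is the lactic (lactate-accumulating glycolytic) rate, dampened by `K`
times the aerobic rate of change and floored at zero; `x1` is the
fractional depletion of the alactic (phosphocreatine) store, which closes
the energy balance instantaneously — whenever `r1 ≥ 0`, alactic + lactic +
aerobic supply equals demand identically. During recovery (`r1 < 0`) only
the fraction `η_al` of the energy diverted to the store is banked (the
hysteresis cost of resynthesis), and the reported alactic supply `MR_al`
is zero: the conservation identity is asserted only on nodes with
non-negative residual. Muscle lactate `x4` accumulates at `x2/V_m` and is
cleared at a rate proportional to `A_red·x4` gated by the demand factor
`Z_dem`, which falls linearly from 1 at `MR_rest` to 0 at the
lactate-threshold rate `MR_lt` — above threshold no net clearance occurs.

Units: the store constants `E_al,max`, `V_m` and `A_red` are kept in
joules (watt-second bookkeeping), so the nominal alactic capacity is
21 000 J before individualization and `A_red` is resolved from its
percentage-of-`V_m` form at load time. `K = 0.8` is a fixed constant.

## Numerical integration

The right-hand side is discontinuous (state floors/caps, the efficiency
switch, piecewise-constant power), which defeats the error control of
adaptive stiff solvers. The integrator is therefore a fixed-step explicit
fourth-order Runge–Kutta scheme with 0.25 s substeps aligned to the 0.5 Hz
input grid (eight substeps per node interval), with the conditions applied
inside every derivative evaluation plus a post-substep clamp of `x2` at 0,
`x3` at its cap and `x4` at 0 to remove truncation overshoot. Power is
held piecewise constant over each node interval; ventilation is
interpolated linearly. Correctness is asserted by a closed-form check
(mono-exponential step response matched to <0.1% at every node) and a
grid-convergence check (halving the substep moves the output by <0.5 W
everywhere). The core loop is compiled with numba.

Initial state is rest equilibrium `(0, 0, 0, 0)` at the start of the
initial passive-rest period; trials begin from seated rest. Fitting is
done on the trimmed series (which starts ~100 s into that rest), where the
carried-over state is negligible (<5 W² objective contribution).

## Individualization

Fourteen parameters are estimated per subject by penalized least squares
against measured `MR_ae` on the fitting trial: `τ_ae`, `MR_rest`, `MR_lt`,
`MR_ae,max`, `A_f`, `B_f`, `A_ve`, `B_ve`, `A_acc`, `B_acc`, `A_red`,
`η_al`, `V_m`, `τ_la`. `V̇E,max` is fixed to the maximum measured
ventilation of the fitting trial and `K` to 0.8. Bounds follow the
standard table; percentage-form bounds (`MR_lt`, `MR_ae,max` relative to
their data-driven initials; `A_ve`, `A_acc` relative to the `MR_ae,max`
initial; `A_red`, `V_m` relative to the `V_m` initial) are resolved to
absolute values once at spec construction. For `V_m`, which has two
initial values, the percentage reference is the mean of the two.

Two soft constraints shape the objective:

* a **feasibility barrier**: modeled `MR_ae` is multiplied by
  `1 + exp((m−1)/0.02) − exp(−2.5)` for `m = max(x1, x4) > 0.95` (factor 1
  below), so the residual explodes as either normalized state approaches
  its feasible maximum of 1. The barrier is applied to `x1` and `x4`, the
  two states defined on a 0–1 range; the only feasible bound on `x2`
  (non-negativity) is already enforced by the ODE floor.
* an **exhaustion constraint**: the muscle-lactate proxy must exceed 0.85
  throughout the final 100 s before exhaustion on the fitting trial;
  violations add `4·10⁶ × mean(shortfall²)` W² to the objective, a weight
  at which a shortfall of 0.05 (10⁴ W²) dominates a typical fit MSE of a
  few thousand W².

Each start runs a bounded trust-region-reflective least-squares fit
(scipy `least_squares`, `ftol = xtol = 1e-8`, per-start budget of 400
function evaluations, finite-difference Jacobian with relative step 1e-6,
parameters scaled by their initial magnitudes). The multi-start grid is
the Cartesian product of the per-parameter initial lists — two values for
each of `A_f`, `A_acc`, `A_red`, `η_al`, `V_m`, `τ_la`, hence 64 starts —
and the arg-min over starts is returned. A failed simulation maps to a
large finite residual so the remaining starts continue. The procedure is
deterministic given the trial and spec.

**Post-hoc adjustment.** The alactic capacity is excluded from the
optimizer (the store is a pure buffer: `x1` feeds back into nothing), held
at its nominal 21 kJ during fitting, and afterwards rescaled to that value
times the achieved maximum of `x1`. Because the `x1` trajectory is exactly
inversely proportional to `E_al,max`, re-simulating the fitting trial then
yields `max x1 = 1` to machine precision — the package asserts 1e-6.

Data-driven initials used by the pipeline: `MR_ae,max` from the maximum
60 s rolling mean of measured `MR_ae`; `MR_rest` from the first 30 s of
the (trimmed) trial, clipped to [70, 220] W; `MR_lt` as 0.58 of the
`MR_ae,max` initial, a mid-range threshold fraction for trained cyclists
(the ±30% bounds make the fit insensitive to this choice).

## Incremental-test anchors

The lactate baseline is the running mean of the first two stage
concentrations, extended while the next value stays within 0.2 mmol·L⁻¹
(the rounded duplicate-sample typical error, fixed rather than
recomputed); LT1 is baseline + 0.2, OBLA is 4 mmol·L⁻¹. Stage lactate vs
power is fitted by a least-squares cubic and inverted for the threshold
powers; when several real roots fall inside the observed power range
(extended 10% above), the smallest is taken — thresholds are
first-crossing definitions. `P_VO2peak` comes from an ordinary
least-squares line of power on V̇O2 over the submaximal stages, evaluated
at peak V̇O2 (regressing V̇O2 on metabolic rate cannot yield a power, so
the power-on-V̇O2 direction is used). `P_max` is the exhaustion-stage
power minus 40 W times the unfinished fraction of the minute. The seven
protocol levels follow the standard table (L4.2 = P_VO2peak + 50% of the
P_max reserve, down to AR = 50% of P_LT1, PR = 0 W).

## Preprocessing

Breath-by-breath records are processed in this order: Haldane (nitrogen
balance) inspiratory ventilation; locally weighted linear smoothing of
ventilations and gas fractions over a centered 40 s time window (tricube
weights, truncated at the record edges — exact for constants and straight
lines); autoregressive filling of mouthpiece-removal gaps (AR order by AIC
up to 16 on the flanking segments, forward and backward forecasts
cross-faded across the gap; gaps under 4 s or with thin flanks fall back
to linear interpolation; gaps over the 30 s protocol limit are filled with
a warning); V̇O2, V̇CO2 and RQ derived from the smoothed channels; the
caloric-equivalent conversion `MR_ae = (1.232·RQ + 3.8149)·V̇O2·4184/60`;
removal of the first 100 s and last 60 s (smoothing edge effects) and
linear resampling to the uniform 2 s grid. Ergometer power is smoothed by
replacing each protocol segment with its mean, which preserves per-segment
work and keeps transitions sharp. The window semantics (seconds, not
samples) and the tricube kernel are fixed choices recorded here; ambient
BTPS/STPD conversion factors default to standard lab conditions
(760 mmHg, 37 °C body temperature) and are configurable.

## Synthetic data

The generator exists so that every stage — anchors, protocols,
ventilation, estimation, validation — is exercisable without any measured
data. Per subject it draws ordered anchors as positive increments
(P_LT1 ≈ 195 ± 15 W, then +60, +135, +45 W), computes the level table, and
derives `MR_lt` and `MR_ae,max` from those anchors exactly as a study
derives them from that subject's own measurements: `MR_lt` as the demand
at `P_LT1`, and `MR_ae,max` as the self-consistent steady-state demand at
the top level L4.2 with a mid-range metabolite load (x4 = 0.45). The
remaining parameters are the cohort-mean optimized values. This coupling
keeps each synthetic subject internally consistent — the final push rides
at the aerobic ceiling, the sustained lactic contribution comes from the
metabolite-demand feedback, and the lactate proxy approaches 1 near
exhaustion while peak alactic depletion in fitting units stays near 0.8,
the regime the estimation's penalty structure assumes.

Ventilation is wholly synthetic (in a real trial it is measured): a
first-order lag (τ = 30 s) toward
`V̇E,rest + (V̇E,max − V̇E,rest)·sat(MR_dem − MR_rest)` with a Hill-type
saturating map (half-saturation 900 W, exponent 2), bounded by
V̇E,max = 197 L·min⁻¹. Because `MR_ve` depends on ventilation and
ventilation tracks demand, trial generation iterates the loop to a fixed
point (1 W tolerance on demand, at most 5 passes; it converges in 2–3).
Measured output is the modeled `MR_ae` plus Gaussian noise of SD 60 W,
the magnitude of typical fitting-trial model-measurement RMSE, so
recovery tests run at realistic signal-to-noise. At that noise level a
few rest nodes can fall below 50 W or zero — physically impossible for a
real metabolic cart but harmless here (the MAPE floor excludes them).

The default P2-like (fitting) and P3-like (validation) protocol layouts
are package inventions: ten segments each, a 200 s initial passive rest
(so the 100 s trim removes about half of it), submaximal steps with
passive/active-rest interludes, an L2 primer, an open-ended top-level
segment whose duration is drawn uniformly from 190–240 s, and a 180 s
concluding period (so the 60 s trim removes a third of it). The first six
periods of both protocols coincide, which is what the day-to-day
comparison metric consumes. Durations were chosen once, by forward
simulation under the default parameters, to satisfy the generator
contract above; they are illustrative, not reproductions of any measured
protocol. Exhaustion is imposed (drawn), not emergent: the model has no
intrinsic task-failure mechanism.

Incremental records are generated from an exact cubic
`conc(P) = baseline + ((P − 80)/s)³` with `s` set so the curve crosses
4 mmol·L⁻¹ at the subject's P_OBLA, stage noise of 0.12 mmol·L⁻¹ (the
duplicate-sample typical error), and V̇O2 linear in power. On such a
smoothly rising curve the running-mean baseline rule includes part of the
early rise, so the estimated baseline sits up to ~0.07 mmol·L⁻¹ above the
generating constant; the threshold powers implied by the generating curve
are returned alongside so inversion can be tested independently of that
bias.

## Validation metrics

RMSE (W) and MAPE (%) on the time-resolved 0.5 Hz traces, with
measurement as the MAPE reference; Bland–Altman mean difference and
±1.96 SD limits of agreement with the measured-minus-modeled sign
convention (model underprediction is positive); a node-wise paired t
statistic across subjects on `MR_ae/MR_ae,max`, reported against the
naive two-tailed critical value with supra-threshold clusters —
random-field (smoothness-corrected) inference is deliberately out of
scope and every output is labelled uncorrected; and the day-to-day RMSE
between two trials of the last-60-s means (31 nodes) of the first six
shared periods. For group statistics, traces with open-ended final
periods are aligned by linear time-warping to a common node count.

## What passing tests do and do not show

The synthetic generator shares the supply model with the estimator, so
parameter-recovery results demonstrate the correctness and conditioning
of the estimation machinery under the model's own assumptions — additive
Gaussian noise, exact piecewise-constant power, a ventilation trace that
saturates smoothly. They do not demonstrate that the model captures real
gas-exchange dynamics: slow-component behavior beyond the demand
feedback, breath-by-breath noise structure, day-to-day physiological
drift and cadence effects are all absent from the generator. Recovery of
weakly identified parameters (`A_f` vs `MR_rest` vs `A_ve` apportionment,
`τ_la`, `MR_lt`) is correspondingly loose; the tested tolerances cover
the well-identified trio `τ_ae`, `MR_ae,max`, `B_f`.

## Problem sizes and runtimes

Default trials are ~2100 s (≈1050 nodes at 0.5 Hz); a simulation costs
under a millisecond, a 64-start fit about a minute on one CPU. The
parameter-recovery suite runs three seeded replicates at the full 64
starts; conservation is checked over 10³ random protocols.
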