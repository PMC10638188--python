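# bioen

Dynamic bioenergetic supply/demand modelling for intermittent ergometer
cycling.

`bioen` is for exercise physiologists and sports-science modellers who want
to decompose a cyclist's metabolism, breath by breath, into its alactic
(phosphocreatine), lactic (lactate-accumulating glycolytic) and aerobic
contributions — and to individualize that decomposition from nothing more
than ergometer power, minute ventilation and gas-exchange measurements of
aerobic metabolic rate.

## The model

Energy conservation, MR_dem = MR_sup, links a demand side

    MR_dem = MR_rest + MR_f(u1) + MR_ve(u2) + MR_acc(x4)

(resting metabolism; an affine cost of pedalling power u1 that vanishes at
passive rest; a linear/quadratic cost of minute ventilation u2 normalized
by the individual maximum V̇E,max; and a metabolite-accumulation cost
driven by the muscle-lactate proxy x4) to a four-state supply ODE

    ẋ1 = r1/E_al,max                      (× η_al when negative)
    ẋ2 = r1/τ_la − K·ẋ3                   (floored at x2 = 0)
    ẋ3 = (MR_dem − MR_rest − x3)/τ_ae     (capped at MR_ae,max − MR_rest)
    ẋ4 = (x2 − A_red·Z_dem·x4)/V_m

with residual r1 = MR_dem − MR_rest − x3 − x2. The aerobic component x3 is
a mono-exponential response; the lactic rate x2 is dampened by the aerobic
rate of change; the alactic store closes the balance instantly, so supply
equals demand exactly whenever the store is discharging; and muscle lactate
x4 accumulates from glycolysis and clears only below the lactate-threshold
rate MR_lt (demand factor Z_dem). Fourteen parameters are individualized by
64-start bounded trust-region least squares against measured MR_ae, with a
feasibility barrier on x1 and x4, an exhaustion constraint on x4, and a
post-hoc rescale of the alactic capacity that pins the peak depletion on
the fitting trial at exactly 1.

The package also computes the incremental-test anchors (lactate baseline,
LT1, OBLA via a cubic lactate–power fit, P_VO2peak, P_max) and the derived
protocol power levels; preprocesses raw breath-by-breath records (Haldane
transformation, 40 s locally weighted smoothing, autoregressive gap
filling, 100 s/60 s trimming, 0.5 Hz resampling, per-segment power
smoothing); scores agreement (RMSE, MAPE, Bland–Altman, uncorrected
pointwise paired t, day-to-day RMSE); and generates complete synthetic
subjects and trials so the whole chain runs without any measured data.

## Worked example

Fit a synthetic subject on its fitting trial and validate on a second,
similar protocol:

```python
from bioen.cli import run_pipeline

report = run_pipeline(seed=11)
print(round(report["fit_rmse_W"], 1), round(report["fit_mape_percent"], 1))
print(round(report["validation_rmse_W"], 1),
      round(report["validation_mape_percent"], 1))
print(round(report["max_x1_fitting"], 3), round(report["max_x4_fitting"], 3))
```

prints

```
59.3 9.4
61.1 11.7
1.0 0.951
```

Read: with 60 W of simulated measurement noise, the individualized model
matches the fitting trial at RMSE 59.3 W (MAPE 9.4%) — the noise floor —
and transfers to the unseen validation protocol at 61.1 W (11.7%). After
the post-hoc capacity rescale the alactic store depletes to exactly its
estimated maximum (x1 = 1.0) on the fitting trial, and the muscle-lactate
proxy peaks at 0.95, just below its feasible ceiling, as the exhaustion
constraint intends. The same run reports Bland–Altman limits of agreement
(−116.5 to 116.0 W, mean difference −0.3 W, 94% of nodes within) and the
fitted parameters themselves (for this seed: τ_ae = 25.3 s against a true
25.8 s, B_f = 2.82 against 2.96).

The same workflow is available from a shell:

```sh
bioen generate --seed 5 --subjects 1 --out data/
bioen fit --trial data/subject00_trial.csv --t-exhaust 1690 --out fit.json
bioen simulate --trial data/subject00_trial.csv --params params.yaml --out sim.csv
bioen evaluate --measured data/subject00_trial.csv --modeled sim.csv --report report.json
bioen pipeline --seed 11 --out run/
```

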