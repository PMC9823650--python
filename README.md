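# coflowmetry

Haemorheology from coflowing-microchannel blood-flow imagery: **viscosity**,
**viscoelastic time constant**, and **RBC aggregation index**, measured
periodically from a single square-wave flow experiment.

## The problem and who this is for

Blood's mechanical behaviour — its viscosity, how quickly its flow relaxes
when the driving pump stops, and how readily its red cells aggregate at
stasis — changes with haematocrit, RBC stiffness, and plasma composition,
and all three are clinically informative. A coflowing-microchannel
viscometer measures them with nothing but a microscope camera: a reference
fluid (1× PBS) and the test fluid (blood, or a calibration liquid such as
30 % glycerin) flow side by side in a shallow rectangular duct, and the
position of their interface encodes the viscosity ratio. Driving the test
pump with a square wave (on at `Q_t0`, off at 0, period `T`) yields, per
period: viscosity from the steady on-phase, the time constant from the
off-phase interface decay, and the aggregation index from the stasis image
intensity. This package is for microfluidics and haemorheology researchers
who want that whole analysis chain — including a forward simulator and a
synthetic-microscopy generator, so every estimator is testable without
laboratory data.

## The model

Each stream is a fluidic resistance of its share of the duct
(`R = 12µL/(w_side h³)`, virtual wall at the interface fraction
`β = w_t/(w_r+w_t)`), and the flexible tubing/device/fluid is an
equivalent compliance `C_e`. At steady coflow the equal-pressure condition
gives the viscometry relation

```
µ_t = µ_r · β/(1−β) · (Q_r/Q_t0) · α_R(β)
```

with `α_R(β)` an empirically calibrated linear correction (here
`α_R = 0.3038 β + 0.7935`). With the pump off, the compliance discharges
through the test stream and β obeys

```
λ(β) · d/dt[1/(1−β)] + α_R(β) · β/(1−β) = 0 ,    λ = 12µ_t L/(wh³) · C_e
```

The package does **not** assume λ constant: a central-difference inversion
of this balance yields a pointwise series λ(t_i), summarised by its
arithmetic mean ⟨λ⟩ and OLS slope dλ/dβ over a β window (default
[0.3, 0.7]). The aggregation index is the syllectogram area ratio
`AI = S_A/(S_A+S_B)` of the stasis intensity curve, and the shear-thinning
analysis uses `γ̇ = 6Q_b/(βwh²)` with a power-law fit `µ = µ0 γ̇^(n−1)`.

## Worked example

Simulate the glycerin calibration run (test fluid 2.977 cP, square wave
1 mL/h / 480 s, four periods) and analyse it back:

```
$ coflowmetry simulate --preset glycerin30 --out fixtures/glycerin
$ coflowmetry analyze --input fixtures/glycerin --out results/glycerin.csv
...
INFO coflowmetry: period 3: mu = 2.977 cP, <lambda> = 5.208 s, dlam/dbeta = -7.753 s, AI = nan
4 periods analyzed; pooled mu = 2.977 cP
```

The per-period table (`results/glycerin.csv`) reads

```
period,mu_cP,mu_sd,lam_mean_s,dlam_dbeta_s,R2_lambda,lambda_pm_s,AI,...
0,2.977,0.0,5.208,-7.753,0.99999,5.060,,...
```

Reading it: the steady-flow viscosity comes back at the generating
2.977 cP in every period; the off-phase estimator recovers the generating
time-constant line `λ = −7.6899β + 8.8902` to better than 1 % in slope
(−7.753 vs −7.6899, the residual being the O(dt²) bias of the 0.5 s
central difference); the constant-λ fit of earlier instruments
(`lambda_pm`) lands at 5.06 s — a single number that cannot show the
β-dependence; and AI is empty because glycerin contains no aggregating
cells, so the stasis intensity is flat and the index is undefined.
Aggregating scenarios (e.g. `--preset dex20`) fill the AI column.

Calibration of the correction line from (flow-ratio, β) measurements:

```
$ coflowmetry calibrate --config calibration.toml --out results/cal
alpha_R(beta) = 0.3236 beta + 0.7850 (R2 = 0.9065)
```

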