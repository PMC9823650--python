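# Methods

## Model

The instrument is modelled as a discrete fluidic circuit. Two streams
share a shallow rectangular coflow duct (width `w = 1 mm`, depth
`h = 50 µm`, coflow section `L = 3.5 mm` from the grounded outlet); each
stream is a resistance `R = 12µL/(w_side h³)` of the rectangle it would
occupy alone, with a virtual wall at the interface fraction β. The
low-aspect-ratio formula assumes `h/w ≤ 0.1`; geometries outside that
regime are accepted with a warning, since the correction factor absorbs
part of the error. No attempt is made to solve the 3-D Stokes problem of
the coflow — the rectangular-resistance approximation plus the empirical
correction line `α_R(β)` *is* the model, by design.

Equal pressures at the junction give the steady balance
`β/(1−β)·α_R(β) = (µ_t/µ_r)(Q_t/Q_r)`. The left side is strictly
increasing in β for every admissible correction line (positivity of α_R
on (0,1) implies monotonicity — a line steep enough to fold the map
already violates positivity and is rejected at construction), so the
steady interface is a unique bracketed root, solved by Brent's method to
machine tolerance.

Compliance (tubing, PDMS, fluid, trapped air) closes the transient:
`λ(β)·d/dt[1/(1−β)] + α_R(β)·β/(1−β) = (Q_t/Q_r)(µ_t/µ_r)` with
`λ = 12µ_t L/(wh³)·C_e`. An air cavity of volume `V_air` at ambient
pressure is linearized isothermally as `C_air = V_air/P_ref`
(`P_ref = 101 325 Pa`), added to `C_base`.

## Numerical choices

* **ODE integration.** Explicit fixed-step RK4, internal step
  `min(0.05 s, sampling_dt/10)` (0.01 s where a contract asks for a finer
  step). The off-phase equation is smooth and non-stiff for the λ values
  of interest (≥ 0.1 s), so no implicit scheme is needed. Steps that
  would leave the physical domain (0, 1) are halved; an underflowing step
  raises with a timestamp. β is *not* clamped: during a long off-phase it
  decays exponentially toward the reference-fluid wall and may become
  arbitrarily small while remaining strictly positive — a hard floor at,
  say, 10⁻⁶ would be crossed legitimately within ~100 s and is therefore
  not imposed.
* **Pointwise λ estimator.** The time derivative of `1/(1−β)` is replaced
  by a central difference on the 0.5 s camera grid, so estimates carry an
  O((dt/λ)²) bias — about 0.2 % for the glycerin profiles (λ ≈ 5 s) and a
  few per cent for the fastest blood profiles (λ ≈ 2 s). Samples whose
  central difference is below 10⁻¹² are emitted as NaN (masked), never as
  infinities, and excluded from summaries.
* **Summaries.** ⟨λ⟩ is the arithmetic mean over samples in the β window
  (the grid is uniform in time, so this is a time-weighted mean); dλ/dβ
  and the intercept come from unweighted OLS, with `R² = 1 − SS_res/SS_tot`.
  The default window [0.3, 0.7] reflects where the decay is well resolved:
  above 0.7 the interface has barely left the steady state, below 0.3 the
  shear rate drops out of the instrument's validated range.
* **Quasi-steady viscosity window.** The trailing half of each on-phase
  is accepted if the OLS trend of β across the window moves it by less
  than 0.002 in total. A per-sample successive-difference test was
  rejected: it trips on ordinary frame-to-frame jitter (sd ≈ 0.003) yet
  passes the slow ramp of a heavily compliant circuit, which is exactly
  the failure that must be caught. The trend test is noise-robust and
  flags the compliant case; when no period passes, the analysis reports
  the steady-window-not-found failure rather than a biased viscosity.
* **Previous-method fit.** `1/(1−β) = a1·exp(−t/λ_pm) + a2` by
  Levenberg–Marquardt with multi-start on λ (span/3 × {0.3, 1, 3}), best
  residual kept. Note that with a *unit* correction factor the off-phase
  solution is exactly this exponential (the logistic in β), so the
  previous method is unbiased there; the bias appears once α_R depends on
  β, which is why the pointwise estimator is preferred.
* **Aggregation index.** S_A and S_B are areas relative to the window
  extrema, integrated by the trapezoid rule over the full stasis window
  (the standard syllectogram convention); AI is invariant to affine
  intensity maps and time shifts by construction.

## Calibration

`calibrate_alpha` inverts the steady balance at each (flow-ratio, β)
point of a known-viscosity run and fits an OLS line. The four printed
reference points reproduce the published intercept to ~1 % and the slope
to ~7 %; the published line was evidently fitted on a larger set of
repeats, so the slope check is treated as a loose consistency property,
and the published line itself (`0.3038β + 0.7935`) ships as the default
correction model.

## Imaging

Interface extraction binarizes the ROI with Otsu's global threshold (the
two-phase histogram is bimodal; the reference method does not name its
binarization), then refines each transverse profile's crossing by linear
interpolation between the straddling pixels. Sub-pixel refinement is
needed to reach the ±0.006 β repeatability of the reference data at
500–1000 px channel widths. Lines with zero or multiple crossings are
rejected; fewer than 50 % valid lines raises. Blood is treated as the
dark phase under transmitted light by default; axis, side and polarity
are explicit per-dataset declarations. Velocimetry is a deliberately
minimal single-pass block matcher: per-block integer displacement by
maximum normalized cross-correlation within a search radius, parabolic
sub-pixel peak refinement, rejection below peak correlation 0.5. It is
accurate to ≲0.05 px on pure translations — sufficient for a mean
velocity — and makes no claim to resolve velocity fields.

## Synthetic data

The generator emulates the bench protocol: square wave 1 mL/h / 480 s /
duty 0.5 against a 1 mL/h reference, sampling at 0.5 s, four periods,
interface jitter sd 0.003, and a stasis intensity
`I_inf + (I0 − I_inf)·exp(−(t−t_off)/τ_agg)`. Presets: `glycerin30`
(2.977 cP, λ-line −7.6899β + 8.8902); `hct{30,40,50,60}` with viscosities
from the published Hct regression (0.0502·Hct + 0.2066 cP) and, since no
per-Hct λ line is published, the normal-blood line −3.4537β + 4.2013;
`ga{0,0.1,0.25}` with the three published hardened-cell λ lines and
viscosities chosen once (2.72/3.2/4.0 cP, the first matching the Hct-50
regression value); `dex{0..20}` with viscosities chosen once
(2.7–4.1 cP) and λ lines derived from the published viscosity→summary
regressions of the aggregation study, anchored at β = 0.5;
`vair{0,0.1,0.2}` with constant λ from the compliance model
(`C_base = 4.96 pm³/Pa` giving λ ≈ 5 s; the air term adds ≈1 s per
0.1 mL). The single-exponential intensity decay and the τ_agg ordering
(∞, 60, 30, 15, 8 s with increasing dextran) are synthetic conventions —
the reference data show the curves only graphically.

What passing tests therefore show: the estimators invert the *model* they
assume, at the sampling rate, noise level and program of the bench
protocol. What they do not show: robustness to optical artefacts
(meniscus shadows, uneven illumination), RBC sedimentation drift, pump
ripple, or any departure of real coflow physics from the lumped circuit.
Notably, the lumped air-cavity model predicts only a ~1–2 s λ increase
per 0.1 mL, far less than the bench observations with trapped air — the
effective resistance seen by a syringe-side cavity includes the whole
upstream tubing, which the single-resistance λ formula does not capture.
The steady-window failure mode of heavy compliance is exercised with an
explicitly large `C_base` instead.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `w, h, L` | 1 mm, 50 µm, 3.5 mm | m | reference device geometry |
| `µ_r` | 1.0 cP | Pa·s | 1× PBS, water-like at 25 °C |
| `α_R` | 0.3038β + 0.7935 | — | published calibration line |
| `Q_r, Q_t0, T, duty` | 1 mL/h, 1 mL/h, 480 s, 0.5 | | bench program |
| `sampling_dt` | 0.5 s | s | camera interval |
| β window | [0.3, 0.7] | — | resolved-decay range |
| drift tolerance | 0.002 | — | quasi-steady acceptance |
| β jitter sd | 0.003 | — | half-width of reported scatter |
| derivative mask | 10⁻¹² | s⁻¹ | flat-interface guard |

## Known limitations

* λ estimates inherit an O((dt/λ)²) bias; profiles with λ ≲ 1 s need a
  faster camera than the 0.5 s default.
* The aggregation model is single-exponential and unsigned; real
  syllectograms have a fast and a slow phase.
* The air-cavity compliance uses an isothermal lumped linearization (see
  above); it reproduces the direction of the effect, not its magnitude.
* Velocimetry is single-pass block matching; strong in-block shear
  degrades the correlation peak and near-wall blocks may be rejected.
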