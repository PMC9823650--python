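"""Inference procedures for the coflow viscometer.

Given an interface trace β(t) and a stasis intensity trace I_b(t), this
module recovers the three haemorheological properties:

* **viscosity** — from quasi-steady on-phase windows via the steady-state
  balance (``viscosity_steady``), after calibrating the resistance
  correction line α_R(β) (``calibrate_alpha``);
* **viscoelastic time constant** — pointwise from the off-phase decay by a
  central-difference inversion of the transient balance
  (``estimate_lambda_series``), summarised as the arithmetic mean ⟨λ⟩ and
  the slope dλ/dβ of an OLS line over a β window (``summarize_lambda``);
  the constant-λ exponential fit of earlier instruments is kept for
  comparison (``fit_lambda_prev``);
* **RBC aggregation index** — the syllectogram area ratio
  AI = S_A/(S_A + S_B) over the stasis window (``aggregation_index``).

Shear-rate evaluation and the power-law (shear-thinning) viscosity fit
complete the blood-analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .circuit import (
    ChannelGeometry,
    CorrectionModel,
    FlowProgram,
    InterfaceTrace,
    viscosity_from_interface,
)
from .exceptions import (
    DomainError,
    FitFailureError,
    GridError,
    InsufficientDataError,
    SteadyWindowNotFoundError,
    UndefinedAIError,
)

__all__ = [
    "IntensityTrace",
    "CalibrationPoint",
    "LambdaSeries",
    "LambdaSummary",
    "PrevMethodFit",
    "AggregationResult",
    "PowerLawFit",
    "SteadyViscosityResult",
    "calibrate_alpha",
    "estimate_lambda_series",
    "summarize_lambda",
    "fit_lambda_prev",
    "viscosity_steady",
    "aggregation_index",
    "shear_rate",
    "fit_power_law",
    "flow_rate_from_velocity",
    "segment_periods",
]

#: central differences with magnitude below this are treated as undefined
#: (masked) rather than producing huge or infinite λ
_DERIV_EPS = 1e-12

#: default β window for λ summaries: trends are reported between β = 0.7
#: and the low threshold β = 0.3
DEFAULT_BETA_WINDOW = (0.3, 0.7)


@dataclass
class IntensityTrace:
    """Mean microscope image intensity over the test channel, vs time."""

    times: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise DomainError("times and intensity must have equal length")
        if self.times.size < 3:
            raise InsufficientDataError("intensity trace needs >= 3 samples")
        if not np.all(np.isfinite(self.intensity)):
            raise DomainError("intensity values must be finite")


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration measurement: flow-rate ratio Q_t/Q_r and observed β."""

    flow_ratio: float
    beta: float

    def __post_init__(self):
        if self.flow_ratio <= 0:
            raise DomainError("flow_ratio must be positive")
        if not 0.0 < self.beta < 1.0:
            raise DomainError("beta must lie in (0, 1)")


@dataclass
class LambdaSeries:
    """Pointwise time-constant estimates λ(t_i) with their β(t_i).

    ``lam`` holds NaN where the central difference was below the masking
    threshold (the interface was locally flat).
    """

    times: np.ndarray
    beta: np.ndarray
    lam: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.lam)


@dataclass(frozen=True)
class LambdaSummary:
    """OLS summary of λ against β over a window: slope dλ/dβ, mean ⟨λ⟩."""

    slope: float
    intercept: float
    mean: float
    r_squared: float
    beta_window: tuple[float, float]
    n: int


@dataclass(frozen=True)
class PrevMethodFit:
    """Constant-λ exponential fit ``1/(1−β) = a1·exp(−t/λ_pm) + a2``."""

    a1: float
    a2: float
    lambda_pm: float
    residual_norm: float


@dataclass(frozen=True)
class AggregationResult:
    """Syllectogram areas above (S_A) and below (S_B) the stasis curve."""

    S_A: float
    S_B: float
    AI: float


@dataclass(frozen=True)
class PowerLawFit:
    """Shear-thinning power law ``µ = µ0·γ̇^(n−1)``."""

    mu0: float
    n: float
    r_squared: float


@dataclass(frozen=True)
class SteadyViscosityResult:
    """Per-period and pooled steady-flow viscosity, Pa·s.

    ``period_mean``/``period_sd`` are per analysed period (NaN for periods
    whose window failed the quasi-steady check); ``mean``/``sd`` pool the
    valid period means.
    """

    period_mean: np.ndarray
    period_sd: np.ndarray
    mean: float
    sd: float


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² of y on x (unweighted)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_alpha(
    points: list[CalibrationPoint], mu_ref_test: float, mu_r: float
) -> CorrectionModel:
    """Calibrate the resistance-correction line from known-viscosity runs.

    Each point is a flow-rate ratio and the interface it produced with a
    test fluid of known viscosity.  Inverting the steady-state balance gives
    the correction factor at that interface,

        α_R = (µ_ref_test/µ_r) · (1−β)/β · (Q_t/Q_r),

    and an ordinary-least-squares line α_R = slope·β + intercept is fitted.
    """
    if mu_ref_test <= 0 or mu_r <= 0:
        raise DomainError("viscosities must be positive")
    betas = np.array([p.beta for p in points], dtype=float)
    if np.unique(betas).size < 2:
        raise InsufficientDataError(
            "alpha_R calibration needs >= 2 points with distinct beta"
        )
    ratios = np.array([p.flow_ratio for p in points], dtype=float)
    alphas = (mu_ref_test / mu_r) * (1.0 - betas) / betas * ratios
    slope, intercept, r2 = _ols(betas, alphas)
    return CorrectionModel(slope=slope, intercept=intercept, r_squared=r2)


# ---------------------------------------------------------------------------
# time-constant estimation
# ---------------------------------------------------------------------------

def _check_uniform(times: np.ndarray) -> float:
    dt = float(times[1] - times[0])
    if np.max(np.abs(np.diff(times) - dt)) > 1e-9:
        raise GridError("trace time grid is not uniform to within 1e-9 s")
    return dt


def estimate_lambda_series(
    trace: InterfaceTrace, alpha: CorrectionModel
) -> LambdaSeries:
    """Pointwise time constant from the off-phase interface decay.

    With the test pump off, the transient balance reads
    ``λ(t)·d/dt[1/(1−β)] = −α_R(β)·β/(1−β)``; replacing the derivative by
    a central difference over the sampling grid yields

        λ(t_i) = − α_R(β_i)·β_i/(1−β_i)
                 ÷ [ (1/(t_{i+1}−t_{i−1})) · (1/(1−β_{i+1}) − 1/(1−β_{i−1})) ]

    for every interior sample.  Samples with a vanishing central difference
    (locally flat interface) are emitted as NaN, not as infinities.
    """
    if trace.times.size < 3:
        raise InsufficientDataError("lambda estimation needs >= 3 samples")
    if np.any(trace.phase == "on"):
        raise DomainError("estimate_lambda_series expects an off-phase trace")
    _check_uniform(trace.times)

    t, b = trace.times, trace.beta
    y = 1.0 / (1.0 - b)
    deriv = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    num = -alpha(b[1:-1]) * b[1:-1] / (1.0 - b[1:-1])
    lam = np.where(np.abs(deriv) < _DERIV_EPS, np.nan, num / np.where(
        np.abs(deriv) < _DERIV_EPS, 1.0, deriv))
    return LambdaSeries(times=t[1:-1], beta=b[1:-1], lam=lam)


def summarize_lambda(
    series: LambdaSeries,
    beta_window: tuple[float, float] = DEFAULT_BETA_WINDOW,
) -> LambdaSummary:
    """⟨λ⟩ and dλ/dβ of the pointwise estimates within a β window.

    The mean is the arithmetic average over samples (the trace is uniformly
    sampled in time, so this is a time-weighted mean); the slope and
    intercept come from an unweighted OLS of λ on β.
    """
    lo, hi = beta_window
    if not lo < hi:
        raise DomainError("beta window must satisfy lo < hi")
    sel = series.defined & (series.beta >= lo) & (series.beta <= hi)
    if np.count_nonzero(sel) < 3:
        raise InsufficientDataError(
            f"need >= 3 defined lambda samples in beta window [{lo}, {hi}]"
        )
    b, lam = series.beta[sel], series.lam[sel]
    slope, intercept, r2 = _ols(b, lam)
    return LambdaSummary(
        slope=slope,
        intercept=intercept,
        mean=float(lam.mean()),
        r_squared=max(0.0, min(1.0, r2)),
        beta_window=(lo, hi),
        n=int(lam.size),
    )


def fit_lambda_prev(trace: InterfaceTrace) -> PrevMethodFit:
    """Constant-λ fit of earlier instruments: ``1/(1−β) = a1 e^(−t/λ) + a2``.

    Nonlinear least squares with multi-start on λ (``span/3 × {0.3, 1, 3}``),
    keeping the best residual.  Time is measured from the first off-phase
    sample.  Raises :class:`FitFailureError` for flat traces (λ
    unidentifiable) or if no start converges.
    """
    if trace.times.size < 5:
        raise InsufficientDataError("previous-method fit needs >= 5 samples")
    if np.any(trace.phase == "on"):
        raise DomainError("fit_lambda_prev expects an off-phase trace")
    t = trace.times - trace.times[0]
    y = 1.0 / (1.0 - trace.beta)
    if np.ptp(y) < 1e-9:
        raise FitFailureError(
            "flat trace: lambda_pm is unidentifiable", residuals=y - y.mean()
        )

    model = lambda tt, a1, a2, lam: a1 * np.exp(-tt / lam) + a2
    a2_0 = y[-1]
    a1_0 = y[0] - y[-1]
    lam_base = (t[-1] - t[0]) / 3.0

    best = None
    for factor in (0.3, 1.0, 3.0):
        try:
            popt, _ = curve_fit(
                model,
                t,
                y,
                p0=(a1_0, a2_0, lam_base * factor),
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - model(t, *popt)
        norm = float(np.linalg.norm(resid))
        if best is None or norm < best[1]:
            best = (popt, norm, resid)
    if best is None:
        raise FitFailureError(
            "previous-method fit failed to converge from all starts",
            residuals=y - model(t, a1_0, a2_0, lam_base),
        )
    (a1, a2, lam_pm), norm, _ = best
    return PrevMethodFit(a1=float(a1), a2=float(a2), lambda_pm=float(lam_pm),
                         residual_norm=norm)


# ---------------------------------------------------------------------------
# steady-flow viscosity
# ---------------------------------------------------------------------------

def segment_periods(
    trace: InterfaceTrace, flows: FlowProgram
) -> list[tuple[InterfaceTrace, InterfaceTrace]]:
    """Split a trace into complete (on-phase, off-phase) sub-traces.

    Phase boundaries follow the known program clock: period k spans
    [kT, (k+1)T) with the on-phase occupying the first ``duty·T``.  A
    trailing partial period is dropped.
    """
    T = flows.period
    t0 = trace.times[0]
    # a trace sampled over [t0, t_end] covers [t0, t_end + dt) of the program
    dt = float(np.median(np.diff(trace.times))) if len(trace) > 1 else 0.0
    duration = trace.times[-1] - t0 + dt
    n_complete = int(np.floor(duration / T + 1e-9))
    if n_complete < 1:
        raise InsufficientDataError("trace shorter than one program period")
    out = []
    for k in range(n_complete):
        lo, mid, hi = t0 + k * T, t0 + (k + flows.duty) * T, t0 + (k + 1) * T
        on = trace.select((trace.times >= lo - 1e-9) & (trace.times < mid - 1e-9))
        off = trace.select((trace.times >= mid - 1e-9) & (trace.times < hi - 1e-9))
        out.append((on, off))
    return out


def viscosity_steady(
    trace: InterfaceTrace,
    flows: FlowProgram,
    mu_r: float,
    alpha: CorrectionModel,
    window_fraction: float = 0.5,
    drift_tol: float = 0.002,
) -> SteadyViscosityResult:
    """Steady-flow viscosity from quasi-steady on-phase windows.

    For each complete period, the trailing ``window_fraction`` of the
    on-phase is tested for quasi-steadiness: the OLS drift of β across the
    window (|slope| × span) must stay below ``drift_tol``.  This trend-based
    check is insensitive to frame-to-frame jitter but catches the slow ramp
    of a heavily compliant circuit.  The steady-state balance is then
    applied samplewise and averaged; valid period means are pooled.

    Raises :class:`SteadyWindowNotFoundError` if no period has a
    quasi-steady window — the failure mode of a large air cavity, whose
    time constant exceeds the on-phase so β never flattens.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise DomainError("window_fraction must lie in (0, 1]")
    periods = segment_periods(trace, flows)
    means, sds = [], []
    for on, _off in periods:
        if len(on) == 0:
            means.append(np.nan)
            sds.append(np.nan)
            continue
        span = on.times[-1] - on.times[0]
        start = on.times[-1] - window_fraction * span
        win = on.select(on.times >= start - 1e-9)
        if len(win) < 3:
            means.append(np.nan)
            sds.append(np.nan)
            continue
        slope, _, _ = _ols(win.times, win.beta)
        if abs(slope) * (win.times[-1] - win.times[0]) >= drift_tol:
            means.append(np.nan)
            sds.append(np.nan)
            continue
        mu = viscosity_from_interface(win.beta, flows.Q_r, flows.Q_t0, mu_r, alpha)
        means.append(float(np.mean(mu)))
        sds.append(float(np.std(mu, ddof=1)) if len(win) > 1 else 0.0)
    means = np.array(means)
    sds = np.array(sds)
    valid = np.isfinite(means)
    if not np.any(valid):
        raise SteadyWindowNotFoundError(
            "no quasi-steady on-phase window found in any period "
            f"(drift tolerance {drift_tol})"
        )
    pooled = float(means[valid].mean())
    pooled_sd = float(np.std(means[valid], ddof=1)) if valid.sum() > 1 else 0.0
    return SteadyViscosityResult(
        period_mean=means, period_sd=sds, mean=pooled, sd=pooled_sd
    )


# ---------------------------------------------------------------------------
# aggregation index
# ---------------------------------------------------------------------------

def aggregation_index(
    trace: IntensityTrace, stasis_window: tuple[float, float]
) -> AggregationResult:
    """Syllectogram aggregation index over the stasis window.

    With ``I_max``/``I_min`` the window extrema, the area above the curve
    ``S_A = ∫(I_max − I)dt`` and below it ``S_B = ∫(I − I_min)dt`` are
    computed by the trapezoid rule, and ``AI = S_A/(S_A + S_B)``.  Fast
    aggregation (a quick intensity drop) pushes AI toward 1.
    """
    t0, t1 = stasis_window
    sel = (trace.times >= t0 - 1e-9) & (trace.times <= t1 + 1e-9)
    t = trace.times[sel]
    I = trace.intensity[sel]
    if t.size < 3:
        raise InsufficientDataError("stasis window must contain >= 3 samples")
    I_max, I_min = float(I.max()), float(I.min())
    if I_max - I_min <= 0:
        raise UndefinedAIError("flat intensity in stasis window: AI undefined")
    S_A = float(np.trapezoid(I_max - I, t))
    S_B = float(np.trapezoid(I - I_min, t))
    return AggregationResult(S_A=S_A, S_B=S_B, AI=S_A / (S_A + S_B))


# ---------------------------------------------------------------------------
# shear rate and shear-thinning fit
# ---------------------------------------------------------------------------

def shear_rate(Q_b: float, beta: float, geometry: ChannelGeometry):
    """Wall shear rate of the blood stream, ``γ̇ = 6 Q_b/(β w h²)`` in 1/s."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise DomainError("beta must lie strictly in (0, 1)")
    if np.any(np.asarray(Q_b) < 0):
        raise DomainError("Q_b must be non-negative")
    out = 6.0 * np.asarray(Q_b, dtype=float) / (
        beta * geometry.width * geometry.depth**2
    )
    return float(out) if out.ndim == 0 else out


def fit_power_law(shear_rates, viscosities) -> PowerLawFit:
    """Fit the shear-thinning power law ``µ = µ0 γ̇^(n−1)`` by log–log OLS."""
    g = np.asarray(shear_rates, dtype=float)
    mu = np.asarray(viscosities, dtype=float)
    if g.size < 2 or g.size != mu.size:
        raise InsufficientDataError("power-law fit needs >= 2 paired samples")
    if np.any(g <= 0) or np.any(mu <= 0):
        raise DomainError("shear rates and viscosities must be positive")
    slope, intercept, r2 = _ols(np.log(g), np.log(mu))
    return PowerLawFit(mu0=float(np.exp(intercept)), n=float(slope + 1.0),
                       r_squared=r2)


def flow_rate_from_velocity(mean_velocity: float, geometry: ChannelGeometry) -> float:
    """Volumetric flow from the PIV mean velocity: ``Q_b = A_c · ⟨U_b⟩``."""
    if mean_velocity < 0:
        raise DomainError("mean velocity must be non-negative")
    return geometry.cross_section * mean_velocity
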