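"""Synthetic traces and microscopy with the structure the analysis assumes.

The generator emulates the bench conditions of the reference experiments:
a square-wave test-fluid program (1 mL/h on / 0 off, period 480 s) against
a 1 mL/h reference stream, a camera sampling both channels at 0.5 s, an
interface obeying the lumped-circuit transient, and a stasis intensity
that decays exponentially as RBCs aggregate.  Scenario presets encode the
study conditions — 30 % glycerin, haematocrit 30–60 %, glutaraldehyde-
hardened cells, dextran-enhanced aggregation, and trapped air cavities —
parameterised from the printed regression lines where available and from
fixed, documented conventions where not (see docs/methods.md).

All randomness flows from a single integer seed; identical configurations
produce bit-identical traces and image stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import (
    ChannelGeometry,
    ComplianceModel,
    CorrectionModel,
    DEFAULT_ALPHA,
    DEFAULT_GEOMETRY,
    FlowProgram,
    FluidPair,
    InterfaceTrace,
    TimeConstantProfile,
    lambda_from_compliance,
    simulate_program,
    steady_interface,
)
from .estimators import IntensityTrace
from .exceptions import DomainError
from .units import CP, ML, ML_PER_H

__all__ = [
    "ScenarioPreset",
    "NoiseModel",
    "DEFAULT_FLOWS",
    "PRESET_LABELS",
    "preset",
    "make_trace",
    "render_coflow_frame",
    "render_coflow_stack",
    "render_tracer_pair",
]

#: the bench flow program: both pumps at 1 mL/h, square wave of period 480 s
DEFAULT_FLOWS = FlowProgram(
    Q_r=1.0 * ML_PER_H, Q_t0=1.0 * ML_PER_H, period=480.0, duty=0.5,
    sampling_dt=0.5,
)

#: viscosity of the 1× PBS reference stream (water-like at 25 °C), Pa·s
MU_REFERENCE = 1.0 * CP

#: base compliance of tubing + PDMS + fluid, chosen so the glycerin run's
#: time constant is ~5 s at 3 cP
C_BASE = 4.96e-12

# printed regression of blood viscosity (cP) on haematocrit (%)
_HCT_SLOPE, _HCT_INTERCEPT = 0.0502, 0.2066
# printed lambda(beta) lines for glutaraldehyde-hardened blood, (slope, icpt) s
_GA_LINES = {0.0: (-3.4537, 4.2013), 0.1: (-5.5687, 7.1681), 0.25: (-10.351, 14.155)}
# printed regressions of the dextran study linking viscosity to the lambda
# summaries: dlam/dbeta = -8.3292 mu + 12.438, <lam> = 3.7111 mu - 3.9552
_DEX_SLOPE_OF_MU = (-8.3292, 12.438)
_DEX_MEAN_OF_MU = (3.7111, -3.9552)
# synthetic conventions (not printed): viscosities assigned to the dextran
# series and aggregation decay times decreasing with dextran concentration
_DEX_MU_CP = {0: 2.7, 5: 2.9, 10: 3.2, 15: 3.6, 20: 4.1}
_DEX_TAU_S = {0: np.inf, 5: 60.0, 10: 30.0, 15: 15.0, 20: 8.0}
_GA_MU_CP = {0.0: 2.7166, 0.1: 3.2, 0.25: 4.0}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise injected into synthetic data.

    ``beta_sd`` is i.i.d. jitter on the interface fraction (default 0.003,
    the half-width of the reported frame-to-frame scatter); ``intensity_sd``
    is Gaussian image/intensity noise as a fraction of contrast.  Identical
    seeds give identical outputs.
    """

    beta_sd: float = 0.003
    intensity_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.beta_sd < 0 or self.intensity_sd < 0:
            raise DomainError("noise standard deviations must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: zero-noise model for deterministic roundtrips
NOISELESS = NoiseModel(beta_sd=0.0, intensity_sd=0.0, seed=0)


@dataclass(frozen=True)
class ScenarioPreset:
    """One bench scenario: fluid, time-constant profile, aggregation kinetics.

    ``tau_agg = inf`` means no aggregation (non-blood or PBS suspensions):
    the stasis intensity stays flat.  ``V_air`` is a trapped air cavity in
    the driving syringe (m³), converted to compliance at ambient pressure.
    """

    label: str
    mu_t: float  # Pa·s
    lam: TimeConstantProfile
    I0: float = 120.0
    I_inf: float = 80.0
    tau_agg: float = np.inf
    V_air: float = 0.0

    def __post_init__(self):
        if self.mu_t <= 0:
            raise DomainError("mu_t must be positive")
        if self.tau_agg <= 0:
            raise DomainError("tau_agg must be positive (use inf to disable)")


def _dex_profile(mu_cp: float) -> TimeConstantProfile:
    slope = _DEX_SLOPE_OF_MU[0] * mu_cp + _DEX_SLOPE_OF_MU[1]
    mean = _DEX_MEAN_OF_MU[0] * mu_cp + _DEX_MEAN_OF_MU[1]
    # anchor the line at the window centre beta = 0.5
    return TimeConstantProfile(lam0=mean - 0.5 * slope, slope_beta=slope)


def _build_presets() -> dict[str, ScenarioPreset]:
    presets: dict[str, ScenarioPreset] = {}
    presets["glycerin30"] = ScenarioPreset(
        label="glycerin30",
        mu_t=2.977 * CP,
        lam=TimeConstantProfile(lam0=8.8902, slope_beta=-7.6899),
    )
    for hct in (30, 40, 50, 60):
        slope, icpt = _GA_LINES[0.0]
        presets[f"hct{hct}"] = ScenarioPreset(
            label=f"hct{hct}",
            mu_t=(_HCT_SLOPE * hct + _HCT_INTERCEPT) * CP,
            lam=TimeConstantProfile(lam0=icpt, slope_beta=slope),
        )
    for ga, (slope, icpt) in _GA_LINES.items():
        key = f"ga{ga:g}"
        presets[key] = ScenarioPreset(
            label=key,
            mu_t=_GA_MU_CP[ga] * CP,
            lam=TimeConstantProfile(lam0=icpt, slope_beta=slope),
        )
    for cdex, mu_cp in _DEX_MU_CP.items():
        key = f"dex{cdex}"
        presets[key] = ScenarioPreset(
            label=key,
            mu_t=mu_cp * CP,
            lam=_dex_profile(mu_cp),
            tau_agg=_DEX_TAU_S[cdex],
        )
    for vair_ml in (0.0, 0.1, 0.2):
        key = f"vair{vair_ml:g}"
        V_air = vair_ml * ML
        comp = ComplianceModel(C_base=C_BASE, V_air=V_air)
        lam_const = lambda_from_compliance(DEFAULT_GEOMETRY, 2.977 * CP, comp)
        presets[key] = ScenarioPreset(
            label=key,
            mu_t=2.977 * CP,
            lam=TimeConstantProfile(lam0=lam_const),
            V_air=V_air,
        )
    return presets


_PRESETS = _build_presets()
PRESET_LABELS = tuple(sorted(_PRESETS))


def preset(label: str) -> ScenarioPreset:
    """Look up a scenario preset by label (see :data:`PRESET_LABELS`)."""
    try:
        return _PRESETS[label]
    except KeyError:
        raise DomainError(
            f"unknown preset {label!r}; choose from {', '.join(PRESET_LABELS)}"
        ) from None


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

def make_trace(
    scenario: ScenarioPreset,
    flows: FlowProgram = DEFAULT_FLOWS,
    alpha: CorrectionModel = DEFAULT_ALPHA,
    noise: NoiseModel = NOISELESS,
    n_periods: int = 4,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    mu_r: float = MU_REFERENCE,
    beta0: float | None = None,
) -> tuple[InterfaceTrace, IntensityTrace]:
    """Simulate β(t) and I_b(t) for a scenario under a square-wave program.

    β(t) integrates the circuit transient with the preset's viscosity and
    λ profile, plus i.i.d. jitter.  The intensity is ``I0`` while the pump
    runs and relaxes as ``I_inf + (I0 − I_inf)·exp(−(t−t_off)/tau_agg)``
    during stasis (flat when ``tau_agg`` is infinite), plus noise scaled to
    the contrast.  ``beta0`` defaults to the scenario's steady interface so
    the first on-phase starts settled, as on the bench after priming.
    """
    if beta0 is None:
        beta0 = steady_interface(scenario.mu_t, mu_r, flows.Q_t0, flows.Q_r, alpha)
    fluids = FluidPair(mu_t=scenario.mu_t, mu_r=mu_r)
    trace = simulate_program(
        geometry, flows, fluids, alpha, scenario.lam, beta0, n_periods
    )
    rng = noise.rng()
    if noise.beta_sd > 0:
        beta = trace.beta + rng.normal(0.0, noise.beta_sd, trace.beta.shape)
        beta = np.clip(beta, 1e-6, 1 - 1e-6)
        trace = InterfaceTrace(trace.times, beta, trace.phase, trace.Q_t)

    t = trace.times
    contrast = scenario.I0 - scenario.I_inf
    I = np.full(t.shape, float(scenario.I0))
    if np.isfinite(scenario.tau_agg) and contrast != 0:
        off = trace.phase == "off"
        t_off = (t // flows.period) * flows.period + flows.duty * flows.period
        decay = np.exp(-(t - t_off) / scenario.tau_agg)
        I[off] = scenario.I_inf + contrast * decay[off]
    if noise.intensity_sd > 0 and contrast != 0:
        I = I + rng.normal(0.0, noise.intensity_sd * abs(contrast), I.shape)
    return trace, IntensityTrace(times=t.copy(), intensity=I)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def render_coflow_frame(
    beta: float,
    n_transverse: int = 1000,
    n_flow: int = 64,
    dark: float = 60.0,
    bright: float = 200.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one two-phase coflow frame with a sub-pixel anti-aliased edge.

    The dark (test) phase occupies fraction ``beta`` of the transverse
    extent starting at the low-index wall; the flow runs along columns.
    The pixel straddling the interface takes its area-weighted value, which
    lets the extractor localise the edge to well under a pixel.
    """
    if not 0.0 < beta < 1.0:
        raise DomainError("beta must lie in (0, 1)")
    edge = beta * n_transverse  # in [0, n_transverse]
    rows = np.arange(n_transverse)
    coverage = np.clip(edge - rows, 0.0, 1.0)  # dark fraction of each pixel row
    profile = dark * coverage + bright * (1.0 - coverage)
    frame = np.tile(profile[:, None], (1, n_flow))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        frame = frame + rng.normal(0.0, noise_sd * (bright - dark), frame.shape)
    return frame


def render_coflow_stack(
    trace: InterfaceTrace,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    pixel_scale: float = 1e-6,
    noise: NoiseModel = NOISELESS,
    n_flow: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Render an image stack from an interface trace.

    Returns ``(stack, timestamps)`` with ``stack`` of shape
    ``(n_frames, n_transverse, n_flow)``.  The transverse extent is the
    channel width divided by the pixel scale and must resolve the channel
    with at least 500 px.
    """
    n_transverse = int(round(geometry.width / pixel_scale))
    if n_transverse < 500:
        raise DomainError(
            f"pixel_scale resolves the channel with only {n_transverse} px; "
            ">= 500 px required"
        )
    rng = noise.rng()
    stack = np.empty((len(trace), n_transverse, n_flow))
    for i, b in enumerate(trace.beta):
        stack[i] = render_coflow_frame(
            b, n_transverse, n_flow, noise_sd=noise.intensity_sd, rng=rng
        )
    return stack, trace.times.copy()


def render_tracer_pair(
    displacement_field,
    shape: tuple[int, int] = (128, 256),
    n_tracers: int = 400,
    pixel_scale: float = 2e-6,
    dt: float = 0.002,
    seed: int = 0,
    sigma: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a tracer-particle frame pair for velocimetry validation.

    ``displacement_field(y, x) -> (dy, dx)`` gives the per-tracer pixel
    displacement between the frames.  Tracers are Gaussian spots of width
    ``sigma`` rendered at sub-pixel positions, so pure translations are
    recovered exactly by correlation.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    ys = rng.uniform(2.0, H - 3.0, n_tracers)
    xs = rng.uniform(2.0, W - 3.0, n_tracers)

    def splat(yy, xx):
        frame = np.zeros(shape)
        half = int(np.ceil(4 * sigma))
        for y, x in zip(yy, xx):
            iy, ix = int(round(y)), int(round(x))
            y0, y1 = max(0, iy - half), min(H, iy + half + 1)
            x0, x1 = max(0, ix - half), min(W, ix + half + 1)
            gy = np.exp(-0.5 * ((np.arange(y0, y1) - y) / sigma) ** 2)
            gx = np.exp(-0.5 * ((np.arange(x0, x1) - x) / sigma) ** 2)
            frame[y0:y1, x0:x1] += np.outer(gy, gx)
        return frame

    frame_a = splat(ys, xs)
    disp = np.array([displacement_field(y, x) for y, x in zip(ys, xs)])
    frame_b = splat(ys + disp[:, 0], xs + disp[:, 1])
    return frame_a, frame_b
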