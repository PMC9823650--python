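"""Lumped fluidic-circuit model of the coflowing microchannel.

Two immiscible-in-practice laminar streams — a reference fluid at constant
flow ``Q_r`` and a test fluid driven with a square-wave program — share a
shallow rectangular coflow duct.  Each stream is modelled as a fluidic
resistance of a rectangle whose width is its share of the channel:
``R = 12 µ L / (w_side h³)``, with a virtual wall at the interface.  The
interface fraction ``β = w_t/(w_r + w_t)`` is the observable.  Flexible
tubing, the PDMS device and any trapped air act together as an equivalent
compliance ``C_e`` in parallel with the test stream, which gives the
transient its time constant ``λ = R_t C_e``.

At steady coflow the two streams see the same pressure, which yields the
viscometry relation

    µ_t = µ_r · β/(1−β) · (Q_r/Q_t0) · α_R(β)

where ``α_R(β)`` is an empirically calibrated correction line compensating
the rectangular-resistance approximation.  When the test pump stops, mass
storage in the compliance discharges through the test stream and β obeys

    λ(β) d/dt[1/(1−β)] + α_R(β)·β/(1−β) = (Q_t/Q_r)(µ_t/µ_r)

which this module integrates for arbitrary square-wave programs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DomainError,
    IntegrationError,
    InvalidCorrectionModelError,
    SingularGeometryError,
    TimeConstantProfileError,
)
from .units import ATM

__all__ = [
    "ChannelGeometry",
    "FlowProgram",
    "FluidPair",
    "CorrectionModel",
    "ComplianceModel",
    "TimeConstantProfile",
    "CircuitState",
    "InterfaceTrace",
    "DEFAULT_GEOMETRY",
    "DEFAULT_ALPHA",
    "fluidic_resistance",
    "viscosity_from_interface",
    "steady_interface",
    "interface_rate",
    "integrate_interface",
    "simulate_program",
    "lambda_from_compliance",
]

#: steps are rejected (halved) if they would leave the physical domain;
#: the true solution stays strictly inside (0, 1), so hitting the guard
#: indicates a numerical overshoot.
_BETA_LO, _BETA_HI = 0.0, 1.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGeometry:
    """Shallow rectangular coflow duct.

    Parameters
    ----------
    width : float
        Channel width ``w`` in m (transverse to flow, shared by both streams).
    depth : float
        Channel depth ``h`` in m.
    length : float
        Distance ``L`` of the coflow section from the outlet, in m.

    The low-aspect-ratio resistance formula ``12µL/(wh³)`` assumes
    ``h/w ≤ 0.1``; a geometry outside that regime is accepted with a warning.
    """

    width: float
    depth: float
    length: float

    def __post_init__(self):
        if self.width <= 0 or self.depth <= 0 or self.length <= 0:
            raise DomainError("channel dimensions must be positive")
        if self.depth / self.width > 0.1:
            warnings.warn(
                f"aspect ratio h/w = {self.depth / self.width:.3f} > 0.1; "
                "the shallow-rectangle resistance formula loses accuracy",
                stacklevel=2,
            )

    @property
    def cross_section(self) -> float:
        """Cross-sectional area ``A_c = w·h`` of the test channel, m²."""
        return self.width * self.depth


#: The device of the reference experiments: w = 1 mm, h = 50 µm, coflow
#: section 3.5 mm from the outlet.
DEFAULT_GEOMETRY = ChannelGeometry(width=1e-3, depth=50e-6, length=3.5e-3)


@dataclass(frozen=True)
class FlowProgram:
    """Square-wave drive of the test pump against a constant reference pump.

    ``Q_t`` alternates between ``Q_t0`` (on-phase, a ``duty`` fraction of the
    period ``T``) and 0 (off-phase); ``Q_r`` is constant.  All flows in m³/s,
    times in s.  ``sampling_dt`` is the camera frame interval.
    """

    Q_r: float
    Q_t0: float
    period: float
    duty: float = 0.5
    sampling_dt: float = 0.5

    def __post_init__(self):
        if self.Q_r <= 0:
            raise DomainError("Q_r must be positive")
        if self.Q_t0 < 0:
            raise DomainError("Q_t0 must be non-negative")
        if self.period <= 0 or self.sampling_dt <= 0:
            raise DomainError("period and sampling_dt must be positive")
        if not 0.0 < self.duty < 1.0:
            raise DomainError("duty must lie strictly between 0 and 1")

    def phase_at(self, t: float) -> str:
        """Return ``'on'`` or ``'off'`` at time ``t`` (program clock at 0)."""
        return "on" if (t % self.period) < self.duty * self.period else "off"


@dataclass(frozen=True)
class FluidPair:
    """Viscosities of the test and reference fluids, Pa·s."""

    mu_t: float
    mu_r: float

    def __post_init__(self):
        if self.mu_t <= 0 or self.mu_r <= 0:
            raise DomainError("viscosities must be positive")


@dataclass(frozen=True)
class CorrectionModel:
    """Linear resistance-correction factor ``α_R(β) = slope·β + intercept``.

    Compensates the rectangular-resistance approximation's error as the
    interface approaches either wall.  Must be positive on (0, 1).
    """

    slope: float
    intercept: float
    r_squared: float | None = None

    def __post_init__(self):
        # positivity on the closed hull of (0,1) <=> positive at both ends
        if self.intercept <= 0 or self.intercept + self.slope <= 0:
            raise InvalidCorrectionModelError(
                "alpha_R(beta) must be positive for all beta in (0, 1)"
            )

    def __call__(self, beta):
        return self.slope * np.asarray(beta, dtype=float) + self.intercept


#: Correction line calibrated on the default device with 30 % glycerin
#: against 1× PBS.
DEFAULT_ALPHA = CorrectionModel(slope=0.3038, intercept=0.7935)

#: Identity correction (no compensation), useful for analytic limits.
UNIT_ALPHA = CorrectionModel(slope=0.0, intercept=1.0)


@dataclass(frozen=True)
class ComplianceModel:
    """Equivalent compliance of the test-fluid branch.

    ``C_base`` lumps tubing, PDMS and fluid compressibility; a trapped air
    cavity of volume ``V_air`` at ambient pressure ``P_ref`` adds the
    isothermal ideal-gas linearization ``V_air/P_ref``.  Units m³/Pa.
    """

    C_base: float = 0.0
    V_air: float = 0.0
    P_ref: float = ATM

    def __post_init__(self):
        if self.C_base < 0 or self.V_air < 0:
            raise DomainError("compliances and volumes must be non-negative")
        if self.P_ref <= 0:
            raise DomainError("P_ref must be positive")

    @property
    def C_air(self) -> float:
        return self.V_air / self.P_ref

    @property
    def C_e(self) -> float:
        """Effective compliance ``C_base + V_air/P_ref``."""
        return self.C_base + self.C_air


@dataclass(frozen=True)
class TimeConstantProfile:
    """Time constant of the transient, possibly varying with the interface.

    ``λ(β) = lam0 + slope_beta·β`` in seconds.  ``kind`` is ``'constant'``
    when ``slope_beta == 0``, else ``'linear'``.
    """

    lam0: float
    slope_beta: float = 0.0

    @property
    def kind(self) -> str:
        return "constant" if self.slope_beta == 0.0 else "linear"

    def __call__(self, beta):
        return self.lam0 + self.slope_beta * np.asarray(beta, dtype=float)

    def check_positive(self, beta_lo: float, beta_hi: float) -> None:
        """Raise unless λ > 0 over [beta_lo, beta_hi]."""
        if min(self(beta_lo), self(beta_hi)) <= 0:
            raise TimeConstantProfileError(
                f"lambda(beta) must be positive on [{beta_lo}, {beta_hi}]"
            )


@dataclass(frozen=True)
class CircuitState:
    """Instantaneous state of the two-stream circuit (diagnostics only)."""

    beta: float
    P_r: float
    P_t: float
    R_r: float
    R_t: float

    def __post_init__(self):
        if not 0.0 < self.beta < 1.0:
            raise DomainError("beta must lie in (0, 1)")
        if self.R_r <= 0 or self.R_t <= 0:
            raise DomainError("resistances must be positive")


@dataclass
class InterfaceTrace:
    """Sampled interface fraction β(t) with square-wave phase labels.

    ``times`` must be uniformly spaced.  ``phase`` holds ``'on'``/``'off'``
    per sample; ``Q_t`` the instantaneous test-pump flow (m³/s).
    """

    times: np.ndarray
    beta: np.ndarray
    phase: np.ndarray
    Q_t: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.phase = np.asarray(self.phase)
        if self.Q_t is not None:
            self.Q_t = np.asarray(self.Q_t, dtype=float)
        if self.times.shape != self.beta.shape or self.times.shape != self.phase.shape:
            raise DomainError("times, beta and phase must have equal length")
        if np.any((self.beta <= 0) | (self.beta >= 1)):
            raise DomainError("beta samples must lie strictly in (0, 1)")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size >= 2 else math.nan

    def __len__(self) -> int:
        return self.times.size

    def select(self, mask: np.ndarray) -> "InterfaceTrace":
        return InterfaceTrace(
            self.times[mask],
            self.beta[mask],
            self.phase[mask],
            None if self.Q_t is None else self.Q_t[mask],
        )


# ---------------------------------------------------------------------------
# steady-state relations
# ---------------------------------------------------------------------------

def fluidic_resistance(
    geometry: ChannelGeometry, mu: float, beta_fraction: float, side: str
) -> float:
    """Fluidic resistance of one stream's share of the coflow duct, Pa·s/m³.

    The stream occupies width ``(1−β)w`` (reference side) or ``βw`` (test
    side) of the shallow rectangle, giving ``R = 12 µ L / (w_side h³)``.
    """
    if mu <= 0:
        raise DomainError("viscosity must be positive")
    if not 0.0 < beta_fraction < 1.0:
        raise SingularGeometryError(
            f"beta = {beta_fraction} collapses one stream to zero width"
        )
    if side == "reference":
        w_side = (1.0 - beta_fraction) * geometry.width
    elif side == "test":
        w_side = beta_fraction * geometry.width
    else:
        raise DomainError(f"side must be 'reference' or 'test', got {side!r}")
    return 12.0 * mu * geometry.length / (w_side * geometry.depth**3)


def viscosity_from_interface(
    beta: float,
    Q_r: float,
    Q_t0: float,
    mu_r: float,
    alpha: CorrectionModel,
):
    """Test-fluid viscosity from the steady interface fraction, Pa·s.

    Evaluates ``µ_t = µ_r · β/(1−β) · (Q_r/Q_t0) · α_R(β)``; the inverse of
    the steady-state balance of the two-stream circuit.  Accepts scalars or
    arrays of β.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise DomainError("beta must lie strictly in (0, 1)")
    if Q_t0 <= 0:
        raise DomainError("steady flow required: Q_t0 must be positive")
    if Q_r <= 0 or mu_r <= 0:
        raise DomainError("Q_r and mu_r must be positive")
    out = mu_r * beta / (1.0 - beta) * (Q_r / Q_t0) * alpha(beta)
    return float(out) if out.ndim == 0 else out


def _steady_lhs(beta: float, alpha: CorrectionModel) -> float:
    return beta / (1.0 - beta) * float(alpha(beta))


def steady_interface(
    mu_t: float,
    mu_r: float,
    Q_t: float,
    Q_r: float,
    alpha: CorrectionModel,
) -> float:
    """Steady interface fraction: the root of the viscometry relation.

    Solves ``β/(1−β)·α_R(β) = (µ_t/µ_r)(Q_t/Q_r)`` by bracketed root-finding
    on (ε, 1−ε).  The left side is strictly increasing for any admissible
    correction line unless its slope is so negative that α_R turns the map
    non-monotone, which is rejected.
    """
    from scipy.optimize import brentq

    if min(mu_t, mu_r, Q_t, Q_r) <= 0:
        raise DomainError("all inputs must be positive")
    target = (mu_t / mu_r) * (Q_t / Q_r)
    eps = 1e-9

    # monotonicity check on a grid: g'(β) = α/(1−β)² + α'·β/(1−β)
    grid = np.linspace(0.01, 0.99, 99)
    gprime = alpha(grid) / (1 - grid) ** 2 + alpha.slope * grid / (1 - grid)
    if np.any(gprime <= 0):
        raise InvalidCorrectionModelError(
            "steady-state map is non-monotone on (0, 1) for this correction line"
        )

    f = lambda b: _steady_lhs(b, alpha) - target
    return float(brentq(f, eps, 1.0 - eps, xtol=1e-15, rtol=8.9e-16, maxiter=200))


# ---------------------------------------------------------------------------
# transient model
# ---------------------------------------------------------------------------

def interface_rate(
    beta: float,
    lam: TimeConstantProfile,
    alpha: CorrectionModel,
    drive: float,
) -> float:
    """Instantaneous dβ/dt of the transient circuit balance, 1/s.

    ``drive = (Q_t/Q_r)(µ_t/µ_r)`` is the dimensionless forcing; with the
    pump off it is zero and the compliance discharges through the test
    stream.  Derived from ``d/dt[1/(1−β)] = β′/(1−β)²``:

        dβ/dt = (1−β)² · [drive − α_R(β)·β/(1−β)] / λ(β)
    """
    if not 0.0 < beta < 1.0:
        raise DomainError("beta must lie strictly in (0, 1)")
    lam_b = float(lam(beta))
    if lam_b <= 0:
        raise TimeConstantProfileError(f"lambda({beta:.4f}) = {lam_b:.4g} <= 0")
    return (1.0 - beta) ** 2 * (drive - _steady_lhs(beta, alpha)) / lam_b


def _rk4_step(beta, h, lam, alpha, drive):
    k1 = interface_rate(beta, lam, alpha, drive)
    b2 = beta + 0.5 * h * k1
    if not _BETA_LO < b2 < _BETA_HI:
        return None
    k2 = interface_rate(b2, lam, alpha, drive)
    b3 = beta + 0.5 * h * k2
    if not _BETA_LO < b3 < _BETA_HI:
        return None
    k3 = interface_rate(b3, lam, alpha, drive)
    b4 = beta + h * k3
    if not _BETA_LO < b4 < _BETA_HI:
        return None
    k4 = interface_rate(b4, lam, alpha, drive)
    out = beta + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if not _BETA_LO < out < _BETA_HI:
        return None
    return out


def integrate_interface(
    beta0: float,
    drive: float,
    lam: TimeConstantProfile,
    alpha: CorrectionModel,
    duration: float,
    sampling_dt: float,
    internal_dt: float | None = None,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the interface ODE at constant drive over ``duration``.

    Explicit RK4 with fixed internal step (default ``min(0.05 s, dt/10)``),
    resampled onto the camera grid ``t0 + k·sampling_dt``.  Steps that would
    push β out of (ε, 1−ε) are halved (step rejection); if the step
    underflows an :class:`IntegrationError` is raised with the time stamp.

    Returns ``(times, beta)`` including the sample at ``t0``.
    """
    if not 0.0 < beta0 < 1.0:
        raise DomainError("beta0 must lie strictly in (0, 1)")
    if internal_dt is None:
        internal_dt = min(0.05, sampling_dt / 10.0)
    n_samples = int(math.floor(duration / sampling_dt + 1e-9)) + 1
    times = t0 + sampling_dt * np.arange(n_samples)
    out = np.empty(n_samples)
    out[0] = beta0

    beta = beta0
    t = 0.0
    for i in range(1, n_samples):
        t_target = sampling_dt * i
        while t < t_target - 1e-12:
            h = min(internal_dt, t_target - t)
            step = _rk4_step(beta, h, lam, alpha, drive)
            while step is None:
                h *= 0.5
                if h < 1e-12:
                    raise IntegrationError(
                        f"beta would leave (0, 1) at t = {t0 + t:.6g} s"
                    )
                step = _rk4_step(beta, h, lam, alpha, drive)
            beta = step
            t += h
        out[i] = beta
    return times, out


def simulate_program(
    geometry: ChannelGeometry,
    flows: FlowProgram,
    fluids: FluidPair,
    alpha: CorrectionModel,
    lam: TimeConstantProfile,
    beta0: float,
    n_periods: int,
    internal_dt: float | None = None,
) -> InterfaceTrace:
    """Simulate β(t) under a square-wave test-flow program.

    The drive switches between ``(Q_t0/Q_r)(µ_t/µ_r)`` during the on-phase
    and 0 during the off-phase; the ODE is integrated phase by phase and
    resampled at ``flows.sampling_dt``.  ``geometry`` is carried for
    interface consistency with downstream shear-rate work (the lumped ODE
    itself is geometry-free once λ is given).
    """
    if n_periods < 1:
        raise DomainError("n_periods must be >= 1")
    drive_on = (flows.Q_t0 / flows.Q_r) * (fluids.mu_t / fluids.mu_r)
    dt = flows.sampling_dt
    t_on = flows.duty * flows.period
    t_off = flows.period - t_on

    all_t, all_b = [], []
    beta = beta0
    t_start = 0.0
    for _ in range(n_periods):
        for drive, span in ((drive_on, t_on), (0.0, t_off)):
            tt, bb = integrate_interface(
                beta, drive, lam, alpha, span, dt, internal_dt, t0=t_start
            )
            # drop the first sample of each segment after the very first to
            # avoid duplicating the shared boundary point
            if all_t:
                tt, bb = tt[1:], bb[1:]
            all_t.append(tt)
            all_b.append(bb)
            beta = bb[-1] if bb.size else beta
            t_start += span

    times = np.concatenate(all_t)
    beta_arr = np.concatenate(all_b)
    phase = np.array([flows.phase_at(t) for t in times])
    Q_t = np.where(phase == "on", flows.Q_t0, 0.0)
    return InterfaceTrace(times, beta_arr, phase, Q_t)


def lambda_from_compliance(
    geometry: ChannelGeometry, mu_t: float, comp: ComplianceModel
) -> float:
    """Transient time constant ``λ = 12 µ_t L/(w h³) · C_e`` in seconds.

    The resistance is that of the full-width test duct; the effective
    compliance includes the ideal-gas linearization of any air cavity.
    """
    if mu_t <= 0:
        raise DomainError("mu_t must be positive")
    R = 12.0 * mu_t * geometry.length / (geometry.width * geometry.depth**3)
    return R * comp.C_e
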