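"""End-to-end analysis pipeline: per-period haemorheology tables.

`analyze_trace` ties the estimators together the way the bench protocol
does: segment the square-wave program into periods, take the viscosity
from each on-phase quasi-steady window, the time-constant series and its
⟨λ⟩/dλ/dβ summaries plus the previous-method exponential fit from each
off-phase, and the aggregation index from the stasis intensity.  Metrics
that fail for a period (e.g. no quasi-steady window under heavy
compliance, flat stasis intensity for a non-aggregating fluid) are
reported as NaN in that row rather than aborting the whole run; a run
where *no* period yields a viscosity raises, mirroring the instrument's
genuine failure mode.

Every output row carries the package version and a configuration hash so
tables are traceable to the run that produced them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .circuit import (
    ChannelGeometry,
    CorrectionModel,
    DEFAULT_ALPHA,
    DEFAULT_GEOMETRY,
    FlowProgram,
    InterfaceTrace,
)
from .estimators import (
    DEFAULT_BETA_WINDOW,
    IntensityTrace,
    LambdaSummary,
    aggregation_index,
    estimate_lambda_series,
    fit_lambda_prev,
    segment_periods,
    summarize_lambda,
    viscosity_steady,
)
from .exceptions import (
    CoflowmetryError,
    SteadyWindowNotFoundError,
)
from .units import si_to_cp

__all__ = ["PeriodResult", "analyze_trace", "results_table"]

logger = logging.getLogger("coflowmetry")


@dataclass
class PeriodResult:
    """Per-period haemorheology metrics (NaN where a metric failed)."""

    period: int
    mu_cP: float
    mu_sd_cP: float
    lam_mean_s: float
    dlam_dbeta_s: float
    r2_lambda: float
    lambda_pm_s: float
    AI: float


def analyze_trace(
    trace: InterfaceTrace,
    flows: FlowProgram,
    intensity: IntensityTrace | None = None,
    alpha: CorrectionModel = DEFAULT_ALPHA,
    mu_r: float = 1e-3,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    beta_window: tuple[float, float] = DEFAULT_BETA_WINDOW,
    window_fraction: float = 0.5,
) -> list[PeriodResult]:
    """Run the full per-period analysis of one square-wave run."""
    periods = segment_periods(trace, flows)
    logger.info("analyzing %d complete periods", len(periods))

    try:
        visc = viscosity_steady(
            trace, flows, mu_r, alpha, window_fraction=window_fraction
        )
        mu_means, mu_sds = visc.period_mean, visc.period_sd
    except SteadyWindowNotFoundError:
        logger.warning("no quasi-steady window in any period; mu reported NaN")
        mu_means = np.full(len(periods), np.nan)
        mu_sds = np.full(len(periods), np.nan)

    results = []
    for k, (on, off) in enumerate(periods):
        lam_mean = dlam = r2 = lam_pm = ai = np.nan
        try:
            series = estimate_lambda_series(off, alpha)
            summ: LambdaSummary = summarize_lambda(series, beta_window)
            lam_mean, dlam, r2 = summ.mean, summ.slope, summ.r_squared
        except CoflowmetryError as exc:
            logger.debug("period %d: lambda summary failed: %s", k, exc)
        try:
            lam_pm = fit_lambda_prev(off).lambda_pm
        except CoflowmetryError as exc:
            logger.debug("period %d: previous-method fit failed: %s", k, exc)
        if intensity is not None and len(off) > 0:
            try:
                ai = aggregation_index(
                    intensity, (off.times[0], off.times[-1])
                ).AI
            except CoflowmetryError as exc:
                logger.debug("period %d: AI undefined: %s", k, exc)
        results.append(
            PeriodResult(
                period=k,
                mu_cP=si_to_cp(mu_means[k]) if np.isfinite(mu_means[k]) else np.nan,
                mu_sd_cP=si_to_cp(mu_sds[k]) if np.isfinite(mu_sds[k]) else np.nan,
                lam_mean_s=lam_mean,
                dlam_dbeta_s=dlam,
                r2_lambda=r2,
                lambda_pm_s=lam_pm,
                AI=ai,
            )
        )
        logger.info(
            "period %d: mu = %.4g cP, <lambda> = %.4g s, dlam/dbeta = %.4g s, "
            "AI = %.4g",
            k, results[-1].mu_cP, lam_mean, dlam, ai,
        )
    return results


def results_table(results: list[PeriodResult], cfg_hash: str = "") -> pd.DataFrame:
    """Per-period results as a DataFrame with provenance columns."""
    df = pd.DataFrame(
        {
            "period": [r.period for r in results],
            "mu_cP": [r.mu_cP for r in results],
            "mu_sd": [r.mu_sd_cP for r in results],
            "lam_mean_s": [r.lam_mean_s for r in results],
            "dlam_dbeta_s": [r.dlam_dbeta_s for r in results],
            "R2_lambda": [r.r2_lambda for r in results],
            "lambda_pm_s": [r.lambda_pm_s for r in results],
            "AI": [r.AI for r in results],
        }
    )
    df["config_hash"] = cfg_hash
    df["version"] = __version__
    return df
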