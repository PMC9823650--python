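"""File I/O: trace CSVs, image stacks, and run configurations.

Traces travel as plain CSV (``time_s,beta,Q_t_mL_per_h,phase`` for the
interface; ``time_s,intensity`` for the stasis curve).  Image stacks are
single- or multi-page TIFF or numbered PNG sequences with a sidecar
``frame,time_s`` CSV for timestamps.  Configurations are TOML or YAML
with explicit unit suffixes on every physical quantity.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import (
    ChannelGeometry,
    ComplianceModel,
    CorrectionModel,
    FlowProgram,
    InterfaceTrace,
)
from .estimators import IntensityTrace
from .exceptions import ConfigError
from .units import ML, ML_PER_H, UM, si_to_ml_per_h

__all__ = [
    "write_interface_csv",
    "read_interface_csv",
    "write_intensity_csv",
    "read_intensity_csv",
    "write_tiff_stack",
    "read_image_stack",
    "load_config",
    "config_hash",
    "geometry_from_config",
    "flows_from_config",
    "correction_from_config",
    "compliance_from_config",
]


def write_interface_csv(trace: InterfaceTrace, path) -> None:
    """Write an interface trace as ``time_s,beta,Q_t_mL_per_h,phase``."""
    q = trace.Q_t if trace.Q_t is not None else np.zeros_like(trace.times)
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "beta": trace.beta,
            "Q_t_mL_per_h": [si_to_ml_per_h(v) for v in q],
            "phase": trace.phase,
        }
    )
    df.to_csv(path, index=False)


def read_interface_csv(path, flows: FlowProgram | None = None) -> InterfaceTrace:
    """Read an interface trace CSV.

    Accepts the full four-column format or a bare ``time_s,beta`` file; in
    the latter case phase labels are reconstructed from ``flows`` (required).
    """
    df = pd.read_csv(path)
    if "time_s" not in df or "beta" not in df:
        raise ConfigError(f"{path}: expected columns time_s,beta")
    times = df["time_s"].to_numpy(dtype=float)
    beta = df["beta"].to_numpy(dtype=float)
    if "phase" in df:
        phase = df["phase"].to_numpy(dtype=str)
    elif flows is not None:
        phase = np.array([flows.phase_at(t) for t in times])
    else:
        raise ConfigError(
            f"{path}: no phase column and no flow program to reconstruct it"
        )
    Q_t = None
    if "Q_t_mL_per_h" in df:
        Q_t = df["Q_t_mL_per_h"].to_numpy(dtype=float) * ML_PER_H
    return InterfaceTrace(times, beta, phase, Q_t)


def write_intensity_csv(trace: IntensityTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "intensity": trace.intensity}).to_csv(
        path, index=False
    )


def read_intensity_csv(path) -> IntensityTrace:
    df = pd.read_csv(path)
    if "time_s" not in df or "intensity" not in df:
        raise ConfigError(f"{path}: expected columns time_s,intensity")
    return IntensityTrace(
        times=df["time_s"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
    )


def write_tiff_stack(stack: np.ndarray, times: np.ndarray, path) -> None:
    """Write a multi-page TIFF plus a ``frame,time_s`` sidecar CSV."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(".times.csv")
    pd.DataFrame({"frame": np.arange(len(times)), "time_s": times}).to_csv(
        sidecar, index=False
    )


def read_image_stack(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TIFF stack or a directory of PNG frames, with timestamps.

    Timestamps come from the sidecar ``*.times.csv`` if present; otherwise
    a constant 0.5 s rate is assumed.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        frames = sorted(path.glob("*.png"))
        stack = np.stack([iio.imread(f).astype(float) for f in frames])
        sidecar = path / "times.csv"
    else:
        import tifffile

        stack = np.asarray(tifffile.imread(path), dtype=float)
        if stack.ndim == 2:
            stack = stack[None]
        sidecar = path.with_suffix(".times.csv")
    if sidecar.exists():
        times = pd.read_csv(sidecar)["time_s"].to_numpy(dtype=float)
    else:
        times = 0.5 * np.arange(stack.shape[0])
    return stack, times


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "paths", "geometry", "flows", "fluids", "correction", "compliance",
    "calibration", "analysis", "noise", "report", "scenario",
}


def load_config(path) -> dict:
    """Load a TOML (.toml) or YAML (.yml/.yaml) run configuration.

    Unknown top-level sections are rejected so typos fail loudly.
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        cfg = tomllib.loads(path.read_text())
    elif path.suffix in (".yml", ".yaml"):
        import yaml

        cfg = yaml.safe_load(path.read_text())
    else:
        raise ConfigError(f"unsupported config format: {path.suffix}")
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a table/mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration for output provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _get(section: dict, key: str, default=None, required=False):
    if key in section:
        return section[key]
    if required:
        raise ConfigError(f"missing required config key: {key}")
    return default


def geometry_from_config(cfg: dict) -> ChannelGeometry:
    g = cfg.get("geometry", {})
    return ChannelGeometry(
        width=_get(g, "width_um", 1000.0) * UM,
        depth=_get(g, "depth_um", 50.0) * UM,
        length=_get(g, "length_um", 3500.0) * UM,
    )


def flows_from_config(cfg: dict) -> FlowProgram:
    f = cfg.get("flows", {})
    return FlowProgram(
        Q_r=_get(f, "Q_r_mL_per_h", 1.0) * ML_PER_H,
        Q_t0=_get(f, "Q_t0_mL_per_h", 1.0) * ML_PER_H,
        period=_get(f, "period_s", 480.0),
        duty=_get(f, "duty", 0.5),
        sampling_dt=_get(f, "sampling_dt_s", 0.5),
    )


def correction_from_config(cfg: dict) -> CorrectionModel:
    c = cfg.get("correction", {})
    return CorrectionModel(
        slope=_get(c, "slope", 0.3038), intercept=_get(c, "intercept", 0.7935)
    )


def compliance_from_config(cfg: dict) -> ComplianceModel:
    c = cfg.get("compliance", {})
    kwargs = {
        "C_base": _get(c, "C_base_m3_per_Pa", 0.0),
        "V_air": _get(c, "V_air_mL", 0.0) * ML,
    }
    if "P_ref_Pa" in c:
        kwargs["P_ref"] = c["P_ref_Pa"]
    return ComplianceModel(**kwargs)
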