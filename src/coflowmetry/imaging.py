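"""Image analysis: interface extraction, intensity, and block velocimetry.

Two observables drive the whole method: the interface fraction β in the
coflowing channel and the mean image intensity I_b in the test channel.
Both come from grayscale transmitted-light microscopy.  A minimal
single-pass block cross-correlation stage estimates the mean blood
velocity for flow-rate monitoring; it deliberately omits the iterative
window deformation of full micro-PIV, which is unnecessary for a mean
velocity over a straight channel.

Coordinate conventions: arrays are indexed ``[row, column]`` with a
top-left origin; ROIs are half-open pixel rectangles.  The channel axis
convention (which array axis carries the flow, which wall the test fluid
hugs, and whether it is the dark or bright phase) is declared explicitly
per dataset because transmitted-light setups differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .exceptions import (
    DegenerateImageError,
    DomainError,
    NoisyInterfaceError,
    UntrackableError,
)

__all__ = [
    "ImageFrame",
    "ROI",
    "ChannelAxisConvention",
    "extract_interface",
    "extract_intensity",
    "mean_velocity",
]


@dataclass
class ImageFrame:
    """One grayscale frame with its timestamp and physical pixel scale."""

    pixels: np.ndarray
    timestamp: float
    pixel_scale: float  # m per pixel

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DomainError("frame must be a 2-D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise DomainError("pixel intensities must be finite")
        if self.pixel_scale <= 0:
            raise DomainError("pixel_scale must be positive")


@dataclass(frozen=True)
class ROI:
    """Half-open pixel rectangle ``[y0, y0+height) × [x0, x0+width)``."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 8 or self.height < 8:
            raise DomainError("ROI must be at least 8 px in each dimension")
        if self.x0 < 0 or self.y0 < 0:
            raise DomainError("ROI origin must be non-negative")

    def slice_from(self, pixels: np.ndarray) -> np.ndarray:
        if (self.y0 + self.height > pixels.shape[0]
                or self.x0 + self.width > pixels.shape[1]):
            raise DomainError("ROI extends beyond the frame")
        return pixels[self.y0:self.y0 + self.height, self.x0:self.x0 + self.width]


@dataclass(frozen=True)
class ChannelAxisConvention:
    """How the physical channel maps onto the pixel array.

    flow_axis : 'columns' if the fluid flows along increasing column index
        (horizontal channel), 'rows' if along increasing row index.
    test_side : which wall the test fluid hugs along the transverse axis,
        'low-index' or 'high-index'.
    test_polarity : whether the test fluid is the 'dark' phase (absorbing
        RBC suspensions under transmitted light — the default) or 'bright'.
    """

    flow_axis: str = "columns"
    test_side: str = "low-index"
    test_polarity: str = "dark"

    def __post_init__(self):
        if self.flow_axis not in ("columns", "rows"):
            raise DomainError("flow_axis must be 'columns' or 'rows'")
        if self.test_side not in ("low-index", "high-index"):
            raise DomainError("test_side must be 'low-index' or 'high-index'")
        if self.test_polarity not in ("dark", "bright"):
            raise DomainError("test_polarity must be 'dark' or 'bright'")


def extract_interface(
    frame: ImageFrame, roi: ROI, convention: ChannelAxisConvention
) -> float:
    """Interface fraction β from one frame.

    The ROI (which must span the full channel transverse to flow) is
    binarized by Otsu's global threshold.  For every line along the flow
    axis, the transverse intensity profile is scanned for threshold
    crossings; the crossing is refined to sub-pixel precision by linear
    interpolation between the straddling pixels.  Lines with zero or more
    than one crossing are rejected; at least half of the lines must
    survive.  β is the mean test-fluid width fraction over valid lines.
    """
    sub = roi.slice_from(frame.pixels)
    if convention.flow_axis == "columns":
        profiles = sub.T  # transverse axis = rows; one profile per column
    else:
        profiles = sub  # one profile per row, transverse along columns

    if float(sub.max()) - float(sub.min()) <= 0:
        raise DegenerateImageError("ROI contains a single intensity level")
    thr = float(threshold_otsu(sub))

    n_lines, n_t = profiles.shape
    widths = []
    for line in profiles:
        s = line - thr
        sign_change = s[:-1] * s[1:] < 0
        idx = np.flatnonzero(sign_change)
        if idx.size != 1:
            continue
        k = int(idx[0])
        # pixel centres sit at integer coordinates; the physical channel
        # spans [-0.5, n_t - 0.5], so edge position within [0, n_t] is +0.5
        x = k + (thr - line[k]) / (line[k + 1] - line[k])
        edge = x + 0.5
        widths.append(edge if convention.test_side == "low-index" else n_t - edge)

    if not widths:
        raise DegenerateImageError("no interface crossing found in any line")
    if len(widths) < 0.5 * n_lines:
        raise NoisyInterfaceError(
            f"only {len(widths)}/{n_lines} lines had a clean single crossing"
        )
    return float(np.mean(widths) / n_t)


def extract_intensity(frame: ImageFrame, roi: ROI) -> float:
    """Mean pixel intensity I_b over the ROI."""
    return float(roi.slice_from(frame.pixels).mean())


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shape patches (NaN-free)."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return np.nan
    return float(np.sum(a * b) / denom)


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:  # no concave peak
        return 0.0
    return 0.5 * (cm1 - cp1) / denom


def mean_velocity(
    frame_a: ImageFrame,
    frame_b: ImageFrame,
    roi: ROI,
    dt: float,
    block_size: int = 32,
    search_radius: int = 8,
    min_peak: float = 0.5,
) -> float:
    """Mean flow speed between two frames by block cross-correlation, m/s.

    The ROI is tiled into ``block_size`` squares.  Each block of frame A is
    matched in frame B over integer displacements within ``search_radius``
    by maximum normalized cross-correlation, refined to sub-pixel precision
    by parabolic interpolation of the correlation peak along each axis.
    Blocks whose peak correlation falls below ``min_peak`` (or that carry no
    texture) are rejected; the mean of the surviving block speeds times
    ``pixel_scale/dt`` is returned.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    if frame_a.pixels.shape != frame_b.pixels.shape:
        raise DomainError("frames must share geometry")
    A = roi.slice_from(frame_a.pixels)
    B_full = frame_b.pixels
    s = search_radius
    bs = block_size

    speeds = []
    for by in range(0, A.shape[0] - bs + 1, bs):
        for bx in range(0, A.shape[1] - bs + 1, bs):
            block = A[by:by + bs, bx:bx + bs]
            if np.ptp(block) == 0:
                continue
            # absolute position of the block in the full frame
            fy, fx = roi.y0 + by, roi.x0 + bx
            corr = np.full((2 * s + 1, 2 * s + 1), -np.inf)
            for iy, dy in enumerate(range(-s, s + 1)):
                y0, y1 = fy + dy, fy + dy + bs
                if y0 < 0 or y1 > B_full.shape[0]:
                    continue
                for ix, dx in enumerate(range(-s, s + 1)):
                    x0, x1 = fx + dx, fx + dx + bs
                    if x0 < 0 or x1 > B_full.shape[1]:
                        continue
                    c = _ncc(block, B_full[y0:y1, x0:x1])
                    if not np.isnan(c):
                        corr[iy, ix] = c
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            c0 = corr[peak]
            if not np.isfinite(c0) or c0 < min_peak:
                continue
            dy = peak[0] - s
            dx = peak[1] - s
            # parabolic sub-pixel refinement where neighbours exist
            if 0 < peak[0] < 2 * s and np.isfinite(corr[peak[0] - 1, peak[1]]) \
                    and np.isfinite(corr[peak[0] + 1, peak[1]]):
                dy += _parabolic_offset(
                    corr[peak[0] - 1, peak[1]], c0, corr[peak[0] + 1, peak[1]]
                )
            if 0 < peak[1] < 2 * s and np.isfinite(corr[peak[0], peak[1] - 1]) \
                    and np.isfinite(corr[peak[0], peak[1] + 1]):
                dx += _parabolic_offset(
                    corr[peak[0], peak[1] - 1], c0, corr[peak[0], peak[1] + 1]
                )
            speeds.append(np.hypot(dy, dx))

    if not speeds:
        raise UntrackableError("all velocimetry blocks were rejected")
    return float(np.mean(speeds) * frame_a.pixel_scale / dt)
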