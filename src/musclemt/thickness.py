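"""Muscle-thickness computation from detected aponeurosis lines.

The measurement pipeline is: enhance (Gabor or vesselness) -> binarize ->
RVHT line detection -> select the aponeurosis pair -> mean middle-line
distance, converted to mm by the scanner calibration.  Among the detected
lines, the pair with the maximum mean distance is taken as the superficial
and deep aponeuroses (with the default of two detected lines this coincides
with "the first two lines detected").

Note on the thickness definition: the middle-line distance between the two
detected aponeurosis centerlines systematically exceeds a manual
border-to-border caliper reading by roughly the aponeurosis wall thickness
(~1.4 mm on typical gastrocnemius images).  This bias is inherent to the
definition and is documented, not corrected, here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

from . import gabor as _gabor
from . import mvef as _mvef
from .edgemap import binarize
from .errors import DetectionFailureError, GeometryError, InputError
from .lines import Line
from .rvht import DEFAULT_HALFWIDTH, DEFAULT_RHO_STEP, DEFAULT_THETA_STEP, rvht_detect

__all__ = [
    "MTResult",
    "MTSeries",
    "mean_line_distance",
    "select_aponeuroses",
    "estimate_mt",
    "smooth_series",
]

logger = logging.getLogger(__name__)


@dataclass
class MTResult:
    """One frame's thickness measurement with the supporting line pair."""

    superficial: Line
    deep: Line
    mt_px: float
    mt_mm: float
    frame_index: int = 0


@dataclass
class MTSeries:
    """Per-frame thickness values in mm, optionally with a median-smoothed
    version and outlier flags (|raw - smoothed| > threshold)."""

    frames: np.ndarray
    mt_mm: np.ndarray
    smoothed_mm: np.ndarray | None = None
    outlier: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.mt_mm = np.asarray(self.mt_mm, dtype=float)
        if len(self.frames) != len(self.mt_mm):
            raise InputError("frames and mt_mm must have equal length")


def _rows_and_overlap(a: Line, b: Line, width: int, height: int | None):
    x = np.arange(width, dtype=float)
    ya, yb = a.row_at(x), b.row_at(x)
    if height is None:
        keep = np.ones(width, dtype=bool)
    else:
        keep = (ya >= 0) & (ya < height) & (yb >= 0) & (yb < height)
    return ya, yb, keep


def mean_line_distance(a: Line, b: Line, width: int, height: int | None = None) -> float:
    """Mean distance between two quasi-horizontal lines over the image width.

    For each column the vertical separation |y_a(x) - y_b(x)| is evaluated
    and projected perpendicular to the mean orientation via
    |sin((theta_a + theta_b)/2)|.  Columns where either line leaves the
    image (when ``height`` is given) are excluded; a warning is logged if
    fewer than half the columns remain.
    """
    if width < 1:
        raise InputError("width must be >= 1")
    if a.is_near_vertical or b.is_near_vertical:
        raise GeometryError(
            "near-vertical line detected; aponeuroses are quasi-horizontal, "
            "so this indicates a detection failure"
        )
    ya, yb, keep = _rows_and_overlap(a, b, width, height)
    if not keep.any():
        raise GeometryError("lines have no overlap inside the image")
    if keep.sum() < 0.5 * width:
        logger.warning("line overlap covers only %d of %d columns", int(keep.sum()), width)
    proj = abs(math.sin((a.theta + b.theta) / 2.0))
    return float(np.mean(np.abs(ya[keep] - yb[keep])) * proj)


def select_aponeuroses(
    lines: list[Line], width: int, height: int | None = None
) -> tuple[Line, Line]:
    """Pick the line pair with maximum mean distance; label by depth.

    Returns (superficial, deep) ordered by mean row over the shared columns.
    Ties in distance break to the pair with the higher combined vote count.
    The result does not depend on the input ordering of the lines.
    """
    if len(lines) < 2:
        raise DetectionFailureError(f"need at least 2 lines, got {len(lines)}")
    best: tuple[float, int, Line, Line] | None = None
    for a, b in combinations(lines, 2):
        try:
            d = mean_line_distance(a, b, width, height)
        except GeometryError:
            continue
        votes = a.votes + b.votes
        if best is None or d > best[0] + 1e-9 or (abs(d - best[0]) <= 1e-9 and votes > best[1]):
            best = (d, votes, a, b)
    if best is None:
        raise DetectionFailureError("no valid quasi-horizontal line pair among detections")
    _, _, a, b = best
    ya, yb, keep = _rows_and_overlap(a, b, width, height)
    if float(np.mean(ya[keep])) <= float(np.mean(yb[keep])):
        return a, b
    return b, a


def estimate_mt(
    image: np.ndarray,
    method: str = "mvef",
    pixel_spacing_mm: float = 0.1,
    *,
    gabor_params: dict | None = None,
    mvef_params: "_mvef.VesselnessParams | None" = None,
    threshold_method: str = "otsu",
    fixed_level: float | None = None,
    rho_step: float = DEFAULT_RHO_STEP,
    theta_step: float = DEFAULT_THETA_STEP,
    halfwidth: float = DEFAULT_HALFWIDTH,
    n_lines: int = 2,
    frame_index: int = 0,
) -> MTResult:
    """Run the full four-step pipeline on one frame.

    ``method`` selects the enhancement: "gabor", "mvef", or "none" (binarize
    the raw image directly, for ablation experiments).  Raises
    :class:`DetectionFailureError` when fewer than two usable lines emerge.
    """
    if pixel_spacing_mm <= 0:
        raise InputError("pixel_spacing_mm must be > 0")
    image = np.asarray(image, dtype=float)
    if method == "gabor":
        enhanced = _gabor.gabor_enhance(image, **(gabor_params or {}))
    elif method == "mvef":
        enhanced = _mvef.mvef_enhance(image, mvef_params)
    elif method == "none":
        enhanced = image
    else:
        raise InputError(f"unknown enhancement method {method!r}")

    edge = binarize(enhanced, threshold_method, fixed_level)
    lines = rvht_detect(edge, n_lines=n_lines, rho_step=rho_step, theta_step=theta_step, halfwidth=halfwidth)
    logger.debug(
        "frame %d: %d lines, votes %s", frame_index, len(lines), [ln.votes for ln in lines]
    )
    if len(lines) < 2:
        raise DetectionFailureError(
            f"frame {frame_index}: only {len(lines)} line(s) detected"
        )
    h, w = image.shape
    sup, deep = select_aponeuroses(lines, w, h)
    mt_px = mean_line_distance(sup, deep, w, h)
    return MTResult(
        superficial=sup,
        deep=deep,
        mt_px=mt_px,
        mt_mm=mt_px * pixel_spacing_mm,
        frame_index=frame_index,
    )


def smooth_series(
    series: MTSeries, window: int = 5, outlier_threshold_mm: float = 0.5
) -> MTSeries:
    """Median-smooth a thickness time series and flag outliers.

    The smoothed version is a centered running median (the window shrinks at
    the edges); a frame is flagged when |raw - smoothed| exceeds
    ``outlier_threshold_mm`` (default 0.5 mm).
    """
    if window < 3 or window % 2 == 0:
        raise InputError("window must be odd and >= 3")
    n = len(series.mt_mm)
    if window > n:
        raise InputError(f"window {window} exceeds series length {n}")
    smoothed = (
        pd.Series(series.mt_mm).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    outlier = np.abs(series.mt_mm - smoothed) > outlier_threshold_mm
    return replace(series, smoothed_mm=smoothed, outlier=outlier)
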