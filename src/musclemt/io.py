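"""Image/sequence I/O, configuration and pipeline orchestration.

Images are read as float grids in [0, 1], row 0 at the top; RGB input is
collapsed to luminance.  A single flat key=value configuration file governs
every stage so a run is fully reproducible from its logged config and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InputError
from .mvef import VesselnessParams
from .thickness import MTSeries, estimate_mt, smooth_series

__all__ = [
    "PipelineConfig",
    "load_image",
    "save_image",
    "crop",
    "load_config",
    "run_pipeline",
    "CSV_SCHEMA_HEADER",
]

logger = logging.getLogger(__name__)

CSV_SCHEMA_HEADER = (
    "# musclemt results schema v1: frame,path,mt_mm,mt_px,"
    "rho1,theta1_deg,votes1,rho2,theta2_deg,votes2,outlier,status"
)

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def load_image(path) -> np.ndarray:
    """Read a grayscale image as float64 in [0, 1] (row 0 at the top)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        raw = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - wrap with path context
        raise InputError(f"cannot read image {path}: {exc}") from exc
    arr = raw[..., :3].astype(float) @ _LUMA if raw.ndim == 3 else raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    return np.clip(arr, 0.0, 1.0)


def save_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG (or format by extension)."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def crop(image: np.ndarray, region: tuple[int, int, int, int]) -> np.ndarray:
    """Exact sub-grid copy; region = (top, bottom, left, right) bounds,
    rows [top:bottom) and columns [left:right)."""
    top, bottom, left, right = region
    h, w = image.shape[:2]
    if not (0 <= top < bottom <= h and 0 <= left < right <= w):
        raise InputError(f"crop region {region} invalid for image of shape {(h, w)}")
    return image[top:bottom, left:right].copy()


@dataclass
class PipelineConfig:
    """All tunable parameters of the measurement pipeline, one flat surface."""

    method: str = "mvef"
    pixel_spacing_mm: float = 0.1
    crop: tuple[int, int, int, int] | None = None
    # gabor
    gabor_block_size: int = 16
    gabor_sigma_x: float = 4.0
    gabor_sigma_y: float = 4.0
    gabor_reliability: float = 0.5
    # mvef
    mvef_scales: tuple[float, ...] = (1.5, 3.0, 5.0, 7.0)
    mvef_beta: float = 0.5
    # edge map
    threshold_method: str = "otsu"
    fixed_level: float | None = None
    # rvht
    rho_step: float = 1.0
    theta_step_deg: float = 1.0
    removal_halfwidth: float = 3.0
    n_lines: int = 2
    # series
    median_window: int = 5
    outlier_threshold_mm: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.method not in ("gabor", "mvef", "none"):
            raise InputError(f"unknown method {self.method!r}")
        if self.pixel_spacing_mm <= 0:
            raise InputError("pixel_spacing_mm must be > 0")
        if not (0 <= self.gabor_reliability <= 1):
            raise InputError("gabor_reliability must be in [0, 1]")
        if self.rho_step <= 0 or self.theta_step_deg <= 0:
            raise InputError("rho_step and theta_step_deg must be > 0")
        if self.n_lines < 2:
            raise InputError("n_lines must be >= 2 to measure a thickness")


def _parse_value(text: str):
    text = text.strip().strip("\"'")
    if "," in text:
        return tuple(_parse_value(t) for t in text.split(","))
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    if text.lower() in ("none", ""):
        return None
    return text


def load_config(path, into=PipelineConfig) -> "PipelineConfig":
    """Parse a flat key=value config file into a config dataclass.

    Lines starting with '#' or ';' (and blank lines) are ignored; keys must
    match the dataclass field names exactly.
    """
    known = {f.name for f in fields(into)}
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", ";", "[")):
            continue
        if "=" not in line:
            raise InputError(f"{path}:{lineno}: expected key = value, got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in known:
            raise InputError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = _parse_value(val)
    return into(**values)


def run_pipeline(
    config: PipelineConfig, inputs: list, out_csv=None
) -> tuple[pd.DataFrame, int]:
    """Measure thickness on every input frame; returns (results, n_failures).

    Per-frame failures are recorded in the `status` column and the run
    continues.  After all frames, the successful measurements are median
    smoothed to fill the `outlier` column (left empty when fewer frames than
    the window).  If ``out_csv`` is given the table is written with a
    versioned schema header comment.
    """
    config.validate()
    logger.info("pipeline config: %s", config)
    records = []
    for i, path in enumerate(inputs):
        rec = {"frame": i, "path": str(path), "status": "ok"}
        try:
            img = path if isinstance(path, np.ndarray) else load_image(path)
            if config.crop is not None:
                img = crop(img, config.crop)
            res = estimate_mt(
                img,
                method=config.method,
                pixel_spacing_mm=config.pixel_spacing_mm,
                gabor_params={
                    "block_size": config.gabor_block_size,
                    "sigma_x": config.gabor_sigma_x,
                    "sigma_y": config.gabor_sigma_y,
                    "reliability_threshold": config.gabor_reliability,
                },
                mvef_params=VesselnessParams(beta=config.mvef_beta, scales=tuple(config.mvef_scales)),
                threshold_method=config.threshold_method,
                fixed_level=config.fixed_level,
                rho_step=config.rho_step,
                theta_step=math.radians(config.theta_step_deg),
                halfwidth=config.removal_halfwidth,
                n_lines=config.n_lines,
                frame_index=i,
            )
            rec.update(
                mt_mm=res.mt_mm,
                mt_px=res.mt_px,
                rho1=res.superficial.rho,
                theta1_deg=math.degrees(res.superficial.theta),
                votes1=res.superficial.votes,
                rho2=res.deep.rho,
                theta2_deg=math.degrees(res.deep.theta),
                votes2=res.deep.votes,
            )
        except Exception as exc:  # noqa: BLE001 - per-frame isolation
            logger.warning("frame %d (%s) failed: %s", i, path, exc)
            rec["status"] = f"error: {exc}"
        records.append(rec)

    df = pd.DataFrame(records)
    if df.empty:
        logger.warning("empty input list: writing empty results")
        df = pd.DataFrame(
            columns=["frame", "path", "mt_mm", "mt_px", "rho1", "theta1_deg", "votes1",
                     "rho2", "theta2_deg", "votes2", "outlier", "status"]
        )
    n_failures = int((df.get("status", pd.Series(dtype=str)) != "ok").sum()) if len(df) else 0

    df["outlier"] = False
    ok = df["status"] == "ok" if len(df) else pd.Series(dtype=bool)
    if len(df) and ok.sum() >= config.median_window:
        series = MTSeries(frames=df.loc[ok, "frame"].to_numpy(), mt_mm=df.loc[ok, "mt_mm"].to_numpy())
        smoothed = smooth_series(series, config.median_window, config.outlier_threshold_mm)
        df.loc[ok, "outlier"] = smoothed.outlier

    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        with open(out_csv, "w") as fh:
            fh.write(CSV_SCHEMA_HEADER + "\n")
            df.to_csv(fh, index=False)
    return df, n_failures
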