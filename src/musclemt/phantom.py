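"""Synthetic ultrasound-like muscle phantoms with known aponeurosis geometry.

The generator emulates a longitudinal B-mode sonogram of a muscle belly:
two bright (hyperechoic) quasi-horizontal bands for the superficial and
deep aponeuroses, oblique periodic streaks for the fascicles / fibroadipose
septa between them, and multiplicative speckle over everything.  Because the
band geometry is known exactly, every downstream stage of the measurement
pipeline can be tested against ground truth.

The speckle model is a first-order surrogate for fully developed speckle:
each pixel is multiplied by an independent Gamma-distributed factor with
unit mean and standard deviation ``speckle_scale``.  No acoustic physics
(point-spread function, attenuation, TGC) is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .lines import Line, line_from_row_slope

__all__ = ["PhantomConfig", "GroundTruth", "generate_phantom", "generate_sequence"]


@dataclass
class PhantomConfig:
    """Geometry, texture and noise parameters of a muscle phantom.

    Rows are 0-based and increase downward, so ``superficial_row`` (nearer
    the probe) must be smaller than ``deep_row``.  ``band_slope`` applies to
    both aponeuroses unless overridden per band.  Intensities are in [0, 1].
    """

    height: int = 384
    width: int = 384
    superficial_row: float = 100.0
    deep_row: float = 250.0
    band_slope: float = 0.0
    superficial_slope: float | None = None
    deep_slope: float | None = None
    band_halfwidth: float = 3.0
    band_intensity: float = 0.9
    fascicle_angle: float = 15.0  # degrees from horizontal
    fascicle_period: float = 12.0  # px along the across-fascicle direction
    fascicle_contrast: float = 0.15  # peak elevation above background
    speckle_scale: float = 0.3  # SD of the unit-mean multiplicative factor
    background_level: float = 0.2
    pixel_spacing_mm: float = 0.1

    @property
    def slope_superficial(self) -> float:
        return self.band_slope if self.superficial_slope is None else self.superficial_slope

    @property
    def slope_deep(self) -> float:
        return self.band_slope if self.deep_slope is None else self.deep_slope

    def validate(self) -> None:
        if not (self.height >= 1 and self.width >= 1):
            raise ConfigurationError("height and width must be >= 1")
        if not (0 <= self.superficial_row < self.deep_row < self.height):
            raise ConfigurationError(
                "invariant violated: 0 <= superficial_row < deep_row < height "
                f"(got {self.superficial_row}, {self.deep_row}, height {self.height})"
            )
        if self.band_halfwidth < 1:
            raise ConfigurationError("invariant violated: band_halfwidth >= 1")
        if self.fascicle_period < 2:
            raise ConfigurationError("invariant violated: fascicle_period >= 2")
        if self.speckle_scale < 0:
            raise ConfigurationError("invariant violated: speckle_scale >= 0")
        if not (0 <= self.band_intensity <= 1 and 0 <= self.background_level <= 1):
            raise ConfigurationError("band_intensity and background_level must be in [0, 1]")
        if not (0 <= self.fascicle_contrast <= 1):
            raise ConfigurationError("fascicle_contrast must be in [0, 1]")
        if self.pixel_spacing_mm <= 0:
            raise ConfigurationError("pixel_spacing_mm must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """True aponeurosis lines and thickness of a generated phantom.

    ``mt_px`` is the mean vertical separation of the two band centerlines
    over all columns; ``mt_mm = mt_px * pixel_spacing_mm``.
    """

    superficial_line: Line
    deep_line: Line
    mt_px: float
    mt_mm: float


def _band_profile(rows: np.ndarray, center: np.ndarray, halfwidth: float) -> np.ndarray:
    # Gaussian cross-profile with sigma = halfwidth/2 so ridge filters see a
    # smooth crest rather than a hard rectangle
    sigma = halfwidth / 2.0
    return np.exp(-((rows - center) ** 2) / (2.0 * sigma**2))


def generate_phantom(config: PhantomConfig, seed: int) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom frame.

    Returns the image (float64 in [0, 1], shape (height, width)) and its
    :class:`GroundTruth`.  Identical (config, seed) pairs give bit-identical
    output.
    """
    config.validate()
    h, w = config.height, config.width
    x = np.arange(w, dtype=float)
    y = np.arange(h, dtype=float)[:, None]

    sup_center = config.superficial_row + config.slope_superficial * x
    deep_center = config.deep_row + config.slope_deep * x

    img = np.full((h, w), config.background_level, dtype=float)

    # fascicle texture: bright oblique streaks strictly between the bands
    if config.fascicle_contrast > 0:
        a = math.radians(config.fascicle_angle)
        # streak direction (cos a, sin a) in (col, row); phase varies across it
        phase = 2.0 * math.pi / config.fascicle_period * (-x * math.sin(a) + y * math.cos(a))
        streaks = np.maximum(np.sin(phase), 0.0)  # hyperechoic septa only
        margin = 2.0 * config.band_halfwidth
        between = (y > sup_center + margin) & (y < deep_center - margin)
        img = np.where(between, config.background_level + config.fascicle_contrast * streaks, img)

    # aponeurosis bands: max-composited so the centerline hits band_intensity
    img = np.maximum(img, config.band_intensity * _band_profile(y, sup_center, config.band_halfwidth))
    img = np.maximum(img, config.band_intensity * _band_profile(y, deep_center, config.band_halfwidth))

    if config.speckle_scale > 0:
        rng = np.random.default_rng(seed)
        shape = 1.0 / config.speckle_scale**2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)

    np.clip(img, 0.0, 1.0, out=img)

    mt_px = float(np.mean(deep_center - sup_center))
    truth = GroundTruth(
        superficial_line=line_from_row_slope(config.superficial_row, config.slope_superficial),
        deep_line=line_from_row_slope(config.deep_row, config.slope_deep),
        mt_px=mt_px,
        mt_mm=mt_px * config.pixel_spacing_mm,
    )
    return img, truth


def generate_sequence(
    config: PhantomConfig,
    n_frames: int,
    mt_trajectory: list[float],
    seed: int,
) -> tuple[list[np.ndarray], list[GroundTruth]]:
    """Render a frame sequence following a prescribed thickness trajectory.

    Frame ``i`` keeps the superficial band fixed and moves the deep band so
    the ground-truth thickness equals ``mt_trajectory[i]`` (in mm).  Speckle
    is drawn independently per frame from a stream derived from ``seed``.
    """
    if len(mt_trajectory) != n_frames:
        raise ConfigurationError(
            f"mt_trajectory has {len(mt_trajectory)} entries for n_frames={n_frames}"
        )
    # per-frame reproducible child seeds
    child = np.random.SeedSequence(seed).generate_state(max(n_frames, 1)) & 0x7FFFFFFF

    frames: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    slope_corr = (config.slope_deep - config.slope_superficial) * (config.width - 1) / 2.0
    for i, mt_mm in enumerate(mt_trajectory):
        mt_px = mt_mm / config.pixel_spacing_mm
        deep_row = config.superficial_row + mt_px - slope_corr
        if not (config.superficial_row < deep_row < config.height):
            raise ConfigurationError(
                f"frame {i}: trajectory value {mt_mm} mm puts the deep band at row "
                f"{deep_row:.1f}, outside the {config.height}-row image"
            )
        cfg_i = replace(config, deep_row=deep_row)
        img, truth = generate_phantom(cfg_i, int(child[i]))
        frames.append(img)
        truths.append(truth)
    return frames, truths
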