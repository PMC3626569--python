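"""Binarization of enhanced images into the edge map the Hough stage votes on."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import InputError

__all__ = ["EdgeMap", "binarize"]

logger = logging.getLogger(__name__)


@dataclass
class EdgeMap:
    """Binary grid of candidate feature pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_on(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def binarize(image: np.ndarray, method: str = "otsu", level: float | None = None) -> EdgeMap:
    """Threshold an image into an edge map.

    ``method="otsu"`` maximizes between-class variance over a 256-bin
    histogram; ``method="fixed"`` uses the supplied ``level``.  The mask is
    ``image > threshold`` in both cases, so both enhancement outputs (which
    suppress background toward 0) give strongly bimodal inputs.
    """
    image = np.asarray(image, dtype=float)
    if method == "fixed":
        if level is None:
            raise InputError("method='fixed' requires a level")
        threshold = float(level)
    elif method == "otsu":
        if image.max() == image.min():
            logger.warning("constant image under Otsu thresholding: edge map is empty")
            threshold = float(image.flat[0])
        else:
            threshold = float(threshold_otsu(image, nbins=256))
    else:
        raise InputError(f"unknown binarization method {method!r}")
    return EdgeMap(mask=image > threshold)
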