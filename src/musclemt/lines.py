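"""Normal-form straight lines in pixel coordinates.

A line is stored as (rho, theta): a pixel at column ``x``, row ``y`` lies on
the line iff ``x*cos(theta) + y*sin(theta) == rho``.  ``theta`` is the angle
of the line's normal, kept in ``[0, pi)`` so that each undirected line has a
unique representation; ``rho`` is signed.  Row index increases downward
("deeper" in the ultrasound image), so a quasi-horizontal aponeurosis has
``theta`` close to ``pi/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Line:
    """A detected line with the Hough votes that supported it."""

    rho: float
    theta: float
    votes: int = 0

    def row_at(self, x: np.ndarray | float) -> np.ndarray | float:
        """Row coordinate of the line at column(s) ``x``.

        Undefined for vertical lines (``sin(theta) == 0``).
        """
        s = math.sin(self.theta)
        return (self.rho - np.asarray(x, dtype=float) * math.cos(self.theta)) / s

    @property
    def is_near_vertical(self) -> bool:
        return abs(math.sin(self.theta)) < 1e-6


def line_from_row_slope(row0: float, slope: float) -> Line:
    """Line through (col=0, row=row0) with d(row)/d(col) = slope.

    Returns the (rho, theta) normal form with theta in [0, pi).  For a
    horizontal line this is (row0, pi/2).
    """
    # normal to direction vector (1, slope) is (-slope, 1)/norm; its angle
    # atan2(1, -slope) lies in (0, pi) for every finite slope
    theta = math.atan2(1.0, -slope)
    rho = row0 * math.sin(theta)
    return Line(rho=rho, theta=theta)
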