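"""Revoting Hough Transform (RVHT) line detection.

The standard Hough transform finds the single most dominant line as the
global maximum of the (rho, theta) accumulator.  RVHT iterates: detect the
accumulator's global peak, remove the edge-map pixels close to that line,
recompute the accumulator from the pruned map, and repeat.  Because removal
only deletes votes, the vote counts of successive lines are non-increasing,
and full re-accumulation (rather than accumulator subtraction) avoids
aliasing between neighbouring bins.

Accumulator conventions, chosen for exactness and testability:

* theta bins at ``i * theta_step`` for ``i in [0, round(pi/theta_step))``;
* rho bins at ``-ceil(D) + j * rho_step`` with D the image diagonal, so
  with the default 1 px step the bins sit on integers;
* every on-pixel votes in exactly one rho bin per theta bin (nearest bin,
  half-up rounding), so total votes == n_on * n_theta_bins exactly;
* peak ties break deterministically to the smallest theta bin, then the
  smallest rho bin.

The accumulator is hand-rolled rather than delegated to a library routine
so that these conventions (and the exact-count invariants built on them)
hold by construction in the revoting loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .edgemap import EdgeMap
from .errors import InputError, NoLineError
from .lines import Line

__all__ = ["Accumulator", "hough_accumulate", "find_peak", "remove_line_pixels", "rvht_detect"]

DEFAULT_RHO_STEP = 1.0
DEFAULT_THETA_STEP = math.radians(1.0)
DEFAULT_HALFWIDTH = 3.0


@dataclass
class Accumulator:
    """Hough vote counts indexed by (rho_bin, theta_bin)."""

    counts: np.ndarray  # (n_rho, n_theta) int64
    rho_step: float
    theta_step: float
    rho_min: float

    @property
    def thetas(self) -> np.ndarray:
        return np.arange(self.counts.shape[1]) * self.theta_step

    @property
    def rhos(self) -> np.ndarray:
        return self.rho_min + np.arange(self.counts.shape[0]) * self.rho_step

    @property
    def total_votes(self) -> int:
        return int(self.counts.sum())


def hough_accumulate(
    edge: EdgeMap,
    rho_step: float = DEFAULT_RHO_STEP,
    theta_step: float = DEFAULT_THETA_STEP,
) -> Accumulator:
    """Accumulate Hough votes for every on-pixel over all theta bins."""
    if rho_step <= 0 or theta_step <= 0:
        raise InputError("rho_step and theta_step must be > 0")
    h, w = edge.shape
    n_theta = int(round(math.pi / theta_step))
    diag = math.hypot(h - 1, w - 1)
    rho_min = -math.ceil(diag)
    n_rho = int(math.floor(2 * math.ceil(diag) / rho_step)) + 1

    counts = np.zeros((n_rho, n_theta), dtype=np.int64)
    ys, xs = np.nonzero(edge.mask)
    if len(xs) == 0:
        return Accumulator(counts, rho_step, theta_step, rho_min)

    thetas = np.arange(n_theta) * theta_step
    for ti, theta in enumerate(thetas):
        rho = xs * math.cos(theta) + ys * math.sin(theta)
        idx = np.floor((rho - rho_min) / rho_step + 0.5).astype(np.int64)  # half-up
        counts[:, ti] = np.bincount(idx, minlength=n_rho)
    return Accumulator(counts, rho_step, theta_step, rho_min)


def find_peak(acc: Accumulator) -> Line:
    """Global accumulator maximum as a Line; ties break to the smallest
    theta bin, then the smallest rho bin."""
    peak = int(acc.counts.max(initial=0))
    if peak == 0:
        raise NoLineError("accumulator is empty: no line to extract")
    # argmax over the transposed array scans theta-major, giving the tie rule
    flat = int(np.argmax(acc.counts.T))
    ti, ri = divmod(flat, acc.counts.shape[0])
    return Line(rho=acc.rho_min + ri * acc.rho_step, theta=ti * acc.theta_step, votes=peak)


def remove_line_pixels(edge: EdgeMap, line: Line, halfwidth: float = DEFAULT_HALFWIDTH) -> EdgeMap:
    """Turn off every on-pixel within perpendicular distance ``halfwidth``
    of the line; all other pixels are unchanged."""
    if halfwidth < 0:
        raise InputError("halfwidth must be >= 0")
    ys, xs = np.nonzero(edge.mask)
    dist = np.abs(xs * math.cos(line.theta) + ys * math.sin(line.theta) - line.rho)
    mask = edge.mask.copy()
    off = dist <= halfwidth
    mask[ys[off], xs[off]] = False
    return EdgeMap(mask=mask)


def rvht_detect(
    edge: EdgeMap,
    n_lines: int = 2,
    rho_step: float = DEFAULT_RHO_STEP,
    theta_step: float = DEFAULT_THETA_STEP,
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> list[Line]:
    """Detect up to ``n_lines`` dominant lines by accumulate / peak / remove.

    Stops early when the edge map empties; returned vote counts are
    non-increasing across iterations.
    """
    if n_lines < 1:
        raise InputError("n_lines must be >= 1")
    lines: list[Line] = []
    current = edge
    for _ in range(n_lines):
        acc = hough_accumulate(current, rho_step, theta_step)
        try:
            line = find_peak(acc)
        except NoLineError:
            break
        lines.append(line)
        current = remove_line_pixels(current, line, halfwidth)
    return lines
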