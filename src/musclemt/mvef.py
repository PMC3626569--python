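"""Multiscale vessel enhancement filtering (Frangi-style vesselness).

Ridge detection from second-order local structure: at each Gaussian scale
sigma the image Hessian is estimated by convolution with scale-normalized
second-derivative kernels (gamma = 1, i.e. multiplied by sigma^2), its
eigenvalues (|lambda1| <= |lambda2|) classify the local geometry, and the
vesselness response combines a blobness term R_B = lambda1/lambda2 with a
structureness term S = sqrt(lambda1^2 + lambda2^2):

    V = 0                                           if lambda2 >= 0
    V = exp(-R_B^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2))   otherwise

(bright-on-dark polarity: hyperechoic aponeuroses have lambda2 < 0).  The
final response is the pixel-wise maximum over the scale set.

When ``c`` is not given it is set per scale to half the maximum Frobenius
norm of the Hessian over the image, the usual auto-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InputError

__all__ = ["HessianEigen", "VesselnessParams", "hessian_eigen", "vesselness", "mvef_enhance"]


@dataclass
class HessianEigen:
    """Ordered Hessian eigenvalue fields at one scale (|lambda1| <= |lambda2|)."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    scale: float


@dataclass
class VesselnessParams:
    """beta: blobness weight; c: structureness weight (None = per-scale auto);
    scales: Gaussian sigmas in pixels."""

    beta: float = 0.5
    c: float | None = None
    scales: tuple[float, ...] = (1.5, 3.0, 5.0, 7.0)

    def validate(self) -> None:
        if self.beta <= 0:
            raise InputError("beta must be > 0")
        if self.c is not None and self.c <= 0:
            raise InputError("c must be > 0 when given")
        if len(self.scales) == 0 or any(s <= 0 for s in self.scales):
            raise InputError("scales must be a nonempty list of positive sigmas")


def hessian_eigen(image: np.ndarray, sigma: float) -> HessianEigen:
    """Eigenvalues of the scale-normalized Gaussian Hessian at ``sigma``."""
    if sigma <= 0:
        raise InputError("sigma must be > 0")
    image = np.asarray(image, dtype=float)
    # remove the DC component: truncated derivative kernels do not sum to
    # exactly zero, and the Hessian must ignore constant offsets
    image = image - image.mean()
    s2 = sigma**2
    hrr = gaussian_filter(image, sigma, order=(2, 0)) * s2
    hcc = gaussian_filter(image, sigma, order=(0, 2)) * s2
    hrc = gaussian_filter(image, sigma, order=(1, 1)) * s2

    half_trace = (hrr + hcc) / 2.0
    root = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc**2)
    e1 = half_trace + root
    e2 = half_trace - root
    swap = np.abs(e1) > np.abs(e2)
    lam1 = np.where(swap, e2, e1)
    lam2 = np.where(swap, e1, e2)
    return HessianEigen(lambda1=lam1, lambda2=lam2, scale=sigma)


def vesselness(eig: HessianEigen, params: VesselnessParams | None = None) -> np.ndarray:
    """Single-scale vesselness response in [0, 1]."""
    params = params or VesselnessParams()
    params.validate()
    lam1, lam2 = eig.lambda1, eig.lambda2

    s_norm = np.sqrt(lam1**2 + lam2**2)
    c = params.c
    if c is None:
        smax = float(s_norm.max())
        if smax <= 0:
            return np.zeros_like(lam1)
        c = 0.5 * smax

    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(lam2 != 0, (lam1 / np.where(lam2 != 0, lam2, 1.0)) ** 2, 0.0)
    resp = np.exp(-rb2 / (2.0 * params.beta**2)) * (1.0 - np.exp(-(s_norm**2) / (2.0 * c**2)))
    resp = np.where(lam2 < 0, resp, 0.0)  # bright structures only; lambda2 == 0 -> 0
    return np.clip(resp, 0.0, 1.0)


def mvef_enhance(image: np.ndarray, params: VesselnessParams | None = None) -> np.ndarray:
    """Pixel-wise maximum vesselness over the scale set, in [0, 1]."""
    params = params or VesselnessParams()
    params.validate()
    image = np.asarray(image, dtype=float)
    out = np.zeros_like(image)
    for sigma in params.scales:
        out = np.maximum(out, vesselness(hessian_eigen(image, sigma), params))
    return out
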