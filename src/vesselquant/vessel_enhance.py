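"""Multiscale Hessian vesselness for bright tubular structures.

The image is convolved with sampled Gaussian derivative kernels (FIR,
truncated at 4 sigma, reflective boundaries) to obtain the scale-normalized
Hessian; the two eigenvalues of the symmetric 2x2 matrix are combined into
a tubularity response in [0, 1], and the response is maximised over a user
set of scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import correlate1d

from .raster_io import RasterImage

__all__ = [
    "VesselnessParams",
    "HessianField",
    "VesselnessMap",
    "gaussian_hessian",
    "hessian_eigenvalues",
    "vesselness_at_scale",
    "multiscale_vesselness",
    "sigma_from_diameter",
]


def sigma_from_diameter(diameter: float) -> float:
    """Map a user-facing vessel diameter to a Gaussian scale (sigma = d/2)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return diameter / 2.0


@dataclass(frozen=True)
class VesselnessParams:
    """Parameters of the tubularity filter.

    ``c=None`` requests automatic structureness sensitivity: half the
    maximum Frobenius norm of the scale-normalized Hessian — resolved over
    all scales jointly in :func:`multiscale_vesselness` (so the per-pixel
    scale maximisation is informative), and per scale when
    :func:`vesselness_at_scale` is called standalone.
    """

    sigmas: tuple[float, ...]
    beta: float = 0.5
    c: float | None = None
    gamma: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigmas", tuple(float(s) for s in self.sigmas))
        if len(self.sigmas) == 0:
            raise ValueError("sigmas must be nonempty")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("all sigmas must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.c is not None and self.c <= 0:
            raise ValueError("c must be positive (or None for auto)")


@dataclass(frozen=True)
class HessianField:
    """gamma-normalized second Gaussian derivatives at one scale.

    ``ixx`` differentiates along columns (x), ``iyy`` along rows (y); the
    field is symmetric by construction (a single ``ixy`` is stored).
    """

    ixx: np.ndarray
    ixy: np.ndarray
    iyy: np.ndarray
    sigma: float


@dataclass(frozen=True)
class VesselnessMap:
    """Per-pixel multiscale response in [0,1] and the best-responding scale."""

    response: np.ndarray
    best_scale: np.ndarray


# Hessian norms at or below this floor are treated as no signal when
# auto-resolving c (keeps constant images at exactly-zero response instead
# of amplifying numerical noise).
_S_FLOOR = 1e-9


def _derivative_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian-derivative FIR kernel, truncated at 4 sigma.

    Truncation removes a few percent of the derivative kernels' moments, so
    the kernels are moment-corrected: order 0 sums to 1; order 1 has zero
    sum (odd) and unit first moment; order 2 has exactly zero sum (constants
    give exactly zero response) and second moment 2 (x^2 gives exactly 2).
    """
    radius = int(math.ceil(4.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-(x**2) / (2.0 * sigma**2))
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = -x / sigma**2 * phi  # antisymmetric: zero-sum by construction
        return k / np.dot(x, k)  # unit response to f(x) = x
    if order == 2:
        k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
        k -= k.mean()  # zero response to constants
        return k * (2.0 / np.dot(x**2, k))  # response 2 to f(x) = x^2
    raise ValueError(f"unsupported derivative order: {order}")


def _as_float_grid(image: "RasterImage | np.ndarray") -> np.ndarray:
    if isinstance(image, RasterImage):
        return image.pixels.astype(np.float64)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grid")
    return arr


def gaussian_hessian(
    image: "RasterImage | np.ndarray", sigma: float, gamma: float = 2.0
) -> HessianField:
    """Scale-normalized Hessian entries (Ixx, Ixy, Iyy) at scale *sigma*.

    FIR convolution with sampled Gaussian derivative kernels, truncated at
    4 sigma, reflective boundary handling; entries are multiplied by
    ``sigma**gamma``.

    The mixed derivative is symmetrised over the two axis orders so that
    90-degree grid rotations commute with the filter bit-exactly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    arr = _as_float_grid(image)
    k0 = _derivative_kernel(sigma, 0)
    k1 = _derivative_kernel(sigma, 1)
    k2 = _derivative_kernel(sigma, 2)

    def _filt(a: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
        return correlate1d(a, kernel, axis=axis, mode="reflect")

    # smooth first, then differentiate along the orthogonal axis
    ixx = _filt(_filt(arr, k0, 0), k2, 1)
    iyy = _filt(_filt(arr, k0, 1), k2, 0)
    ixy = 0.5 * (_filt(_filt(arr, k1, 0), k1, 1) + _filt(_filt(arr, k1, 1), k1, 0))

    norm = sigma**gamma
    return HessianField(ixx * norm, ixy * norm, iyy * norm, sigma=float(sigma))


def hessian_eigenvalues(field: HessianField) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (l1, l2) of [[Ixx, Ixy], [Ixy, Iyy]] with |l1| <= |l2|.

    Closed form for symmetric 2x2 matrices; absolute-value ordering with
    ties broken by signed value ascending.
    """
    mean = 0.5 * (field.ixx + field.iyy)
    disc = np.sqrt((0.5 * (field.ixx - field.iyy)) ** 2 + field.ixy**2)
    lo, hi = mean - disc, mean + disc  # signed ascending
    swap = np.abs(lo) > np.abs(hi)
    l1 = np.where(swap, hi, lo)
    l2 = np.where(swap, lo, hi)
    return l1, l2


def _blobness_structureness(
    l1: np.ndarray, l2: np.ndarray, beta: float, c: float
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(l2 != 0, (l1 / np.where(l2 != 0, l2, 1.0)) ** 2, 0.0)
    s2 = l1**2 + l2**2
    resp = np.exp(-rb2 / (2.0 * beta**2)) * (1.0 - np.exp(-s2 / (2.0 * c**2)))
    return np.where(l2 < 0, resp, 0.0)


def vesselness_at_scale(
    l1: np.ndarray, l2: np.ndarray, params: VesselnessParams
) -> np.ndarray:
    """Single-scale tubularity response for bright vessels on dark background.

    Zero where l2 >= 0, else ``exp(-R_B^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2))``
    with ``R_B = l1/l2`` and ``S = sqrt(l1^2 + l2^2)``. When ``params.c`` is
    None, c is resolved per call as half the maximum S over the grids.
    """
    l1 = np.asarray(l1, dtype=np.float64)
    l2 = np.asarray(l2, dtype=np.float64)
    if l1.shape != l2.shape:
        raise ValueError("eigenvalue grids must be congruent")
    c = params.c
    if c is None:
        s_max = float(np.sqrt((l1**2 + l2**2).max(initial=0.0)))
        c = 0.5 * s_max if s_max > _S_FLOOR else 1.0
    return _blobness_structureness(l1, l2, params.beta, c)


def multiscale_vesselness(
    image: "RasterImage | np.ndarray", params: VesselnessParams
) -> VesselnessMap:
    """Maximise the tubularity response over ``params.sigmas``.

    Intensities are normalized to [0, 1] by the bit depth first (when a
    RasterImage is given) so one parameter set works across depths.
    ``best_scale`` records the argmax sigma, the first maximal one on ties;
    where the response is 0 it holds the first sigma.
    """
    if isinstance(image, RasterImage):
        arr = image.normalized()
    else:
        arr = _as_float_grid(image)

    eigs: list[tuple[np.ndarray, np.ndarray]] = []
    for sigma in params.sigmas:
        field = gaussian_hessian(arr, sigma, gamma=params.gamma)
        eigs.append(hessian_eigenvalues(field))

    c = params.c
    if c is None:
        # resolved globally over all scales so the per-pixel argmax over
        # sigmas stays informative (a per-scale c would tie all scales)
        s_max = max(
            float(np.sqrt((l1**2 + l2**2).max(initial=0.0))) for l1, l2 in eigs
        )
        c = 0.5 * s_max if s_max > _S_FLOOR else 1.0

    response = np.zeros_like(arr, dtype=np.float64)
    best = np.full(arr.shape, params.sigmas[0], dtype=np.float64)
    for sigma, (l1, l2) in zip(params.sigmas, eigs):
        resp = _blobness_structureness(l1, l2, params.beta, c)
        better = resp > response  # strict: first maximal sigma wins ties
        response[better] = resp[better]
        best[better] = sigma
    return VesselnessMap(response=response, best_scale=best)
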