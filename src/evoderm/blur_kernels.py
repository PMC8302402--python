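"""Motion-blur point-spread functions and the eight-member parametric filter bank.

Linear camera motion during exposure convolves the scene with a line-segment
point-spread function (PSF) parameterized by the motion ``length`` (pixels)
and ``theta`` (degrees counterclockwise from the horizontal axis).  The same
module builds the small parametric kernels (average, disk, gaussian,
laplacian, LoG, motion, median-equivalent box, unsharp) that the genetic
search uses as a secondary correction stage, and applies any kernel to an
image by convolution with symmetric boundary padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "SMOOTHING",
    "DERIVATIVE_LIKE",
    "FILTER_FAMILIES",
    "InvalidParameterError",
    "MotionBlurSpec",
    "FilterBankSpec",
    "Kernel",
    "make_motion_psf",
    "make_filter",
    "apply_kernel",
]

SMOOTHING = "smoothing"
DERIVATIVE_LIKE = "derivative-like"

#: Integer codes of the filter bank, in chromosome gene-value order.
FILTER_FAMILIES = {
    1: "average",
    2: "disk",
    3: "gaussian",
    4: "laplacian",
    5: "log",
    6: "motion",
    7: "median_box",
    8: "unsharp",
}

_SUPERSAMPLE = 8  # line samples per pixel of motion length


class InvalidParameterError(ValueError):
    """Raised when a kernel specification is outside its valid domain."""


@dataclass(frozen=True)
class MotionBlurSpec:
    """Uniform linear camera motion: ``length`` pixels at ``theta`` degrees.

    ``theta`` is measured counterclockwise from the horizontal axis; the
    generating range used throughout the package is length 9..100 and theta
    0..5 degrees, but any finite length >= 1 is accepted.
    """

    length: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.length) and math.isfinite(self.theta)):
            raise InvalidParameterError("motion-blur parameters must be finite")
        if self.length < 1:
            raise InvalidParameterError(
                f"motion length must be >= 1 pixel, got {self.length}"
            )


@dataclass(frozen=True)
class FilterBankSpec:
    """Parameters of one member of the filter bank.

    Each family reads only its relevant genes and ignores the rest:
    average/median_box use ``hsize``; disk uses ``radius``; gaussian and log
    use ``hsize`` and ``sigma``; laplacian and unsharp use ``alpha``; motion
    uses ``length`` and ``theta``.
    """

    type: int
    hsize: int = 3
    radius: float = 1.0
    sigma: float = 0.5
    alpha: float = 0.2
    length: float = 9.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.type not in FILTER_FAMILIES:
            raise InvalidParameterError(f"unknown filter type code {self.type}")
        if self.hsize < 1 or self.hsize % 2 == 0:
            raise InvalidParameterError(f"hsize must be a positive odd integer, got {self.hsize}")
        if not self.radius > 0:
            raise InvalidParameterError(f"radius must be positive, got {self.radius}")
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")
        if not 0 < self.alpha <= 1:
            raise InvalidParameterError(f"alpha must lie in (0, 1], got {self.alpha}")

    @property
    def family(self) -> str:
        return FILTER_FAMILIES[self.type]


@dataclass(frozen=True)
class Kernel:
    """A small 2-D array of filter coefficients with a normalization class.

    Smoothing kernels have nonnegative entries summing to 1; derivative-like
    kernels sum to their analytic total (0 for laplacian/log, 1 for unsharp).
    """

    coefficients: np.ndarray = field(repr=False)
    kind: str

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=float)
        if coeff.ndim != 2 or coeff.shape[0] % 2 == 0 or coeff.shape[1] % 2 == 0:
            raise InvalidParameterError("kernel must be 2-D with odd dimensions")
        if self.kind not in (SMOOTHING, DERIVATIVE_LIKE):
            raise InvalidParameterError(f"unknown kernel kind {self.kind!r}")
        object.__setattr__(self, "coefficients", coeff)

    @property
    def shape(self) -> tuple[int, int]:
        return self.coefficients.shape


def make_motion_psf(spec: MotionBlurSpec) -> Kernel:
    """Rasterize the line-segment PSF of uniform linear motion.

    The segment of the given length, centered on the kernel center, is
    sampled at 8 points per pixel of length; each sample deposits its weight
    into the nearest bin along the dominant axis and splits linearly between
    the two neighboring bins along the minor axis.  The result is the
    smallest odd-dimension bounding box of the segment, normalized to sum 1.
    """
    length = float(spec.length)
    theta = math.radians(float(spec.theta))
    if length == 1.0:
        return Kernel(np.array([[1.0]]), SMOOTHING)

    dx, dy = math.cos(theta), math.sin(theta)
    n = max(1, int(math.ceil(_SUPERSAMPLE * length)))
    t = (np.arange(n) + 0.5) / n - 0.5  # midpoint rule, symmetric about 0
    xs = t * length * dx
    ys = t * length * dy

    # Dominant axis gets nearest-bin assignment (so an axis-aligned segment of
    # length L covers exactly round(L) uniform pixels); the minor axis gets
    # linear (anti-aliased) splitting so the PSF varies continuously in theta.
    if abs(dx) >= abs(dy):
        major, minor = xs, ys
        transpose = False
    else:
        major, minor = ys, xs
        transpose = True

    mj = np.rint(major).astype(int)
    lo = np.floor(minor).astype(int)
    frac = minor - lo
    carry = frac > 1e-12  # samples that spill into the bin above
    half_major = int(np.max(np.abs(mj)))
    half_minor = int(np.max(np.abs(lo)))
    if carry.any():
        half_minor = max(half_minor, int(np.max(np.abs(lo[carry] + 1))))
    grid = np.zeros((2 * half_minor + 1, 2 * half_major + 1))
    w = 1.0 / n
    np.add.at(grid, (lo + half_minor, mj + half_major), (1.0 - frac) * w)
    if carry.any():
        np.add.at(
            grid,
            (lo[carry] + 1 + half_minor, mj[carry] + half_major),
            frac[carry] * w,
        )

    grid[grid < 1e-12] = 0.0  # drop float dust from near-axis angles
    # trim all-zero border rows/cols, keeping the box odd and centered
    while grid.shape[0] > 1 and not grid[0].any() and not grid[-1].any():
        grid = grid[1:-1]
    while grid.shape[1] > 1 and not grid[:, 0].any() and not grid[:, -1].any():
        grid = grid[:, 1:-1]

    if transpose:
        grid = grid.T
    # positive theta tilts the segment counterclockwise: up in image terms,
    # i.e. toward smaller row indices
    grid = grid[::-1].copy()
    return Kernel(grid / grid.sum(), SMOOTHING)


def _average(hsize: int) -> np.ndarray:
    return np.full((hsize, hsize), 1.0 / (hsize * hsize))


def _disk(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    ss = 8
    ax = np.arange(-r, r + 1)
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    xx = ax[:, None] + sub[None, :]  # (2r+1, ss) subpixel coordinates
    # fraction of subpixel centers inside the disk, per pixel
    X = xx.reshape(2 * r + 1, 1, ss, 1)
    Y = xx.reshape(1, 2 * r + 1, 1, ss)
    inside = (X**2 + Y**2) <= radius**2
    grid = inside.mean(axis=(2, 3))
    if grid.sum() == 0:
        grid[r, r] = 1.0
    return grid / grid.sum()


def _gaussian(hsize: int, sigma: float) -> np.ndarray:
    ax = np.arange(hsize) - (hsize - 1) / 2
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _laplacian(alpha: float) -> np.ndarray:
    # parametric 3x3 Laplacian stencil; entries sum to 0 for any alpha
    a = alpha
    k = np.array(
        [
            [a / 4, (1 - a) / 4, a / 4],
            [(1 - a) / 4, -1.0, (1 - a) / 4],
            [a / 4, (1 - a) / 4, a / 4],
        ]
    )
    return k * (4.0 / (a + 1.0))


def _log(hsize: int, sigma: float) -> np.ndarray:
    # Laplacian of Gaussian; mean-subtracted so the response to a flat field
    # is exactly zero
    ax = np.arange(hsize) - (hsize - 1) / 2
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    g = np.exp(-r2 / (2 * sigma**2))
    g /= g.sum()
    k = g * (r2 - 2 * sigma**2) / sigma**4
    return k - k.mean()


def _median_box(hsize: int) -> np.ndarray:
    # cross-shaped (plus) box: the uniform smoothing surrogate of a
    # cross-window median filter
    k = np.zeros((hsize, hsize))
    c = hsize // 2
    k[c, :] = 1.0
    k[:, c] = 1.0
    return k / k.sum()


def _unsharp(alpha: float) -> np.ndarray:
    # identity minus parametric Laplacian; entries sum to 1
    a = alpha
    k = np.array(
        [
            [-a, a - 1, -a],
            [a - 1, a + 5, a - 1],
            [-a, a - 1, -a],
        ]
    )
    return k / (a + 1.0)


def make_filter(spec: FilterBankSpec) -> Kernel:
    """Build the kernel of the filter family selected by ``spec.type``."""
    family = spec.family
    if family == "average":
        return Kernel(_average(spec.hsize), SMOOTHING)
    if family == "disk":
        return Kernel(_disk(spec.radius), SMOOTHING)
    if family == "gaussian":
        return Kernel(_gaussian(spec.hsize, spec.sigma), SMOOTHING)
    if family == "laplacian":
        return Kernel(_laplacian(spec.alpha), DERIVATIVE_LIKE)
    if family == "log":
        return Kernel(_log(spec.hsize, spec.sigma), DERIVATIVE_LIKE)
    if family == "motion":
        return make_motion_psf(MotionBlurSpec(spec.length, spec.theta))
    if family == "median_box":
        return Kernel(_median_box(spec.hsize), SMOOTHING)
    if family == "unsharp":
        return Kernel(_unsharp(spec.alpha), DERIVATIVE_LIKE)
    raise InvalidParameterError(f"unknown filter family {family!r}")  # pragma: no cover


def _convolve2d(plane: np.ndarray, coeff: np.ndarray) -> np.ndarray:
    """2-D convolution with symmetric padding; FFT path for large kernels."""
    if coeff.size <= 81:
        return ndimage.convolve(plane, coeff, mode="reflect")
    ph, pw = coeff.shape[0] // 2, coeff.shape[1] // 2
    padded = np.pad(plane, ((ph, ph), (pw, pw)), mode="symmetric")
    return signal.fftconvolve(padded, coeff, mode="valid")


def apply_kernel(image: np.ndarray, kernel: Kernel, clip: bool = True) -> np.ndarray:
    """Convolve an image (2-D, or 3-D filtered channel-wise) with a kernel.

    Boundaries are handled with symmetric padding; the output has the shape
    of the input and, for ``clip=True``, is clipped to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise InvalidParameterError("image must be 2-D or 3-D")
    if not np.all(np.isfinite(image)):
        raise InvalidParameterError("image must be finite")
    coeff = kernel.coefficients
    if coeff.shape[0] > image.shape[0] or coeff.shape[1] > image.shape[1]:
        raise InvalidParameterError(
            f"kernel {coeff.shape} larger than image {image.shape[:2]}"
        )
    if image.ndim == 2:
        out = _convolve2d(image, coeff)
    else:
        out = np.dstack([_convolve2d(image[..., c], coeff) for c in range(image.shape[-1])])
    return np.clip(out, 0.0, 1.0) if clip else out
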