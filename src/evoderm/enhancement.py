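"""Chromosome-to-image restoration: the operator the GA's fitness evaluates.

A chromosome is a blur hypothesis plus a secondary correction.  Enhancement
runs two stages: (1) frequency-domain regularized inverse (Wiener-form)
deconvolution with the motion PSF built from the chromosome's ``length`` and
``theta``; (2) the secondary filter selected by ``type`` — smoothing kernels
by plain convolution, derivative-like kernels as an additive unsharp-style
correction.  Output is clipped to [0, 1] and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .blur_kernels import (
    SMOOTHING,
    FilterBankSpec,
    Kernel,
    MotionBlurSpec,
    apply_kernel,
    make_filter,
    make_motion_psf,
)

__all__ = ["RestorationConfig", "DegradedRestorationWarning", "wiener_deconvolve", "enhance"]


class DegradedRestorationWarning(RuntimeWarning):
    """Signals that an ill-conditioned inverse was replaced by the unprocessed input."""


@dataclass(frozen=True)
class RestorationConfig:
    """Noise-to-signal regularization of the deconvolution step."""

    regularization: float = 3e-4
    clip: bool = True

    def __post_init__(self) -> None:
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")


def _psf_otf(psf: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Optical transfer function: FFT of the PSF centered at the origin."""
    padded = np.zeros(shape)
    kh, kw = psf.shape
    padded[:kh, :kw] = psf
    padded = np.roll(padded, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return sp_fft.rfft2(padded)


def _wiener_plane(plane: np.ndarray, psf: np.ndarray, nsr: float) -> np.ndarray:
    kh, kw = psf.shape
    ph, pw = kh, kw  # symmetric pad by the full kernel extent kills wrap-around
    padded = np.pad(plane, ((ph, ph), (pw, pw)), mode="symmetric")
    H = _psf_otf(psf, padded.shape)
    denom = (H * np.conj(H)).real + nsr
    denom[denom == 0] = np.inf  # unregularized zeros of the OTF pass nothing
    G = np.conj(H) / denom
    out = sp_fft.irfft2(sp_fft.rfft2(padded) * G, s=padded.shape)
    return out[ph : ph + plane.shape[0], pw : pw + plane.shape[1]]


def wiener_deconvolve(
    image: np.ndarray, psf: Kernel | np.ndarray, nsr: float = 1e-2
) -> np.ndarray:
    """Regularized inverse filter ``conj(H) / (|H|^2 + nsr)`` per channel."""
    coeff = psf.coefficients if isinstance(psf, Kernel) else np.asarray(psf, float)
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return _wiener_plane(image, coeff, nsr)
    return np.dstack(
        [_wiener_plane(image[..., c], coeff, nsr) for c in range(image.shape[-1])]
    )


def enhance(image: np.ndarray, chromosome, config: RestorationConfig | None = None) -> np.ndarray:
    """Restore an image under a chromosome's blur hypothesis.

    Falls back to the unprocessed input (with a :class:`DegradedRestorationWarning`)
    if the inverse produces non-finite values, so a GA fitness evaluation
    always receives a valid image.
    """
    if config is None:
        config = RestorationConfig()
    image = np.asarray(image, dtype=float)

    psf = make_motion_psf(MotionBlurSpec(chromosome.length, chromosome.theta))
    out = wiener_deconvolve(image, psf, config.regularization)

    spec = FilterBankSpec(
        type=int(chromosome.type),
        hsize=int(chromosome.hsize),
        radius=chromosome.radius,
        sigma=chromosome.sigma,
        alpha=chromosome.alpha,
        length=chromosome.length,
        theta=chromosome.theta,
    )
    if spec.family != "motion":  # re-blurring with the motion PSF would undo stage 1
        kernel = make_filter(spec)
        if kernel.kind == SMOOTHING:
            out = apply_kernel(out, kernel, clip=False)
        else:
            out = out + apply_kernel(out, kernel, clip=False)

    if not np.all(np.isfinite(out)):
        warnings.warn(
            "ill-conditioned restoration produced non-finite values; "
            "returning the unprocessed input",
            DegradedRestorationWarning,
            stacklevel=2,
        )
        out = image
    return np.clip(out, 0.0, 1.0) if config.clip else out
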