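"""Naturalness Image Quality Evaluator (NIQE): a no-reference quality score.

The score measures how far an image's natural-scene statistics sit from those
of pristine images; smaller is better.  The pipeline is the classical one:

1. mean-subtracted contrast-normalized (MSCN) coefficients
   ``(I - mu) / (sigma + C)`` with a Gaussian-weighted local mean and
   standard deviation — near unit-variance Gaussian for undistorted images;
2. asymmetric generalized Gaussian (AGGD) fits, by gamma-ratio moment
   matching, to the MSCN field and its four directional pairwise products,
   per patch and at two scales (18 features per scale, 36 per patch);
3. a pristine model (mean vector and covariance of patch features pooled
   over a sharp-texture corpus) and the Mahalanobis-type distance
   ``sqrt((nu1-nu2)^T ((S1+S2)/2)^+ (nu1-nu2))`` between the model and the
   test image's patch-feature distribution.

Because no pre-trained reference model is assumed, the default model is
fitted on the packaged synthetic texture corpus; scores are comparable
within a model, which is all a relative fitness ranking requires.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import gamma as _gamma_fn

__all__ = [
    "InvalidInputError",
    "DegenerateInputError",
    "InsufficientDataError",
    "MSCNField",
    "AGGDParams",
    "NIQEModel",
    "compute_mscn",
    "fit_aggd",
    "image_patch_features",
    "extract_features",
    "fit_pristine_model",
    "niqe_score",
    "default_model",
    "to_grayscale",
]

#: default stabilizer on the [0, 1] intensity scale (1 gray level of 8-bit)
DEFAULT_C = 1.0 / 255.0
#: Gaussian weighting window: 7x7, sigma 7/6
_WINDOW_SIGMA = 7.0 / 6.0
_WINDOW_RADIUS = 3

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])  # ITU-R 601


class InvalidInputError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


# --- AGGD moment-matching lookup ------------------------------------------

_ALPHA_GRID = np.arange(0.05, 10.0 + 1e-9, 0.001)
_RHO_GRID = (
    _gamma_fn(2.0 / _ALPHA_GRID) ** 2
    / (_gamma_fn(1.0 / _ALPHA_GRID) * _gamma_fn(3.0 / _ALPHA_GRID))
)  # strictly increasing in alpha, range (0, 0.75)


@dataclass(frozen=True)
class AGGDParams:
    """Asymmetric generalized Gaussian parameters (moment-matching fit)."""

    shape: float
    left_scale: float
    right_scale: float
    mean_offset: float


def fit_aggd(samples: np.ndarray) -> AGGDParams:
    """Fit an AGGD by the standard gamma-ratio moment-matching estimator.

    Deterministic for fixed input.  Requires at least 100 finite samples
    that are not all equal.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise InvalidInputError(f"need >= 100 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("samples must be finite")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero-variance input")

    left = x[x < 0]
    right = x[x >= 0]
    left_sd = np.sqrt(np.mean(left**2)) if left.size else 0.0
    right_sd = np.sqrt(np.mean(right**2)) if right.size else 0.0
    eps = np.finfo(float).tiny
    gamma_hat = (left_sd + eps) / (right_sd + eps)
    r_hat = np.mean(np.abs(x)) ** 2 / np.mean(x**2)
    r_norm = (
        r_hat
        * (gamma_hat**3 + 1.0)
        * (gamma_hat + 1.0)
        / (gamma_hat**2 + 1.0) ** 2
    )
    alpha = float(np.interp(r_norm, _RHO_GRID, _ALPHA_GRID))
    conv = np.sqrt(_gamma_fn(1.0 / alpha) / _gamma_fn(3.0 / alpha))
    beta_l = left_sd * conv
    beta_r = right_sd * conv
    eta = (beta_r - beta_l) * _gamma_fn(2.0 / alpha) / _gamma_fn(1.0 / alpha)
    return AGGDParams(alpha, float(beta_l), float(beta_r), float(eta))


# --- MSCN -------------------------------------------------------------------


@dataclass(frozen=True)
class MSCNField:
    """Mean-subtracted contrast-normalized coefficients and their stabilizer."""

    values: np.ndarray = field(repr=False)
    stabilizer: float = DEFAULT_C
    local_sd: np.ndarray | None = field(default=None, repr=False)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance (ITU-R 601 weights) of an RGB image; 2-D input passes through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[-1] == 3:
        return image @ _LUMA_WEIGHTS
    raise InvalidInputError(f"expected 2-D or RGB image, got shape {image.shape}")


def compute_mscn(
    image_gray: np.ndarray,
    sigma_window: float = _WINDOW_SIGMA,
    C: float = DEFAULT_C,
) -> MSCNField:
    """Local Gaussian-weighted normalization ``(I - mu) / (sigma + C)``."""
    img = np.asarray(image_gray, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("compute_mscn expects a 2-D grayscale image")
    if min(img.shape) < 2 * _WINDOW_RADIUS + 1:
        raise InvalidInputError(
            f"image {img.shape} smaller than the {2 * _WINDOW_RADIUS + 1}-pixel window"
        )
    mu = ndimage.gaussian_filter(img, sigma_window, radius=_WINDOW_RADIUS)
    mu2 = ndimage.gaussian_filter(img * img, sigma_window, radius=_WINDOW_RADIUS)
    sigma = np.sqrt(np.maximum(mu2 - mu * mu, 0.0))
    return MSCNField((img - mu) / (sigma + C), C, sigma)


def _directional_products(mscn: np.ndarray) -> tuple[np.ndarray, ...]:
    # horizontal, vertical, main-diagonal, anti-diagonal neighbor products
    h = mscn[:, :-1] * mscn[:, 1:]
    v = mscn[:-1, :] * mscn[1:, :]
    d1 = mscn[:-1, :-1] * mscn[1:, 1:]
    d2 = mscn[:-1, 1:] * mscn[1:, :-1]
    return h, v, d1, d2


def _patch_scale_features(mscn: np.ndarray) -> np.ndarray:
    """18 features of one patch at one scale."""
    feats = np.empty(18)
    p = fit_aggd(mscn)
    feats[0] = p.shape
    feats[1] = 0.5 * (p.left_scale + p.right_scale)
    for i, prod in enumerate(_directional_products(mscn)):
        p = fit_aggd(prod)
        feats[2 + 4 * i : 6 + 4 * i] = (p.shape, p.mean_offset, p.left_scale, p.right_scale)
    return feats


def _half_scale(img: np.ndarray) -> np.ndarray:
    # 2x2 block mean (low-pass + decimate)
    h, w = img.shape[0] // 2 * 2, img.shape[1] // 2 * 2
    a = img[:h, :w]
    return 0.25 * (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2])


def image_patch_features(
    image_gray: np.ndarray,
    patch_size: int = 96,
    sharpness_fraction: float = 0.75,
    C: float = DEFAULT_C,
    stride: int | None = None,
) -> np.ndarray:
    """Per-patch 36-feature vectors of an image, shape ``(n_patches, 36)``.

    The image is tiled into ``patch_size`` squares spaced ``stride`` pixels
    apart (default: non-overlapping); patches whose mean local variance falls
    below the ``sharpness_fraction`` quantile are excluded (flat skin regions
    carry little quality information), and the 18 half-resolution features of
    each surviving patch are appended.  Overlapping strides increase the
    number of feature samples, stabilizing the mean and covariance on small
    images.
    """
    img = np.asarray(image_gray, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("expected a 2-D grayscale image")
    if min(img.shape) < 2 * patch_size:
        raise InvalidInputError(
            f"image {img.shape} must be at least twice the patch size {patch_size} per side"
        )
    if stride is None:
        stride = patch_size
    if stride < 1 or stride % 2:
        raise InvalidInputError("stride must be a positive even integer")
    full = compute_mscn(img, C=C)
    half = compute_mscn(_half_scale(img), C=C)

    ny = (img.shape[0] - patch_size) // stride + 1
    nx = (img.shape[1] - patch_size) // stride + 1
    # center the tiling so mirroring maps the patch grid onto itself
    oy = (img.shape[0] - ((ny - 1) * stride + patch_size)) // 2
    ox = (img.shape[1] - ((nx - 1) * stride + patch_size)) // 2

    sharp = np.empty(ny * nx)
    coords = []
    for iy in range(ny):
        for ix in range(nx):
            y = oy + iy * stride
            x = ox + ix * stride
            sharp[len(coords)] = np.mean(
                full.local_sd[y : y + patch_size, x : x + patch_size] ** 2
            )
            coords.append((y, x))
    threshold = np.quantile(sharp, sharpness_fraction)
    keep = [c for c, s in zip(coords, sharp) if s >= threshold]

    hp = patch_size // 2
    feats = np.empty((len(keep), 36))
    for row, (y, x) in enumerate(keep):
        pf = full.values[y : y + patch_size, x : x + patch_size]
        ph = half.values[y // 2 : y // 2 + hp, x // 2 : x // 2 + hp]
        feats[row, :18] = _patch_scale_features(pf)
        feats[row, 18:] = _patch_scale_features(ph)
    return feats


def extract_features(
    image_gray: np.ndarray,
    patch_size: int = 96,
    sharpness_fraction: float = 0.75,
    C: float = DEFAULT_C,
    stride: int | None = None,
) -> np.ndarray:
    """Mean 36-entry feature vector of an image (average over kept patches)."""
    return image_patch_features(
        image_gray, patch_size, sharpness_fraction, C, stride
    ).mean(axis=0)


# --- pristine model and score ----------------------------------------------

_MODEL_FORMAT = "evoderm-niqe-model-v1"


@dataclass(frozen=True)
class NIQEModel:
    """Mean and covariance of pristine patch features; the scoring reference."""

    feature_mean: np.ndarray = field(repr=False)
    feature_cov: np.ndarray = field(repr=False)
    patch_size: int = 96
    sharpness_fraction: float = 0.75
    stride: int | None = None

    def __post_init__(self) -> None:
        mean = np.asarray(self.feature_mean, dtype=float)
        cov = np.asarray(self.feature_cov, dtype=float)
        if mean.ndim != 1 or cov.shape != (mean.size, mean.size):
            raise InvalidInputError("inconsistent model dimensions")
        if not np.allclose(cov, cov.T, atol=1e-9):
            raise InvalidInputError("covariance must be symmetric")
        object.__setattr__(self, "feature_mean", mean)
        object.__setattr__(self, "feature_cov", cov)

    def save(self, path: str | Path) -> None:
        payload = {
            "format": _MODEL_FORMAT,
            "patch_size": self.patch_size,
            "sharpness_fraction": self.sharpness_fraction,
            "stride": self.stride,
            "feature_mean": self.feature_mean.tolist(),
            "feature_cov": self.feature_cov.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "NIQEModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != _MODEL_FORMAT:
            raise InvalidInputError(f"not a {_MODEL_FORMAT} file: {path}")
        return cls(
            np.array(payload["feature_mean"]),
            np.array(payload["feature_cov"]),
            int(payload["patch_size"]),
            float(payload["sharpness_fraction"]),
            payload.get("stride"),
        )


def fit_pristine_model(
    corpus: list[np.ndarray],
    patch_size: int = 96,
    sharpness_fraction: float = 0.75,
    stride: int | None = None,
) -> NIQEModel:
    """Fit the pristine reference: feature mean/covariance pooled over patches."""
    if len(corpus) < 10:
        raise InsufficientDataError(f"corpus must hold >= 10 images, got {len(corpus)}")
    feats = np.vstack(
        [
            image_patch_features(to_grayscale(img), patch_size, sharpness_fraction,
                                 stride=stride)
            for img in corpus
        ]
    )
    mean = feats.mean(axis=0)
    if feats.shape[0] > 1:
        cov = np.cov(feats, rowvar=False)
    else:
        cov = np.zeros((feats.shape[1], feats.shape[1]))
    cov = 0.5 * (cov + cov.T)
    return NIQEModel(mean, cov, patch_size, sharpness_fraction, stride)


@dataclass(frozen=True)
class NIQEScore:
    """A nonnegative, unitless quality index; smaller means more natural."""

    score: float

    def __float__(self) -> float:
        return self.score


def niqe_score(image: np.ndarray, model: NIQEModel) -> NIQEScore:
    """Distance of an image's patch-feature distribution from the model.

    ``sqrt((nu1-nu2)^T ((S1+S2)/2)^+ (nu1-nu2))`` with a pseudo-inverse to
    tolerate rank deficiency; deterministic.
    """
    gray = to_grayscale(image)
    feats = image_patch_features(gray, model.patch_size, model.sharpness_fraction,
                                 stride=model.stride)
    nu = feats.mean(axis=0)
    if feats.shape[0] > 1:
        cov = np.cov(feats, rowvar=False)
    else:
        cov = np.zeros((feats.shape[1], feats.shape[1]))
    pooled = 0.5 * (model.feature_cov + cov)
    diff = model.feature_mean - nu
    dist2 = float(diff @ np.linalg.pinv(pooled, hermitian=True) @ diff)
    return NIQEScore(float(np.sqrt(max(dist2, 0.0))))


@functools.lru_cache(maxsize=1)
def default_model() -> NIQEModel:
    """The packaged pristine model, fitted on the synthetic texture corpus."""
    from .synthetic_data import make_pristine_corpus

    corpus = make_pristine_corpus(25, size=288, seed=7)
    return fit_pristine_model(corpus, patch_size=48, stride=24)
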