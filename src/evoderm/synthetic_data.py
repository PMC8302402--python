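"""Seeded generators for lesion-like images, pristine texture corpora and labels.

Nothing in the package needs an external dataset: this module produces
(i) lesion photographs — a compact darker elliptical lesion with an irregular
border on correlated-noise skin texture — whose border sharpness visibly
degrades under motion blur, (ii) a corpus of sharp multi-scale textures with
natural-scene-like statistics on which the no-reference quality model is
fitted, and (iii) synthetic true/predicted label sets realizing prescribed
per-class accuracies.  Every generator is bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "InsufficientDataError",
    "LesionImageSpec",
    "LabelSetSpec",
    "DEFAULT_CLASS_ORDER",
    "make_lesion_image",
    "lesion_mask",
    "make_pristine_corpus",
    "make_label_set",
]


class InsufficientDataError(ValueError):
    """Raised when a generator is asked for fewer samples than it can support."""


@dataclass(frozen=True)
class LesionImageSpec:
    """Parameters of a synthetic skin-lesion photograph (square RGB frame)."""

    size: int = 256
    lesion_axes: tuple[float, float] = (58.0, 42.0)
    border_irregularity: float = 0.12
    lesion_color: tuple[float, float, float] = (0.38, 0.24, 0.20)
    skin_color: tuple[float, float, float] = (0.78, 0.60, 0.52)
    texture_scale: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.lesion_axes
        if not (a > 0 and b > 0):
            raise ValueError("lesion axes must be positive")
        if max(a, b) * (1 + 2 * max(self.border_irregularity, 0)) >= self.size / 2:
            raise ValueError("lesion does not fit inside the frame")
        if not 0 <= self.noise_sd < 0.2:
            raise ValueError("noise_sd must lie in [0, 0.2)")
        if self.border_irregularity < 0:
            raise ValueError("border_irregularity must be >= 0")


def _correlated_field(rng: np.random.Generator, size: int,
                      scales_amps: list[tuple[float, float]]) -> np.ndarray:
    """Zero-mean multi-scale texture: sum of Gaussian-filtered white noise."""
    out = np.zeros((size, size))
    for scale, amp in scales_amps:
        f = ndimage.gaussian_filter(rng.standard_normal((size, size)), scale)
        sd = f.std()
        if sd > 0:
            out += amp * f / sd
    return out


def make_lesion_image(spec: LesionImageSpec) -> np.ndarray:
    """Render a lesion-like RGB image in [0, 1], deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size

    texture = _correlated_field(
        rng, size, [(1.0, 0.5), (3.0, 0.3), (8.0, 0.2)]
    ) * 0.10 * spec.texture_scale

    # elliptical lesion with a sinusoid-perturbed boundary radius
    ax = np.arange(size) - (size - 1) / 2
    xx, yy = np.meshgrid(ax, ax)
    a, b = spec.lesion_axes
    phi = np.arctan2(yy / b, xx / a)
    r = np.hypot(xx / a, yy / b)
    wobble = np.zeros_like(phi)
    for k in (3, 5, 8):
        wobble += rng.uniform(0.3, 1.0) * np.sin(k * phi + rng.uniform(0, 2 * np.pi))
    boundary = 1.0 + spec.border_irregularity * wobble / 3.0
    mask = (r <= boundary).astype(float)
    mask = ndimage.gaussian_filter(mask, 1.0)  # soft sub-pixel edge

    skin = np.asarray(spec.skin_color)
    lesion = np.asarray(spec.lesion_color)
    channel_gain = np.array([1.0, 0.85, 0.7])  # texture is strongest in red
    img = skin[None, None, :] + mask[..., None] * (lesion - skin)[None, None, :]
    img = img + texture[..., None] * channel_gain[None, None, :]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def lesion_mask(spec: LesionImageSpec) -> np.ndarray:
    """Boolean interior mask of the lesion rendered by :func:`make_lesion_image`.

    Replays the generator's random draws so the mask matches the image of the
    same spec exactly.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    _ = _correlated_field(rng, size, [(1.0, 0.5), (3.0, 0.3), (8.0, 0.2)])
    ax = np.arange(size) - (size - 1) / 2
    xx, yy = np.meshgrid(ax, ax)
    a, b = spec.lesion_axes
    phi = np.arctan2(yy / b, xx / a)
    r = np.hypot(xx / a, yy / b)
    wobble = np.zeros_like(phi)
    for k in (3, 5, 8):
        wobble += rng.uniform(0.3, 1.0) * np.sin(k * phi + rng.uniform(0, 2 * np.pi))
    boundary = 1.0 + spec.border_irregularity * wobble / 3.0
    return r <= boundary


def make_pristine_corpus(n: int, size: int = 288, seed: int = 0) -> list[np.ndarray]:
    """Generate ``n`` sharp grayscale skin-like textures for quality-model fitting.

    The no-reference quality model is only meaningful when fitted on the
    statistics of the pristine image domain being restored, so each corpus
    image reproduces the luminance statistics of an undistorted lesion
    photograph: fine/medium/coarse correlated texture at skin-like contrast,
    a soft-edged darker elliptical region standing in for the lesion's macro
    structure, and a dash of white sensor grain.  Deterministic per seed.
    """
    if n < 10:
        raise InsufficientDataError(f"a pristine corpus needs >= 10 images, got {n}")
    rng = np.random.default_rng(seed)
    ax = np.arange(size) - (size - 1) / 2
    xx, yy = np.meshgrid(ax, ax)
    corpus = []
    for _ in range(n):
        scales = [
            (rng.uniform(0.8, 1.3), 0.5),
            (rng.uniform(2.5, 4.0), 0.3),
            (rng.uniform(6.0, 10.0), 0.2),
        ]
        texture = _correlated_field(rng, size, scales)
        texture = texture / texture.std() * rng.uniform(0.045, 0.070)
        img = rng.uniform(0.45, 0.72) + texture
        # macro structure: a soft-edged darker ellipse at random pose
        a, b = rng.uniform(size / 7, size / 3, 2)
        th = rng.uniform(0, np.pi)
        xr = xx * np.cos(th) + yy * np.sin(th)
        yr = -xx * np.sin(th) + yy * np.cos(th)
        blob = (np.hypot(xr / a, yr / b) <= 1).astype(float)
        img = img - rng.uniform(0.15, 0.35) * ndimage.gaussian_filter(blob, 1.0)
        img = img + rng.normal(0.0, rng.uniform(0.010, 0.018), (size, size))
        corpus.append(np.clip(img, 0.0, 1.0))
    return corpus


# ---------------------------------------------------------------------------
# label sets

#: Class order used for every tabular output of the package (row order of the
#: bundled seven-class dermoscopy case study).
DEFAULT_CLASS_ORDER = (
    "melanoma",
    "melanocytic nevus",
    "basal cell carcinoma",
    "actinic keratosis",
    "benign keratosis",
    "vascular lesion",
    "squamous cell carcinoma",
)


@dataclass(frozen=True)
class LabelSetSpec:
    """Recipe for a synthetic (true, predicted) label set.

    For each class exactly ``round(accuracy * count)`` predictions are
    correct; the remaining errors are spread over the other classes either
    uniformly in rotation (``spread='cyclic'``) or at random
    (``spread='random'``).
    """

    class_names: tuple[str, ...] = DEFAULT_CLASS_ORDER
    counts: tuple[int, ...] = (130, 201, 128, 40, 54, 13, 23)
    accuracies: tuple[float, ...] = (1.0,) * 7
    spread: str = "cyclic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.class_names) == len(self.counts) == len(self.accuracies)):
            raise ValueError("class_names, counts and accuracies must align")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")
        if any(not 0 <= a <= 1 for a in self.accuracies):
            raise ValueError("accuracies must lie in [0, 1]")
        if self.spread not in ("cyclic", "random"):
            raise ValueError("spread must be 'cyclic' or 'random'")


def make_label_set(spec: LabelSetSpec) -> tuple[list[str], list[str]]:
    """Materialize true and predicted label lists realizing the spec exactly."""
    rng = np.random.default_rng(spec.seed)
    true_labels: list[str] = []
    pred_labels: list[str] = []
    names = list(spec.class_names)
    for i, (name, count, acc) in enumerate(
        zip(names, spec.counts, spec.accuracies)
    ):
        n_correct = int(round(acc * count))
        n_wrong = count - n_correct
        true_labels.extend([name] * count)
        pred_labels.extend([name] * n_correct)
        others = [c for c in names if c != name]
        if spec.spread == "cyclic":
            wrong = [others[j % len(others)] for j in range(n_wrong)]
        else:
            wrong = list(rng.choice(others, size=n_wrong))
        pred_labels.extend(wrong)
    return true_labels, pred_labels
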