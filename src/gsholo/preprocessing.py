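"""Image preprocessing: RGB cell image -> normalised square greyscale amplitude.

The retrieval consumes a real amplitude in [0, 1] on a square grid (256x256
by default).  The pipeline is: optional centred crop, luma-weighted greyscale
conversion (ITU-R BT.601 weights 0.299/0.587/0.114), local-mean (area)
resampling to the target size, and min-max normalisation to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize_local_mean

from .errors import DegenerateInputWarning, FormatError, InvalidConfigError, ShapeError

__all__ = [
    "AmplitudeImage",
    "to_grayscale",
    "resize_square",
    "normalize01",
    "center_crop",
    "preprocess_image",
]

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class AmplitudeImage:
    """A normalised amplitude in [0, 1] on a square grid."""

    values: np.ndarray
    source_dims: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"amplitude must be 2-D, got shape {self.values.shape}")
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ShapeError("amplitude values must lie in [0, 1]")
        self.source_dims = tuple(int(d) for d in self.source_dims)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def to_grayscale(rgb_image: np.ndarray) -> np.ndarray:
    """Luma-weighted greyscale in [0, 1] from a 3-channel image.

    Integer images are scaled by their dtype maximum before weighting; float
    images are assumed already on [0, 1].
    """
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise FormatError(f"expected an H x W x 3 image, got shape {rgb_image.shape}")
    if np.issubdtype(rgb_image.dtype, np.integer):
        scale = float(np.iinfo(rgb_image.dtype).max)
        rgb = rgb_image.astype(float) / scale
    else:
        rgb = rgb_image.astype(float)
    return np.clip(rgb @ _LUMA_WEIGHTS, 0.0, 1.0)


def resize_square(image: np.ndarray, target: int) -> np.ndarray:
    """Area-style (local-mean) resample of a 2-D image to target x target.

    An image already at the target size is returned unchanged; local-mean
    resampling keeps output values inside the input's [min, max] range and
    maps constants to themselves.
    """
    image = np.asarray(image, dtype=float)
    target = int(target)
    if target < 2:
        raise InvalidConfigError(f"target size must be >= 2, got {target}")
    if image.ndim != 2 or min(image.shape) < 2:
        raise ShapeError(f"expected a 2-D image with dims >= 2, got shape {image.shape}")
    if image.shape == (target, target):
        return image.copy()
    return resize_local_mean(image, (target, target))


def normalize01(image: np.ndarray, source_dims: tuple[int, int] | None = None) -> AmplitudeImage:
    """Min-max rescale to [0, 1], packaged as an :class:`AmplitudeImage`.

    Constant images are degenerate: all-zeros are returned with a
    :class:`DegenerateInputWarning` (same convention as phase normalisation).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {image.shape}")
    dims = tuple(source_dims) if source_dims is not None else image.shape
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        warnings.warn("constant image; returning all zeros", DegenerateInputWarning)
        return AmplitudeImage(np.zeros_like(image), dims)
    return AmplitudeImage((image - lo) / (hi - lo), dims)


def center_crop(image: np.ndarray, box: tuple[int, int]) -> np.ndarray:
    """Centred crop to (height, width); the box must fit inside the image."""
    image = np.asarray(image)
    h, w = int(box[0]), int(box[1])
    if h < 2 or w < 2:
        raise InvalidConfigError(f"crop box must be >= 2 per axis, got {box}")
    if h > image.shape[0] or w > image.shape[1]:
        raise ShapeError(f"crop box {box} exceeds image dims {image.shape[:2]}")
    top = (image.shape[0] - h) // 2
    left = (image.shape[1] - w) // 2
    return image[top : top + h, left : left + w]


def preprocess_image(
    image: np.ndarray,
    target: int = 256,
    crop: tuple[int, int] | None = None,
) -> AmplitudeImage:
    """Full pipeline: [crop] -> greyscale -> area resize -> min-max normalise.

    Accepts an RGB (H x W x 3) or greyscale (H x W) image and returns a
    ``target x target`` amplitude in [0, 1].  Running the pipeline on its own
    output is the identity.
    """
    image = np.asarray(image)
    source_dims = image.shape[:2]
    if crop is not None:
        image = center_crop(image, crop)
    if image.ndim == 3:
        gray = to_grayscale(image)
    elif image.ndim == 2:
        gray = image.astype(float)
    else:
        raise FormatError(f"expected a 2-D or H x W x 3 image, got shape {image.shape}")
    resized = resize_square(gray, target)
    return normalize01(resized, source_dims)
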