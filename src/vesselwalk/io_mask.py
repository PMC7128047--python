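"""Image loading, working-channel extraction and field-of-view masking.

Fundus photographs show the retina through a circular camera aperture; all
computation and evaluation is restricted to that field of view (FOV).  The
green channel of the RGB photograph carries the best vessel/background
contrast and is used as the working image throughout the pipeline.

Conventions: images are row-major ``(row, col)`` arrays with 0-based pixel
coordinates; intensities are normalized to ``[0, 1]`` immediately at load,
and every downstream parameter is interpreted on that scale.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import morphology


class DegenerateInputError(ValueError):
    """Raised when an input leaves a stage with nothing to work on."""


def load_image(path: str | Path) -> np.ndarray:
    """Load an RGB image from ``path`` as an ``H x W x 3`` uint8 array.

    Grayscale files are replicated to three channels (with a warning);
    an alpha channel, if present, is dropped.

    Raises
    ------
    IOError
        If the file cannot be read.
    ValueError
        If the decoded image has zero size.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps many decoder errors
        raise IOError(f"cannot read image file: {path}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 2:
        warnings.warn(
            f"{path.name}: grayscale input replicated to 3 channels",
            stacklevel=2,
        )
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image shape {arr.shape}: {path}")
    return arr


def normalize_intensity(channel: np.ndarray) -> np.ndarray:
    """Rescale an integer or float channel to float64 in ``[0, 1]``.

    Integer dtypes are divided by their dtype maximum; float inputs are
    assumed to already lie in ``[0, 1]`` and are clipped.
    """
    channel = np.asarray(channel)
    if np.issubdtype(channel.dtype, np.integer):
        out = channel.astype(np.float64) / np.iinfo(channel.dtype).max
    else:
        out = np.clip(channel.astype(np.float64), 0.0, 1.0)
    return out


def green_channel(img: np.ndarray) -> np.ndarray:
    """Extract the green channel of an RGB image, normalized to ``[0, 1]``."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {img.shape}")
    return normalize_intensity(img[:, :, 1])


def compute_fov_mask(
    img: np.ndarray,
    low_frac: float = 0.15,
    open_radius: int = 3,
) -> np.ndarray:
    """Estimate the circular field-of-view mask of a fundus photograph.

    The red channel is brightest inside the aperture, so the mask is the
    largest 4-connected component of ``red > low_frac * max(red)``,
    morphologically opened with a disc of ``open_radius`` pixels and with
    interior holes filled.

    Raises
    ------
    DegenerateInputError
        If no pixel survives; lowering ``low_frac`` may help.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {img.shape}")
    red = normalize_intensity(img[:, :, 0])
    bright = red > low_frac * red.max()
    if not bright.any():
        raise DegenerateInputError(
            f"empty FOV mask at low_frac={low_frac}; try a lower threshold"
        )
    labels, n = ndimage.label(bright, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        sizes = ndimage.sum_labels(bright, labels, index=np.arange(1, n + 1))
        bright = labels == (1 + int(np.argmax(sizes)))
    if open_radius > 0:
        bright = morphology.opening(bright, morphology.disk(open_radius))
    bright = ndimage.binary_fill_holes(bright)
    if not bright.any():
        raise DegenerateInputError(
            f"FOV mask vanished after opening (radius {open_radius}); "
            f"try a lower low_frac than {low_frac}"
        )
    return bright


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG with values 0/255."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def save_float_png(path: str | Path, values: np.ndarray) -> None:
    """Write a float map in ``[0, 1]`` as a 16-bit PNG."""
    v = np.clip(np.asarray(values, np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(v * 65535).astype(np.uint16))
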