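"""Intensity preprocessing: histogram, histogram equalization, median filter.

Images are 2-D integer arrays on the gray scale [0, L-1] (L = 256 for 8-bit
input). Equalization maps input level v to round((L-1) * CDF(v)) with
round-half-away-from-zero — the plain cumulative-distribution remap, with no
cdf-min renormalization, so a constant image maps to L-1.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage


def validate_image(image: np.ndarray, levels: int = 256) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {image.shape}")
    if not np.issubdtype(image.dtype, np.integer):
        raise ValueError(f"expected integer pixels, got dtype {image.dtype}")
    if image.min() < 0 or image.max() > levels - 1:
        raise ValueError(f"pixels outside [0, {levels - 1}]")
    return image


def compute_histogram(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Normalized histogram Z with one bin per feasible intensity.

    Z[n] = (# pixels of level n) / (total pixels); sums to one.
    """
    image = validate_image(image, levels)
    counts = np.bincount(image.ravel(), minlength=levels)
    return counts / image.size


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def equalization_map(hist: np.ndarray, levels: int = 256) -> np.ndarray:
    """Level -> level lookup table for histogram equalization.

    Maps v to round((L-1) * sum_{n<=v} Z_n); monotone non-decreasing.
    """
    cdf = np.cumsum(hist)
    return _round_half_away((levels - 1) * cdf).astype(np.int64)


def equalize(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Histogram-equalize an image via its cumulative distribution."""
    image = validate_image(image, levels)
    lut = equalization_map(compute_histogram(image, levels), levels)
    out = lut[image]
    return out.astype(np.uint8) if levels <= 256 else out


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Square median filter; borders handled by edge replication."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    image = validate_image(image)
    return ndimage.median_filter(image, size=window, mode="nearest")


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF (RGB input is averaged to gray)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = np.rint(arr[..., :3].mean(axis=-1)).astype(np.uint8)
    return validate_image(arr)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, validate_image(image).astype(np.uint8))


def read_dicom(path: str | Path) -> np.ndarray:
    """Optional thin DICOM reader: pixel array rescaled to 8-bit.

    Requires the ``pydicom`` extra; raises ImportError otherwise.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    arr = arr * float(getattr(ds, "RescaleSlope", 1.0)) + float(getattr(ds, "RescaleIntercept", 0.0))
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    else:
        arr = np.zeros_like(arr)
    return np.rint(arr).astype(np.uint8)
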