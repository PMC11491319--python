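"""Local binary pattern (LBP) texture codes and histograms.

The code of a pixel compares H sampling points on a circle of radius R
against the center: bit h is 1 when the neighbor is greater than or equal
to the center (ties count as 1), and the code is sum_h bit_h * 2^h.
Neighbor h = 0 lies due east and the index proceeds counterclockwise;
circle points are sampled by nearest-neighbor rounding. Codes are therefore
invariant under any strictly increasing intensity transform. Border pixels
(closer than R to an edge) are excluded rather than padded — padding would
fabricate texture at image edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import validate_image
from .segment import NoduleRegion


@dataclass(frozen=True)
class LBPConfig:
    """H sampling points on a circle of radius R (defaults: classic 8, 1)."""

    H: int = 8
    R: int = 1

    def validate(self) -> None:
        if self.H < 4:
            raise ValueError("H must be >= 4")
        if self.R < 1:
            raise ValueError("R must be >= 1")

    def offsets(self) -> list[tuple[int, int]]:
        """(drow, dcol) per neighbor: east start, counterclockwise."""
        out = []
        for h in range(self.H):
            angle = 2.0 * np.pi * h / self.H
            # counterclockwise on screen: +x east, +y up = -row
            out.append((-int(round(self.R * np.sin(angle))), int(round(self.R * np.cos(angle)))))
        return out


def lbp_code(center: float, neighbors, H: int | None = None) -> int:
    """Code of one pixel from its ordered neighbor intensities.

    ``H``, when given, asserts the expected sampling-point count; at least
    four neighbors are required either way.
    """
    neighbors = np.asarray(neighbors, dtype=float)
    if H is not None and neighbors.size != H:
        raise ValueError(f"expected {H} neighbors, got {neighbors.size}")
    if neighbors.size < 4:
        raise ValueError(f"need at least 4 neighbors, got {neighbors.size}")
    bits = (neighbors - center >= 0).astype(np.int64)
    return int(bits @ (2 ** np.arange(neighbors.size)))


def lbp_map(image: np.ndarray, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Code image over the interior (pixels >= R from every border).

    Returns an array of shape (rows - 2R, cols - 2R) of integer codes in
    [0, 2^H - 1]; entry (i, j) is the code of image pixel (i + R, j + R).
    """
    config.validate()
    image = validate_image(image)
    rows, cols = image.shape
    R = config.R
    if rows <= 2 * R or cols <= 2 * R:
        raise ValueError(f"image {image.shape} too small for radius {R}")
    img = image.astype(np.int64)
    center = img[R : rows - R, R : cols - R]
    codes = np.zeros_like(center)
    for h, (dr, dc) in enumerate(config.offsets()):
        neighbor = img[R + dr : rows - R + dr, R + dc : cols - R + dc]
        codes += ((neighbor - center) >= 0).astype(np.int64) << h
    return codes


def lbp_histogram(
    code_image: np.ndarray,
    mask: np.ndarray | None = None,
    H: int = 8,
) -> np.ndarray:
    """Normalized 2^H-bin histogram of codes, optionally within a mask.

    ``mask`` has the same shape as the code image (i.e. already cropped to
    the coded interior).
    """
    codes = np.asarray(code_image)
    if mask is not None:
        codes = codes[np.asarray(mask, dtype=bool)]
    codes = codes.ravel()
    if codes.size == 0:
        raise ValueError("no coded pixels in region")
    counts = np.bincount(codes, minlength=2**H)
    return counts / codes.size


def feature_vector(
    image: np.ndarray,
    nodule: NoduleRegion,
    config: LBPConfig = LBPConfig(),
) -> np.ndarray:
    """Per-nodule descriptor: LBP histogram over the nodule mask, then
    area, equivalent diameter, centroid (row, col), mean intensity.

    Length is 2^H + 5 (261 for the default H = 8).
    """
    codes = lbp_map(image, config)
    R = config.R
    full_mask = nodule.mask(image.shape)
    interior = full_mask[R:-R, R:-R]
    hist = lbp_histogram(codes, mask=interior, H=config.H)
    mean_intensity = nodule.mean_intensity
    if mean_intensity is None:
        mean_intensity = float(image[full_mask].mean())
    tail = np.array(
        [nodule.area, nodule.equivalent_diameter, nodule.centroid[0], nodule.centroid[1], mean_intensity],
        dtype=float,
    )
    return np.concatenate([hist, tail])
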