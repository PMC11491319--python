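"""Otsu thresholding — exhaustive bilevel and CBO-optimized multilevel —
and nodule region extraction.

The Otsu criterion is the between-class variance of the classes a threshold
set induces on the gray-level histogram,

    sigma_B^2 = sum_j w_j (mu_j - mu_T)^2,

maximized over strictly increasing integer thresholds t_1 < ... < t_k in
[0, L-2] (class j = levels in (t_{j-1}, t_j]). The CBO route minimizes the
positive fitness 1/(1 + sigma_B^2) over continuous positions that are
rounded, sorted, and de-duplicated at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from . import cbo as cbo_mod
from .preprocess import compute_histogram, validate_image


def _class_edges(thresholds: np.ndarray, levels: int) -> np.ndarray:
    return np.concatenate(([-1], thresholds, [levels - 1]))


def between_class_variance(hist: np.ndarray, thresholds) -> float:
    """sigma_B^2 of the classes induced by ``thresholds`` on histogram ``hist``.

    ``hist`` may be counts or normalized; the result scales with the total
    mass, so normalized input gives the standard statistic. Empty classes
    contribute zero.
    """
    hist = np.asarray(hist, dtype=float)
    levels = hist.size
    t = np.asarray(thresholds, dtype=int)
    if t.size and (np.any(np.diff(t) <= 0) or t.min() < 0 or t.max() > levels - 2):
        raise ValueError(f"thresholds must be strictly increasing in [0, {levels - 2}]")
    total = hist.sum()
    if total == 0:
        raise ValueError("empty histogram")
    p = hist / total
    lv = np.arange(levels, dtype=float)
    mu_t = float(p @ lv)
    edges = _class_edges(t, levels)
    sigma2 = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = p[lo + 1 : hi + 1].sum()
        if w > 0:
            mu = float(p[lo + 1 : hi + 1] @ lv[lo + 1 : hi + 1]) / w
            sigma2 += w * (mu - mu_t) ** 2
    return sigma2


def _bilevel_curve(hist: np.ndarray) -> np.ndarray:
    """sigma_B^2 for every bilevel threshold t in [0, L-2], vectorized."""
    p = np.asarray(hist, dtype=float)
    p = p / p.sum()
    lv = np.arange(p.size, dtype=float)
    w0 = np.cumsum(p)[:-1]
    s0 = np.cumsum(p * lv)[:-1]
    mu_t = float(p @ lv)
    w1 = 1.0 - w0
    sigma2 = np.zeros(p.size - 1)
    nz = (w0 > 0) & (w1 > 0)
    mu0 = np.where(nz, s0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(nz, (mu_t - s0) / np.where(w1 > 0, w1, 1), 0.0)
    sigma2[nz] = (w0 * (mu0 - mu_t) ** 2 + w1 * (mu1 - mu_t) ** 2)[nz]
    return sigma2


def otsu_bilevel_exhaustive(hist: np.ndarray) -> int:
    """Exhaustive-scan bilevel Otsu threshold; ties -> smallest t."""
    hist = np.asarray(hist, dtype=float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("histogram must occupy at least two levels")
    return int(np.argmax(_bilevel_curve(hist)))


def repair_thresholds(position: np.ndarray, levels: int) -> np.ndarray:
    """Round a continuous CBO position to a valid strictly increasing set.

    Rounds, clips to [0, L-2], sorts, and nudges duplicates to the nearest
    free level.
    """
    t = np.sort(np.clip(np.rint(position).astype(int), 0, levels - 2))
    used = set()
    out = []
    for v in t:
        if v not in used:
            used.add(v)
            out.append(v)
            continue
        for delta in range(1, levels):
            for cand in (v + delta, v - delta):
                if 0 <= cand <= levels - 2 and cand not in used:
                    used.add(cand)
                    out.append(cand)
                    break
            else:
                continue
            break
    return np.sort(np.array(out, dtype=int))


def cbo_multilevel_threshold(
    image: np.ndarray,
    k: int = 1,
    config: cbo_mod.CBOConfig | None = None,
    levels: int = 256,
) -> np.ndarray:
    """CBO-optimized k-level Otsu thresholds for an image.

    Fitness is 1/(1 + sigma_B^2), positive by construction, so maximizing
    between-class variance is a CBO minimization. Returns the best strictly
    increasing integer ThresholdSet found.
    """
    image = validate_image(image, levels)
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(image).size
    if k >= distinct:
        raise ValueError(f"k={k} >= {distinct} distinct gray levels")
    hist = compute_histogram(image, levels)

    if config is None:
        config = cbo_mod.CBOConfig(
            n=20, dims=k, bounds=tuple((0.0, float(levels - 2)) for _ in range(k)),
            max_iters=100, seed=0,
        )

    best = {"sigma2": -1.0, "thresholds": None}

    def fitness(x: np.ndarray) -> float:
        t = repair_thresholds(x, levels)
        sigma2 = between_class_variance(hist, t)
        if sigma2 > best["sigma2"]:
            best["sigma2"] = sigma2
            best["thresholds"] = t
        return 1.0 / (1.0 + sigma2)

    cbo_mod.optimize(fitness, config)
    assert best["thresholds"] is not None
    return best["thresholds"]


def apply_thresholds(image: np.ndarray, thresholds) -> np.ndarray:
    """Label image: pixel v -> j where t_{j-1} < v <= t_j (labels 0..k)."""
    image = np.asarray(image)
    t = np.asarray(thresholds)
    return np.digitize(image, t, right=True).astype(np.uint8)


@dataclass(frozen=True)
class NoduleRegion:
    """One connected segmented region (8-connectivity, 0-based coordinates)."""

    area: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    equivalent_diameter: float  # sqrt(4 * area / pi)
    mean_intensity: float | None
    coords: np.ndarray  # (area, 2) member pixel coordinates

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


def extract_nodules(
    label_image: np.ndarray,
    foreground_label: int,
    min_area: int = 1,
    intensity_image: np.ndarray | None = None,
    exclude_border: bool = False,
) -> list[NoduleRegion]:
    """Connected components of the foreground label, largest area first.

    Components smaller than ``min_area`` pixels are discarded. Centroid is
    the arithmetic mean of member pixel coordinates; ``mean_intensity``
    requires ``intensity_image``. ``exclude_border`` drops components whose
    bounding box touches the image edge — an intrapulmonary nodule never
    does, while the bright body/background always does, so this is the
    candidate filter the pipeline applies.
    """
    arr = np.asarray(label_image)
    fg = arr == foreground_label
    labeled = measure.label(fg, connectivity=2)
    regions = []
    for rp in measure.regionprops(labeled, intensity_image=intensity_image):
        if rp.area < min_area:
            continue
        if exclude_border and (
            rp.bbox[0] == 0 or rp.bbox[1] == 0
            or rp.bbox[2] == arr.shape[0] or rp.bbox[3] == arr.shape[1]
        ):
            continue
        regions.append(
            NoduleRegion(
                area=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=tuple(int(b) for b in rp.bbox),
                equivalent_diameter=float(np.sqrt(4.0 * rp.area / np.pi)),
                mean_intensity=float(rp.intensity_mean) if intensity_image is not None else None,
                coords=np.asarray(rp.coords),
            )
        )
    regions.sort(key=lambda r: -r.area)
    return regions


def regions_to_records(regions: list[NoduleRegion]) -> list[dict]:
    """Flatten regions for CSV/JSON export."""
    return [
        {
            "area": r.area,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "bbox_min_row": r.bbox[0],
            "bbox_min_col": r.bbox[1],
            "bbox_max_row": r.bbox[2],
            "bbox_max_col": r.bbox[3],
            "equivalent_diameter": r.equivalent_diameter,
            "mean_intensity": r.mean_intensity,
        }
        for r in regions
    ]
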