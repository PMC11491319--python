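"""Synthetic lung-CT phantoms with ground-truth nodule masks.

A phantom is an 8-bit grayscale slice: bright soft-tissue background, two
darker elliptical lung fields, and one circular nodule inside the left lung.
Malignant nodules get a spiculated (radially perturbed) margin and stronger
intra-nodule texture than benign ones; additive Gaussian noise and a
low-frequency multiplicative bias field emulate acquisition artifacts.

The module also manages dataset manifests (CSV) and train/val/test and
k-fold split assignment, so downstream stages are testable without any
external imaging archive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

BENIGN = "benign"
MALIGNANT = "malignant"

MANIFEST_COLUMNS = ["image_path", "label", "split", "fold"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Intensities are on the [0, levels-1] gray scale. ``spiculation_amplitude``
    is the radial margin perturbation in pixels (0 = smooth benign margin);
    ``texture_contrast`` the amplitude of intra-nodule texture;
    ``bias_amplitude`` the peak intensity excursion of the multiplicative
    low-frequency shading field.
    """

    image_size: int = 128
    background_level: float = 180.0
    lung_level: float = 70.0
    nodule_radius_px: float = 10.0
    nodule_class: str = BENIGN
    spiculation_amplitude: float = 0.0
    texture_contrast: float = 10.0
    noise_sd: float = 4.0
    bias_amplitude: float = 20.0
    seed: int = 0
    levels: int = 256

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.nodule_class not in (BENIGN, MALIGNANT):
            raise ValueError(f"unknown nodule_class {self.nodule_class!r}")
        top = self.levels - 1
        for name in ("background_level", "lung_level", "texture_contrast", "noise_sd", "bias_amplitude"):
            v = getattr(self, name)
            if not 0 <= v <= top:
                raise ValueError(f"{name}={v} outside [0, {top}]")
        if self.nodule_radius_px < 0 or self.spiculation_amplitude < 0:
            raise ValueError("nodule_radius_px and spiculation_amplitude must be >= 0")
        # lung semi-minor axis (see generate_phantom geometry)
        b = 0.18 * self.image_size
        if self.nodule_radius_px + self.spiculation_amplitude >= b:
            raise ValueError(
                f"nodule (radius {self.nodule_radius_px} + spiculation "
                f"{self.spiculation_amplitude}) does not fit inside the lung field "
                f"(semi-minor axis {b:.1f}px)"
            )


# class-conditional defaults: malignant nodules are spiculated and more textured
_MALIGNANT_SPICULATION = 2.5
_MALIGNANT_TEXTURE = 45.0


def spec_for_class(base: PhantomSpec, nodule_class: str, seed: int) -> PhantomSpec:
    """Derive a class-conditioned spec from a base spec.

    Benign keeps the base margin/texture settings; malignant overrides with
    the spiculated, high-texture defaults unless the base already sets them.
    """
    if nodule_class == BENIGN:
        return replace(base, nodule_class=BENIGN, seed=seed)
    return replace(
        base,
        nodule_class=MALIGNANT,
        seed=seed,
        spiculation_amplitude=max(base.spiculation_amplitude, _MALIGNANT_SPICULATION),
        texture_contrast=max(base.texture_contrast, _MALIGNANT_TEXTURE),
    )


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one phantom.

    Returns ``(image, mask, label)``: an ``image_size``-square uint8 image
    quantized to [0, levels-1], a boolean mask of exactly the nodule pixels,
    and the class label. Identical specs (including seed) give bit-identical
    output.
    """
    spec.validate()
    n = spec.image_size
    rng = np.random.default_rng(spec.seed)

    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    cy = n / 2.0

    img = np.full((n, n), spec.background_level, dtype=float)

    # two elliptical lung fields, left and right of the midline
    lung_b = 0.18 * n  # semi-minor (horizontal)
    lung_a = 0.32 * n  # semi-major (vertical)
    lung_centers = [(cy, 0.28 * n), (cy, 0.72 * n)]
    for lcy, lcx in lung_centers:
        inside = ((rows - lcy) / lung_a) ** 2 + ((cols - lcx) / lung_b) ** 2 <= 1.0
        img[inside] = spec.lung_level

    # nodule: radial boundary r <= R(theta), R = radius + spiculation * s(theta)
    mask = np.zeros((n, n), dtype=bool)
    if spec.nodule_radius_px > 0:
        ncy, ncx = lung_centers[0]
        dy, dx = rows - ncy, cols - ncx
        r = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        boundary = np.full_like(r, spec.nodule_radius_px)
        if spec.spiculation_amplitude > 0:
            # a few random harmonics, normalized to [-1, 1]
            harmonics = rng.integers(4, 9, size=3)
            phases = rng.uniform(0, 2 * np.pi, size=3)
            weights = rng.uniform(0.5, 1.0, size=3)
            s = np.zeros_like(theta)
            for m, ph, w in zip(harmonics, phases, weights):
                s += w * np.cos(m * theta + ph)
            s /= np.sum(weights)
            boundary = boundary + spec.spiculation_amplitude * s
        mask = r <= boundary
        # soft-tissue-dense nodule: the brightest structure in the slice
        nodule_level = spec.background_level + 30.0
        img[mask] = min(nodule_level, spec.levels - 1.0)
        if spec.texture_contrast > 0:
            texture = rng.standard_normal((n, n))
            img[mask] += spec.texture_contrast * texture[mask]

    if spec.bias_amplitude > 0:
        shade = np.sin(np.pi * rows / n) * np.sin(np.pi * cols / n)
        img *= 1.0 + (spec.bias_amplitude / (spec.levels - 1)) * (shade - 0.5)

    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal((n, n))

    img = np.clip(np.rint(img), 0, spec.levels - 1).astype(np.uint8)
    label = spec.nodule_class
    return img, mask, label


def _child_seed(master_seed: int, index: int) -> int:
    """Counter-based per-image seed: independent of generation order."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n: int,
    class_balance: float,
    base_spec: PhantomSpec,
    out_dir: str | Path,
    seed: int,
) -> pd.DataFrame:
    """Write ``n`` phantom PNGs plus masks and a manifest CSV.

    ``class_balance`` is the malignant fraction; exactly
    ``round(n * class_balance)`` records are malignant. Per-image seeds derive
    deterministically from ``seed`` by a counter scheme, so regeneration is
    bit-reproducible.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < class_balance < 1:
        raise ValueError("class_balance must be in (0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_mal = round(n * class_balance)
    labels = np.array([MALIGNANT] * n_mal + [BENIGN] * (n - n_mal))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    records = []
    for i, label in enumerate(labels):
        spec_i = spec_for_class(base_spec, label, _child_seed(seed, i))
        img, mask, _ = generate_phantom(spec_i)
        img_name = f"phantom_{i:04d}.png"
        iio.imwrite(out_dir / img_name, img)
        iio.imwrite(out_dir / f"phantom_{i:04d}_mask.png", (mask * 255).astype(np.uint8))
        records.append((img_name, label, "unassigned", pd.NA))

    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"image_path": str, "label": str, "split": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def apportion(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items to ``fractions``.

    Floors first; remaining items go to the largest fractional parts, ties
    broken in listed order. E.g. 1135 at (0.70, 0.10, 0.20) -> (795, 113, 227).
    """
    ideal = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in ideal]
    remainder = n - sum(counts)
    # stable sort on -fractional part preserves listed order on ties
    order = sorted(range(len(fractions)), key=lambda i: -(ideal[i] - counts[i]))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_dataset(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign every record to train/val/test by largest-remainder counts.

    Fractions must be positive and sum to 1. Records are shuffled with
    ``seed`` before assignment; the result partitions the manifest.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(manifest)
    if n < 3:
        raise ValueError("need at least 3 records for three non-empty splits")

    counts = apportion(n, fractions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    splits = np.empty(n, dtype=object)
    start = 0
    for name, c in zip(("train", "val", "test"), counts):
        splits[order[start : start + c]] = name
        start += c

    out = manifest.copy()
    out["split"] = splits
    return out


def kfold_assign(manifest: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """Assign fold numbers 1..k; fold sizes differ by at most one."""
    n = len(manifest)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    base, extra = divmod(n, k)
    start = 0
    for fold in range(1, k + 1):
        size = base + (1 if fold <= extra else 0)
        folds[order[start : start + size]] = fold
        start += size
    out = manifest.copy()
    out["fold"] = folds
    return out
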