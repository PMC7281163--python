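"""Geometric augmentation of combined change images.

Each cell contributes one combined image; augmentation expands it into
``n_augment_per_cell`` randomly rotated, shifted and zoomed variants plus
the untransformed original (201 per cell at the default 200).  Every
transform is a single affine map about the image centre applied identically
to the three channels, so the ON/OFF change encoding stays registered —
a rotation can never decouple the red and green channels.

Photometric jitter is deliberately excluded: brightness or contrast changes
would corrupt the change encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .synth import replace  # noqa: F401  (re-export convenience)

__all__ = ["AugmentConfig", "AugmentedDataset", "affine_params", "apply_affine",
           "augment_cell", "augment_dataset"]


@dataclass(frozen=True)
class AugmentConfig:
    n_augment_per_cell: int = 200
    rotation_range: float = 30.0  # degrees, sampled U(-r, r)
    shift_range: float = 0.10  # fraction of height/width, U(-s, s)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    fill_mode: str = "nearest"  # scipy.ndimage boundary mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_augment_per_cell < 0:
            raise ValueError("n_augment_per_cell must be >= 0")
        lo, hi = self.zoom_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("zoom_range must be a positive interval")


def affine_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one transform: rotation (deg), shift (fractions), zoom."""
    return {
        "angle": rng.uniform(-config.rotation_range, config.rotation_range),
        "shift_y": rng.uniform(-config.shift_range, config.shift_range),
        "shift_x": rng.uniform(-config.shift_range, config.shift_range),
        "zoom": rng.uniform(*config.zoom_range),
    }


def apply_affine(
    image: np.ndarray, params: dict, fill_mode: str = "nearest"
) -> np.ndarray:
    """Rotate/zoom about the centre then translate; channels independently
    but with the identical map (channel-synchronous by construction)."""
    image = np.asarray(image)
    single = image.ndim == 2
    if single:
        image = image[..., None]
    h, w, _ = image.shape
    theta = np.deg2rad(params["angle"])
    c, s = np.cos(theta), np.sin(theta)
    # output -> input mapping: inverse of (zoom then rotate), row/col order
    inv = np.array([[c, -s], [s, c]]) / params["zoom"]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([params["shift_y"] * h, params["shift_x"] * w])
    offset = center - inv @ (center + shift)
    out = np.empty_like(image)
    for ch in range(image.shape[-1]):
        warped = ndimage.affine_transform(
            image[..., ch].astype(np.float32),
            inv,
            offset=offset,
            order=1,
            mode=fill_mode,
        )
        out[..., ch] = np.clip(np.rint(warped), 0, 255).astype(image.dtype)
    return out[..., 0] if single else out


def augment_cell(
    combined: np.ndarray, config: AugmentConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """The original plus n_augment_per_cell transformed variants, in order."""
    out = [np.asarray(combined)]
    for _ in range(config.n_augment_per_cell):
        out.append(apply_affine(combined, affine_params(config, rng), config.fill_mode))
    return out


@dataclass
class AugmentedDataset:
    """Augmented images with their provenance manifest.

    ``manifest`` columns: image_id, cell_id (parent), label, fluorescent,
    is_original, aug_index.
    """

    images: np.ndarray  # (n, H, W, 3) uint8
    manifest: pd.DataFrame = field(repr=False)

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.manifest["cell_id"].to_numpy()


def augment_dataset(
    images: np.ndarray, cell_manifest: pd.DataFrame, config: AugmentConfig
) -> AugmentedDataset:
    """Expand each cell's combined image; deterministic for a fixed seed.

    Per-cell generators are spawned from the config seed, so each cell's
    variants are independent of dataset order.
    """
    n_cells = len(cell_manifest)
    seeds = np.random.SeedSequence(config.seed).spawn(max(n_cells, 1))
    all_images: list[np.ndarray] = []
    rows = []
    for i, row in enumerate(cell_manifest.itertuples(index=False)):
        rng = np.random.default_rng(seeds[i])
        variants = augment_cell(images[i], config, rng)
        for j, img in enumerate(variants):
            all_images.append(img)
            rows.append(
                {
                    "image_id": f"{row.cell_id}_a{j:03d}",
                    "cell_id": row.cell_id,
                    "label": row.label,
                    "fluorescent": row.fluorescent,
                    "is_original": j == 0,
                    "aug_index": j,
                }
            )
    return AugmentedDataset(
        images=np.stack(all_images), manifest=pd.DataFrame(rows)
    )


def save_augmented(ds: AugmentedDataset, outdir: str | Path) -> Path:
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, image_id in zip(ds.images, ds.manifest["image_id"]):
        path = outdir / f"{image_id}.png"
        iio.imwrite(path, img)
        paths.append(path.name)
    out = ds.manifest.copy()
    out["path"] = paths
    manifest_path = outdir / "augmented_manifest.csv"
    out.to_csv(manifest_path, index=False)
    return manifest_path
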