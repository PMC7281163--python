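"""Contrast enhancement and OFF/ON channel composition.

The change between the trap-off and trap-on photomicrographs of a cell is
encoded in a single three-channel image I = <B, A, N>: the trap-ON frame in
the red channel (A), the trap-OFF frame in the green channel (B), and their
per-pixel mean in the blue channel (N).  Averaging dilutes the change and
preserves the background, so pixels that moved show up as red/green fringes
while static structure — including reflected-light noise — stays grey.

Each gray image is first contrast-stretched to span [0, 255]:

    p* = round((p - min p) / (max p - min p) * 255)

with round-half-up.  No denoising, background subtraction or segmentation
is applied: the classifier is expected to absorb the noise.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CellRecord, ImagePair

__all__ = [
    "enhance_contrast",
    "compose_channels",
    "combine_pair",
    "combine_dataset",
]

CHANNEL_ORDERS = ("on_red", "off_red")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def enhance_contrast(image: np.ndarray) -> np.ndarray:
    """Min-max stretch a gray image to [0, 255] with round-half-up.

    A constant image has no contrast to stretch; it is mapped to all zeros
    and a warning is emitted.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    lo = float(image.min())
    hi = float(image.max())
    if hi == lo:
        warnings.warn(
            "constant image: contrast stretch undefined, returning zeros",
            stacklevel=2,
        )
        return np.zeros(image.shape, dtype=np.uint8)
    stretched = _round_half_up((image.astype(np.float64) - lo) / (hi - lo) * 255.0)
    return stretched.astype(np.uint8)


def compose_channels(
    off: np.ndarray, on: np.ndarray, channel_order: str = "on_red"
) -> np.ndarray:
    """Stack an enhanced OFF/ON pair into one (H, W, 3) uint8 image.

    ``channel_order="on_red"`` puts the trap-ON frame in red and the OFF
    frame in green; ``"off_red"`` swaps them (both conventions occur in the
    literature).  Blue is always the round-half-up per-pixel mean.
    """
    off = np.asarray(off)
    on = np.asarray(on)
    if off.shape != on.shape:
        raise ValueError(f"shape mismatch: off {off.shape} vs on {on.shape}")
    if channel_order not in CHANNEL_ORDERS:
        raise ValueError(f"channel_order must be one of {CHANNEL_ORDERS}")
    blue = _round_half_up(
        (off.astype(np.float64) + on.astype(np.float64)) / 2.0
    ).astype(np.uint8)
    if channel_order == "on_red":
        red, green = on, off
    else:
        red, green = off, on
    return np.stack(
        [red.astype(np.uint8), green.astype(np.uint8), blue], axis=-1
    )


def combine_pair(pair: ImagePair, channel_order: str = "on_red") -> np.ndarray:
    """Enhance both frames of a pair, then compose the three channels."""
    return compose_channels(
        enhance_contrast(pair.off_image),
        enhance_contrast(pair.on_image),
        channel_order=channel_order,
    )


def combine_dataset(
    records: list[CellRecord], channel_order: str = "on_red"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Combine every record; returns (n, H, W, 3) images and a cell manifest."""
    if not records:
        raise ValueError("no records to combine")
    images = np.stack([combine_pair(r.image_pair, channel_order) for r in records])
    manifest = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "label": [r.label for r in records],
            "fluorescent": [r.fluorescent for r in records],
        }
    )
    return images, manifest


def save_combined(
    images: np.ndarray, manifest: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write combined images as lossless RGB PNGs plus an updated manifest."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, cell_id in zip(images, manifest["cell_id"]):
        path = outdir / f"{cell_id}_combined.png"
        iio.imwrite(path, img)
        paths.append(path.name)
    out = manifest.copy()
    out["combined_path"] = paths
    manifest_path = outdir / "combined_manifest.csv"
    out.to_csv(manifest_path, index=False)
    return manifest_path
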