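"""Organelle-fraction quantification from two-channel fluorescence images.

Implements the live-cell Golgi-targeting readout: the organelle (red)
channel is thresholded at image mean + 5 population standard deviations to
define the Golgi mask; the reporter (green) channel is thresholded at its
image mean to delineate the cell; the reported quantity is the percentage
of in-cell green intensity that falls inside the Golgi mask.

Both thresholds are strict inequalities over whole-image (field-level)
statistics, which makes the masks invariant under positive affine intensity
transforms b + c·I (c > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

GOLGI_SD_MULTIPLIER = 5.0


@dataclass(frozen=True)
class ChannelImage:
    """Single-plane nonnegative grayscale intensities."""

    pixels: np.ndarray
    channel: str = ""  # "green" (reporter) | "red" (organelle stain)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("channel image must be a non-empty 2-D array")
        if not np.isfinite(arr).all():
            raise ValueError("channel image contains non-finite intensities")
        if (arr < 0).any():
            raise ValueError("channel image contains negative intensities")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GolgiFractionResult:
    golgi_mask: np.ndarray
    cell_mask: np.ndarray
    total_green: float
    golgi_green: float
    percent_at_golgi: float
    empty_cell: bool  # flagged when no in-cell signal was found


def golgi_mask(red: ChannelImage, sd_multiplier: float = GOLGI_SD_MULTIPLIER) -> np.ndarray:
    """Pixels strictly above mean + sd_multiplier × population SD."""
    arr = red.pixels
    return arr > arr.mean() + sd_multiplier * arr.std()


def cell_mask(green: ChannelImage) -> np.ndarray:
    """Pixels strictly above the whole-image mean green intensity."""
    arr = green.pixels
    return arr > arr.mean()


def golgi_fraction(
    green: ChannelImage,
    red: ChannelImage,
    sd_multiplier: float = GOLGI_SD_MULTIPLIER,
) -> GolgiFractionResult:
    """Percent of in-cell reporter intensity inside the organelle mask."""
    if green.shape != red.shape:
        raise ValueError(f"channel shape mismatch: {green.shape} vs {red.shape}")
    cmask = cell_mask(green)
    gmask = golgi_mask(red, sd_multiplier)
    total = float(green.pixels[cmask].sum())
    at_golgi = float(green.pixels[cmask & gmask].sum())
    empty = total == 0.0
    percent = 0.0 if empty else 100.0 * at_golgi / total
    return GolgiFractionResult(
        golgi_mask=gmask,
        cell_mask=cmask,
        total_green=total,
        golgi_green=at_golgi,
        percent_at_golgi=percent,
        empty_cell=empty,
    )


def read_channel(path: str | Path, channel: str = "") -> ChannelImage:
    """Read a single-plane grayscale TIFF or PNG image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # collapse an accidental color axis
        arr = arr.mean(axis=-1)
    return ChannelImage(pixels=arr, channel=channel)


def write_channel(image: ChannelImage, path: str | Path) -> None:
    path = Path(path)
    arr = np.clip(image.pixels, 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), arr)


def report_fields(results: dict[str, GolgiFractionResult]) -> str:
    """Per-field tab-separated report."""
    lines = ["field_id\ttotal_green\tgolgi_green\tpercent_at_golgi"]
    for field_id, res in results.items():
        lines.append(
            f"{field_id}\t{res.total_green:.1f}\t{res.golgi_green:.1f}"
            f"\t{res.percent_at_golgi:.2f}"
        )
    return "\n".join(lines) + "\n"
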