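"""Image containers and TIFF + sidecar-YAML I/O for fluorescence frames."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["ImageFrame", "max_projection", "write_image", "read_image"]


@dataclass
class ImageFrame:
    """A single-channel fluorescence frame (optionally a z-stack).

    Attributes
    ----------
    pixels : ndarray
        2-D ``(rows, cols)`` intensity grid, or 3-D ``(z, rows, cols)`` for
        a z-stack.
    pixel_size_um : float
        Physical pixel pitch, micrometres per pixel.
    well_centre_px : tuple (x, y) or None
        Well centre in image coordinates (x = column, y = row).  It may lie
        outside the frame (e.g. a tile far from the centre).
    """

    pixels: np.ndarray
    pixel_size_um: float
    well_centre_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 3-D (z, rows, cols)")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0] if self.is_stack else 1


def max_projection(frame: ImageFrame) -> ImageFrame:
    """Per-pixel maximum across the slices of a z-stack.

    A 2-D frame (or single-slice stack) is returned unchanged apart from
    dropping the z axis.
    """
    if not frame.is_stack:
        return ImageFrame(frame.pixels.copy(), frame.pixel_size_um, frame.well_centre_px)
    if frame.pixels.shape[0] < 1:
        raise ValueError("stack must contain at least one slice")
    return ImageFrame(
        frame.pixels.max(axis=0), frame.pixel_size_um, frame.well_centre_px
    )


def write_image(frame: ImageFrame, path) -> None:
    """Write a frame as TIFF plus a ``.yaml`` sidecar with its metadata."""
    path = Path(path)
    tifffile.imwrite(path, frame.pixels)
    meta = {
        "pixel_size_um": float(frame.pixel_size_um),
        "well_centre_px": (
            None if frame.well_centre_px is None
            else [float(frame.well_centre_px[0]), float(frame.well_centre_px[1])]
        ),
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_image(path) -> ImageFrame:
    """Read a TIFF written by :func:`write_image` together with its sidecar."""
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    centre = meta.get("well_centre_px")
    return ImageFrame(
        pixels,
        float(meta["pixel_size_um"]),
        None if centre is None else (float(centre[0]), float(centre[1])),
    )
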