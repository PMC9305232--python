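"""Raster containers and image I/O for network micrographs.

The canonical acquisition geometry is a 5 x 5 mm^2 region of interest imaged
at 640 x 640 px^2, i.e. a pixel pitch of 7.8125 um.  Images are single-channel
grayscale (8/16-bit) or binary; binary masks are written as 8-bit PNG/TIFF
with foreground 255 and background 0, alongside a JSON sidecar carrying
provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile

#: physical pixel pitch of the canonical 5 mm / 640 px acquisition, in um
CANONICAL_PIXEL_SIZE_UM = 5000.0 / 640.0


@dataclass
class NetworkImage:
    """A 2D micrograph of an extraradical fungal network.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Grayscale intensities or a binary mask (bool).
    pixel_size_um : float
        Physical size of one pixel in micrometres. Defaults to the canonical
        7.8125 um (5 mm field imaged at 640 px).
    provenance : str
        Free-text source tag (file path, generator preset, ...).
    metadata : dict
        Optional ground-truth or acquisition metadata (e.g. realized coverage
        and branch counts for synthetic networks, ROI position labels).
    """

    pixels: np.ndarray
    pixel_size_um: float = CANONICAL_PIXEL_SIZE_UM
    provenance: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D raster")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        return _is_binary(self.pixels)


def _is_binary(arr: np.ndarray) -> bool:
    """True for bool rasters or integer rasters with values in {0,1} or {0,255}."""
    if arr.dtype == bool:
        return True
    vals = np.unique(arr)
    if vals.size > 2:
        return False
    return set(vals.tolist()) <= {0, 1} or set(vals.tolist()) <= {0, 255}


def as_bool_mask(arr: np.ndarray | NetworkImage) -> np.ndarray:
    """Coerce a binary raster (bool, {0,1} or {0,255}) to a bool array."""
    if isinstance(arr, NetworkImage):
        arr = arr.pixels
    arr = np.asarray(arr)
    if not _is_binary(arr):
        raise ValueError("raster is not binary; run binarize() first")
    return arr.astype(bool)


def read_image(path: str | Path, pixel_size_um: float = CANONICAL_PIXEL_SIZE_UM) -> NetworkImage:
    """Read a single-page PNG/TIFF micrograph.

    A JSON sidecar ``<path>.json``, if present, supplies ``pixel_size_um``
    and generator metadata.
    """
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse trivial channel axes
        arr = arr[..., 0] if arr.shape[-1] in (3, 4) else arr.squeeze()
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size_um = float(meta.get("pixel_size_um", pixel_size_um))
    return NetworkImage(arr, pixel_size_um=pixel_size_um, provenance=str(path), metadata=meta)


def read_images(path: str | Path, pixel_size_um: float = CANONICAL_PIXEL_SIZE_UM) -> list[NetworkImage]:
    """Read an image file; each page of a multi-page TIFF becomes one image."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        return [
            NetworkImage(p, pixel_size_um=pixel_size_um, provenance=f"{path}#page{i}")
            for i, p in enumerate(pages)
        ]
    return [read_image(path, pixel_size_um=pixel_size_um)]


def write_image(path: str | Path, img: NetworkImage, sidecar: bool = True) -> Path:
    """Write an 8-bit single-channel PNG/TIFF (binary masks as 0/255).

    When ``sidecar`` is set, a ``<path>.json`` file records pixel size,
    provenance and metadata.
    """
    path = Path(path)
    arr = img.pixels
    if arr.dtype == bool or _is_binary(arr):
        out = np.where(as_bool_mask(arr), 255, 0).astype(np.uint8)
    else:
        out = np.clip(arr, 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
    if sidecar:
        doc = {
            "pixel_size_um": img.pixel_size_um,
            "provenance": img.provenance,
            **{k: _jsonable(v) for k, v in img.metadata.items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def _jsonable(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
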