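"""Micrograph preprocessing: binarization, mask cleaning, skeletonization, ROIs.

The chain mirrors standard practice for sparse filamentous micrographs:
threshold the grayscale image (Otsu by default, assuming bright hyphae on a
dark background), optionally close small gaps with a disk, remove isolated
small clusters (background noise), then thin to a 1-px topology-preserving
skeleton.  With the closing radius at 0 the chain is monotone:
``foreground(skeleton) <= foreground(clean) <= foreground(binarized)``.

Transformers follow the scikit-learn estimator protocol so the chain can be
assembled with :class:`sklearn.pipeline.Pipeline`; the module-level
functions are the equivalent one-shot calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

from .images import NetworkImage, _is_binary, as_bool_mask

__all__ = [
    "RoiSpec",
    "binarize",
    "clean_mask",
    "skeletonize",
    "extract_rois",
    "Binarizer",
    "MaskCleaner",
    "Skeletonizer",
]


def binarize(
    img: np.ndarray | NetworkImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Threshold a grayscale raster to a bool foreground mask.

    Foreground means network pixels: strictly above the threshold by default
    (bright hyphae on dark background), strictly below it with ``invert``.
    Already-binary input (bool, {0,1} or {0,255}) is returned unchanged as
    bool, making the operation idempotent.

    Raises
    ------
    ValueError
        For a constant image under Otsu (no threshold separates it), an
        unknown method, or ``method="fixed"`` without a threshold.
    """
    arr = img.pixels if isinstance(img, NetworkImage) else np.asarray(img)
    if _is_binary(arr):
        return arr.astype(bool)
    if method == "otsu":
        if np.all(arr == arr.flat[0]):
            raise ValueError("constant image: Otsu threshold is undefined")
        t = threshold_otsu(arr)
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        t = fixed_threshold
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return (arr < t) if invert else (arr > t)


def clean_mask(
    mask: np.ndarray | NetworkImage,
    min_cluster_px: int = 20,
    connectivity: int = 8,
    smoothing_radius_px: int = 1,
) -> np.ndarray:
    """Morphologically smooth a binary mask and remove small clusters.

    Applies a closing with a disk of ``smoothing_radius_px`` (0 skips it),
    then deletes every connected foreground component with fewer than
    ``min_cluster_px`` pixels, under 4- or 8-connectivity.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_cluster_px < 1:
        raise ValueError("min_cluster_px must be >= 1")
    out = as_bool_mask(mask)
    if smoothing_radius_px > 0:
        out = morphology.closing(out, morphology.disk(smoothing_radius_px))
    # max_size removes components of <= max_size px, i.e. < min_cluster_px
    return morphology.remove_small_objects(
        out, max_size=min_cluster_px - 1, connectivity=1 if connectivity == 4 else 2
    )


def skeletonize(mask: np.ndarray | NetworkImage) -> np.ndarray:
    """Thin a binary mask to its 1-px-wide, topology-preserving skeleton.

    The skeleton foreground is a subset of the input foreground, and
    re-thinning a skeleton is a no-op.
    """
    return morphology.skeletonize(as_bool_mask(mask))


@dataclass(frozen=True)
class RoiSpec:
    """A square region of interest, 0-based (row, col) top-left, half-open.

    ``label`` indexes the position along the barrier-to-centre axis
    (1 = nearest the partner-compartment barrier).
    """

    top_left: tuple[int, int]
    side_px: int = 640
    label: int = 1

    def __post_init__(self) -> None:
        if self.side_px < 64:
            raise ValueError("side_px must be >= 64")


def extract_rois(img: NetworkImage, rois: list[RoiSpec]) -> list[NetworkImage]:
    """Crop ROI sub-images, propagating pixel scale and position labels."""
    out = []
    h, w = img.shape
    for roi in rois:
        r, c = roi.top_left
        if r < 0 or c < 0 or r + roi.side_px > h or c + roi.side_px > w:
            raise ValueError(
                f"ROI label={roi.label} at {roi.top_left} side={roi.side_px} "
                f"exceeds image bounds {img.shape}"
            )
        crop = img.pixels[r : r + roi.side_px, c : c + roi.side_px].copy()
        out.append(
            NetworkImage(
                crop,
                pixel_size_um=img.pixel_size_um,
                provenance=f"{img.provenance}[roi {roi.label}]",
                metadata={**img.metadata, "label": roi.label, "roi_top_left": roi.top_left},
            )
        )
    return out


class Binarizer(BaseEstimator, TransformerMixin):
    """Thresholding transformer (Otsu default, fixed-threshold override)."""

    def __init__(self, method: str = "otsu", fixed_threshold: float | None = None, invert: bool = False):
        self.method = method
        self.fixed_threshold = fixed_threshold
        self.invert = invert

    def fit(self, X, y=None):
        self.n_features_in_ = 0  # stateless image transformer
        return self

    def transform(self, X):
        return binarize(X, self.method, self.fixed_threshold, self.invert)


class MaskCleaner(BaseEstimator, TransformerMixin):
    """Closing + small-cluster removal transformer."""

    def __init__(self, min_cluster_px: int = 20, connectivity: int = 8, smoothing_radius_px: int = 1):
        self.min_cluster_px = min_cluster_px
        self.connectivity = connectivity
        self.smoothing_radius_px = smoothing_radius_px

    def fit(self, X, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        return clean_mask(X, self.min_cluster_px, self.connectivity, self.smoothing_radius_px)


class Skeletonizer(BaseEstimator, TransformerMixin):
    """Topology-preserving thinning transformer."""

    def fit(self, X, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        return skeletonize(X)
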