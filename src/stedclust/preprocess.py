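"""Preprocessing and cluster localization for raw STED images.

The chain converts a raw image into a list of cluster coordinates:

1. binarize the raw image into a cell mask,
2. zero the out-of-cell background by multiplication with the mask,
3. difference-of-Gaussians band-pass (sigma1 = 0 nm, sigma2 = 100 nm),
4. clip negatives to 0 and Gaussian-smooth with sigma = 15 nm,
5. standardize by dividing by (mean + std) of the in-cell pixels,
6. detect local intensity peaks above a global threshold and merge
   peaks in adjacent pixels into one localization.

All sigma parameters are physical (nm) and converted to pixels via the
image's pixel size.  Gaussian filters use reflect boundary handling,
fixed for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .core import CellMask, ClusterLocalizations, StedImage

__all__ = [
    "PreprocessParams",
    "PreprocessResult",
    "binarize_cell",
    "mask_background",
    "dog_filter",
    "clip_and_smooth",
    "standardize",
    "localize_clusters",
    "run_preprocessing",
    "suggest_peak_threshold",
]

logger = logging.getLogger(__name__)

_BOUNDARY_MODE = "reflect"


@dataclass
class PreprocessParams:
    """Parameters of the localization chain.

    ``peak_threshold`` is in standardized-intensity units and is a
    global, batch-level setting (the original analysis set it per
    acquisition day); there is no universal default — calibrate it with
    :func:`suggest_peak_threshold` or set it explicitly.
    """

    peak_threshold: float
    dog_sigma1: float = 0.0
    dog_sigma2: float = 100.0
    smooth_sigma: float = 15.0
    binarize_sigma: float = 50.0
    edge_exclusion_nm: float = 60.0

    def __post_init__(self) -> None:
        if not self.dog_sigma2 > self.dog_sigma1 >= 0:
            raise ValueError("need dog_sigma2 > dog_sigma1 >= 0")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if not self.peak_threshold > 0:
            raise ValueError("peak_threshold must be > 0")


@dataclass
class PreprocessResult:
    """Outcome of the full chain for one cell."""

    localizations: ClusterLocalizations
    mask: CellMask
    standardized: StedImage


def binarize_cell(img: StedImage, smooth_sigma: float = 50.0) -> CellMask:
    """Segment the cell support from the raw image.

    Otsu threshold on the log-transformed, lightly smoothed
    (sigma = 50 nm) image, then hole filling and retention of the
    largest connected component.  The log transform keeps the bright
    receptor spots from dominating the histogram, so the threshold
    separates in-cell from out-of-cell background rather than spots
    from everything else.
    """
    pix = img.pixels
    if np.ptp(pix) == 0:
        raise ValueError("cannot binarize a constant image")
    sm = ndimage.gaussian_filter(pix, smooth_sigma / img.pixel_size, mode=_BOUNDARY_MODE)
    logsm = np.log1p(np.clip(sm, 0.0, None))
    thr = filters.threshold_otsu(logsm)
    fg = logsm > thr
    if not fg.any():
        raise ValueError("no foreground found during binarization")
    fg = ndimage.binary_fill_holes(fg)
    labels = measure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return CellMask(mask=labels == largest, pixel_size=img.pixel_size)


def mask_background(img: StedImage, mask: CellMask) -> StedImage:
    """Zero out-of-cell pixels; in-cell pixels pass through unchanged."""
    if img.pixels.shape != mask.mask.shape:
        raise ValueError(
            f"image shape {img.pixels.shape} != mask shape {mask.mask.shape}"
        )
    return img.with_pixels(np.where(mask.mask, img.pixels, 0.0))


def dog_filter(img: StedImage, sigma1: float = 0.0, sigma2: float = 100.0) -> StedImage:
    """Difference-of-Gaussians band-pass; sigmas in nm, 0 = no blur."""
    if not sigma2 > sigma1:
        raise ValueError("need sigma2 > sigma1")
    if sigma1 < 0:
        raise ValueError("sigma1 must be >= 0")
    px = img.pixel_size
    low = (
        img.pixels
        if sigma1 == 0
        else ndimage.gaussian_filter(img.pixels, sigma1 / px, mode=_BOUNDARY_MODE)
    )
    high = ndimage.gaussian_filter(img.pixels, sigma2 / px, mode=_BOUNDARY_MODE)
    return img.with_pixels(low - high)


def clip_and_smooth(img: StedImage, smooth_sigma: float = 15.0) -> StedImage:
    """Clip negative values to 0, then Gaussian-smooth (sigma in nm)."""
    clipped = np.clip(img.pixels, 0.0, None)
    if smooth_sigma > 0:
        clipped = ndimage.gaussian_filter(
            clipped, smooth_sigma / img.pixel_size, mode=_BOUNDARY_MODE
        )
    return img.with_pixels(clipped)


def standardize(img: StedImage, mask: CellMask) -> StedImage:
    """Divide by (mean + std) of the in-cell pixels; outside stays 0.

    Makes intensity ranges comparable across acquisitions; the output
    is invariant to global scaling of the input.  Population std
    (ddof=0) over in-mask pixels.
    """
    if not mask.mask.any():
        raise ValueError("mask is empty")
    inside = img.pixels[mask.mask]
    denom = inside.mean() + inside.std()
    if not denom > 0:
        raise ValueError("degenerate cell: mean + std of in-mask pixels is 0")
    out = img.pixels / denom
    out = np.where(mask.mask, out, 0.0)
    return img.with_pixels(out)


def merged_local_maxima(
    pixels: np.ndarray, threshold: float, restrict: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima above ``threshold``, 8-connected groups merged.

    A pixel is a local maximum when it equals the maximum over its 3x3
    neighbourhood (plateaus included).  Touching maxima merge into one
    detection at their intensity-weighted centroid.

    Returns ``(rc, intensity)``: fractional (row, col) centroids and
    the peak intensity of each merged group.
    """
    is_max = pixels >= ndimage.maximum_filter(pixels, size=3, mode=_BOUNDARY_MODE)
    is_max &= pixels > threshold
    if restrict is not None:
        is_max &= restrict
    labels, n = ndimage.label(is_max, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    idx = np.arange(1, n + 1)
    rc = np.asarray(ndimage.center_of_mass(pixels, labels, idx), dtype=float)
    intensity = ndimage.maximum(pixels, labels, idx)
    return rc, np.asarray(intensity, dtype=float)


def localize_clusters(
    img: StedImage,
    threshold: float,
    mask: CellMask | None = None,
    cell_id: str = "",
    condition: str = "",
) -> ClusterLocalizations:
    """Detect clusters in the standardized, smoothed image.

    Local maxima above the global threshold; maxima in adjacent pixels
    (8-connectivity) merge to a single localization at their
    intensity-weighted centroid.  Coordinates are returned in nm with
    the pixel-centre convention.
    """
    restrict = mask.mask if mask is not None else None
    rc, _ = merged_local_maxima(img.pixels, threshold, restrict)
    # (row, col) fractional indices -> nm; centre of pixel i is (i + 0.5) px
    pts = np.column_stack([(rc[:, 1] + 0.5), (rc[:, 0] + 0.5)]) * img.pixel_size
    return ClusterLocalizations(points=pts, cell_id=cell_id, condition=condition)


def run_preprocessing(
    raw: StedImage,
    params: PreprocessParams,
    cell_id: str = "",
    condition: str = "",
    mask: CellMask | None = None,
) -> PreprocessResult:
    """Run the full chain: binarize, mask, DoG, clip+smooth, standardize,
    localize.  Pass ``mask`` to skip binarization (e.g. a known support)."""
    if mask is None:
        mask = binarize_cell(raw, smooth_sigma=params.binarize_sigma)
    masked = mask_background(raw, mask)
    banded = dog_filter(masked, params.dog_sigma1, params.dog_sigma2)
    smooth = clip_and_smooth(banded, params.smooth_sigma)
    std = standardize(smooth, mask)
    # The DoG of the sharp cell edge leaves a positive ridge just inside
    # the boundary; detections within one resolution length of the edge
    # are artifacts, so they are excluded.
    detect_mask = mask
    it = int(round(params.edge_exclusion_nm / raw.pixel_size))
    if it > 0:
        eroded = ndimage.binary_erosion(mask.mask, iterations=it)
        if eroded.any():
            detect_mask = CellMask(mask=eroded, pixel_size=mask.pixel_size)
    locs = localize_clusters(
        std, params.peak_threshold, detect_mask, cell_id=cell_id, condition=condition
    )
    return PreprocessResult(localizations=locs, mask=mask, standardized=std)


def suggest_peak_threshold(
    images: list[StedImage],
    masks: list[CellMask],
    true_points: list[np.ndarray],
    params: PreprocessParams | None = None,
    exclusion_nm: float = 200.0,
    margin: float = 2.0,
) -> float:
    """Calibrate the global peak threshold from calibration images.

    Runs synthetic calibration images with known spot positions
    through the chain and measures the intensities of local maxima in
    the blank regions of the cell (further than ``exclusion_nm`` from
    any true spot).  Returns ``margin`` times the strongest such
    background maximum — a level noise peaks do not reach while real
    spots standardize well above it.  The synthetic analogue of
    setting the threshold per acquisition batch.

    Spot content matters: the standardization divisor (mean + std of
    the cell) is dominated by spot signal, so a spot-free image would
    calibrate on the wrong intensity scale.
    """
    if params is None:
        params = PreprocessParams(peak_threshold=1.0)
    from scipy.spatial import cKDTree

    background_max = []
    for img, mask, truth in zip(images, masks, true_points):
        masked = mask_background(img, mask)
        banded = dog_filter(masked, params.dog_sigma1, params.dog_sigma2)
        smooth = clip_and_smooth(banded, params.smooth_sigma)
        std = standardize(smooth, mask)
        rc, inten = merged_local_maxima(std.pixels, 1e-9, mask.mask)
        if len(rc) == 0:
            continue
        pts = np.column_stack([rc[:, 1] + 0.5, rc[:, 0] + 0.5]) * img.pixel_size
        truth = np.asarray(truth, dtype=float).reshape(-1, 2)
        if len(truth):
            d, _ = cKDTree(truth).query(pts)
            inten = inten[d > exclusion_nm]
        background_max.extend(inten.tolist())
    if not background_max:
        raise ValueError("no background maxima found; cannot calibrate")
    return float(margin * max(background_max))
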