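"""Per-cell cluster statistics: density peaks, k-NN distances, FWHM sizes.

Three analyses are computed from each cell's cluster localizations:

* **local density** — a 2D Gaussian kernel density map (bandwidth
  200 nm) whose local-maximum intensities form the density-peak
  distribution.  The map uses unit-peak kernels, so intensities read
  directly as the kernel-weighted number of clusters around a pixel.
* **nearest neighbours** — for every cluster, the distances to its
  k = 4 nearest neighbours (self excluded), pooled per cell.
* **cluster size** — four 400 nm line profiles (0/45/90/135 degrees)
  through each localization, each fitted with a Lorentzian
  ``offset + A / (1 + ((x - x0)/gamma)^2)``; of the profiles whose fit
  reaches R^2 > 0.9, the minimum FWHM (= 2 gamma) is the cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from sklearn.neighbors import KernelDensity, NearestNeighbors

from .core import ClusterLocalizations, PerCellDistribution, StedImage
from .preprocess import merged_local_maxima

__all__ = [
    "DensityMap",
    "LineProfile",
    "LorentzianFit",
    "density_map",
    "density_peak_intensities",
    "knn_distances",
    "extract_line_profiles",
    "fit_lorentzian",
    "cluster_fwhm",
]

logger = logging.getLogger(__name__)


@dataclass
class DensityMap:
    """KDE map of cluster localizations on a regular grid.

    ``grid[r, c]`` is the kernel-weighted number of clusters around the
    point ``origin + ((c + 0.5), (r + 0.5)) * grid_spacing`` (nm).
    """

    grid: np.ndarray
    grid_spacing: float
    bandwidth: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be > 0")


def density_map(
    locs: ClusterLocalizations,
    bandwidth: float = 200.0,
    grid_spacing: float = 20.0,
    extent_nm: tuple[float, float] | None = None,
    normalization: str = "kernel_sum",
) -> DensityMap:
    """Fit a 2D Gaussian KDE to the point cloud of localizations.

    With ``normalization='kernel_sum'`` (default) each kernel has unit
    peak amplitude: the value at p is ``sum_i exp(-|p - x_i|^2 / (2 bw^2))``,
    i.e. the number of clusters per Gaussian kernel around p.  A single
    isolated cluster gives a peak of exactly 1; m coincident clusters
    give m.  ``'density'`` returns the probability density instead
    (the two differ by the constant ``n * 2 pi bw^2``).

    ``extent_nm`` is the (width, height) of the field; defaults to the
    bounding box of the points padded by 3 bandwidths.
    """
    if len(locs) == 0:
        raise ValueError("cannot build a density map from zero localizations")
    if normalization not in ("kernel_sum", "density"):
        raise ValueError(f"unknown normalization {normalization!r}")
    pts = locs.points
    if extent_nm is None:
        pad = 3.0 * bandwidth
        x0, y0 = pts.min(axis=0) - pad
        x1, y1 = pts.max(axis=0) + pad
    else:
        x0 = y0 = 0.0
        x1, y1 = extent_nm
    nx = max(2, int(np.ceil((x1 - x0) / grid_spacing)))
    ny = max(2, int(np.ceil((y1 - y0) / grid_spacing)))
    gx = x0 + (np.arange(nx) + 0.5) * grid_spacing
    gy = y0 + (np.arange(ny) + 0.5) * grid_spacing
    xx, yy = np.meshgrid(gx, gy)
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(pts)
    logd = kde.score_samples(np.column_stack([xx.ravel(), yy.ravel()]))
    dens = np.exp(logd).reshape(ny, nx)
    if normalization == "kernel_sum":
        dens = dens * len(pts) * 2.0 * np.pi * bandwidth**2
    return DensityMap(
        grid=dens, grid_spacing=grid_spacing, bandwidth=bandwidth, origin=(x0, y0)
    )


def density_peak_intensities(
    dmap: DensityMap,
    cell_id: str = "",
    condition: str = "",
    min_intensity: float = 1e-6,
) -> PerCellDistribution:
    """Intensities of the local maxima of the density map.

    Adjacent-maximum merging follows the same rule as cluster
    localization; maxima below ``min_intensity`` (numerically empty
    regions of the map) are discarded.  A flat map yields an empty
    distribution.
    """
    grid = dmap.grid
    if np.ptp(grid) == 0:
        vals = np.empty(0)
    else:
        _, vals = merged_local_maxima(grid, min_intensity)
    return PerCellDistribution(
        values=vals, cell_id=cell_id, condition=condition, analysis="density_peaks"
    )


def knn_distances(locs: ClusterLocalizations, k: int = 4) -> PerCellDistribution:
    """k nearest-neighbour distances per cluster, self excluded.

    k = 4 targets the ~200 nm neighbourhood of each cluster while
    excluding neighbours beyond ~800 nm at typical densities.  The
    distribution holds k distances per localization (length k * n).
    """
    n = len(locs)
    if n <= k:
        raise ValueError(
            f"cell {locs.cell_id or '<unnamed>'}: need more than k={k} "
            f"localizations, got {n}"
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(locs.points)
    dist, _ = nn.kneighbors(locs.points)
    return PerCellDistribution(
        values=dist[:, 1:].ravel(),
        cell_id=locs.cell_id,
        condition=locs.condition,
        analysis="nn_distance",
    )


@dataclass
class LineProfile:
    """Intensity profile along a line through a cluster centre."""

    positions: np.ndarray  # nm, relative to the centre (signed)
    values: np.ndarray
    angle_deg: float


def extract_line_profiles(
    img: StedImage,
    center: tuple[float, float],
    length: float = 400.0,
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    step: float | None = None,
    order: int = 3,
) -> list[LineProfile]:
    """Sample line profiles through ``center`` by spline interpolation.

    Sampling step defaults to half the pixel size.  Cubic spline
    interpolation (``order=3``) is the default: it tracks narrow
    (~2-3 pixel FWHM) peaks much more faithfully than bilinear, which
    flattens the peak apex and inflates fitted widths; ``order=1``
    gives plain bilinear.  A profile whose sample points leave the
    image is skipped (the caller counts skips).
    """
    px = img.pixel_size
    if step is None:
        step = px / 2.0
    cx, cy = center
    half = length / 2.0
    t = np.arange(-half, half + step / 2, step)
    rows, cols = img.pixels.shape
    out: list[LineProfile] = []
    for ang in angles_deg:
        rad = np.deg2rad(ang)
        xs = cx + t * np.cos(rad)
        ys = cy + t * np.sin(rad)
        # nm -> fractional index (pixel centres at (i + 0.5) px)
        ci = xs / px - 0.5
        ri = ys / px - 0.5
        if ci.min() < 0 or ri.min() < 0 or ci.max() > cols - 1 or ri.max() > rows - 1:
            continue  # would extrapolate: skip this profile
        vals = ndimage.map_coordinates(img.pixels, [ri, ci], order=order)
        out.append(LineProfile(positions=t.copy(), values=vals, angle_deg=ang))
    return out


@dataclass
class LorentzianFit:
    """Result of fitting ``offset + A / (1 + ((x - x0)/gamma)^2)``."""

    amplitude: float
    center: float
    gamma: float
    offset: float
    r_squared: float
    ok: bool

    @property
    def fwhm(self) -> float:
        return 2.0 * self.gamma


def _lorentzian(x: np.ndarray, amp: float, x0: float, gamma: float, offset: float) -> np.ndarray:
    return offset + amp / (1.0 + ((x - x0) / gamma) ** 2)


_FAILED_FIT = LorentzianFit(np.nan, np.nan, np.nan, np.nan, -np.inf, False)


def fit_lorentzian(profile: LineProfile) -> LorentzianFit:
    """Least-squares Lorentzian fit of a line profile.

    Initialization: amplitude = max - min, centre at the maximum,
    gamma = 50 nm, offset = min; gamma bounded to (5, 400) nm.  A
    failed fit is returned flagged (``ok=False``), never raised.
    """
    x, y = profile.positions, profile.values
    if len(x) < 8:
        raise ValueError("profile needs at least 8 samples")
    ymin, ymax = float(y.min()), float(y.max())
    p0 = [ymax - ymin, float(x[np.argmax(y)]), 50.0, ymin]
    bounds = ([0.0, x.min(), 5.0, -np.inf], [np.inf, x.max(), 400.0, np.inf])
    try:
        popt, _ = optimize.curve_fit(
            _lorentzian, x, y, p0=p0, bounds=bounds, maxfev=5000
        )
    except (RuntimeError, ValueError):
        return _FAILED_FIT
    resid = y - _lorentzian(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 0.0  # constant profile carries no peak information
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return LorentzianFit(
        amplitude=float(popt[0]),
        center=float(popt[1]),
        gamma=float(popt[2]),
        offset=float(popt[3]),
        r_squared=r2,
        ok=True,
    )


def cluster_fwhm(
    img: StedImage,
    locs: ClusterLocalizations,
    r2_threshold: float = 0.9,
    length: float = 400.0,
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
) -> PerCellDistribution:
    """Per-cluster FWHM from line-profile Lorentzian fits.

    For each localization, the profiles whose fit reaches
    ``R^2 > r2_threshold`` contribute their FWHM; the minimum of those
    is the cluster size (the narrowest cut through an elongated or
    partially overlapping cluster).  Clusters with no passing fit are
    dropped; skipped edge profiles and dropped clusters are counted in
    ``meta``.
    """
    fwhms = []
    n_dropped = 0
    n_skipped_profiles = 0
    for pt in locs.points:
        profiles = extract_line_profiles(img, tuple(pt), length=length, angles_deg=angles_deg)
        n_skipped_profiles += len(angles_deg) - len(profiles)
        passing = []
        for prof in profiles:
            fit = fit_lorentzian(prof)
            if fit.ok and fit.r_squared > r2_threshold:
                passing.append(fit.fwhm)
        if passing:
            fwhms.append(min(passing))
        else:
            n_dropped += 1
    if n_dropped or n_skipped_profiles:
        logger.debug(
            "cell %s: %d clusters without passing fits, %d edge profiles skipped",
            locs.cell_id, n_dropped, n_skipped_profiles,
        )
    return PerCellDistribution(
        values=np.asarray(fwhms),
        cell_id=locs.cell_id,
        condition=locs.condition,
        analysis="fwhm",
        meta={"n_dropped": n_dropped, "n_skipped_profiles": n_skipped_profiles},
    )
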