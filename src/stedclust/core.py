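"""Shared containers for the STED nanocluster pipeline.

Coordinate convention
---------------------
All physical quantities are in nanometres.  Points live on a continuous
2D plane whose origin is the image corner; the centre of pixel
``(row, col)`` sits at ``x = (col + 0.5) * pixel_size`` and
``y = (row + 0.5) * pixel_size``.  Point arrays are shaped ``(n, 2)``
with columns ``(x_nm, y_nm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StedImage",
    "CellMask",
    "ClusterLocalizations",
    "PerCellDistribution",
    "pixel_centers",
]


def pixel_centers(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(x, y)`` nm coordinate grids for the centres of every pixel."""
    rows, cols = shape
    x = (np.arange(cols) + 0.5) * pixel_size
    y = (np.arange(rows) + 0.5) * pixel_size
    return np.meshgrid(x, y)


@dataclass
class StedImage:
    """A single-channel STED intensity image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D non-negative (for raw images) intensity grid, at least 64x64.
    pixel_size : float
        Physical pixel size in nm.  STED acquisitions in this pipeline's
        regime use 20-25 nm pixels.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < 64:
            raise ValueError(f"image must be at least 64x64, got {self.pixels.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical (width, height) of the image in nm."""
        rows, cols = self.pixels.shape
        return cols * self.pixel_size, rows * self.pixel_size

    def with_pixels(self, pixels: np.ndarray) -> "StedImage":
        """Copy carrying the same pixel size with new pixel data."""
        return StedImage(pixels=pixels, pixel_size=self.pixel_size)


@dataclass
class CellMask:
    """Binary support region marking in-cell pixels."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * (self.pixel_size / 1000.0) ** 2

    @property
    def area_fraction(self) -> float:
        return self.n_pixels / self.mask.size

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean array: which (x_nm, y_nm) points fall on in-mask pixels."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cols = np.floor(pts[:, 0] / self.pixel_size).astype(int)
        rows = np.floor(pts[:, 1] / self.pixel_size).astype(int)
        inside = (
            (rows >= 0)
            & (rows < self.mask.shape[0])
            & (cols >= 0)
            & (cols < self.mask.shape[1])
        )
        out = np.zeros(len(pts), dtype=bool)
        out[inside] = self.mask[rows[inside], cols[inside]]
        return out


@dataclass
class ClusterLocalizations:
    """Cluster coordinates (nm, continuous plane) for one cell."""

    points: np.ndarray
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {pts.shape}")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PerCellDistribution:
    """A 1D sample of per-cluster values attributed to one cell.

    ``analysis`` is one of ``density_peaks`` (kernel-weighted counts),
    ``nn_distance`` (nm) or ``fwhm`` (nm).
    """

    values: np.ndarray
    cell_id: str = ""
    condition: str = ""
    analysis: str = ""
    meta: dict = field(default_factory=dict)

    _POSITIVE = ("nn_distance", "fwhm")

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("distribution values must be finite")
        if self.analysis in self._POSITIVE and vals.size and not np.all(vals > 0):
            raise ValueError(f"{self.analysis} values must be positive")
        self.values = vals

    def __len__(self) -> int:
        return len(self.values)
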