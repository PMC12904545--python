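"""Speckle statistics: ROI normalization, contrast ratio, kernel density.

Two normalizations put simulated envelopes and 8-bit device images on the
matching scale:

* simulated ROIs are divided by their maximum and then by the RMS of the
  result, so the output has unit RMS and is invariant to positive rescaling;
* experimental ROIs are divided by 255, divided by the RMS of the result,
  and inverse-transformed with y = 10**x, undoing the log compression that
  OCT devices apply for display.

The matching currency is a :class:`SpeckleSummary`: the contrast ratio
(sample standard deviation over mean -- the standard speckle-contrast
definition, computed with the n-1 variance) plus a Gaussian kernel density
estimate evaluated on a shared grid.  Distances between summaries are
meaningful only when the two densities share the same grid, so the grid is
always constructed per analysis with :func:`shared_grid`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "DensityEstimate",
    "SpeckleSummary",
    "normalize_sim",
    "normalize_exp",
    "contrast_ratio",
    "estimate_density",
    "shared_grid",
    "summarize",
    "DEFAULT_GRID_POINTS",
]

DEFAULT_GRID_POINTS = 512


@dataclass
class DensityEstimate:
    """KDE values on a fixed evaluation grid, renormalized to unit mass.

    The Gaussian kernel spills probability mass below zero for data
    clustered near zero, so the raw KDE is renormalized to integrate to one
    over the grid (trapezoid rule); ``values`` therefore always satisfy the
    unit-mass invariant.
    """

    grid: np.ndarray
    values: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")

    @property
    def mass(self) -> float:
        return float(np.trapezoid(self.values, self.grid))

    def same_grid(self, other: "DensityEstimate") -> bool:
        return self.grid.shape == other.grid.shape and np.array_equal(
            self.grid, other.grid
        )


@dataclass
class SpeckleSummary:
    """Contrast ratio plus kernel density estimate of a normalized ROI."""

    cr: float
    density: DensityEstimate


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x, dtype=float))))


def normalize_sim(roi: np.ndarray) -> np.ndarray:
    """Normalize a simulated envelope ROI: divide by max, then by RMS.

    The output has RMS exactly 1 and is invariant to positive rescaling of
    the input.  An all-zero ROI is rejected (flagged entry upstream).
    """
    roi = np.asarray(roi, dtype=float)
    peak = roi.max()
    if peak <= 0:
        raise ValueError("all-zero ROI cannot be normalized")
    scaled = roi / peak
    return scaled / _rms(scaled)


def normalize_exp(roi: np.ndarray) -> np.ndarray:
    """Normalize an 8-bit device ROI: /255, /RMS, then invert log compression.

    x = (roi/255)/RMS(roi/255); output = 10**x elementwise, which undoes the
    base-10 log compression applied for display.  Output is >= 1 everywhere.
    """
    roi = np.asarray(roi)
    if roi.min() < 0 or roi.max() > 255:
        raise ValueError("experimental ROI must hold 8-bit values in [0, 255]")
    x = roi.astype(float) / 255.0
    rms = _rms(x)
    if rms == 0:
        raise ValueError("all-zero ROI cannot be normalized")
    return np.power(10.0, x / rms)


def contrast_ratio(block: np.ndarray) -> float:
    """Speckle contrast: sample standard deviation over mean.

    Invariant under positive rescaling of the block.
    """
    block = np.asarray(block, dtype=float)
    if block.size < 2:
        raise ValueError("contrast ratio needs at least 2 pixels")
    mean = block.mean()
    if mean <= 0:
        raise ValueError("contrast ratio undefined for non-positive mean")
    return float(block.std(ddof=1) / mean)


def shared_grid(*blocks: np.ndarray, n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Evaluation abscissae shared by all densities compared in one analysis.

    Spans [0, 1.05 x max over the supplied blocks] with ``n_points`` points.
    """
    top = max(float(np.asarray(b).max()) for b in blocks)
    if top <= 0:
        raise ValueError("blocks must contain positive values")
    return np.linspace(0.0, 1.05 * top, n_points)


def estimate_density(block: np.ndarray, grid: np.ndarray) -> DensityEstimate:
    """Gaussian-kernel density of the block's pixels on ``grid``.

    Bandwidth by Silverman's rule of thumb; the result is renormalized to
    unit trapezoid mass over the grid.  A single-valued block is degenerate
    and rejected.
    """
    data = np.asarray(block, dtype=float).ravel()
    if np.unique(data).size < 2:
        raise ValueError("density estimation needs >= 2 distinct pixel values")
    kde = gaussian_kde(data, bw_method="silverman")
    values = kde(np.asarray(grid, dtype=float))
    mass = np.trapezoid(values, grid)
    if mass <= 0:
        raise ValueError("degenerate density (zero mass on grid)")
    bandwidth = float(kde.factor * data.std(ddof=1))
    return DensityEstimate(grid=np.asarray(grid, float), values=values / mass,
                           bandwidth=bandwidth)


def summarize(block: np.ndarray, grid: np.ndarray) -> SpeckleSummary:
    """Contrast ratio and density of an already-normalized ROI block."""
    return SpeckleSummary(cr=contrast_ratio(block),
                          density=estimate_density(block, grid))
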