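"""Statistical matching of a sample ROI against the look-up map.

Three distances compare the sample speckle summary with every reference k:

    D_CR(k)  = |CR_sample - CR_k|
    D_ISE(k) = integral (f_sample(x) - f_k(x))^2 dx      (trapezoid rule)
    D_KL(k)  = sum_x f_sample(x) log(f_sample(x)/f_k(x)) (natural log)

The second distance is often called an RMS error; it is computed here as the
integrated squared difference, without the square root -- the argmin is
unaffected by the monotone root.  The KL divergence is evaluated on the
shared grid after flooring both densities at eps = 1e-12 and renormalizing
to unit mass, which keeps it finite and non-negative.

Each distance is minimized over the map (first occurrence wins on ties) and
the three minimizing (mu_s, g) grid pairs are ensemble-averaged into the
final estimate (mu_s_hat, g_hat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .speckle_stats import (
    DensityEstimate,
    SpeckleSummary,
    contrast_ratio,
    estimate_density,
    normalize_exp,
    normalize_sim,
    shared_grid,
    summarize,
)

__all__ = [
    "DistanceTriple",
    "PerDistancePick",
    "EstimateResult",
    "d_cr",
    "d_rms",
    "d_kl",
    "match",
    "match_roi",
    "KL_FLOOR",
]

logger = logging.getLogger(__name__)

KL_FLOOR = 1e-12


@dataclass(frozen=True)
class DistanceTriple:
    """The three distances between a sample and one reference."""

    d_cr: float
    d_rms: float
    d_kl: float


@dataclass(frozen=True)
class PerDistancePick:
    """Minimum value of one distance and the (mu_s, g) of its minimizer."""

    name: str
    min_value: float
    mu_s: float
    g: float
    index: int


@dataclass(frozen=True)
class EstimateResult:
    """Per-distance minimizers and their ensemble average (mu_s_hat, g_hat)."""

    per_distance: tuple  # three PerDistancePick, order (CR, RMS, KL)
    mu_s_hat: float
    g_hat: float

    def as_dict(self) -> dict:
        return {
            "per_distance": [
                {
                    "distance": p.name,
                    "min": p.min_value,
                    "mu_s": p.mu_s,
                    "g": p.g,
                }
                for p in self.per_distance
            ],
            "mu_s_hat": self.mu_s_hat,
            "g_hat": self.g_hat,
        }


def ensemble_average(picks) -> tuple:
    """Arithmetic mean of the per-distance (mu_s, g) picks."""
    mu = float(np.mean([p.mu_s for p in picks]))
    g = float(np.mean([p.g for p in picks]))
    return mu, g


def d_cr(sample: SpeckleSummary, ref: SpeckleSummary) -> float:
    """Absolute contrast-ratio difference."""
    return abs(sample.cr - ref.cr)


def _check_grids(a: DensityEstimate, b: DensityEstimate) -> None:
    if not a.same_grid(b):
        raise ValueError("densities must share the same evaluation grid")


def d_rms(sample_density: DensityEstimate, ref_density: DensityEstimate) -> float:
    """Integrated squared difference between densities on the shared grid."""
    _check_grids(sample_density, ref_density)
    diff = sample_density.values - ref_density.values
    return float(np.trapezoid(diff * diff, sample_density.grid))


def d_kl(sample_density: DensityEstimate, ref_density: DensityEstimate) -> float:
    """Discrete KL divergence on the shared grid, natural log.

    Both densities are floored at KL_FLOOR and renormalized to unit sum, so
    the result is finite and >= 0 (Gibbs' inequality).
    """
    _check_grids(sample_density, ref_density)
    p = np.maximum(sample_density.values, KL_FLOOR)
    q = np.maximum(ref_density.values, KL_FLOOR)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def _argmin_first(values: np.ndarray) -> int:
    idx = int(np.argmin(values))
    ties = np.flatnonzero(values == values[idx])
    if ties.size > 1:
        logger.info("distance tie among references %s; keeping first", ties.tolist())
    return idx


def match(sample: SpeckleSummary, lookup) -> EstimateResult:
    """Match a sample summary against every valid map entry.

    The sample summary and all entry summaries must share one density grid.
    Per-distance argmins take the first occurrence on ties; the ensemble
    estimate is the arithmetic mean of the three per-distance (mu_s, g).
    """
    entries = [e for e in lookup.entries if e.valid]
    if not entries:
        raise ValueError("look-up map has no valid entries to match against")
    return _match_summaries(sample, [e.summary for e in entries], entries)


def match_roi(roi: np.ndarray, lookup, kind: str = "sim") -> EstimateResult:
    """Normalize a raw ROI block and match it against the map.

    ``kind`` selects the normalization: "sim" for simulated envelope ROIs,
    "exp" for 8-bit device images.  One evaluation grid is shared by every
    density in the analysis, as the density distances require: the map-wide
    grid when it covers the sample's values, otherwise a widened grid on
    which all reference densities are recomputed.
    """
    if kind == "sim":
        sample_block = normalize_sim(roi)
    elif kind == "exp":
        sample_block = normalize_exp(roi)
    else:
        raise ValueError("kind must be 'sim' or 'exp'")
    entries = [e for e in lookup.entries if e.valid]
    if not entries:
        raise ValueError("look-up map has no valid entries to match against")
    map_grid = np.asarray(lookup.density_grid)
    if map_grid.size and float(sample_block.max()) <= float(map_grid[-1]):
        sample = summarize(sample_block, map_grid)
        return match(sample, lookup)
    # sample exceeds the map grid: widen and recompute reference densities
    ref_blocks = [normalize_sim(e.roi) for e in entries]
    grid = shared_grid(sample_block, *ref_blocks)
    sample = summarize(sample_block, grid)
    ref_summaries = [
        SpeckleSummary(cr=contrast_ratio(b), density=estimate_density(b, grid))
        for b in ref_blocks
    ]
    return _match_summaries(sample, ref_summaries, entries)


def _match_summaries(sample, ref_summaries, entries) -> EstimateResult:
    n = len(entries)
    dc = np.empty(n)
    dr = np.empty(n)
    dk = np.empty(n)
    for i, ref in enumerate(ref_summaries):
        dc[i] = d_cr(sample, ref)
        dr[i] = d_rms(sample.density, ref.density)
        dk[i] = d_kl(sample.density, ref.density)
    picks = []
    for name, values in (("CR", dc), ("RMS", dr), ("KL", dk)):
        i = _argmin_first(values)
        picks.append(
            PerDistancePick(name=name, min_value=float(values[i]),
                            mu_s=entries[i].mu_s, g=entries[i].g, index=i)
        )
    mu_hat, g_hat = ensemble_average(picks)
    return EstimateResult(per_distance=tuple(picks), mu_s_hat=mu_hat, g_hat=g_hat)
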