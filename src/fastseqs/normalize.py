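"""Quantile normalization of tag-count tables with left-tail exclusion.

Different samples (and runs) yield different tag totals and, because the
assay's amplicons fall into two size classes with the smaller preferentially
amplified, a bimodal, negatively skewed per-position count distribution.
Normalization proceeds in three stages over an *experimental group*:

1. restrict to positions with at least one tag in every sample
   (:func:`shared_positions`);
2. quantile-normalize: sort each sample's counts, replace each rank with the
   across-sample mean at that rank, unsort (:func:`quantile_normalize`);
3. estimate a Gaussian-kernel density of the log per-position means, find the
   density minimum between the two principal modes, drop positions below it,
   and quantile-normalize again (:func:`exclude_and_renormalize`).

After this every sample has the same total and an identical sorted value
vector, so chromosome totals are directly comparable across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)


@dataclass
class DensityCurve:
    """KDE of log-scale per-position values with its modes and valley cutoff."""

    grid: np.ndarray
    density: np.ndarray
    modes: np.ndarray        # abscissae of local maxima, ascending
    bandwidth: float
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


@dataclass
class NormalizedCountTable:
    """Positions x samples matrix after normalization, plus what was dropped."""

    values: pd.DataFrame
    excluded_positions: pd.MultiIndex
    density: DensityCurve | None = None


def shared_positions(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.MultiIndex]:
    """Keep positions with a count >= 1 in every sample of the group.

    Returns the restricted table and the excluded position identities.
    """
    if table.shape[1] < 2:
        raise ValueError("an experimental group needs at least 2 samples")
    keep = (table > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no positions are shared by all samples")
    excluded = table.index[~keep]
    return table.loc[keep], excluded


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization on a positions x samples matrix.

    Each sample's counts are sorted (stable, position order breaking ties),
    the mean across samples is taken at each rank, every sample's value at
    that rank is replaced by the mean, and values are unsorted back to
    position order. Every column of the result has the same sorted vector and
    the same total (the mean of the input totals).
    """
    if table.isna().any().any():
        raise ValueError("table contains missing values")
    x = table.to_numpy(float)
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    row_means = sorted_vals.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = row_means
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def estimate_log_density(
    mean_values: np.ndarray | pd.Series,
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    min_mode_frac: float = 0.01,
) -> DensityCurve:
    """Gaussian KDE of log-transformed per-position values.

    The grid spans the data range plus 3 bandwidths on either side. Modes are
    strict local maxima (flat plateaus collapsed to their left edge) whose
    density reaches at least ``min_mode_frac`` of the global maximum (1% by
    default) — sampling wiggles in the far tails do not count as peaks.
    """
    v = np.asarray(mean_values, float)
    if v.size < 10:
        raise ValueError("need at least 10 values for density estimation")
    if np.any(v <= 0):
        raise ValueError("values must be positive for the log transform")
    logv = np.log(v)
    kde = gaussian_kde(logv, bw_method=bandwidth)
    bw = float(kde.factor * logv.std(ddof=1))
    grid = np.linspace(logv.min() - 3 * bw, logv.max() + 3 * bw, grid_size)
    dens = kde(grid)
    peaks = _local_maxima(dens)
    peaks = peaks[dens[peaks] >= min_mode_frac * dens.max()]
    return DensityCurve(grid=grid, density=dens, modes=grid[peaks], bandwidth=bw)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima, collapsing flat plateaus."""
    # collapse exact ties so plateaus register once
    keep = np.r_[True, np.diff(y) != 0]
    idx = np.nonzero(keep)[0]
    yy = y[idx]
    interior = np.nonzero((yy[1:-1] > yy[:-2]) & (yy[1:-1] > yy[2:]))[0] + 1
    return idx[interior]


def find_left_tail_cutoff(curve: DensityCurve) -> float | None:
    """Valley abscissa between the two principal peaks, or None if unimodal.

    The cutoff is the grid point of minimum density strictly between the two
    highest-density modes. Positions whose (log) value falls below it form
    the left tail.
    """
    if len(curve.modes) < 2:
        return None
    mode_dens = np.interp(curve.modes, curve.grid, curve.density)
    top2 = curve.modes[np.argsort(mode_dens)[-2:]]
    lo, hi = sorted(top2)
    between = (curve.grid > lo) & (curve.grid < hi)
    if not between.any():
        return None
    seg = np.nonzero(between)[0]
    return float(curve.grid[seg[np.argmin(curve.density[seg])]])


def exclude_and_renormalize(table: pd.DataFrame) -> NormalizedCountTable:
    """Full normalization: quantile pass, left-tail exclusion, second pass.

    ``table`` must already be restricted to shared positions. When the log
    density of per-position means is unimodal no positions are dropped and a
    warning is logged.
    """
    first = quantile_normalize(table)
    means = first.mean(axis=1)
    curve = estimate_log_density(means)
    cutoff = find_left_tail_cutoff(curve)
    curve.cutoff = cutoff
    if cutoff is None:
        logger.warning("log-count density is unimodal; no left tail excluded")
        return NormalizedCountTable(values=first,
                                    excluded_positions=table.index[:0],
                                    density=curve)
    drop = np.log(means.to_numpy()) < cutoff
    excluded = table.index[drop]
    second = quantile_normalize(table.loc[~drop])
    return NormalizedCountTable(values=second, excluded_positions=excluded,
                                density=curve)


def normalize_group(table: pd.DataFrame) -> NormalizedCountTable:
    """shared_positions + exclude_and_renormalize; the one-call entry point.

    The returned ``excluded_positions`` covers both unshared and left-tail
    positions.
    """
    restricted, unshared = shared_positions(table)
    result = exclude_and_renormalize(restricted)
    result.excluded_positions = unshared.append(result.excluded_positions)
    return result
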