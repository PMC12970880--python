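"""Mark-correlation statistics for quantitatively marked planar patterns.

Three complementary test-function statistics are estimated on a common
distance grid with a box kernel (closed band ``|d - r| <= h``):

* ``r_mark`` — normalized mean mark of the first point of ordered pairs at
  distance r; values > 1 mean points with neighbors at r carry
  above-average marks.
* ``schlather`` — Moran-like correlation of the two marks of pairs at
  distance r, centred on the distance-conditional mean and normalized by the
  overall (population, denominator n) mark variance.
* ``density_corr`` — Pearson correlation between each point's mark and its
  cumulative neighbor count within distance r.

No edge correction is applied: all statistics are ratio estimators whose
geometry is shared with the random-labelling null, so edge effects cancel
between observed and simulated curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .deposit_io import MarkedPointPattern, ValidationError

R_MARK = "r_mark"
SCHLATHER = "schlather"
DENSITY_CORR = "density_corr"
STATISTICS = (R_MARK, SCHLATHER, DENSITY_CORR)


class MarkStatisticError(ValueError):
    """A statistic is undefined for the given marks (e.g. zero variance)."""


@dataclass(frozen=True)
class DistanceGrid:
    """Bin centers and box-kernel half-width, in meters.

    The default lattice is centers 0.5, 1.5, ..., 49.5 m with h = 0.5,
    i.e. contiguous 1 m bands up to 50 m.
    """

    r_centers: np.ndarray
    h: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.r_centers, dtype=float)
        if centers.ndim != 1 or len(centers) == 0:
            raise ValidationError("r_centers must be a non-empty 1-d sequence")
        if np.any(centers <= 0) or np.any(np.diff(centers) <= 0):
            raise ValidationError("r_centers must be positive and increasing")
        if not self.h > 0:
            raise ValidationError("bandwidth h must be > 0")
        object.__setattr__(self, "r_centers", centers)
        object.__setattr__(self, "h", float(self.h))

    @classmethod
    def default(
        cls, r_max: float = 50.0, bin_width: float = 1.0, h: float = 0.5
    ) -> "DistanceGrid":
        centers = np.arange(bin_width / 2.0, r_max, bin_width)
        return cls(centers, h)

    @property
    def n_bins(self) -> int:
        return len(self.r_centers)


@dataclass
class MarkCorrCurve:
    """A statistic evaluated on a distance grid, with per-bin validity.

    ``values`` holds NaN where a bin is undefined (no pairs in band, or a
    constant neighbor-count vector for the density correlation).
    """

    statistic: str
    r_centers: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray
    mark_mean_mu: float
    mark_variance_sigma2: float
    intensity_lambda: float

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": self.statistic,
                "r_center": self.r_centers,
                "value": self.values,
                "pair_count": self.pair_counts,
                "missing_flag": self.missing,
            }
        )


def box_kernel(d: float, r: float, h: float) -> float:
    """Box kernel: 1/(2h) when |d - r| <= h (boundary inclusive), else 0."""
    if not h > 0:
        raise ValidationError("bandwidth h must be > 0")
    return 1.0 / (2.0 * h) if abs(d - r) <= h else 0.0


def ring_pairs(
    pattern: MarkedPointPattern, r: float, h: float
) -> list[tuple[int, int]]:
    """All ordered index pairs (i, j), i != j, with ||x_i - x_j|| in r +- h."""
    if pattern.n < 2:
        raise ValidationError("ring_pairs requires n >= 2")
    d = squareform(pdist(pattern.points))
    mask = np.abs(d - r) <= h
    np.fill_diagonal(mask, False)
    ii, jj = np.nonzero(mask)
    return list(zip(ii.tolist(), jj.tolist()))


def neighbor_counts(pattern: MarkedPointPattern, r: float) -> np.ndarray:
    """K_i = number of other points within distance r of point i (disc count,
    ties at d == r included)."""
    if pattern.n < 2:
        raise ValidationError("neighbor_counts requires n >= 2")
    d = squareform(pdist(pattern.points))
    mask = d <= r
    np.fill_diagonal(mask, False)
    return mask.sum(axis=1).astype(int)


class BinnedGeometry:
    """Distance-bin structures of a fixed point configuration.

    Precomputing the per-bin pair masks lets an entire random-labelling
    ensemble (hundreds of mark vectors on the same points) be evaluated with
    a handful of matrix products per bin.
    """

    def __init__(self, pattern: MarkedPointPattern, grid: DistanceGrid):
        if pattern.n < 2:
            raise ValidationError("mark correlation requires n >= 2")
        self.pattern = pattern
        self.grid = grid
        d = squareform(pdist(pattern.points))
        r = grid.r_centers
        masks = np.abs(d[None, :, :] - r[:, None, None]) <= grid.h
        idx = np.arange(pattern.n)
        masks[:, idx, idx] = False
        self.masks = masks                             # (n_bins, n, n) bool
        self.row_counts = masks.sum(axis=2)            # (n_bins, n)
        self.pair_counts = self.row_counts.sum(axis=1)  # ordered pairs per bin
        disc = d[None, :, :] <= r[:, None, None]
        disc[:, idx, idx] = False
        self.K = disc.sum(axis=2).astype(float)        # (n_bins, n)

    # All evaluators take a (n_curves, n) stack of mark vectors and return a
    # (n_curves, n_bins) array with NaN at undefined bins.

    def r_mark(self, marks2d: np.ndarray) -> np.ndarray:
        marks2d = np.atleast_2d(np.asarray(marks2d, dtype=float))
        mu = marks2d.mean(axis=1)
        if np.any(mu <= 0):
            raise MarkStatisticError("r-mark normalization undefined: mu == 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            ct = (marks2d @ self.row_counts.T) / self.pair_counts
            km = ct / mu[:, None]
        km[:, self.pair_counts == 0] = np.nan
        return km

    def schlather(self, marks2d: np.ndarray) -> np.ndarray:
        marks2d = np.atleast_2d(np.asarray(marks2d, dtype=float))
        sigma2 = marks2d.var(axis=1)  # population variance per curve
        if np.any(sigma2 <= 0):
            raise MarkStatisticError("Schlather normalization undefined: "
                                     "zero mark variance")
        n_curves = marks2d.shape[0]
        n_bins = self.grid.n_bins
        out = np.full((n_curves, n_bins), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu_r = (marks2d @ self.row_counts.T) / self.pair_counts
        for b in range(n_bins):
            npairs = self.pair_counts[b]
            if npairs == 0:
                continue
            # sum over ordered pairs of m_i m_j, then centre on mu(r):
            # E[(m_i - mu_r)(m_j - mu_r)] = E[m_i m_j] - mu_r^2
            quad = ((marks2d @ self.masks[b]) * marks2d).sum(axis=1)
            out[:, b] = (quad / npairs - mu_r[:, b] ** 2) / sigma2
        return out

    def density_corr(self, marks2d: np.ndarray) -> np.ndarray:
        marks2d = np.atleast_2d(np.asarray(marks2d, dtype=float))
        if self.pattern.n < 3:
            raise ValidationError("density correlation requires n >= 3")
        mc = marks2d - marks2d.mean(axis=1, keepdims=True)
        m_norm = np.sqrt((mc**2).sum(axis=1))
        if np.any(m_norm == 0):
            raise MarkStatisticError("density correlation undefined for "
                                     "constant marks")
        kc = self.K - self.K.mean(axis=1, keepdims=True)
        k_norm = np.sqrt((kc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (mc @ kc.T) / (m_norm[:, None] * k_norm[None, :])
        corr[:, k_norm == 0] = np.nan
        return corr

    def evaluate(self, statistic: str, marks2d: np.ndarray) -> np.ndarray:
        try:
            fn = {
                R_MARK: self.r_mark,
                SCHLATHER: self.schlather,
                DENSITY_CORR: self.density_corr,
            }[statistic]
        except KeyError:
            raise ValidationError(
                f"unknown statistic {statistic!r}; expected one of {STATISTICS}"
            ) from None
        return fn(marks2d)


def _curve(
    statistic: str, geom: BinnedGeometry, values: np.ndarray
) -> MarkCorrCurve:
    marks = geom.pattern.marks
    return MarkCorrCurve(
        statistic=statistic,
        r_centers=geom.grid.r_centers.copy(),
        values=values,
        pair_counts=geom.pair_counts.copy(),
        mark_mean_mu=float(marks.mean()),
        mark_variance_sigma2=float(marks.var()),
        intensity_lambda=geom.pattern.intensity,
    )


def r_mark_correlation(
    pattern: MarkedPointPattern, grid: DistanceGrid | None = None
) -> MarkCorrCurve:
    """Normalized r-mark correlation k_m(r) = c_t(r) / mu."""
    grid = grid or DistanceGrid.default()
    geom = BinnedGeometry(pattern, grid)
    return _curve(R_MARK, geom, geom.r_mark(pattern.marks)[0])


def schlather_imm(
    pattern: MarkedPointPattern, grid: DistanceGrid | None = None
) -> MarkCorrCurve:
    """Schlather's I_mm(r), normalized by the overall mark variance."""
    grid = grid or DistanceGrid.default()
    geom = BinnedGeometry(pattern, grid)
    return _curve(SCHLATHER, geom, geom.schlather(pattern.marks)[0])


def density_correlation(
    pattern: MarkedPointPattern, grid: DistanceGrid | None = None
) -> MarkCorrCurve:
    """Pearson correlation C_m,K(r) between marks and neighbor counts."""
    grid = grid or DistanceGrid.default()
    geom = BinnedGeometry(pattern, grid)
    return _curve(DENSITY_CORR, geom, geom.density_corr(pattern.marks)[0])


def compute_statistic(
    pattern: MarkedPointPattern, statistic: str, grid: DistanceGrid | None = None
) -> MarkCorrCurve:
    grid = grid or DistanceGrid.default()
    geom = BinnedGeometry(pattern, grid)
    return _curve(statistic, geom, geom.evaluate(statistic, pattern.marks)[0])
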