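"""Random-labelling null ensembles, simulation envelopes and GoF testing.

The null model holds point locations fixed and permutes the marks among the
points (mark multiset preserved exactly).  Pointwise envelopes are the k-th
extreme values of the simulated curves (k = 5 of 199 gives a two-sided
pointwise level of 2k/(n_sim+1) = 0.05).  The goodness-of-fit test sums the
squared deviation of each curve from the leave-one-out mean of the others
over the selected distance range and ranks the observed sum among the
simulated ones; ties count as ">=" so the minimum attainable p with 199
simulations is exactly 1/200 = 0.005.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .deposit_io import MarkedPointPattern, ValidationError
from .markcorr import (
    BinnedGeometry,
    DistanceGrid,
    MarkCorrCurve,
    compute_statistic,
    _curve,
)


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    """Derive a named, reproducible stream from one master seed.

    The stream key is a CRC32 of the label, so adding analyses never
    perturbs the draws of existing ones.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


@dataclass
class NullEnsemble:
    """Curves of one statistic under mark permutation on fixed points."""

    statistic: str
    n_sim: int
    r_centers: np.ndarray
    curves: np.ndarray  # (n_sim, n_bins), NaN where a bin is undefined
    rng_seed: int | None

    @property
    def null_mean(self) -> np.ndarray:
        out = np.full(self.curves.shape[1], np.nan)
        finite = np.isfinite(self.curves)
        counts = finite.sum(axis=0)
        sums = np.where(finite, self.curves, 0.0).sum(axis=0)
        np.divide(sums, counts, out=out, where=counts > 0)
        return out


@dataclass(frozen=True)
class EnvelopeResult:
    lo: np.ndarray
    hi: np.ndarray
    k: int


def envelope_level(k: int, n_sim: int) -> float:
    """Implied two-sided pointwise level of a k-th extreme-value envelope."""
    return 2.0 * k / (n_sim + 1.0)


@dataclass(frozen=True)
class GoFResult:
    u_observed: float
    u_simulated: np.ndarray
    p_value: float
    r_min: float
    r_max: float

    @property
    def degenerate(self) -> bool:
        """True when neither data nor null show any deviation (e.g. constant
        marks): every summed deviation is zero and the test is uninformative."""
        return self.u_observed == 0 and bool(np.all(self.u_simulated == 0))


def permuted_marks(
    marks: np.ndarray, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_sim, n) stack of uniform random permutations of ``marks``."""
    marks = np.asarray(marks, dtype=float)
    return np.stack([rng.permutation(marks) for _ in range(n_sim)])


def random_labelling(
    pattern: MarkedPointPattern, n_sim: int, rng_seed: int | np.random.Generator
) -> list[MarkedPointPattern]:
    """Simulated patterns: identical points, marks permuted uniformly."""
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return [
        pattern.with_marks(row)
        for row in permuted_marks(pattern.marks, n_sim, rng)
    ]


def build_null_ensemble(
    pattern: MarkedPointPattern,
    statistic: str,
    grid: DistanceGrid | None = None,
    n_sim: int = 199,
    rng_seed: int | np.random.Generator = 0,
    geometry: BinnedGeometry | None = None,
) -> NullEnsemble:
    """Evaluate one statistic on ``n_sim`` random relabellings of a pattern.

    A prebuilt :class:`BinnedGeometry` may be passed to share the distance
    binning across several statistics on the same points.
    """
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    grid = grid or DistanceGrid.default()
    geom = geometry if geometry is not None else BinnedGeometry(pattern, grid)
    seed = rng_seed if isinstance(rng_seed, int) else None
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sims = permuted_marks(pattern.marks, n_sim, rng)
    curves = geom.evaluate(statistic, sims)
    return NullEnsemble(
        statistic=statistic,
        n_sim=n_sim,
        r_centers=geom.grid.r_centers.copy(),
        curves=curves,
        rng_seed=seed,
    )


def pointwise_envelopes(ensemble: NullEnsemble, k: int = 5) -> EnvelopeResult:
    """Per-bin k-th smallest / k-th largest simulated values."""
    if k < 1:
        raise ValidationError("envelope rank k must be >= 1")
    if 2 * k > ensemble.n_sim:
        raise ValidationError(
            f"envelope rank k={k} too large for n_sim={ensemble.n_sim}"
        )
    curves = ensemble.curves
    n_bins = curves.shape[1]
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    for b in range(n_bins):
        col = curves[:, b]
        if np.all(np.isfinite(col)):
            ordered = np.sort(col)
            lo[b] = ordered[k - 1]
            hi[b] = ordered[-k]
    return EnvelopeResult(lo=lo, hi=hi, k=k)


def gof_test(
    observed: MarkCorrCurve | np.ndarray,
    ensemble: NullEnsemble,
    r_min: float = 0.0,
    r_max: float = 50.0,
) -> GoFResult:
    """Rank-based summed-deviation GoF test against the null ensemble.

    u_i = sum over jointly valid bins in [r_min, r_max] of
    (H_i(r) - Hbar_(-i)(r))^2, where Hbar_(-i) is the mean of all other
    curves (observed included).  p = (1 + #{sim u >= observed u}) / (1 + n_sim).
    """
    obs = observed.values if isinstance(observed, MarkCorrCurve) else observed
    obs = np.asarray(obs, dtype=float)
    stack = np.vstack([obs, ensemble.curves])  # row 0 = observed
    r = ensemble.r_centers
    valid = (
        (r >= r_min)
        & (r <= r_max)
        & np.all(np.isfinite(stack), axis=0)
    )
    if not valid.any():
        raise ValidationError(
            f"no jointly valid bins in [{r_min}, {r_max}] for GoF test"
        )
    h = stack[:, valid]
    m = h.shape[0]
    total = h.sum(axis=0)
    loo_mean = (total[None, :] - h) / (m - 1)
    u = ((h - loo_mean) ** 2).sum(axis=1)
    p = (1.0 + np.sum(u[1:] >= u[0])) / (1.0 + ensemble.n_sim)
    return GoFResult(
        u_observed=float(u[0]),
        u_simulated=u[1:],
        p_value=float(p),
        r_min=r_min,
        r_max=r_max,
    )


@dataclass
class AnalysisConfig:
    """Knobs of one envelope + GoF analysis."""

    grid: DistanceGrid = field(default_factory=DistanceGrid.default)
    n_sim: int = 199
    k: int = 5
    rng_seed: int = 0
    r_min: float = 0.0
    r_max: float = 50.0


@dataclass
class MarkAnalysisResult:
    observed: MarkCorrCurve
    ensemble: NullEnsemble
    envelope: EnvelopeResult
    gof: GoFResult

    @property
    def null_mean(self) -> np.ndarray:
        return self.ensemble.null_mean

    def to_frame(self):
        import pandas as pd

        obs = self.observed.values
        above = obs > self.envelope.hi
        below = obs < self.envelope.lo
        return pd.DataFrame(
            {
                "r_center": self.observed.r_centers,
                "observed": obs,
                "null_mean": self.null_mean,
                "env_lo": self.envelope.lo,
                "env_hi": self.envelope.hi,
                "pair_count": self.observed.pair_counts,
                "outside_envelope": above | below,
                "above_envelope": above,
                "below_envelope": below,
            }
        )

    def to_report(self) -> dict:
        return {
            "statistic": self.observed.statistic,
            "n_sim": self.ensemble.n_sim,
            "envelope_k": self.envelope.k,
            "rng_seed": self.ensemble.rng_seed,
            "r_min": self.gof.r_min,
            "r_max": self.gof.r_max,
            "p_value": self.gof.p_value,
            "u_observed": self.gof.u_observed,
            "degenerate": self.gof.degenerate,
            "mark_mean_mu": self.observed.mark_mean_mu,
            "mark_variance_sigma2": self.observed.mark_variance_sigma2,
            "intensity_lambda": self.observed.intensity_lambda,
        }


def run_mark_analysis(
    pattern: MarkedPointPattern,
    statistic: str,
    config: AnalysisConfig | None = None,
) -> MarkAnalysisResult:
    """Observed curve, null ensemble, envelopes and GoF p for one statistic.

    Fully deterministic given (pattern, config): the ensemble stream is
    derived from ``config.rng_seed`` and the statistic name.
    """
    config = config or AnalysisConfig()
    geom = BinnedGeometry(pattern, config.grid)
    observed = _curve(statistic, geom, geom.evaluate(statistic, pattern.marks)[0])
    rng = rng_for(config.rng_seed, f"random_labelling:{statistic}")
    ensemble = build_null_ensemble(
        pattern,
        statistic,
        grid=config.grid,
        n_sim=config.n_sim,
        rng_seed=rng,
        geometry=geom,
    )
    ensemble.rng_seed = config.rng_seed
    envelope = pointwise_envelopes(ensemble, config.k)
    gof = gof_test(observed, ensemble, config.r_min, config.r_max)
    return MarkAnalysisResult(
        observed=observed, ensemble=ensemble, envelope=envelope, gof=gof
    )
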