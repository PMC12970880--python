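"""Seed-content standardization, per-defecation scaling and survey summaries.

Seed counts from a weighed fecal subsample are standardized to seeds per gram
of dry weight, then scaled to seeds per defecation using species mean dung
dry weights.  The module also provides the single-outlier Grubbs screen used
to drop anomalous samples, and the descriptive per-species / per-family /
microsite summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deposit_io import FecalDeposit, Species, ValidationError


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero at the given precision (reporting only)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, ROUND_HALF_UP))


@dataclass(frozen=True)
class DungWeightTable:
    """Species -> mean dung dry weight per defecation (grams)."""

    weights: Mapping[Species, float]

    def __post_init__(self) -> None:
        missing = [s for s in Species if s not in self.weights]
        if missing:
            raise ValidationError(
                f"dung weight table missing species: {[s.value for s in missing]}"
            )
        for s, w in self.weights.items():
            if not (math.isfinite(w) and w > 0):
                raise ValidationError(f"dung weight for {s.value} must be > 0")
        object.__setattr__(self, "weights", dict(self.weights))

    def __getitem__(self, species: Species) -> float:
        return self.weights[Species.parse(species)]

    def replace(self, **overrides: float) -> "DungWeightTable":
        new = dict(self.weights)
        for name, w in overrides.items():
            new[Species.parse(name)] = float(w)
        return DungWeightTable(new)


#: Published mean dung dry weights per defecation event (grams).
DEFAULT_DUNG_WEIGHTS = DungWeightTable(
    {
        Species.DEER: 49.6,
        Species.COW: 630.0,
        Species.HORSE: 300.0,
        Species.WILD_BOAR: 12.9,
    }
)


def standardize_seed_content(total_seed_count: int, sample_dw_g: float) -> float:
    """Seeds per gram dry weight of the processed subsample."""
    if total_seed_count < 0:
        raise ValidationError("seed count must be >= 0")
    if not (sample_dw_g and sample_dw_g > 0):
        raise ValidationError("sample_dw_g must be > 0")
    return total_seed_count / sample_dw_g


def per_fecal_unit(
    seeds_per_g: float,
    species: Species,
    dung: DungWeightTable = DEFAULT_DUNG_WEIGHTS,
) -> float:
    """Estimated seeds per defecation: seeds/g times species mean dung DW."""
    if seeds_per_g < 0:
        raise ValidationError("seeds_per_g must be >= 0")
    return seeds_per_g * dung[species]


@dataclass(frozen=True)
class SeedContentRecord:
    deposit_id: str
    species: Species
    seeds_per_g: float
    seeds_per_unit: float


def seed_content_records(
    deposits: Sequence[FecalDeposit],
    dung: DungWeightTable = DEFAULT_DUNG_WEIGHTS,
) -> list[SeedContentRecord]:
    """Standardized + per-unit content for deposits with a recorded weight."""
    out = []
    for d in deposits:
        if d.sample_dw_g is None:
            continue
        spg = standardize_seed_content(d.total_seed_count, d.sample_dw_g)
        out.append(
            SeedContentRecord(
                deposit_id=d.deposit_id,
                species=d.species,
                seeds_per_g=spg,
                seeds_per_unit=per_fecal_unit(spg, d.species, dung),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Grubbs single-outlier screen


@dataclass(frozen=True)
class GrubbsResult:
    g_statistic: float
    g_critical: float
    alpha: float
    n: int
    outlier_index: int | None
    is_outlier: bool


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided single-outlier Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValidationError("Grubbs test requires n >= 3")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), df=n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """One-pass two-sided Grubbs test for a single outlier.

    G = max_i |x_i - mean| / sd with the n-1 (sample) standard deviation.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("Grubbs test requires n >= 3")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValidationError("degenerate sample: zero variance")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    g_crit = grubbs_critical(n, alpha)
    outlier = g > g_crit
    return GrubbsResult(
        g_statistic=g,
        g_critical=g_crit,
        alpha=alpha,
        n=n,
        outlier_index=idx if outlier else None,
        is_outlier=outlier,
    )


# ---------------------------------------------------------------------------
# descriptive summaries


def species_totals(records: Sequence[SeedContentRecord]) -> pd.DataFrame:
    """Cumulated per-unit seeds per species and their share of the site total.

    Returns a frame with columns ``species``, ``cumulated_seeds`` and
    ``pct_of_site_total`` (half-up rounded to 1 decimal).
    """
    if not records:
        raise ValidationError("species_totals needs at least one record")
    totals: dict[Species, float] = {}
    for r in records:
        totals[r.species] = totals.get(r.species, 0.0) + r.seeds_per_unit
    grand = sum(totals.values())
    rows = [
        {
            "species": s.value,
            "cumulated_seeds": tot,
            "pct_of_site_total": round_half_up(100.0 * tot / grand, 1)
            if grand > 0
            else float("nan"),
        }
        for s, tot in totals.items()
    ]
    return pd.DataFrame(rows, columns=["species", "cumulated_seeds", "pct_of_site_total"])


@dataclass(frozen=True)
class FamilySummary:
    family: str
    relative_abundance_pct: float
    frequency_pct: float


def family_summary(deposits: Sequence[FecalDeposit]) -> list[FamilySummary]:
    """Relative abundance (share of the pooled identified seed count) and
    frequency of occurrence (share of samples where the family is present)
    per family.  Unidentified seeds are excluded from the pool; report their
    share separately via :func:`share_of_total`.
    """
    if not deposits:
        raise ValidationError("family_summary needs at least one deposit")
    pooled: dict[str, int] = {}
    presence: dict[str, int] = {}
    for d in deposits:
        fams = d.family_totals()
        for fam, count in fams.items():
            key = fam.casefold()
            pooled[key] = pooled.get(key, 0) + count
            if count > 0:
                presence[key] = presence.get(key, 0) + 1
    canon: dict[str, str] = {}
    for d in deposits:
        for fam in d.family_totals():
            canon.setdefault(fam.casefold(), fam)
    pool_total = sum(pooled.values())
    if pool_total == 0:
        raise ValidationError("no identified seeds in any deposit")
    n_dep = len(deposits)
    out = [
        FamilySummary(
            family=canon[key],
            relative_abundance_pct=100.0 * count / pool_total,
            frequency_pct=100.0 * presence.get(key, 0) / n_dep,
        )
        for key, count in pooled.items()
    ]
    out.sort(key=lambda f: (-f.relative_abundance_pct, f.family.casefold()))
    return out


def share_of_total(part: int, total: int, decimals: int = 0) -> float:
    """100 * part / total, half-up rounded to the requested precision."""
    if total <= 0:
        raise ValidationError("total must be > 0")
    if not 0 <= part <= total:
        raise ValidationError("part must satisfy 0 <= part <= total")
    return round_half_up(100.0 * part / total, decimals)


def fecal_density(n_units: int, area_ha: float) -> float:
    """Feces per hectare, to one decimal."""
    if area_ha <= 0:
        raise ValidationError("area_ha must be > 0")
    return round_half_up(n_units / area_ha, 1)


@dataclass(frozen=True)
class MicrositeSummary:
    pct_open: float
    pct_shrubby: float
    mean_cover_in_shrubby: float | None
    dominant_shrub_shares: dict[str, float] | None = None


def microsite_summary(
    deposits: Sequence[FecalDeposit],
    shrub_species_labels: Mapping[str, str] | None = None,
) -> MicrositeSummary:
    """Open vs shrubby deposition microsites; open means 0% shrub cover.

    Mean cover is taken over shrubby microsites only (``None`` when there are
    none).  ``shrub_species_labels`` maps deposit_id to the dominant shrub at
    that microsite; shares are computed over labelled shrubby deposits.
    """
    if not deposits:
        raise ValidationError("microsite_summary needs at least one deposit")
    covers = np.array([d.shrub_cover_pct for d in deposits], dtype=float)
    shrubby = covers > 0
    n = len(deposits)
    pct_open = 100.0 * (~shrubby).sum() / n
    pct_shrubby = 100.0 * shrubby.sum() / n
    mean_cover = float(covers[shrubby].mean()) if shrubby.any() else None

    shares = None
    if shrub_species_labels is not None:
        labels = [
            shrub_species_labels[d.deposit_id]
            for d, is_shrubby in zip(deposits, shrubby)
            if is_shrubby and d.deposit_id in shrub_species_labels
        ]
        if labels:
            shares = {
                lab: 100.0 * labels.count(lab) / len(labels)
                for lab in sorted(set(labels))
            }
    return MicrositeSummary(pct_open, pct_shrubby, mean_cover, shares)
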