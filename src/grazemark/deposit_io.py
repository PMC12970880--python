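"""Data model and I/O for georeferenced fecal-deposit and seed-count tables.

Two plain-text tables describe a survey:

* ``deposits.csv`` — one row per fecal unit:
  ``deposit_id,site,date,species,x_m,y_m[,lon,lat],shrub_cover_pct,sample_dw_g``
* ``seeds.csv`` — long format, one row per (deposit, taxon):
  ``deposit_id,family,genus,species_epithet,count``

The module also turns deposit collections into planar marked point patterns
(one non-negative quantitative mark per point) for the correlation analyses.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: Family label reserved for seeds that could not be identified.  Such rows
#: count toward total recovered seeds but never toward family-level summaries.
UNIDENTIFIED_FAMILY = "unidentified"


class DepositError(ValueError):
    """Base class for validation problems in deposit/seed tables."""


class SchemaError(DepositError):
    """Malformed header or an out-of-vocabulary field value."""


class ReferentialError(DepositError):
    """A seeds row references a deposit_id absent from the deposits table."""


class ValidationError(DepositError):
    """A field value violates a domain invariant (range, sign, geometry)."""


class Species(str, Enum):
    """The four ungulate dispersers recognized by the pipeline."""

    DEER = "deer"
    COW = "cow"
    HORSE = "horse"
    WILD_BOAR = "wild_boar"

    @classmethod
    def parse(cls, value: object, row: int | None = None) -> "Species":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            where = f" (row {row})" if row is not None else ""
            valid = ", ".join(s.value for s in cls)
            raise SchemaError(
                f"unknown species {value!r}{where}; expected one of: {valid}"
            ) from None


@dataclass(frozen=True, eq=False)
class TaxonKey:
    """Taxon identifier; family is the analysis level, lower ranks optional.

    Keys compare (and hash) case-insensitively after whitespace trimming.
    """

    family: str
    genus: str | None = None
    species_epithet: str | None = None

    def __post_init__(self) -> None:
        fam = (self.family or "").strip()
        if not fam:
            raise ValidationError("TaxonKey.family must be non-empty")
        object.__setattr__(self, "family", fam)
        for attr in ("genus", "species_epithet"):
            val = getattr(self, attr)
            if val is not None:
                val = str(val).strip() or None
            object.__setattr__(self, attr, val)

    @property
    def _norm(self) -> tuple[str, str, str]:
        return (
            self.family.casefold(),
            (self.genus or "").casefold(),
            (self.species_epithet or "").casefold(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonKey):
            return NotImplemented
        return self._norm == other._norm

    def __hash__(self) -> int:
        return hash(self._norm)

    @property
    def is_unidentified(self) -> bool:
        return self.family.casefold() == UNIDENTIFIED_FAMILY


@dataclass
class FecalDeposit:
    """One georeferenced fecal unit with its per-taxon seed counts.

    ``sample_dw_g`` may be ``None`` (sample weight not recorded); such
    deposits are excluded from seed-content operations but still count
    toward fecal density.
    """

    deposit_id: str
    site: str
    date: _dt.date | None
    species: Species
    x: float
    y: float
    shrub_cover_pct: float
    sample_dw_g: float | None = None
    seed_counts: dict[TaxonKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = Species.parse(self.species)
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"deposit {self.deposit_id!r}: coordinates must be finite"
            )
        if not 0.0 <= float(self.shrub_cover_pct) <= 100.0:
            raise ValidationError(
                f"deposit {self.deposit_id!r}: shrub_cover_pct "
                f"{self.shrub_cover_pct!r} outside [0, 100]"
            )
        if self.sample_dw_g is not None:
            dw = float(self.sample_dw_g)
            if not (math.isfinite(dw) and dw > 0):
                raise ValidationError(
                    f"deposit {self.deposit_id!r}: sample_dw_g must be > 0"
                )
            self.sample_dw_g = dw
        for taxon, count in self.seed_counts.items():
            if int(count) < 0:
                raise ValidationError(
                    f"deposit {self.deposit_id!r}: negative seed count for "
                    f"{taxon.family}"
                )
            self.seed_counts[taxon] = int(count)

    @property
    def total_seed_count(self) -> int:
        """All recovered seeds in the processed subsample (incl. unidentified)."""
        return sum(self.seed_counts.values())

    def family_totals(self, include_unidentified: bool = False) -> dict[str, int]:
        """Seed counts aggregated to family level (casefold-merged)."""
        out: dict[str, int] = {}
        canon: dict[str, str] = {}
        for taxon, count in self.seed_counts.items():
            if taxon.is_unidentified and not include_unidentified:
                continue
            key = taxon.family.casefold()
            name = canon.setdefault(key, taxon.family)
            out[name] = out.get(name, 0) + count
        return out

    def count_for_family(self, family: str) -> int:
        key = family.strip().casefold()
        return sum(
            c for t, c in self.seed_counts.items() if t.family.casefold() == key
        )


@dataclass(frozen=True)
class StudyWindow:
    """Axis-aligned rectangular observation window in meters."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValidationError("StudyWindow must have positive extent")

    @property
    def area_m2(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 10_000.0

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (
            (pts[:, 0] >= self.x_min - atol)
            & (pts[:, 0] <= self.x_max + atol)
            & (pts[:, 1] >= self.y_min - atol)
            & (pts[:, 1] <= self.y_max + atol)
        )

    @classmethod
    def from_points(cls, points: np.ndarray) -> "StudyWindow":
        pts = np.asarray(points, dtype=float)
        x_min, y_min = pts.min(axis=0)
        x_max, y_max = pts.max(axis=0)
        # degenerate bbox (collinear points) gets a hair of padding
        eps = 1e-9
        if x_max - x_min <= 0:
            x_min, x_max = x_min - eps, x_max + eps
        if y_max - y_min <= 0:
            y_min, y_max = y_min - eps, y_max + eps
        return cls(x_min, x_max, y_min, y_max)


@dataclass
class MarkedPointPattern:
    """Planar points in a rectangular window, one non-negative mark each."""

    window: StudyWindow
    points: np.ndarray
    marks: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.marks = np.asarray(self.marks, dtype=float).ravel()
        if self.points.shape[1] != 2:
            raise ValidationError("points must be an (n, 2) array")
        if len(self.points) != len(self.marks):
            raise ValidationError("points and marks must have equal length")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point coordinates must be finite")
        if not np.all(np.isfinite(self.marks)) or np.any(self.marks < 0):
            raise ValidationError("marks must be finite and >= 0")
        if not bool(self.window.contains(self.points).all()):
            raise ValidationError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def intensity(self) -> float:
        """Points per square meter (lambda)."""
        return self.n / self.window.area_m2

    def with_marks(self, marks: np.ndarray) -> "MarkedPointPattern":
        return MarkedPointPattern(self.window, self.points, marks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1], "mark": self.marks}
        )


# ---------------------------------------------------------------------------
# readers / writers

_DEPOSIT_COLUMNS = [
    "deposit_id", "site", "date", "species", "shrub_cover_pct", "sample_dw_g",
]
_SEED_COLUMNS = ["deposit_id", "family", "genus", "species_epithet", "count"]


def _opt(value: object) -> object | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def read_deposits(
    deposits_path: str | Path, seeds_path: str | Path
) -> list[FecalDeposit]:
    """Read the two-table survey format into :class:`FecalDeposit` records.

    Row order of the deposits file is preserved; taxa missing from the seeds
    file simply contribute count 0.  Raises :class:`SchemaError`,
    :class:`ReferentialError` or :class:`ValidationError` on bad input,
    naming the offending row where possible.
    """
    dep = pd.read_csv(deposits_path, dtype={"deposit_id": str})
    missing = [c for c in _DEPOSIT_COLUMNS if c not in dep.columns]
    if missing:
        raise SchemaError(f"deposits file missing columns: {missing}")
    has_xy = {"x_m", "y_m"}.issubset(dep.columns)
    has_ll = {"lon", "lat"}.issubset(dep.columns)
    if not has_xy and not has_ll:
        raise SchemaError("deposits file needs x_m,y_m or lon,lat columns")

    if has_xy and dep[["x_m", "y_m"]].notna().all().all():
        xy = dep[["x_m", "y_m"]].to_numpy(dtype=float)
    elif has_ll:
        lonlat = dep[["lon", "lat"]].to_numpy(dtype=float)
        ref = (float(np.mean(lonlat[:, 0])), float(np.mean(lonlat[:, 1])))
        xy = project_lonlat(lonlat, ref)
    else:
        raise ValidationError("deposits file has missing x_m/y_m values")

    seeds = pd.read_csv(seeds_path, dtype={"deposit_id": str})
    if len(seeds) and not set(_SEED_COLUMNS).issubset(seeds.columns):
        raise SchemaError(
            f"seeds file missing columns: "
            f"{[c for c in _SEED_COLUMNS if c not in seeds.columns]}"
        )

    known_ids = set(dep["deposit_id"])
    counts: dict[str, dict[TaxonKey, int]] = {}
    for i, row in seeds.iterrows():
        did = row["deposit_id"]
        if did not in known_ids:
            raise ReferentialError(
                f"seeds row {i + 2}: deposit_id {did!r} not in deposits file"
            )
        count = int(row["count"])
        if count < 0:
            raise ValidationError(f"seeds row {i + 2}: negative count {count}")
        taxon = TaxonKey(
            family=str(row["family"]),
            genus=_opt(row.get("genus")),
            species_epithet=_opt(row.get("species_epithet")),
        )
        bucket = counts.setdefault(did, {})
        bucket[taxon] = bucket.get(taxon, 0) + count

    deposits: list[FecalDeposit] = []
    for i, row in dep.iterrows():
        species = Species.parse(row["species"], row=i + 2)
        raw_date = _opt(row["date"])
        date = _dt.date.fromisoformat(str(raw_date)) if raw_date else None
        dw = _opt(row["sample_dw_g"])
        deposits.append(
            FecalDeposit(
                deposit_id=row["deposit_id"],
                site=str(row["site"]),
                date=date,
                species=species,
                x=float(xy[i, 0]),
                y=float(xy[i, 1]),
                shrub_cover_pct=float(row["shrub_cover_pct"]),
                sample_dw_g=None if dw is None else float(dw),
                seed_counts=counts.get(row["deposit_id"], {}),
            )
        )
    return deposits


def write_deposits(
    deposits: Sequence[FecalDeposit],
    deposits_path: str | Path,
    seeds_path: str | Path,
) -> None:
    """Write records back to the two-table CSV format (round-trip safe)."""
    dep_rows = []
    seed_rows = []
    for d in deposits:
        dep_rows.append(
            {
                "deposit_id": d.deposit_id,
                "site": d.site,
                "date": d.date.isoformat() if d.date else "",
                "species": d.species.value,
                "x_m": d.x,
                "y_m": d.y,
                "shrub_cover_pct": d.shrub_cover_pct,
                "sample_dw_g": "" if d.sample_dw_g is None else d.sample_dw_g,
            }
        )
        for taxon, count in d.seed_counts.items():
            seed_rows.append(
                {
                    "deposit_id": d.deposit_id,
                    "family": taxon.family,
                    "genus": taxon.genus or "",
                    "species_epithet": taxon.species_epithet or "",
                    "count": count,
                }
            )
    pd.DataFrame(dep_rows, columns=[
        "deposit_id", "site", "date", "species", "x_m", "y_m",
        "shrub_cover_pct", "sample_dw_g",
    ]).to_csv(deposits_path, index=False)
    pd.DataFrame(seed_rows, columns=_SEED_COLUMNS).to_csv(seeds_path, index=False)


def project_lonlat(
    lonlat_points: Sequence[tuple[float, float]] | np.ndarray,
    reference: tuple[float, float],
) -> np.ndarray:
    """Local equirectangular projection about ``reference`` (lon, lat), meters.

    x = R cos(lat_ref) dlon, y = R dlat on a sphere of radius 6,371,000 m.
    Only valid for small extents; spans >= 1 degree are rejected.
    """
    pts = np.atleast_2d(np.asarray(lonlat_points, dtype=float))
    lon_ref, lat_ref = float(reference[0]), float(reference[1])
    if abs(lat_ref) >= 89 or np.any(np.abs(pts[:, 1]) >= 89):
        raise DepositError("latitudes must satisfy |lat| < 89 degrees")
    span = max(
        np.ptp(np.append(pts[:, 0], lon_ref)),
        np.ptp(np.append(pts[:, 1], lat_ref)),
    )
    if span >= 1.0:
        raise DepositError(
            "coordinate span >= 1 degree: the local tangent-plane projection "
            "is inadequate; re-project input with a proper projected CRS"
        )
    dlon = np.radians(pts[:, 0] - lon_ref)
    dlat = np.radians(pts[:, 1] - lat_ref)
    x = EARTH_RADIUS_M * math.cos(math.radians(lat_ref)) * dlon
    y = EARTH_RADIUS_M * dlat
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# marked-pattern construction

#: Recognized mark sources.  ``*_per_unit`` scale standardized content by the
#: species' mean dung dry weight per defecation; ``*_per_g`` stay per gram.
MARK_SOURCES = (
    "total_seeds_per_unit",
    "family_seeds_per_unit",
    "total_seeds_per_g",
    "family_seeds_per_g",
)


def _parse_mark_source(mark_source: str) -> tuple[str, str | None]:
    base, _, family = mark_source.partition(":")
    base = base.strip()
    if base not in MARK_SOURCES:
        raise DepositError(f"unknown mark_source {mark_source!r}")
    if base.startswith("family") and not family.strip():
        raise DepositError(f"mark_source {base!r} requires ':<family>'")
    return base, (family.strip() or None)


def to_marked_pattern(
    deposits: Sequence[FecalDeposit],
    mark_source: str = "total_seeds_per_unit",
    window: StudyWindow | str = "auto",
    dung: "object | None" = None,
) -> tuple[MarkedPointPattern, int]:
    """Build a marked pattern whose marks are per-deposit seed estimates.

    ``mark_source`` is ``"total_seeds_per_unit"``,
    ``"family_seeds_per_unit:<Family>"`` or the per-gram variants.  Deposits
    lacking ``sample_dw_g`` are dropped (their number is returned alongside
    the pattern).  ``window="auto"`` uses the bounding box of the retained
    points.
    """
    from . import seedload  # local import to avoid a module cycle

    base, family = _parse_mark_source(mark_source)
    dung_table = dung if dung is not None else seedload.DEFAULT_DUNG_WEIGHTS

    usable = [d for d in deposits if d.sample_dw_g is not None]
    n_excluded = len(deposits) - len(usable)
    if n_excluded:
        logger.warning(
            "to_marked_pattern: excluded %d deposit(s) without sample_dw_g",
            n_excluded,
        )
    if len(usable) < 2:
        raise DepositError(
            f"need at least 2 deposits with sample dry weight, got {len(usable)}"
        )

    marks = np.empty(len(usable))
    for i, d in enumerate(usable):
        count = d.total_seed_count if family is None else d.count_for_family(family)
        spg = seedload.standardize_seed_content(count, d.sample_dw_g)
        if base.endswith("per_unit"):
            marks[i] = seedload.per_fecal_unit(spg, d.species, dung_table)
        else:
            marks[i] = spg

    points = np.array([[d.x, d.y] for d in usable])
    if isinstance(window, str):
        if window != "auto":
            raise DepositError(f"unknown window spec {window!r}")
        window = StudyWindow.from_points(points)
    elif not bool(window.contains(points).all()):
        raise ValidationError("a deposit lies outside the explicit window")

    return MarkedPointPattern(window, points, marks), n_excluded


def pattern_to_csv(pattern: MarkedPointPattern, path: str | Path) -> None:
    pattern.to_frame().to_csv(path, index=False)


def pattern_to_geojson(pattern: MarkedPointPattern, path: str | Path) -> None:
    import json

    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"mark": float(m)},
        }
        for (x, y), m in zip(pattern.points, pattern.marks)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
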