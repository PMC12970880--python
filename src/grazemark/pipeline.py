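"""Configuration-driven end-to-end runner.

One run = load (or simulate) a site, screen per-sample seed totals with a
one-pass Grubbs test, write the descriptive summaries, then run the three
mark-correlation analyses with random-labelling envelopes and GoF tests on
the total-seed marks and on the top-k most frequent seed families.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .deposit_io import (
    DepositError,
    FecalDeposit,
    StudyWindow,
    read_deposits,
    to_marked_pattern,
)
from .markcorr import DENSITY_CORR, R_MARK, SCHLATHER, DistanceGrid, MarkStatisticError
from .mc_inference import AnalysisConfig, MarkAnalysisResult, run_mark_analysis
from .seedload import (
    DEFAULT_DUNG_WEIGHTS,
    DungWeightTable,
    ValidationError,
    family_summary,
    fecal_density,
    grubbs_test,
    microsite_summary,
    seed_content_records,
    species_totals,
)
from .synthgrass import sim_site

logger = logging.getLogger(__name__)

STATISTIC_ALIASES = {
    "rmark": R_MARK,
    "r_mark": R_MARK,
    "schlather": SCHLATHER,
    "density": DENSITY_CORR,
    "density_corr": DENSITY_CORR,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run exactly."""

    out_dir: Path
    deposits_path: Path | None = None
    seeds_path: Path | None = None
    template: str | None = None           # simulate instead of loading
    dung_weights: DungWeightTable = field(default=DEFAULT_DUNG_WEIGHTS)
    r_max: float = 50.0
    bin_width: float = 1.0
    h: float = 0.5
    n_sim: int = 199
    envelope_k: int = 5
    alpha_grubbs: float = 0.05
    n_families: int = 3
    rng_seed: int = 0
    mark_basis: str = "per_unit"          # or "per_g"
    window: StudyWindow | None = None     # None -> bounding box of points

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.n_sim < 2 * self.envelope_k:
            raise ValidationError("n_sim must be >= 2 * envelope_k")
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        if self.mark_basis not in ("per_unit", "per_g"):
            raise ValidationError(f"unknown mark_basis {self.mark_basis!r}")
        if self.template is None and (
            self.deposits_path is None or self.seeds_path is None
        ):
            raise ValidationError(
                "config needs either a template or deposits/seeds paths"
            )

    @property
    def grid(self) -> DistanceGrid:
        return DistanceGrid.default(self.r_max, self.bin_width, self.h)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        kwargs: dict = {}
        for key in (
            "out_dir", "deposits_path", "seeds_path", "template", "r_max",
            "bin_width", "h", "n_sim", "envelope_k", "alpha_grubbs",
            "n_families", "rng_seed", "mark_basis",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "dung_weights" in raw:
            kwargs["dung_weights"] = DEFAULT_DUNG_WEIGHTS.replace(
                **raw["dung_weights"]
            )
        if "window" in raw:
            w = raw["window"]
            kwargs["window"] = StudyWindow(
                w["x_min"], w["x_max"], w["y_min"], w["y_max"]
            )
        if "out_dir" not in kwargs:
            raise ValidationError("config must set out_dir")
        for key in ("deposits_path", "seeds_path"):
            if key in kwargs:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)

    def to_manifest(self) -> dict:
        return {
            "grazemark_version": __version__,
            "out_dir": str(self.out_dir),
            "deposits_path": str(self.deposits_path) if self.deposits_path else None,
            "seeds_path": str(self.seeds_path) if self.seeds_path else None,
            "template": self.template,
            "dung_weights": {
                s.value: w for s, w in self.dung_weights.weights.items()
            },
            "r_max": self.r_max,
            "bin_width": self.bin_width,
            "h": self.h,
            "n_sim": self.n_sim,
            "envelope_k": self.envelope_k,
            "alpha_grubbs": self.alpha_grubbs,
            "n_families": self.n_families,
            "rng_seed": self.rng_seed,
            "mark_basis": self.mark_basis,
            "window": None
            if self.window is None
            else [self.window.x_min, self.window.x_max,
                  self.window.y_min, self.window.y_max],
        }


def select_families(deposits: Sequence[FecalDeposit], k: int) -> list[str]:
    """The k families with highest frequency of occurrence.

    Ties break by higher pooled abundance, then lexicographically.  Returns
    every family (with a warning) when fewer than k exist.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    summaries = family_summary(deposits)
    ranked = sorted(
        summaries,
        key=lambda f: (
            -f.frequency_pct,
            -f.relative_abundance_pct,
            f.family.casefold(),
        ),
    )
    if len(ranked) < k:
        logger.warning(
            "select_families: only %d families available (k=%d)", len(ranked), k
        )
    return [f.family for f in ranked[:k]]


@dataclass
class RunResult:
    config: RunConfig
    deposits: list[FecalDeposit]
    flagged_ids: list[str]
    analyses: dict[str, MarkAnalysisResult | None]
    selected_families: list[str]
    out_dir: Path


def _mark_source(basis: str, family: str | None) -> str:
    suffix = "per_unit" if basis == "per_unit" else "per_g"
    if family is None:
        return f"total_seeds_{suffix}"
    return f"family_seeds_{suffix}:{family}"


def run_full(config: RunConfig) -> RunResult:
    """Execute the whole analysis and write every artifact under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: load or simulate ------------------------------------------
    if config.template is not None:
        dep_path, seed_path = sim_site(
            config.template, config.rng_seed, out / "data"
        )
    else:
        dep_path, seed_path = config.deposits_path, config.seeds_path
    deposits = read_deposits(dep_path, seed_path)
    logger.info("load: %d deposits from %s", len(deposits), dep_path)
    if not deposits:
        raise DepositError("no deposits to analyze")

    sites = sorted({d.site for d in deposits})

    # --- stage: Grubbs screen on per-sample total seed counts -------------
    flagged_ids: list[str] = []
    grubbs_reports = {}
    for site in sites:
        site_dep = [d for d in deposits if d.site == site]
        counts = [d.total_seed_count for d in site_dep]
        if len(counts) < 3 or float(np.std(counts, ddof=1)) == 0:
            grubbs_reports[site] = {"skipped": "fewer than 3 samples or no variance"}
            continue
        res = grubbs_test(counts, config.alpha_grubbs)
        report = {
            "g_statistic": res.g_statistic,
            "g_critical": res.g_critical,
            "alpha": res.alpha,
            "n": res.n,
            "is_outlier": res.is_outlier,
            "outlier_id": None,
        }
        if res.is_outlier:
            outlier = site_dep[res.outlier_index]
            flagged_ids.append(outlier.deposit_id)
            report["outlier_id"] = outlier.deposit_id
            logger.info(
                "grubbs: flagged %s at %s (G=%.2f > %.2f)",
                outlier.deposit_id, site, res.g_statistic, res.g_critical,
            )
        grubbs_reports[site] = report
    (out / "grubbs.json").write_text(json.dumps(grubbs_reports, indent=2))

    # Flagged samples leave seed-content analyses; density keeps everything.
    retained = [d for d in deposits if d.deposit_id not in flagged_ids]
    logger.info(
        "screen: %d deposits retained, %d flagged", len(retained), len(flagged_ids)
    )

    # --- stage: descriptive summaries -------------------------------------
    records = seed_content_records(retained, config.dung_weights)
    species_totals(records).to_csv(out / "species_totals.csv", index=False)

    fam = family_summary(retained)
    pd.DataFrame(
        [
            {
                "family": f.family,
                "relative_abundance_pct": f.relative_abundance_pct,
                "frequency_pct": f.frequency_pct,
            }
            for f in fam
        ]
    ).to_csv(out / "family_summary.csv", index=False)

    micro = microsite_summary(retained)
    pd.DataFrame(
        [
            {
                "pct_open": micro.pct_open,
                "pct_shrubby": micro.pct_shrubby,
                "mean_cover_in_shrubby": micro.mean_cover_in_shrubby,
            }
        ]
    ).to_csv(out / "microsites.csv", index=False)

    density = {}
    for site in sites:
        site_all = [d for d in deposits if d.site == site]  # incl. flagged
        if config.window is not None:
            area = config.window.area_ha
        else:
            pts = np.array([[d.x, d.y] for d in site_all])
            area = StudyWindow.from_points(pts).area_ha
        density[site] = {
            "n_units": len(site_all),
            "area_ha": area,
            "feces_per_ha": fecal_density(len(site_all), area),
        }
    (out / "fecal_density.json").write_text(json.dumps(density, indent=2))

    # --- stage: mark-correlation analyses ---------------------------------
    selected = select_families(retained, config.n_families)
    logger.info("families selected for spatial analysis: %s", selected)

    analyses: dict[str, MarkAnalysisResult | None] = {}
    targets: list[tuple[str, str | None]] = [("total", None)]
    targets += [(f"family_{f}", f) for f in selected]
    ana_cfg = AnalysisConfig(
        grid=config.grid,
        n_sim=config.n_sim,
        k=config.envelope_k,
        rng_seed=config.rng_seed,
        r_min=0.0,
        r_max=config.r_max,
    )
    for label, family in targets:
        mark_source = _mark_source(config.mark_basis, family)
        window = config.window if config.window is not None else "auto"
        pattern, n_excluded = to_marked_pattern(
            retained, mark_source, window, config.dung_weights
        )
        for statistic in (R_MARK, SCHLATHER, DENSITY_CORR):
            key = f"{label}__{statistic}"
            try:
                result = run_mark_analysis(pattern, statistic, ana_cfg)
            except MarkStatisticError as exc:
                logger.warning("analysis %s skipped: %s", key, exc)
                analyses[key] = None
                (out / f"{key}.json").write_text(
                    json.dumps({"statistic": statistic, "mark": label,
                                "skipped": str(exc)}, indent=2)
                )
                continue
            analyses[key] = result
            report = result.to_report()
            report["mark"] = label
            report["n_points"] = pattern.n
            report["n_excluded_no_dw"] = n_excluded
            (out / f"{key}.json").write_text(json.dumps(report, indent=2))
            result.to_frame().to_csv(out / f"{key}.csv", index=False)
            logger.info(
                "analysis %s: p=%.3f (n=%d)", key, result.gof.p_value, pattern.n
            )

    # --- stage: manifest ---------------------------------------------------
    manifest = config.to_manifest()
    manifest["flagged_ids"] = flagged_ids
    manifest["selected_families"] = selected
    manifest["n_deposits"] = len(deposits)
    blob = json.dumps(manifest, sort_keys=True).encode()
    manifest["config_hash"] = hashlib.sha256(blob).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunResult(
        config=config,
        deposits=deposits,
        flagged_ids=flagged_ids,
        analyses=analyses,
        selected_families=selected,
        out_dir=out,
    )
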