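"""End-to-end driver: simulate -> screen -> cv -> fit -> predict -> bootstrap -> report.

A single global seed is expanded into per-stage seeds by a documented rule
(``stage_seed(seed, index)`` hashes the pair through ``numpy``'s
``SeedSequence``), so each stage is independently reproducible.  Every JSON
output carries provenance metadata: the configuration hash, the global seed,
and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import carbon_accounting as ca
from . import fusion_model as fm
from . import io_utils as io
from . import model_selection as ms
from . import screening as sc
from . import synthetic_landscape as sl
from . import uncertainty as un

log = logging.getLogger("gsvfuse")

STAGES = ("simulate", "screen", "cv", "fit", "predict", "bootstrap", "report")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence((int(global_seed), idx))
    return int(ss.generate_state(1)[0] % (2**31))


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings (usually loaded from YAML)."""

    seed: int = 0
    out_dir: str = "gsvfuse_out"
    simulate: dict | None = None  # LandscapeConfig overrides; None -> load landscape_dir
    landscape_dir: str | None = None
    plots_path: str | None = None  # None with simulate -> sample synthetic plots
    n_plots: int = 2000
    sampling_design: str = "uniform"
    screening: dict = field(default_factory=dict)  # ScreeningRules overrides
    cv: dict = field(default_factory=lambda: {"k": 20})
    model: dict = field(default_factory=dict)  # ModelSpec overrides
    bootstrap: dict = field(default_factory=lambda: {"B": 1000})
    baseline_path: str | None = None
    years: float = 26.0
    factors: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = io.read_yaml(path)
        return cls(**raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(cfg: PipelineConfig, stage: str) -> dict:
    return {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage": stage,
        "gsvfuse_version": __version__,
    }


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run all stages in order; any failure halts naming the stage and cause.

    Returns the in-memory bundle (landscape, tables, fit, estimates, report);
    artifacts are archived under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}

    def run(stage, fn):
        try:
            log.info("stage %s starting", stage)
            fn()
        except Exception as exc:  # halt with context, keep the original chain
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # -- simulate (or load) ------------------------------------------------
    def _simulate():
        if cfg.simulate is not None:
            lcfg = sl.LandscapeConfig(seed=stage_seed(cfg.seed, "simulate"), **cfg.simulate)
            landscape = sl.generate_landscape(lcfg)
            bundle["landscape_config"] = lcfg
            if cfg.plots_path is None:
                plots = sl.sample_plots(
                    landscape,
                    cfg.n_plots,
                    lcfg,
                    seed=stage_seed(cfg.seed, "simulate") + 1,
                    design=cfg.sampling_design,
                )
            else:
                plots = io.read_plots(cfg.plots_path)
            io.write_landscape(landscape, out / "landscape")
            io.write_plots(plots, out / "plots.csv")
        else:
            if cfg.landscape_dir is None:
                raise ValueError("need either simulate settings or landscape_dir")
            landscape = io.read_landscape(cfg.landscape_dir)
            if cfg.plots_path is None:
                raise ValueError("plots_path required when loading an existing landscape")
            plots = io.read_plots(cfg.plots_path)
        bundle["landscape"] = landscape
        bundle["plots"] = plots
        log.info("landscape %sx%s, %d plots", *landscape.shape, len(plots))

    run("simulate", _simulate)

    # -- screen -------------------------------------------------------------
    def _screen():
        landscape, plots = bundle["landscape"], bundle["plots"]
        records = sc.match_plots_to_pixels(plots, landscape)
        rules = sc.ScreeningRules(**cfg.screening)
        kept, report = sc.screen(records, rules, map_epoch=landscape.map_epoch)
        bundle["records"] = kept
        bundle["screen_report"] = report
        sc.annotate_screening(records, report).to_csv(out / "screened.csv", index=False)
        io.write_json(
            {"provenance": _provenance(cfg, "screen"), **report.to_dict()},
            out / "screen_report.json",
        )
        log.info("screening kept %d / %d plots", report.n_kept, report.n_input)

    run("screen", _screen)

    # -- cross-validation ---------------------------------------------------
    def _cv():
        landscape = bundle["landscape"]
        cvres = ms.cross_validate(
            bundle["records"],
            candidates=None,
            k=cfg.cv.get("k", 20),
            seed=stage_seed(cfg.seed, "cv"),
            zones=landscape.zones,
            pfts=landscape.pfts,
        )
        bundle["cv"] = cvres
        cvres.per_fold.to_csv(out / "cv_folds.csv", index=False)
        io.write_json(
            {
                "provenance": _provenance(cfg, "cv"),
                "selected": cvres.selected,
                "summary": cvres.summary.to_dict(orient="records"),
            },
            out / "cv_summary.json",
        )
        log.info("cross-validation selected %s", cvres.selected)

    run("cv", _cv)

    # -- fit ------------------------------------------------------------------
    def _fit():
        landscape = bundle["landscape"]
        spec = fm.ModelSpec(**cfg.model)
        weights = None
        if spec.weighted:
            mask = landscape.forest_mask.astype(bool)
            weights = fm.compute_weights(bundle["records"], landscape.map_gb[mask]).weights
        res = fm.fit(
            bundle["records"], weights=weights,
            zones=landscape.zones, pfts=landscape.pfts, spec=spec,
        )
        bundle["fit"] = res
        try:
            res.coefficient_set().to_json(out / "coefficients.json")
        except ValueError:
            pass  # reduced model forms have no zone/PFT coefficient structure
        io.write_json(
            {
                "provenance": _provenance(cfg, "fit"),
                "r_squared": res.r_squared,
                "het_spearman": res.het_spearman,
                "het_pvalue": res.het_pvalue,
                "weighted_residual_sum": res.weighted_residual_sum,
                "params": dict(zip(res.column_names, res.params.tolist())),
            },
            out / "fit_report.json",
        )
        log.info("fit R^2=%.4f", res.r_squared)

    run("fit", _fit)

    # -- predict -----------------------------------------------------------
    def _predict():
        landscape = bundle["landscape"]
        pred = fm.predict(bundle["fit"], landscape)
        bundle["prediction"] = pred
        io.write_raster(out / "prediction.tif", pred.raster, nodata=io.RASTER_NODATA)
        io.write_json(
            {
                "provenance": _provenance(cfg, "predict"),
                "negative_fraction": pred.negative_fraction,
                "n_fallback_pixels": pred.n_fallback,
            },
            out / "prediction_meta.json",
        )
        log.info("negative-prediction fraction %.3f%%", 100 * pred.negative_fraction)

    run("predict", _predict)

    # -- bootstrap -----------------------------------------------------------
    def _bootstrap():
        landscape = bundle["landscape"]
        boot = un.BootstrapConfig(
            seed=stage_seed(cfg.seed, "bootstrap"), **cfg.bootstrap
        )
        estimates = un.bootstrap_regions(
            bundle["records"], landscape, spec=fm.ModelSpec(**cfg.model), boot=boot
        )
        bundle["estimates"] = estimates
        un.estimates_to_frame(estimates).to_csv(out / "region_estimates.csv", index=False)
        summary = un.summarize_errors(estimates)
        bundle["error_summary"] = summary
        io.write_json(
            {
                "provenance": _provenance(cfg, "bootstrap"),
                "B": boot.B,
                # "error" below means the relative standard error in percent
                "error_definition": "relative SE (%) of region mean density",
                **summary,
            },
            out / "error_summary.json",
        )

    run("bootstrap", _bootstrap)

    # -- report -------------------------------------------------------------
    def _report():
        landscape = bundle["landscape"]
        factors = ca.ConversionFactors(**cfg.factors)
        factors.validate()
        agg = ca.aggregate(
            bundle["prediction"].raster,
            landscape.region,
            landscape.forest_mask,
            landscape.pixel_area,
        )
        bundle["aggregate"] = agg
        report: dict[str, Any] = {
            "provenance": _provenance(cfg, "report"),
            "national_total_gsv_m3": agg.national_total,
            "national_forest_area_ha": agg.national_area,
            "national_density_m3_ha": agg.national_density,
            "pools": {
                pool: ca.convert(agg.national_total, factors, pool) for pool in ca.POOLS
            },
        }
        if cfg.baseline_path is not None:
            base = ca.BaselineTable(pd.read_csv(cfg.baseline_path))
            change = ca.change_rate(
                agg.national_total, base.total_gsv, cfg.years, base.total_area, factors
            )
            report["baseline_total_gsv_m3"] = base.total_gsv
            report["change"] = change.report()
            report["exceedance_vs_baseline_pct"] = round(
                ca.percent_exceedance(agg.national_total, base.total_gsv)
            )
            if "managed_area" in base.table.columns:
                dens = agg.per_region.rename(columns={"density": "density"})
                managed = ca.managed_subset(
                    dens[["region", "density", "forest_area"]],
                    base.table[["region", "managed_area"]],
                )
                report["managed_total_gsv_m3"] = managed.total_gsv
            bundle["change"] = change
        bundle["report"] = report
        io.write_json(report, out / "report.json")
        with open(out / "report.txt", "w") as fh:
            fh.write(format_report(report))

    run("report", _report)
    return bundle


def format_report(report: dict) -> str:
    lines = [
        "National growing stock report",
        "=============================",
        f"Total GSV:        {report['national_total_gsv_m3']:.3e} m3",
        f"Forest area:      {report['national_forest_area_ha']:.3e} ha",
        f"Mean density:     {report['national_density_m3_ha']:.1f} m3/ha",
        "Carbon/biomass pools (from total GSV):",
    ]
    for pool, val in report["pools"].items():
        unit = "t C" if pool.endswith("_c") else "t"
        lines.append(f"  {pool:8s} {val:.3e} {unit}")
    if "change" in report:
        ch = report["change"]
        lines += [
            f"Change vs baseline: {report['exceedance_vs_baseline_pct']}%",
            f"Annual GSV rate:  {ch['annual_gsv_rate_1e6_m3_yr']} x 1e6 m3/yr",
            f"Carbon rate:      {ch['carbon_rate_tg_c_yr']} Tg C/yr",
            f"Per-ha rates:     {ch['per_ha_rate_m3_ha_yr']} m3/ha/yr, "
            f"{ch['per_ha_carbon_rate_t_c_ha_yr']} t C/ha/yr",
        ]
    return "\n".join(lines) + "\n"
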