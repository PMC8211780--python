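"""Growing stock to biomass/carbon conversion and change accounting.

Predicted GSV rasters are aggregated to per-region and national totals, then
converted to biomass and carbon pools with country-level conversion factors
(derived from species, age, stocking and productivity distributions):

* GSV -> total live biomass carbon of trees: 0.35035 t C per m3
* GSV -> above-ground biomass (AGB) carbon:  0.27923 t C per m3
* GSV -> AGB:                                0.56131 t per m3
* root-to-shoot ratio (BGB = AGB x R:S):     0.288
* carbon content: ~50% of woody biomass, 45% of foliage

Change against a historical baseline yields annual accumulation rates in
volume and carbon, nationally and per hectare, and for the managed-forest
subset used in greenhouse-gas reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

T_PER_TG = 1e6  # teragram = 10^6 tonnes, exact


@dataclass(frozen=True)
class ConversionFactors:
    """Country-level GSV-to-biomass/carbon factors (units per m3 of GSV)."""

    gsv_to_live_c: float = 0.35035  # t C / m3, total live biomass carbon
    gsv_to_agb_c: float = 0.27923  # t C / m3, above-ground carbon
    gsv_to_agb: float = 0.56131  # t / m3, above-ground dry biomass
    root_to_shoot: float = 0.288  # dimensionless
    wood_c_content: float = 0.50
    foliage_c_content: float = 0.45
    houghton_gsv_to_agb: float = 0.6859  # t / m3, literature comparison only

    def validate(self) -> None:
        """Sanity checks that flag mistyped factor tables."""
        for name in (
            "gsv_to_live_c",
            "gsv_to_agb_c",
            "gsv_to_agb",
            "root_to_shoot",
            "wood_c_content",
            "foliage_c_content",
            "houghton_gsv_to_agb",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gsv_to_agb_c >= self.gsv_to_agb:
            raise ValueError("AGB carbon factor must be below the AGB biomass factor")
        implied_c = self.gsv_to_agb_c / self.gsv_to_agb
        if abs(implied_c - self.wood_c_content) > 0.01:
            raise ValueError(
                f"AGB carbon/biomass factor ratio {implied_c:.4f} inconsistent with "
                f"wood carbon content {self.wood_c_content}"
            )

POOLS = ("live_c", "agb_c", "agb", "bgb")


def convert(gsv: float | np.ndarray, factors: ConversionFactors, pool: str):
    """Convert GSV (m3 or m3/ha) to a biomass/carbon pool (t, t C; per-ha alike).

    Pools: ``live_c`` (total live carbon), ``agb_c`` (above-ground carbon),
    ``agb`` (above-ground dry biomass), ``bgb`` (below-ground biomass,
    AGB x root-to-shoot).  Linear, so totals and densities convert alike.
    """
    g = np.asarray(gsv, dtype=float)
    if np.any(g < 0):
        raise ValueError("GSV must be nonnegative")
    if pool == "live_c":
        out = g * factors.gsv_to_live_c
    elif pool == "agb_c":
        out = g * factors.gsv_to_agb_c
    elif pool == "agb":
        out = g * factors.gsv_to_agb
    elif pool == "bgb":
        out = g * factors.gsv_to_agb * factors.root_to_shoot
    else:
        raise ValueError(f"unknown pool {pool!r}; known pools: {POOLS}")
    return float(out) if np.isscalar(gsv) else out


def tonnes_to_tg(t: float) -> float:
    return t / T_PER_TG


@dataclass
class AggregateResult:
    """Zonal totals from a prediction raster."""

    per_region: pd.DataFrame  # region, total_gsv (m3), forest_area (ha), density (m3/ha)
    national_total: float  # m3
    national_area: float  # ha
    national_density: float  # m3/ha


def aggregate(
    prediction: np.ndarray,
    region: np.ndarray,
    forest_mask: np.ndarray,
    pixel_area: float,
) -> AggregateResult:
    """Per-region and national GSV totals and mean densities.

    Masked-out pixels contribute nothing; the national total is the sum of
    the regional totals in the same summation order, so the books balance
    exactly.  Regions with zero forest pixels get NaN density and a flag.
    """
    shapes = {np.shape(prediction), np.shape(region), np.shape(forest_mask)}
    if len(shapes) != 1:
        raise ValueError(f"raster dimension mismatch: {sorted(shapes)}")
    mask = np.asarray(forest_mask, dtype=bool)
    pred = np.asarray(prediction, dtype=float)
    reg = np.asarray(region)

    rows = []
    for r in np.unique(reg):
        sel = (reg == r) & mask
        n_px = int(sel.sum())
        total = float(np.nansum(pred[sel]) * pixel_area)
        area = n_px * pixel_area
        rows.append(
            {
                "region": int(r),
                "total_gsv": total,
                "forest_area": area,
                "density": total / area if area > 0 else np.nan,
                "no_forest": n_px == 0,
            }
        )
    per_region = pd.DataFrame(rows)
    national_total = float(per_region["total_gsv"].sum())
    national_area = float(per_region["forest_area"].sum())
    return AggregateResult(
        per_region=per_region,
        national_total=national_total,
        national_area=national_area,
        national_density=national_total / national_area if national_area > 0 else np.nan,
    )


@dataclass
class BaselineTable:
    """Historical reference stocks: per-region (or single national row)."""

    table: pd.DataFrame  # region, gsv_1988 (m3), area_1988 (ha), managed_area (ha)

    def __post_init__(self) -> None:
        req = {"region", "gsv_1988", "area_1988"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"baseline table missing columns: {sorted(missing)}")
        bad = (self.table["gsv_1988"] > 0) & (self.table["area_1988"] <= 0)
        if bad.any():
            raise ValueError("baseline rows with positive GSV need positive area")

    @property
    def total_gsv(self) -> float:
        return float(self.table["gsv_1988"].sum())

    @property
    def total_area(self) -> float:
        return float(self.table["area_1988"].sum())


@dataclass
class ChangeEstimate:
    """Stock change between the baseline year and the estimate year."""

    delta_gsv: float  # m3
    years: float
    annual_gsv_rate: float  # m3 / yr
    per_ha_rate: float  # m3 / ha / yr
    carbon_rate_tg: float  # Tg C / yr (total live biomass carbon)
    per_ha_carbon_rate: float  # t C / ha / yr

    def report(self) -> dict:
        """Rounded to customary reporting precision."""
        return {
            "delta_gsv_m3": self.delta_gsv,
            "annual_gsv_rate_1e6_m3_yr": round(self.annual_gsv_rate / 1e6),
            "carbon_rate_tg_c_yr": round(self.carbon_rate_tg),
            "per_ha_rate_m3_ha_yr": round(self.per_ha_rate, 2),
            "per_ha_carbon_rate_t_c_ha_yr": round(self.per_ha_carbon_rate, 2),
        }


def change_rate(
    gsv_now: float,
    baseline_gsv: float,
    years: float,
    area_basis: float,
    factors: ConversionFactors = ConversionFactors(),
) -> ChangeEstimate:
    """Annual GSV and live-carbon accumulation rates against a baseline.

    ``area_basis`` is the (assumed unchanged) forest area over which per-ha
    rates are expressed.  Rounding happens only in :meth:`ChangeEstimate.report`.
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if area_basis <= 0:
        raise ValueError("area must be positive")
    delta = gsv_now - baseline_gsv
    annual = delta / years
    carbon_t = annual * factors.gsv_to_live_c
    return ChangeEstimate(
        delta_gsv=delta,
        years=years,
        annual_gsv_rate=annual,
        per_ha_rate=annual / area_basis,
        carbon_rate_tg=tonnes_to_tg(carbon_t),
        per_ha_carbon_rate=carbon_t / area_basis,
    )


def annual_rate_change(
    annual_gsv_rate: float,
    area_basis: float,
    factors: ConversionFactors = ConversionFactors(),
) -> ChangeEstimate:
    """Same bookkeeping starting from an already-annualised volume rate."""
    return change_rate(annual_gsv_rate, 0.0, 1.0, area_basis, factors)


def percent_exceedance(ours: float, reference: float) -> float:
    """How much higher (in %) our estimate is than a reference statistic.

    Returned unrounded; report at integer precision.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (ours - reference) / reference


@dataclass
class ManagedResult:
    total_gsv: float  # m3 over managed forest
    change: ChangeEstimate | None


def managed_subset(
    densities: pd.DataFrame,  # region, density (m3/ha), forest_area (ha)
    managed_areas: pd.DataFrame,  # region, managed_area (ha)
    baseline_managed_gsv: float | None = None,
    years: float | None = None,
    factors: ConversionFactors = ConversionFactors(),
) -> ManagedResult:
    """GSV total over the managed-forest subset, optionally with sequestration.

    The managed total is sum over regions of density x managed area.  Raises
    when a region with forest lacks a managed-area entry or reports managed
    area above its forest area.
    """
    merged = densities.merge(managed_areas, on="region", how="left")
    has_forest = merged["forest_area"] > 0
    if merged.loc[has_forest, "managed_area"].isna().any():
        missing = merged.loc[has_forest & merged["managed_area"].isna(), "region"].tolist()
        raise ValueError(f"missing managed area for forested region(s): {missing}")
    merged["managed_area"] = merged["managed_area"].fillna(0.0)
    if (merged["managed_area"] > merged["forest_area"] + 1e-9).any():
        raise ValueError("managed area exceeds forest area in some region")
    total = float((merged["density"].fillna(0.0) * merged["managed_area"]).sum())
    change = None
    if baseline_managed_gsv is not None and years is not None:
        area = float(merged["managed_area"].sum())
        change = change_rate(total, baseline_managed_gsv, years, area, factors)
    return ManagedResult(total_gsv=total, change=change)
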