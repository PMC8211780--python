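"""Plot-pixel consistency screening.

Before calibration, each ground plot is joined to the map pixel that contains
it, and records with obvious plot/map contradictions are discarded.  The
original vetting of such datasets is largely manual (very-high-resolution
imagery); this module provides three automatable proxies:

* ``require_forest_mask`` — drop plots falling on pixels the forest mask
  excludes (forest-cover contradiction);
* ``max_year_gap`` — drop plots measured too long before/after the map epoch
  (disturbance between measurement and acquisition);
* ``relative_divergence_cap`` — optionally drop plots whose ground GSV
  diverges from both maps by more than a relative threshold.  This rule
  defaults to OFF: genuine plot-to-pixel divergences (plot-size mismatch,
  retrieval cut-offs) are part of the calibration signal, not contamination.

Snags (standing dead trees) are excluded from live GSV: the plot table stores
live GSV and snag volume separately, and calibration uses live GSV only.  If
an input table stores total standing volume instead, ``gsv_includes_snags``
subtracts the snag volume during matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_landscape import Landscape

CALIBRATION_COLUMNS = [
    "plot_id",
    "row",
    "col",
    "year",
    "gsv_gt",
    "gsv_gb",
    "gsv_cci",
    "zone",
    "pft",
    "region",
    "on_forest_mask",
]


@dataclass
class ScreeningRules:
    """Thresholds of the rule-based screen; ``None`` disables a rule."""

    require_forest_mask: bool = True
    max_year_gap: int | None = 5  # years between plot measurement and map epoch
    relative_divergence_cap: float | None = None
    divergence_floor: float = 20.0  # m3/ha, stabilises the relative divergence
    exclude_snags_from_gsv: bool = True

    def __post_init__(self) -> None:
        if self.max_year_gap is not None and self.max_year_gap <= 0:
            raise ValueError("max_year_gap must be positive when set")
        if self.relative_divergence_cap is not None and self.relative_divergence_cap <= 0:
            raise ValueError("relative_divergence_cap must be positive when set")
        if self.divergence_floor <= 0:
            raise ValueError("divergence_floor must be positive")


@dataclass
class DiscardReport:
    """Per-region, per-rule discard counts from one screening pass."""

    counts: pd.DataFrame  # columns: region, rule, n_discarded
    n_input: int
    n_kept: int
    reasons: np.ndarray = field(default=None, repr=False)  # per input record, "" if kept

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_kept

    def fraction_discarded_by_region(self) -> pd.Series:
        by_region = self.counts.groupby("region")["n_discarded"].sum()
        return by_region / self._region_totals.reindex(by_region.index)

    _region_totals: pd.Series = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_input": int(self.n_input),
            "n_kept": int(self.n_kept),
            "n_discarded": int(self.n_discarded),
            "by_region_rule": [
                {"region": int(r), "rule": str(rule), "n_discarded": int(n)}
                for r, rule, n in self.counts.itertuples(index=False)
            ],
        }


def match_plots_to_pixels(
    plots: pd.DataFrame,
    landscape: Landscape,
    gsv_includes_snags: bool = False,
    exclude_snags: bool = True,
) -> pd.DataFrame:
    """Join each plot to its containing pixel's map values and categories.

    Returns a calibration table with one row per plot carrying ``gsv_gb``,
    ``gsv_cci``, zone/PFT/region labels (strings for zone/PFT, integer id for
    region) and an ``on_forest_mask`` flag.  Raises if any plot lies outside
    the grid, naming the offending plot.
    """
    rows = plots["row"].to_numpy(dtype=int)
    cols = plots["col"].to_numpy(dtype=int)
    nr, nc = landscape.shape
    bad = (rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)
    if bad.any():
        first = plots.loc[np.flatnonzero(bad)[0], "plot_id"]
        raise ValueError(f"plot {first!r} falls outside the {nr}x{nc} grid")

    gsv_gt = plots["gsv_gt"].to_numpy(dtype=float)
    snag = plots["snag_volume"].to_numpy(dtype=float)
    if gsv_includes_snags and exclude_snags:
        gsv_gt = np.maximum(gsv_gt - snag, 0.0)

    zone_labels = np.asarray(landscape.zones)[landscape.zone[rows, cols]]
    pft_labels = np.asarray(landscape.pfts)[landscape.pft[rows, cols]]
    return pd.DataFrame(
        {
            "plot_id": plots["plot_id"].to_numpy(),
            "row": rows,
            "col": cols,
            "year": plots["year"].to_numpy(dtype=int),
            "gsv_gt": gsv_gt,
            "gsv_gb": landscape.map_gb[rows, cols],
            "gsv_cci": landscape.map_cci[rows, cols],
            "zone": zone_labels,
            "pft": pft_labels,
            "region": landscape.region[rows, cols].astype(int),
            "on_forest_mask": landscape.forest_mask[rows, cols].astype(bool),
        }
    )


def screen(
    records: pd.DataFrame,
    rules: ScreeningRules,
    map_epoch: int = 2014,
) -> tuple[pd.DataFrame, DiscardReport]:
    """Apply the screening rules; returns kept records and a discard report.

    Rules are checked in a fixed order (mask, year gap, divergence) and each
    discarded record is attributed to the first rule it violates, so the
    per-rule counts partition the discards.  Input order is preserved and
    kept + discarded = input.  Raises if every record would be discarded.
    """
    if len(records) == 0:
        raise ValueError("no records to screen")

    reason = np.full(len(records), "", dtype=object)

    if rules.require_forest_mask:
        viol = ~records["on_forest_mask"].to_numpy(dtype=bool)
        reason[viol & (reason == "")] = "mask"

    if rules.max_year_gap is not None:
        gap = np.abs(records["year"].to_numpy(dtype=int) - map_epoch)
        viol = gap > rules.max_year_gap
        reason[viol & (reason == "")] = "year_gap"

    if rules.relative_divergence_cap is not None:
        gt = records["gsv_gt"].to_numpy(dtype=float)
        div_gb = np.abs(gt - records["gsv_gb"].to_numpy(dtype=float))
        div_cci = np.abs(gt - records["gsv_cci"].to_numpy(dtype=float))
        denom_gb = np.maximum(records["gsv_gb"].to_numpy(dtype=float), rules.divergence_floor)
        denom_cci = np.maximum(records["gsv_cci"].to_numpy(dtype=float), rules.divergence_floor)
        # Discard only when the plot contradicts BOTH maps.
        viol = (div_gb / denom_gb > rules.relative_divergence_cap) & (
            div_cci / denom_cci > rules.relative_divergence_cap
        )
        reason[viol & (reason == "")] = "divergence"

    kept_mask = reason == ""
    if not kept_mask.any():
        raise ValueError("screening discarded every record; calibration impossible")

    kept = records.loc[kept_mask].copy()
    discarded = records.loc[~kept_mask]
    counts = (
        pd.DataFrame({"region": discarded["region"].to_numpy(), "rule": reason[~kept_mask]})
        .groupby(["region", "rule"])
        .size()
        .rename("n_discarded")
        .reset_index()
    )
    report = DiscardReport(
        counts=counts,
        n_input=len(records),
        n_kept=int(kept_mask.sum()),
        reasons=reason,
    )
    report._region_totals = records.groupby("region").size()
    return kept, report


def annotate_screening(records: pd.DataFrame, report: DiscardReport) -> pd.DataFrame:
    """Input table with ``kept``/``discard_reason`` columns (screened-CSV output)."""
    out = records.copy()
    out["kept"] = report.reasons == ""
    out["discard_reason"] = report.reasons
    return out
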