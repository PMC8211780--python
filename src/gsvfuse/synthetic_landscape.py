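"""Synthetic forest landscapes with known ground truth.

Real calibration of satellite growing-stock-volume (GSV) maps uses restricted
national-inventory plots and continental rasters; this module generates small
gridded landscapes with the same statistical structure so that every stage of
the pipeline can be exercised against a known truth:

* six latitudinal bioecological zones arranged as north-to-south bands, four
  plant functional types (PFTs) in smooth patches, rectangular administrative
  regions, and a forest mask with non-forest holes;
* two correlated smooth latent fields play the role of the noiseless signals
  behind the two GSV maps; the *true* pixel GSV is defined as the fusion
  model's mean response applied to those clean signals, so the calibration
  model's coefficients are exactly recoverable by construction;
* the observed maps add zone/PFT-dependent multiplicative bias and Gaussian
  retrieval noise to the clean signals and are truncated at a per-region
  cut-off, reproducing the strong underestimation of extreme GSV values that
  retrieval cut-off levels cause in real products;
* ground plots are small (0.05 ha inventory plots on ~0.5 ha pixels), so the
  plot-scale measurement differs from the pixel mean: this mismatch is
  modelled as additive noise whose standard deviation grows linearly with the
  true GSV (heteroscedasticity), which is what forces bootstrap uncertainty
  downstream; plots carry a snag (standing dead wood) volume averaging a
  configurable fraction of live GSV.

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .fusion_model import PFTS, ZONES, CoefficientSet

# Realistic zone-mean GSV levels (m3/ha) from sparse northern belts to
# productive temperate forest.
ZONE_MEAN_GSV = {
    "forest-tundra": 40.0,
    "north taiga": 70.0,
    "middle taiga": 110.0,
    "south taiga": 160.0,
    "temperate forest": 220.0,
    "forest-steppe": 150.0,
}

MAP_EPOCH = 2014  # nominal acquisition year of both map products
PLOT_YEARS = (2008, 2019)  # inventory measurement window

SamplingDesign = Literal["uniform", "stratified-by-zone", "clustered-with-coverage-gaps"]


def default_true_coeffs(
    n_zones: int = len(ZONES), n_pfts: int = len(PFTS)
) -> CoefficientSet:
    """Plausible generating coefficients: both maps informative, mild structure."""
    zones, pfts = ZONES[:n_zones], PFTS[:n_pfts]
    z = np.arange(n_zones, dtype=float)
    p = np.arange(n_pfts, dtype=float)
    return CoefficientSet(
        zones=zones,
        pfts=pfts,
        a0=8.0 + 2.0 * z,
        a1=0.55 + 0.03 * z,
        a2=0.40 - 0.02 * z,
        a3=np.full(n_zones, 2e-4),
        b0=np.where(p == 0, 0.0, 3.0 * p),
        b1=np.where(p == 0, 0.0, 0.02 * p),
        b2=np.where(p == 0, 0.0, -0.015 * p),
    )


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    ``map_cutoff`` is the per-region retrieval ceiling (scalar broadcast or
    one value per region; ``inf`` disables truncation).  ``map_noise_sd`` is
    the retrieval noise of each map, ``plot_noise_sd`` the plot-scale
    measurement noise floor and ``heteroscedastic_slope`` its growth per unit
    of true GSV.  ``gb_bias``/``cci_bias`` are per-zone and per-PFT
    multiplicative map biases (fractions).
    """

    grid_rows: int = 100
    grid_cols: int = 100
    pixel_area: float = 0.5  # ha
    n_zones: int = 6
    n_pfts: int = 4
    n_regions: int = 9
    true_coeffs: CoefficientSet | None = None
    map_noise_sd: float = 20.0  # m3/ha, per map
    map_cutoff: float | np.ndarray = 300.0  # m3/ha, per region
    plot_noise_sd: float = 25.0  # m3/ha
    heteroscedastic_slope: float = 0.15
    snag_ratio: float = 0.12
    gb_bias: float = 0.05  # amplitude of zone-dependent bias on the first map
    cci_bias: float = 0.05  # amplitude of PFT-dependent bias on the second map
    correlation_length: float = 5.0  # pixels, smoothness of the latent fields
    signal_correlation: float = 0.9  # correlation between the two clean signals
    forest_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one pixel")
        if not (1 <= self.n_zones <= len(ZONES)):
            raise ValueError(f"n_zones must be in 1..{len(ZONES)}")
        if not (1 <= self.n_pfts <= len(PFTS)):
            raise ValueError(f"n_pfts must be in 1..{len(PFTS)}")
        if self.n_regions < 1:
            raise ValueError("need at least one region")
        for name in ("map_noise_sd", "plot_noise_sd", "heteroscedastic_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.snag_ratio < 1):
            raise ValueError("snag_ratio must be in [0, 1)")
        if self.true_coeffs is None:
            self.true_coeffs = default_true_coeffs(self.n_zones, self.n_pfts)

    @property
    def zones(self) -> tuple[str, ...]:
        return ZONES[: self.n_zones]

    @property
    def pfts(self) -> tuple[str, ...]:
        return PFTS[: self.n_pfts]

    def region_cutoffs(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.map_cutoff, dtype=float), (self.n_regions,)
        ).copy()


@dataclass
class Landscape:
    """Co-registered rasters: truth, the two maps, and the categorical layers.

    ``zone``/``pft``/``region`` are integer-coded (indices into the label
    lists); ``forest_mask`` is boolean.  GSV rasters are m3/ha.
    """

    true_gsv: np.ndarray
    map_gb: np.ndarray
    map_cci: np.ndarray
    zone: np.ndarray
    pft: np.ndarray
    region: np.ndarray
    forest_mask: np.ndarray
    pixel_area: float
    zones: tuple[str, ...] = ZONES
    pfts: tuple[str, ...] = PFTS
    map_epoch: int = MAP_EPOCH

    @property
    def shape(self) -> tuple[int, int]:
        return self.true_gsv.shape

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (
                self.true_gsv,
                self.map_gb,
                self.map_cci,
                self.zone,
                self.pft,
                self.region,
                self.forest_mask,
            )
        }
        if len(shapes) != 1:
            raise ValueError(f"all rasters must share dimensions, got {sorted(shapes)}")


def _smooth_field(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Unit-variance Gaussian random field via Gaussian smoothing of white noise."""
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    f = ndimage.gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate one landscape; bit-reproducible for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    rows = np.arange(config.grid_rows)

    # Zones as horizontal (latitudinal) bands, north at row 0.
    zone = np.repeat(
        np.minimum(rows * config.n_zones // max(config.grid_rows, 1), config.n_zones - 1),
        config.grid_cols,
    ).reshape(shape)

    # PFT patches: argmax over smoothed per-class noise fields.
    pft_fields = np.stack(
        [_smooth_field(rng, shape, config.correlation_length) for _ in range(config.n_pfts)]
    )
    pft = np.argmax(pft_fields, axis=0).astype(np.uint8)

    # Regions: near-square blocks tiling the grid.
    nr_blocks = int(np.ceil(np.sqrt(config.n_regions)))
    nc_blocks = int(np.ceil(config.n_regions / nr_blocks))
    bi = np.minimum(rows * nr_blocks // max(config.grid_rows, 1), nr_blocks - 1)
    cols = np.arange(config.grid_cols)
    bj = np.minimum(cols * nc_blocks // max(config.grid_cols, 1), nc_blocks - 1)
    region = np.minimum(
        bi[:, None] * nc_blocks + bj[None, :], config.n_regions - 1
    ).astype(np.uint16)

    # Forest mask: threshold a smooth field to the requested forest fraction.
    if config.forest_fraction >= 1.0:
        forest = np.ones(shape, dtype=bool)
    else:
        mfield = _smooth_field(rng, shape, config.correlation_length)
        thr = np.quantile(mfield, 1.0 - config.forest_fraction)
        forest = mfield >= thr

    # Two correlated clean signals behind the maps, per-zone mean + GRF.
    zone_means = np.array([ZONE_MEAN_GSV[z] for z in config.zones])
    base = zone_means[zone]
    g1 = _smooth_field(rng, shape, config.correlation_length)
    g2 = (
        config.signal_correlation * g1
        + np.sqrt(1.0 - config.signal_correlation**2)
        * _smooth_field(rng, shape, config.correlation_length)
    )
    spread = 0.35 * base  # spatial variability scales with zone productivity
    gb_clean = np.maximum(base + spread * g1, 0.0)
    cci_clean = np.maximum(base + spread * g2, 0.0)

    # Truth is the fusion model's mean response to the clean signals.
    coeffs = config.true_coeffs
    true_gsv = np.maximum(
        coeffs.mean_response(gb_clean.ravel(), cci_clean.ravel(), zone.ravel(), pft.ravel()),
        0.0,
    ).reshape(shape)

    # Observed maps: zone/PFT multiplicative bias + retrieval noise + cut-off.
    nz, npft = config.n_zones, config.n_pfts
    gb_bias = 1.0 + config.gb_bias * np.linspace(-1, 1, nz)[zone]
    cci_bias = 1.0 + config.cci_bias * np.linspace(-1, 1, npft)[pft]
    map_gb = gb_clean * gb_bias + rng.normal(0.0, config.map_noise_sd, shape)
    map_cci = cci_clean * cci_bias + rng.normal(0.0, config.map_noise_sd, shape)
    cutoffs = config.region_cutoffs()[region]
    map_gb = np.clip(map_gb, 0.0, cutoffs)
    map_cci = np.clip(map_cci, 0.0, cutoffs)

    return Landscape(
        true_gsv=true_gsv.astype(np.float64),
        map_gb=map_gb.astype(np.float64),
        map_cci=map_cci.astype(np.float64),
        zone=zone.astype(np.uint8),
        pft=pft,
        region=region,
        forest_mask=forest,
        pixel_area=config.pixel_area,
        zones=config.zones,
        pfts=config.pfts,
    )


def sample_plots(
    landscape: Landscape,
    n: int,
    config: LandscapeConfig,
    seed: int,
    design: SamplingDesign = "uniform",
    nfi_fraction: float = 0.9,
) -> pd.DataFrame:
    """Draw ground plots on forest pixels under a sampling design.

    The measured plot GSV is the true pixel GSV plus heteroscedastic
    plot-scale noise (sd = plot_noise_sd + heteroscedastic_slope x truth),
    floored at zero.  Snag volume is drawn so its mean ratio to live GSV
    matches ``config.snag_ratio``.  Designs: ``uniform`` (simple random
    without replacement), ``stratified-by-zone`` (proportional allocation
    with at least one plot per forested zone), ``clustered-with-coverage-gaps``
    (the eastern third of the grid receives no plots, emulating large
    uncovered northern regions).

    Returns a DataFrame with columns
    ``plot_id,row,col,year,gsv_gt,snag_volume,source,plot_area``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    forest_idx = np.flatnonzero(landscape.forest_mask.ravel())
    if forest_idx.size == 0:
        raise ValueError("landscape has no forest pixels to sample")

    if design == "uniform":
        if n > forest_idx.size:
            raise ValueError(
                f"cannot draw {n} plots without replacement from "
                f"{forest_idx.size} forest pixels"
            )
        chosen = rng.choice(forest_idx, size=n, replace=False)
    elif design == "stratified-by-zone":
        zflat = landscape.zone.ravel()[forest_idx]
        strata = np.unique(zflat)
        if n < strata.size:
            raise ValueError(f"n={n} smaller than the number of forested zones ({strata.size})")
        if n > forest_idx.size:
            raise ValueError("n exceeds available forest pixels")
        # Proportional allocation, minimum one per stratum.
        counts = np.array([(zflat == s).sum() for s in strata])
        alloc = np.maximum(1, np.floor(n * counts / counts.sum()).astype(int))
        alloc = np.minimum(alloc, counts)
        while alloc.sum() < n:  # distribute the remainder to the largest strata
            room = counts - alloc
            j = int(np.argmax(room))
            if room[j] <= 0:
                break
            alloc[j] += 1
        parts = [
            rng.choice(forest_idx[zflat == s], size=a, replace=False)
            for s, a in zip(strata, alloc)
        ]
        chosen = np.concatenate(parts)
    elif design == "clustered-with-coverage-gaps":
        cols = forest_idx % landscape.shape[1]
        covered = forest_idx[cols < (2 * landscape.shape[1]) // 3]
        if covered.size == 0:
            raise ValueError("coverage gap removes all forest pixels")
        if n > covered.size:
            raise ValueError("n exceeds forest pixels in the covered area")
        chosen = rng.choice(covered, size=n, replace=False)
    else:
        raise ValueError(f"unknown sampling design {design!r}")

    r, c = np.unravel_index(chosen, landscape.shape)
    truth = landscape.true_gsv[r, c]
    sd = config.plot_noise_sd + config.heteroscedastic_slope * truth
    # Plot-scale measurement: Gamma with mean = true pixel GSV and the
    # configured sd, so values stay nonnegative without biasing the mean
    # (a zero-floored Gaussian would inflate low-GSV plots).
    gsv_gt = truth.copy()
    noisy = (truth > 0) & (sd > 0)
    shape_p = (truth[noisy] / sd[noisy]) ** 2
    scale_p = sd[noisy] ** 2 / truth[noisy]
    gsv_gt[noisy] = rng.gamma(shape_p, scale_p)

    # Per-plot snag ratio ~ Gamma with mean snag_ratio (right-skewed, >= 0).
    if config.snag_ratio > 0:
        ratios = rng.gamma(shape=4.0, scale=config.snag_ratio / 4.0, size=truth.shape)
    else:
        ratios = np.zeros_like(truth)
    snag = gsv_gt * ratios

    source = np.where(rng.random(truth.shape) < nfi_fraction, "NFI", "FOS")
    plot_area = np.where(source == "NFI", 0.05, 0.25)
    # Inventory effort ramps up over the window: early years carry few plots.
    years = np.arange(PLOT_YEARS[0], PLOT_YEARS[1] + 1)
    effort = np.linspace(0.4, 1.2, years.size)
    year = rng.choice(years, size=truth.shape, p=effort / effort.sum())

    return pd.DataFrame(
        {
            "plot_id": [f"P{i:06d}" for i in range(len(r))],
            "row": r.astype(int),
            "col": c.astype(int),
            "year": year.astype(int),
            "gsv_gt": gsv_gt,
            "snag_volume": snag,
            "source": source,
            "plot_area": plot_area,
        }
    )


def noiseless_config(**overrides) -> LandscapeConfig:
    """Convenience: a config with no map noise/bias and no truncation."""
    base = dict(
        map_noise_sd=0.0,
        map_cutoff=np.inf,
        gb_bias=0.0,
        cci_bias=0.0,
        plot_noise_sd=0.0,
        heteroscedastic_slope=0.0,
        snag_ratio=0.0,
        forest_fraction=1.0,
    )
    base.update(overrides)
    return LandscapeConfig(**base)
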