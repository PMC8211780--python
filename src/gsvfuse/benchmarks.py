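"""Statistical validation experiments on synthetic landscapes.

The study-scale results of a national map calibration (total stocks, regional
standard errors) depend on restricted inventory plots and continental
rasters, so the method is validated here on landscapes with known truth:

* **parameter recovery** — do bootstrap 95% intervals for the fusion-model
  coefficients cover the generating values at roughly their nominal rate?
* **CI coverage** — do the regional percentile intervals cover the true
  regional mean densities?
* **weighting efficacy** — when plots oversample high-GSV forest, does the
  frequency-bin weighted fit reduce the area-mean bias of a (deliberately
  reduced, hence misspecified) model relative to the unweighted fit?

Fixtures use noise on the plot measurements only (maps clean): these checks
concern bootstrap calibration of the mean model, and retrieval noise on the
regressors would confound them with an errors-in-variables effect the method
does not claim to remove.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fusion_model as fm
from . import screening as sc
from . import synthetic_landscape as sl
from . import uncertainty as un


def _recovery_config(seed: int, rows: int, cols: int) -> sl.LandscapeConfig:
    """Heteroscedastic plot noise, clean maps, no truncation."""
    return sl.LandscapeConfig(
        grid_rows=rows,
        grid_cols=cols,
        map_noise_sd=0.0,
        map_cutoff=np.inf,
        gb_bias=0.0,
        cci_bias=0.0,
        plot_noise_sd=15.0,
        heteroscedastic_slope=0.15,
        seed=seed,
    )


def parameter_recovery(
    seed: int = 0,
    n_replicates: int = 20,
    n_plots: int = 10_000,
    B: int = 200,
    grid: tuple[int, int] = (200, 200),
) -> dict:
    """Pooled coverage of bootstrap 95% CIs over coefficients and replicates.

    Each replicate draws a fresh landscape generated from known coefficients,
    samples heteroscedastic plots, bootstraps the fit, and records which true
    coefficients fall inside their percentile intervals.  Returns the pooled
    coverage fraction over (replicate, coefficient) pairs.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(3 * n_replicates) % (2**31)
    covered = []
    for i in range(n_replicates):
        cfg = _recovery_config(int(rep_seeds[3 * i]), *grid)
        L = sl.generate_landscape(cfg)
        plots = sl.sample_plots(L, n_plots, cfg, seed=int(rep_seeds[3 * i + 1]))
        records = sc.match_plots_to_pixels(plots, L)
        # True parameter vector in design-column order.
        c = cfg.true_coeffs
        truth = np.concatenate(
            [c.a0, c.b0[1:], c.a1, c.b1[1:], c.a2, c.b2[1:], c.a3]
        )
        _, ci = un.bootstrap_coefficients(
            records, B=B, seed=int(rep_seeds[3 * i + 2]),
            zones=cfg.zones, pfts=cfg.pfts,
        )
        covered.append((ci[0] <= truth) & (truth <= ci[1]))
    covered = np.asarray(covered)
    return {
        "coverage": float(covered.mean()),
        "n_replicates": n_replicates,
        "n_coefficients": covered.shape[1],
    }


def ci_coverage(
    seed: int = 0,
    n_replicates: int = 40,
    n_plots: int = 2000,
    B: int = 200,
    grid: tuple[int, int] = (100, 100),
) -> dict:
    """Pooled coverage of regional 95% percentile CIs for true mean density."""
    ss = np.random.SeedSequence((seed, 1))
    rep_seeds = ss.generate_state(3 * n_replicates) % (2**31)
    hits, total = 0, 0
    for i in range(n_replicates):
        cfg = _recovery_config(int(rep_seeds[3 * i]), *grid)
        L = sl.generate_landscape(cfg)
        plots = sl.sample_plots(L, n_plots, cfg, seed=int(rep_seeds[3 * i + 1]))
        records = sc.match_plots_to_pixels(plots, L)
        est = un.bootstrap_regions(
            records, L, boot=un.BootstrapConfig(B=B, seed=int(rep_seeds[3 * i + 2]))
        )
        mask = L.forest_mask.astype(bool)
        for e in est:
            sel = (L.region == e.region) & mask
            truth = float(L.true_gsv[sel].mean())
            hits += int(e.ci95[0] <= truth <= e.ci95[1])
            total += 1
    return {"coverage": hits / total, "n_intervals": total}


def _curved_coeffs() -> fm.CoefficientSet:
    """Generating coefficients with a strong map interaction (convex truth)."""
    z = np.arange(6, dtype=float)
    p = np.arange(4, dtype=float)
    return fm.CoefficientSet(
        zones=fm.ZONES,
        pfts=fm.PFTS,
        a0=5.0 + 4.0 * z,
        a1=0.25 + 0.05 * z,
        a2=0.35 - 0.03 * z,
        a3=np.full(6, 3e-3),
        b0=np.where(p == 0, 0, 3.0 * p),
        b1=np.where(p == 0, 0, 0.02 * p),
        b2=np.where(p == 0, 0, -0.015 * p),
    )


def weighting_efficacy(
    seed: int = 0,
    n_plots: int = 4000,
    grid: tuple[int, int] = (100, 100),
    selection_scale: float = 40.0,
) -> dict:
    """Area-mean bias of a reduced model, weighted vs unweighted fit.

    Plots oversample high-GSV pixels (selection probability grows
    exponentially with the first map's GSV, the variable the frequency bins
    use); the fitted candidate is the pooled main-effects model, which lacks
    the generating model's map interaction and is therefore misspecified
    (curved truth, linear fit).  Fitted on high-GSV-heavy plots, the
    unweighted line matches the oversampled range and systematically misses
    the abundant low-GSV forest; frequency-bin weights retarget the fit to
    the landscape's GSV distribution and shrink the area-mean bias.
    """
    cfg = sl.LandscapeConfig(
        grid_rows=grid[0],
        grid_cols=grid[1],
        map_noise_sd=0.0,
        map_cutoff=np.inf,
        gb_bias=0.0,
        cci_bias=0.0,
        plot_noise_sd=2.0,
        heteroscedastic_slope=0.02,
        true_coeffs=_curved_coeffs(),
        seed=seed,
    )
    L = sl.generate_landscape(cfg)
    rng = np.random.default_rng(seed + 1)
    mask = L.forest_mask.astype(bool)
    forest_idx = np.flatnonzero(mask.ravel())
    gb_flat = L.map_gb.ravel()[forest_idx]
    p_sel = np.exp(gb_flat / selection_scale)
    p_sel /= p_sel.sum()
    chosen = rng.choice(forest_idx, size=n_plots, replace=False, p=p_sel)
    r, c = np.unravel_index(chosen, L.shape)
    truth = L.true_gsv[r, c]
    sd = cfg.plot_noise_sd + cfg.heteroscedastic_slope * truth
    gsv_gt = rng.gamma((truth / sd) ** 2, sd**2 / truth)  # mean-preserving, >= 0
    records = pd.DataFrame(
        {
            "gsv_gt": gsv_gt,
            "gsv_gb": L.map_gb[r, c],
            "gsv_cci": L.map_cci[r, c],
            "zone": np.asarray(L.zones)[L.zone[r, c]],
            "pft": np.asarray(L.pfts)[L.pft[r, c]],
        }
    )

    spec = fm.ModelSpec(use_interaction=False, zone_blocks=False, pft_offsets=False)
    target = L.map_gb[mask]
    scheme = fm.compute_weights(records, target)
    true_mean = float(L.true_gsv[mask].mean())

    def area_mean(weights):
        res = fm.fit(records, weights=weights, zones=L.zones, pfts=L.pfts, spec=spec)
        pred = fm.predict(res, L)
        return float(np.nanmean(pred.raster[mask]))

    bias_unweighted = abs(area_mean(None) - true_mean)
    bias_weighted = abs(area_mean(scheme.weights) - true_mean)
    return {
        "true_mean": true_mean,
        "bias_unweighted": bias_unweighted,
        "bias_weighted": bias_weighted,
        "n_plots": n_plots,
    }
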