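"""Linear fusion of two growing-stock-volume (GSV) maps against ground plots.

The calibration model predicts plot-measured GSV from the two map retrievals
with coefficients structured by bioecological zone and plant functional type
(PFT):

    E(GSV_GT) = (a0_z + b0_p)
              + (a1_z + b1_p) * GSV_GB
              + (a2_z + b2_p) * GSV_CCI
              + a3_z          * GSV_GB * GSV_CCI

where z indexes the zone and p the PFT of the plot's pixel.  The interaction
coefficient is per-zone by default; ``interaction_pft_offsets=True`` adds
per-PFT offsets to it as well.  Identifiability of the additive a+b structure
is obtained by reference-level coding: all b-coefficients of the first PFT
level are fixed at zero.

Predictions can be negative near the origin; they are truncated at zero at
prediction time and the fraction of raw-negative pixels is reported.

An optional per-record weighting corrects covariate shift between the
calibration plots and a target area: weights are ratios of relative GSV
frequencies in bins of width 10 from 0 to 1000 m3/ha, renormalised to mean 1.
A weighted fit drives the weighted sum of residuals to zero, which makes the
area mean (or total) of predictions unbiased for the target area.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Canonical category labels: six latitudinal forest belts and four forest types.
ZONES = (
    "forest-tundra",
    "north taiga",
    "middle taiga",
    "south taiga",
    "temperate forest",
    "forest-steppe",
)
PFTS = (
    "evergreen needleleaf",
    "deciduous needleleaf",
    "deciduous broadleaf",
    "mixed forest",
)

NODATA = -9999.0


# ---------------------------------------------------------------------------
# Coefficient container
# ---------------------------------------------------------------------------


@dataclass
class CoefficientSet:
    """Zone/PFT-structured coefficients of the fusion model.

    ``a0..a3`` are arrays over zones (intercept, slope on GSV_GB, slope on
    GSV_CCI, interaction slope); ``b0..b2`` are arrays over PFTs (offsets to
    intercept and the two main-effect slopes) with the first PFT as reference
    level (entries fixed at 0).  ``b3`` is the optional per-PFT interaction
    offset; ``None`` means the interaction is purely zonal.
    Units: a0, b0 in m3/ha; a1, a2, b1, b2 dimensionless; a3, b3 in ha/m3.
    """

    zones: tuple[str, ...]
    pfts: tuple[str, ...]
    a0: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    b3: np.ndarray | None = None

    def __post_init__(self) -> None:
        nz, np_ = len(self.zones), len(self.pfts)
        for name in ("a0", "a1", "a2", "a3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (nz,):
                raise ValueError(f"{name} must have one entry per zone ({nz})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        for name in ("b0", "b1", "b2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (np_,):
                raise ValueError(f"{name} must have one entry per PFT ({np_})")
            if arr[0] != 0.0:
                raise ValueError(f"{name}[0] must be 0 (reference-level constraint)")
            setattr(self, name, arr)
        if self.b3 is not None:
            arr = np.asarray(self.b3, dtype=float)
            if arr.shape != (np_,) or arr[0] != 0.0:
                raise ValueError("b3 must have one zero-referenced entry per PFT")
            self.b3 = arr

    def mean_response(
        self,
        gsv_gb: np.ndarray,
        gsv_cci: np.ndarray,
        zone_idx: np.ndarray,
        pft_idx: np.ndarray,
    ) -> np.ndarray:
        """Model mean E(GSV_GT) without zero-truncation (vectorised)."""
        gb = np.asarray(gsv_gb, dtype=float)
        cci = np.asarray(gsv_cci, dtype=float)
        z = np.asarray(zone_idx)
        p = np.asarray(pft_idx)
        inter = self.a3[z]
        if self.b3 is not None:
            inter = inter + self.b3[p]
        return (
            (self.a0[z] + self.b0[p])
            + (self.a1[z] + self.b1[p]) * gb
            + (self.a2[z] + self.b2[p]) * cci
            + inter * gb * cci
        )

    @classmethod
    def identity(
        cls,
        zones: Sequence[str] = ZONES,
        pfts: Sequence[str] = PFTS,
    ) -> "CoefficientSet":
        """Coefficients reproducing the first map exactly (a1=1, rest 0)."""
        nz, np_ = len(zones), len(pfts)
        return cls(
            zones=tuple(zones),
            pfts=tuple(pfts),
            a0=np.zeros(nz),
            a1=np.ones(nz),
            a2=np.zeros(nz),
            a3=np.zeros(nz),
            b0=np.zeros(np_),
            b1=np.zeros(np_),
            b2=np.zeros(np_),
        )

    def to_dict(self) -> dict:
        d = {
            "zones": list(self.zones),
            "pfts": list(self.pfts),
            "constraint": "reference-level: b-coefficients of the first PFT are 0",
            "a0": dict(zip(self.zones, self.a0.tolist())),
            "a1": dict(zip(self.zones, self.a1.tolist())),
            "a2": dict(zip(self.zones, self.a2.tolist())),
            "a3": dict(zip(self.zones, self.a3.tolist())),
            "b0": dict(zip(self.pfts, self.b0.tolist())),
            "b1": dict(zip(self.pfts, self.b1.tolist())),
            "b2": dict(zip(self.pfts, self.b2.tolist())),
        }
        if self.b3 is not None:
            d["b3"] = dict(zip(self.pfts, self.b3.tolist()))
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        zones = tuple(d["zones"])
        pfts = tuple(d["pfts"])
        get = lambda fam, labels: np.array([d[fam][k] for k in labels], dtype=float)
        return cls(
            zones=zones,
            pfts=pfts,
            a0=get("a0", zones),
            a1=get("a1", zones),
            a2=get("a2", zones),
            a3=get("a3", zones),
            b0=get("b0", pfts),
            b1=get("b1", pfts),
            b2=get("b2", pfts),
            b3=get("b3", pfts) if "b3" in d else None,
        )

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Model form and design matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the design matrix.

    The default is the selected full model: zone-structured intercepts and
    slopes on both maps, PFT offsets on intercept and the two main effects,
    and a per-zone interaction.  Flags switch blocks off to express the
    reduced candidate forms compared during cross-validation.
    """

    use_gb: bool = True
    use_cci: bool = True
    use_interaction: bool = True
    zone_blocks: bool = True
    pft_offsets: bool = True
    interaction_pft_offsets: bool = False
    weighted: bool = False

    def column_names(self, zones: Sequence[str], pfts: Sequence[str]) -> list[str]:
        """Deterministic column order of the design matrix.

        Order: intercept block (zones or pooled), PFT intercept offsets,
        GB block, PFT x GB offsets, CCI block, PFT x CCI offsets,
        interaction block, PFT x interaction offsets.  The first PFT level
        is the dropped reference in every offset block.
        """
        cols: list[str] = []
        zlabels = list(zones) if self.zone_blocks else ["pooled"]
        cols += [f"a0[{z}]" for z in zlabels]
        if self.pft_offsets:
            cols += [f"b0[{p}]" for p in pfts[1:]]
        if self.use_gb:
            cols += [f"a1[{z}]" for z in zlabels]
            if self.pft_offsets:
                cols += [f"b1[{p}]" for p in pfts[1:]]
        if self.use_cci:
            cols += [f"a2[{z}]" for z in zlabels]
            if self.pft_offsets:
                cols += [f"b2[{p}]" for p in pfts[1:]]
        if self.use_interaction:
            cols += [f"a3[{z}]" for z in zlabels]
            if self.interaction_pft_offsets:
                cols += [f"b3[{p}]" for p in pfts[1:]]
        return cols


def _category_index(values: pd.Series | np.ndarray, levels: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(values)
    lookup = {lab: i for i, lab in enumerate(levels)}
    idx = np.empty(arr.shape[0], dtype=np.int64)
    for i, v in enumerate(arr):
        try:
            idx[i] = lookup[v]
        except KeyError:
            raise ValueError(
                f"unknown {what} category {v!r}; known levels: {list(levels)}"
            ) from None
    return idx


def build_design(
    gsv_gb: np.ndarray,
    gsv_cci: np.ndarray,
    zone_idx: np.ndarray,
    pft_idx: np.ndarray,
    n_zones: int,
    n_pfts: int,
    spec: ModelSpec = ModelSpec(),
) -> np.ndarray:
    """Design matrix rows for the fusion model (vectorised over records).

    ``zone_idx``/``pft_idx`` are integer codes into the category level lists.
    Column order follows :meth:`ModelSpec.column_names`.
    """
    gb = np.asarray(gsv_gb, dtype=float)
    cci = np.asarray(gsv_cci, dtype=float)
    n = gb.shape[0]
    z = np.asarray(zone_idx)
    p = np.asarray(pft_idx)

    zdummy = np.zeros((n, n_zones if spec.zone_blocks else 1))
    if spec.zone_blocks:
        zdummy[np.arange(n), z] = 1.0
    else:
        zdummy[:, 0] = 1.0
    # PFT offsets drop the reference (first) level.
    pdummy = np.zeros((n, n_pfts - 1))
    nonref = p > 0
    pdummy[np.arange(n)[nonref], p[nonref] - 1] = 1.0

    blocks = [zdummy]
    if spec.pft_offsets:
        blocks.append(pdummy)
    for use, v in ((spec.use_gb, gb), (spec.use_cci, cci)):
        if use:
            blocks.append(zdummy * v[:, None])
            if spec.pft_offsets:
                blocks.append(pdummy * v[:, None])
    if spec.use_interaction:
        gxc = gb * cci
        blocks.append(zdummy * gxc[:, None])
        if spec.interaction_pft_offsets:
            blocks.append(pdummy * gxc[:, None])
    return np.hstack(blocks)


def build_design_row(
    record,
    zones: Sequence[str] = ZONES,
    pfts: Sequence[str] = PFTS,
    spec: ModelSpec = ModelSpec(),
) -> np.ndarray:
    """Feature vector for one calibration record (mapping or object).

    The record must expose ``gsv_gb``, ``gsv_cci``, ``zone``, ``pft``.
    """
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    z = _category_index([get("zone")], zones, "zone")
    p = _category_index([get("pft")], pfts, "pft")
    return build_design(
        np.array([float(get("gsv_gb"))]),
        np.array([float(get("gsv_cci"))]),
        z,
        p,
        len(zones),
        len(pfts),
        spec,
    )[0]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted fusion model: parameter vector plus diagnostics."""

    spec: ModelSpec
    zones: tuple[str, ...]
    pfts: tuple[str, ...]
    params: np.ndarray
    column_names: list[str]
    residuals: np.ndarray
    fitted: np.ndarray
    r_squared: float
    het_spearman: float  # rank corr of |residual| with fitted value
    het_pvalue: float
    seen_combos: set[tuple[int, int]]  # (zone_idx, pft_idx) present in training
    weights: np.ndarray | None = None

    @property
    def weighted_residual_sum(self) -> float:
        w = self.weights if self.weights is not None else np.ones_like(self.residuals)
        return float(np.sum(w * self.residuals))

    def coefficient_set(self) -> CoefficientSet:
        """Structured view of the parameters (full-model specs only)."""
        s = self.spec
        if not (s.zone_blocks and s.pft_offsets and s.use_gb and s.use_cci and s.use_interaction):
            raise ValueError("coefficient_set() requires the full zone/PFT model form")
        nz, np_ = len(self.zones), len(self.pfts)
        i = 0

        def take(k):
            nonlocal i
            out = self.params[i : i + k]
            i += k
            return out

        a0 = take(nz)
        b0 = np.concatenate([[0.0], take(np_ - 1)])
        a1 = take(nz)
        b1 = np.concatenate([[0.0], take(np_ - 1)])
        a2 = take(nz)
        b2 = np.concatenate([[0.0], take(np_ - 1)])
        a3 = take(nz)
        b3 = None
        if s.interaction_pft_offsets:
            b3 = np.concatenate([[0.0], take(np_ - 1)])
        return CoefficientSet(self.zones, self.pfts, a0, a1, a2, a3, b0, b1, b2, b3)


def _records_to_arrays(records, zones, pfts):
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    gb = df["gsv_gb"].to_numpy(dtype=float)
    cci = df["gsv_cci"].to_numpy(dtype=float)
    z = _category_index(df["zone"], zones, "zone")
    p = _category_index(df["pft"], pfts, "pft")
    y = df["gsv_gt"].to_numpy(dtype=float)
    return gb, cci, z, p, y


def fit(
    records,
    weights: np.ndarray | None = None,
    zones: Sequence[str] = ZONES,
    pfts: Sequence[str] = PFTS,
    spec: ModelSpec = ModelSpec(),
) -> FitResult:
    """Least-squares (optionally weighted) fit of the fusion model.

    ``records`` is a DataFrame (or record list) with columns ``gsv_gt``,
    ``gsv_gb``, ``gsv_cci``, ``zone``, ``pft``.  With weights, parameters
    minimise the weighted sum of squared errors, which drives the weighted
    sum of residuals to zero (the defining property used to make target-area
    means unbiased).
    """
    gb, cci, z, p, y = _records_to_arrays(records, zones, pfts)
    X = build_design(gb, cci, z, p, len(zones), len(pfts), spec)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} records to fit {k} coefficients, got {n}")

    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must align with records")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if w.sum() <= 0:
            raise ValueError("weights sum to zero; nothing to fit")
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
    else:
        w = None
        Xw, yw = X, y

    params, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < k:
        # Name the collinear columns via QR pivoting on the weighted design.
        from scipy.linalg import qr

        _, _, piv = qr(Xw, mode="economic", pivoting=True)
        names = spec.column_names(zones, pfts)
        bad = [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"collinear columns: {bad}"
        )

    fitted = X @ params
    resid = y - fitted
    wts = w if w is not None else np.ones(n)
    ybar = np.average(y, weights=wts)
    ss_tot = float(np.sum(wts * (y - ybar) ** 2))
    ss_res = float(np.sum(wts * resid**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if np.ptp(fitted) > 0 and np.ptp(np.abs(resid)) > 0:
        rho, pval = stats.spearmanr(fitted, np.abs(resid))
    else:
        rho, pval = float("nan"), float("nan")
    return FitResult(
        spec=spec,
        zones=tuple(zones),
        pfts=tuple(pfts),
        params=params,
        column_names=spec.column_names(zones, pfts),
        residuals=resid,
        fitted=fitted,
        r_squared=r2,
        het_spearman=float(rho),
        het_pvalue=float(pval),
        seen_combos=set(zip(z.tolist(), p.tolist())),
        weights=w,
    )


# ---------------------------------------------------------------------------
# Frequency-bin weighting
# ---------------------------------------------------------------------------

BIN_EDGES = np.arange(0.0, 1001.0, 10.0)  # bins of width 10 from 0 to 1000
N_BINS = len(BIN_EDGES) - 1


@dataclass
class WeightScheme:
    """Per-record covariate-shift weights from binned GSV frequencies."""

    bin_edges: np.ndarray
    calib_freq: np.ndarray
    target_freq: np.ndarray
    weights: np.ndarray
    merged_bins: list[int] = field(default_factory=list)


def _bin_index(values: np.ndarray) -> np.ndarray:
    """Bin of width 10 on [0, 1000); values >= 1000 clamp into the last bin."""
    idx = np.floor(np.asarray(values, dtype=float) / 10.0).astype(np.int64)
    return np.clip(idx, 0, N_BINS - 1)


def compute_weights(records, target_gsv_values, binning_column: str = "gsv_gb") -> WeightScheme:
    """Frequency-ratio weights aligning the calibration GSV distribution to a target area.

    Both distributions are binned on the first map's GSV (the only quantity
    available both at plots and wall-to-wall).  Each record's raw weight is
    target_freq(bin) / calib_freq(bin); bins occupied in the target but empty
    in the calibration data have their target mass merged into the nearest
    occupied calibration bin (with a warning); weights are renormalised to
    mean 1 so weighted and unweighted fits are comparable in scale.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    g = df[binning_column].to_numpy(dtype=float)
    t = np.asarray(target_gsv_values, dtype=float)
    if g.size == 0 or t.size == 0:
        raise ValueError("calibration records and target values must be nonempty")

    gbins = _bin_index(g)
    tbins = _bin_index(t)
    calib = np.bincount(gbins, minlength=N_BINS).astype(float)
    target = np.bincount(tbins, minlength=N_BINS).astype(float)
    calib_freq = calib / calib.sum()
    target_freq = target / target.sum()

    merged: list[int] = []
    orphan = (target_freq > 0) & (calib_freq == 0)
    if np.any(orphan):
        occupied = np.flatnonzero(calib_freq > 0)
        for b in np.flatnonzero(orphan):
            nearest = occupied[np.argmin(np.abs(occupied - b))]
            target_freq[nearest] += target_freq[b]
            target_freq[b] = 0.0
            merged.append(int(b))
        warnings.warn(
            f"{len(merged)} target-occupied bin(s) empty in calibration data; "
            "their target mass was merged into the nearest occupied bin",
            stacklevel=2,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(calib_freq > 0, target_freq / calib_freq, 0.0)
    w = ratio[gbins]
    mean_w = w.mean()
    if mean_w <= 0:
        raise ValueError("all record weights are zero under the target distribution")
    w = w / mean_w
    return WeightScheme(BIN_EDGES.copy(), calib_freq, target_freq, w, merged)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictionResult:
    """Zero-truncated GSV prediction raster plus truncation/fallback diagnostics."""

    raster: np.ndarray  # float, NaN outside the forest mask
    negative_fraction: float  # share of forest pixels with raw-negative prediction
    fallback: np.ndarray  # bool raster: zone x PFT combo unseen in calibration
    n_fallback: int


def predict(model: FitResult | CoefficientSet, landscape) -> PredictionResult:
    """Predict GSV over a landscape's forest pixels, truncating negatives at zero.

    ``landscape`` must expose ``map_gb``, ``map_cci``, ``zone``, ``pft``,
    ``forest_mask`` rasters of identical shape.  Pixels whose zone x PFT
    combination was absent from calibration fall back to zone-level
    coefficients with the reference-PFT offsets and are flagged.
    """
    gb, cci = np.asarray(landscape.map_gb, float), np.asarray(landscape.map_cci, float)
    zone, pft = np.asarray(landscape.zone), np.asarray(landscape.pft)
    mask = np.asarray(landscape.forest_mask).astype(bool)
    shapes = {gb.shape, cci.shape, zone.shape, pft.shape, mask.shape}
    if len(shapes) != 1:
        raise ValueError(f"raster dimension mismatch: {sorted(shapes)}")

    if isinstance(model, CoefficientSet):
        zones, pfts = model.zones, model.pfts
        seen = None  # a bare coefficient set covers every combination
    else:
        zones, pfts = model.zones, model.pfts
        seen = model.seen_combos

    z = zone[mask].astype(np.int64)
    p = pft[mask].astype(np.int64)
    if z.size and (z.min() < 0 or z.max() >= len(zones)):
        raise ValueError(f"zone codes outside coefficient coverage (0..{len(zones)-1})")
    if p.size and (p.min() < 0 or p.max() >= len(pfts)):
        raise ValueError(f"PFT codes outside coefficient coverage (0..{len(pfts)-1})")

    fb = np.zeros(z.shape, dtype=bool)
    if seen is not None:
        seen_arr = np.zeros((len(zones), len(pfts)), dtype=bool)
        for zi, pi in seen:
            seen_arr[zi, pi] = True
        fb = ~seen_arr[z, p]
        p = np.where(fb, 0, p)  # reference-PFT offsets for unseen combos

    if isinstance(model, CoefficientSet):
        raw = model.mean_response(gb[mask], cci[mask], z, p)
    else:
        X = build_design(gb[mask], cci[mask], z, p, len(zones), len(pfts), model.spec)
        raw = X @ model.params

    neg_frac = float(np.mean(raw < 0)) if raw.size else 0.0
    out = np.full(gb.shape, np.nan)
    out[mask] = np.maximum(raw, 0.0)
    fb_raster = np.zeros(gb.shape, dtype=bool)
    fb_raster[mask] = fb
    return PredictionResult(out, neg_frac, fb_raster, int(fb.sum()))
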