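# Methods

## 1. The fusion calibration model

Two satellite GSV maps are fused by regressing plot-measured GSV on both map
values within a stratified linear model. For plot GSV $V$, map values $G$ and
$C$, zone index $z$ (six bioecological zones from forest-tundra to
forest-steppe) and plant functional type $p$ (evergreen needleleaf, deciduous
needleleaf, deciduous broadleaf, mixed forest):

$$
\mathbb{E}(V) = (a_{0,z} + b_{0,p}) + (a_{1,z} + b_{1,p})G
             + (a_{2,z} + b_{2,p})C + a_{3,z}\,GC
$$

- Zone coefficients are free per zone. PFT offsets use reference-level coding:
  the first PFT's offsets are fixed at zero, so each column block is full rank
  without dropping the zone intercepts.
- The $G\times C$ interaction carries per-zone coefficients only, by default.
  `ModelSpec(interaction_pft_offsets=True)` adds PFT offsets to it; with four
  PFTs and six zones the default already has 33 parameters, and in our
  synthetic experiments the extra three offsets were never selected by
  cross-validation, so the leaner form is the default.
- Predictions are truncated at zero (`max(0, Xβ)`). `PredictionResult`
  reports the pre-truncation negative fraction so truncation is never silent.
- Zone×PFT combinations absent from the training records fall back to the
  reference-PFT prediction for that zone; a boolean raster flags affected
  pixels and their count is reported.

### Assumptions

- Plot GSV is an unbiased (if noisy and heteroscedastic) measurement of pixel
  GSV: the model calibrates the maps toward the plots, so plot bias propagates
  directly into the result.
- Map error enters only through the conditional mean: the model corrects the
  maps' conditional bias given $(G, C, z, p)$, but does not deconvolve
  retrieval noise on the regressors (errors-in-variables attenuation is
  accepted, not removed).
- Plots and pixels refer to comparable GSV definitions after screening
  (standing live volume; snags removed when the source includes them).

## 2. Covariate-shift weighting

Plot samples rarely match the landscape's GSV distribution. Weights are the
ratio of landscape frequency to plot-sample frequency in fixed-width bins of
the first map's GSV:

- bins of 10 m³/ha over [0, 1000); values ≥ 1000 fall in the last bin;
- target bins with no calibration plots are merged into the nearest occupied
  bin (with a warning), so no landscape mass is dropped;
- weights are renormalised to mean 1, leaving effective sample size
  interpretable.

Weighted least squares then zeroes the weighted residual sum, i.e. the fit is
unbiased on average *under the landscape's* GSV distribution rather than the
sample's. The weights correct shift in the binning variable only; selection
effects that operate through other variables at fixed map GSV are not
corrected (this is demonstrated, not hidden, by the design of the
`weighting_efficacy` experiment below).

## 3. Screening

Rules are applied in a fixed order with first-violation attribution
(`screen`): forest-mask membership, plot-to-map-epoch year gap, optional
relative map/plot divergence. Defaults:

| rule | default | rationale |
| --- | --- | --- |
| `require_forest_mask` | on | plots outside the mapped forest cannot calibrate the maps |
| `max_year_gap` | 5 years | growth/disturbance decorrelates plot and map beyond ~half a decade |
| `relative_divergence_cap` | off | outlier capping distorts calibration of genuinely biased maps; available for QA |
| `divergence_floor` | 20 m³/ha | avoids flagging low-GSV plots where relative error is ill-defined |
| `exclude_snags_from_gsv` | on | maps see standing live biomass; snag volume is bookkept separately |

## 4. Model selection

Twenty-fold cross-validation (`cross_validate`) with balanced folds (sizes
differ by at most one; optional stratification). Candidates range from the
full stratified interaction model down to a pooled four-parameter model;
selection minimises out-of-fold MSE, ties broken by MAE then parsimony.
Candidates that fail to fit (rank deficiency) are marked, not silently
dropped. K=20 keeps each training set at 95% of the data, so the selected
complexity is close to what the full fit supports.

## 5. Uncertainty

Plot-resampling bootstrap (`bootstrap_regions`): resample plots with
replacement, refit the selected model, re-predict, and record per-region mean
densities; 95% intervals are percentile intervals. If weighting is on, the
weights are rederived inside each replicate so their sampling variability is
included. Rank-deficient replicates are redrawn, capped at 10% of B. Defaults:
B = 1000 for production; experiments and the acceptance script use B = 200,
which is sufficient for SE and 95%-percentile estimation at the tolerances
tested and keeps runtimes in minutes. Regional relative standard errors are
summarised as min/max/median and area-weighted mean.

## 6. Carbon accounting

`ConversionFactors` (all dimensionless ratios except as noted):

| factor | default | meaning |
| --- | --- | --- |
| `gsv_to_live_c` | 0.35035 t C/m³ | total live biomass carbon per stem volume |
| `gsv_to_agb_c` | 0.27923 t C/m³ | aboveground biomass carbon per stem volume |
| `gsv_to_agb` | 0.56131 t/m³ | aboveground biomass per stem volume |
| `root_to_shoot` | 0.288 | belowground:aboveground biomass |
| `houghton_gsv_to_agb` | 0.6859 t/m³ | comparison factor from the independent literature baseline |

`validate()` checks internal consistency (AGB carbon fraction ≈ 0.50).
Conversions are linear, so regional totals convert exactly to national totals
(`aggregate` conserves sums). Change rates against a historical baseline
(`change_rate`, `annual_rate_change`) keep full precision internally and round
only in `report()` (integer Tg, 2 decimal per-hectare rates).

## 7. The synthetic landscape generator

What it emulates:

- two *correlated* smooth GSV fields (Gaussian-filtered random fields with a
  tunable correlation length and inter-map signal correlation ~0.9), standing
  in for two retrievals of the same forest;
- ground truth defined as the fusion model applied to the *clean* signals
  with known coefficients (`default_true_coeffs`), making "generated exactly
  from known coefficients" well-defined and the model exactly recoverable;
- zone-dependent mean GSV (latitudinal bands, 40–220 m³/ha), PFT mosaics,
  administrative regions (grid blocks), a forest mask;
- map imperfections: per-zone/PFT multiplicative bias (default ±5%),
  additive retrieval noise (sd 20 m³/ha), and a saturation cutoff
  (default 300 m³/ha) emulating radar saturation;
- plot measurement error drawn from a Gamma distribution with mean equal to
  pixel truth and sd = 25 + 0.15·truth m³/ha — mean-preserving *and*
  nonnegative (a zero-floored Gaussian would bias low-GSV plot means upward
  and corrupt parameter-recovery experiments);
- snag volume as a Gamma-distributed fraction (mean 0.12) bookkept separately;
- plot campaigns over 2008–2019 with effort ramping up over time, and three
  sampling designs (uniform, zone-stratified, clustered with coverage gaps).

What it does **not** emulate: geolocation error, mixed pixels, seasonal or
phenological retrieval effects, disturbance between plot and map dates beyond
the year-gap screen, spatially correlated plot errors, and any geodesy — the
grid is row/column with a constant per-pixel area (0.5 ha default).

### Experiment fixtures (`benchmarks.py`)

Recovery and coverage fixtures set map noise, map bias, and the cutoff to
zero/∞ *by design, decided before the experiments were run*: those checks
concern bootstrap calibration of the mean model, and regressor noise would
confound them with the errors-in-variables attenuation the method does not
claim to remove. The weighting-efficacy fixture oversamples plots on the
first map's GSV (selection probability ∝ exp(G/40)) and uses a deliberately
curved truth fitted by a pooled linear candidate, so the unweighted fit has a
systematic area-mean bias that the weights are designed to remove.

## 8. Numerical choices

- Fitting uses `numpy.linalg.lstsq` on the √w-scaled system; rank deficiency
  is detected and the offending columns are *named* via pivoted QR
  (`scipy.linalg.qr`) rather than silently regularised.
- Heteroscedasticity is flagged with a Spearman rank correlation between
  |residual| and fitted value (no distributional assumptions).
- All seeds derive from a single integer through `numpy.random.SeedSequence`
  with per-stage indices; derived seeds are reduced mod 2³¹.
- Rasters are GeoTIFF-format TIFFs via `tifffile` with JSON metadata in the
  image description (nodata −9999, float32, labels for categorical layers).

## 9. Open design decisions

- **Binning variable.** Weights bin on the first map's GSV. Binning on the
  fused prediction would be self-referential; binning on both maps jointly
  fragments the sample. The first map is the primary calibration target.
- **Percentile vs basic bootstrap intervals.** Percentile intervals were
  chosen for positivity and simplicity; regional mean densities are close to
  symmetric at the sample sizes involved, where the two coincide.
- **Fallback for unseen strata.** Reference-PFT fallback (rather than refusing
  to predict or pooling zones) keeps the map complete while flagging every
  affected pixel.
- **Selection metric.** MSE primary, MAE tiebreak. ME is reported but not used
  for selection, since weighting already targets bias.

## 10. Limitations

- The calibration inherits plot-network biases the weighting cannot see
  (selection at fixed map GSV, geolocation mismatch).
- Errors-in-variables attenuation from map retrieval noise is not corrected;
  coefficients are calibrated for *these* maps' noise level and should not be
  ported to maps with different noise.
- Bootstrap intervals capture sampling variability of the plots, not
  structural model error or map-epoch mismatch.
- Carbon factors are fixed national averages; regional variation in wood
  density and carbon fraction is not modelled.
- The synthetic generator validates the statistical machinery, not the
  remote-sensing physics; real-map performance must be established on real
  plots.
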