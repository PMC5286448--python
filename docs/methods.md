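# Methods

## The problem

Annual gross primary productivity (GPP) of an ecosystem — the yearly
integral of its photosynthetic carbon uptake — varies from year to year
because the growing season shifts (phenology) and because the photosynthetic
machinery itself strengthens or weakens (physiology).  This package
separates the two.  From each year's seasonal GPP curve it extracts three
indicators:

* `GS_start` — the first day of year (DOY) on which the smoothed curve is at
  or above a threshold;
* `GS_end` — the last such day;
* `GPP_max` — the peak of the smoothed curve (g C m⁻² d⁻¹), the physiology
  indicator.

The threshold is 10 % of the *long-term mean* `GPP_max` of the pixel or
site, shared across all of its years, so phenology is measured against a
fixed bar.

## The anomaly regression (SMIPP)

Writing Δ for a year's departure from the record mean, and adopting the sign
convention that a season-start **advance** and a season-end **delay** are
positive, annual GPP anomalies are modelled as

    ΔGPP = η_start·ΔGS_start + η_max·ΔGPP_max + η_end·ΔGS_end + ε

and the sensitivities η are estimated per pixel/site by ordinary least
squares (with an intercept; mean-centred anomalies force it to ≈ 0, but it
protects the decomposition identity when years are dropped after centring).
The fit splits each year's anomaly into three additive components
η·Δ plus an OLS residual; the reconstruction identity
`ΔGPP = intercept + Σ components + residual` holds to machine precision by
construction.  The three predictors are assumed (and per-record checked, via
pairwise R²) to be approximately independent; correlation is reported but
never corrected for, and the fit is plain OLS — no regularisation, no
robust variants.

A minimum of 5 usable years is required (4 parameters need at least one
residual degree of freedom); years flagged invalid at extraction are
excluded listwise.

## Smoothing

* **8-day gridded data** (46 composites/year, composite *k* starting at DOY
  8(k−1)+1, the last covering 5 days): a degree-6 polynomial in DOY fitted
  by least squares to the composite mid-points (start DOY + 3.5).  The
  predictor is mapped affinely onto [−1, 1] before powers are formed — raw
  DOY⁶ ≈ 2×10¹⁵ destroys the conditioning of the design — and coefficients
  are stored in that scaled basis with the transform recorded.
* **Daily site data**: singular spectrum analysis — Hankel trajectory matrix
  with a 120-day embedding window, SVD, reconstruction from the 4 leading
  eigentriples (counted singly, not as paired groups) by anti-diagonal
  averaging.  The window length is a free choice: ≥ one season, ≤ N/3,
  standard SSA practice; it and the component count are config-exposed.

Missing data: ≤ 20 % of a year may be missing — omitted from the polynomial
design, linearly interpolated before SSA; beyond that the year is flagged
unusable.  Negative smoothed values are retained in the stored curve and
clamped to zero only at indicator extraction, keeping the fit faithful while
preventing negative "crossings".

### Crossing rule

Degree-6 polynomial fits of a dormant-winter seasonal cycle ring at the year
edges: on the canonical synthetic bump the fitted curve carries a winter
side lobe of ≈ 11 % of the peak near DOY 25 — above the 10 % threshold.  A
literal "first day above threshold anywhere in the year" rule therefore
reports midwinter season starts.  The default rule instead takes the
contiguous at-or-above-threshold run that contains the seasonal peak; the
literal whole-year rule remains available (`crossing_rule: whole_year`) for
curves known to be clean.  Crossings are reported at whole-day resolution
(no sub-daily interpolation: indicator noise dwarfs interpolation
precision); ties at the maximum break to the earliest day; for polynomial
curves the peak search is restricted to DOY 15–350 to avoid the diverging
tails.  A year whose peak falls outside its own detected season, or whose
curve never reaches the threshold, is flagged invalid rather than filled.

## Attribution

* **Trend mode**: each component series gets an OLS trend
  (`Slope_start/max/end`); component *x* contributes
  `c_x = 100·sign(Slope_x·Slope_GPP)·|Slope_x| / Σ|Slope|` percent, so the
  absolute contributions sum to 100.
* **IAV mode**: consistency-weighted shares
  `c_x = 100·Σᵢ component_x,i·sign(Ĝᵢ) / Σᵢ|Ĝᵢ|`, where Ĝ is by default the
  reconstructed anomaly (the per-year sum of the three components) — signed
  shares then sum to exactly 100.  Judging consistency against the observed
  ΔGPP instead is a config option (`iav_reference: observed`); closure is
  then only approximate, the residual absorbing the rest.

Trend p-values use a plain two-sided t test with no autocorrelation
correction (the records are ~15 annual points).  All-zero slopes or a zero
reference anomaly yield an "undefined" flag, not an exception.  Spatial
correlations between trend maps treat pixels as observations (plain Pearson,
≥ 10 jointly finite pixels).

## Climate sensitivity

`GS_start` and `GS_end` are regressed on the mean temperature (or other
climate variable) of the 30 days preceding their own *long-term mean* dates
— windows fixed across years, anchored to the record mean rather than each
year's date, so that indicator noise cannot leak into the predictor.
`GPP_max` uses June–August aggregates (DOY 152–243 on the fixed calendar);
precipitation defaults to mean *monthly* JJA totals (season total / 3),
temperature and radiation to plain means.  Sensitivity is Pearson r plus the
OLS slope in raw calendar units — a spring advance with warming appears as a
*negative* slope; the "days earlier per °C" reading is applied only in
reporting.  Partial correlations (indicator vs one climate variable,
controlling the other two) are residual-on-residual Pearson r with p from a
t distribution on n − 4 degrees of freedom.

## Calendar

All series live on a fixed 365-day year; leap days are dropped on ingest and
DOYs after Feb 28 in leap years shift back one day.  This matches the 8-day
composite layout (45 × 8 + 5 days) and keeps DOY arithmetic exact.

## The synthetic generator

The generator emulates the two data families the pipeline targets — a
gridded 8-day GPP product with co-registered daily reanalysis-style climate,
and daily flux-tower-style site records — with bit-defined ground truth.

* **Curve family**: a symmetric sine-power bump (exponent 2) whose support
  half-width is solved analytically so the curve equals exactly 10 % of its
  peak at `gs_start` and `gs_end`.  Threshold-crossing truth is therefore
  exact, not itself estimated.  Annual-GPP truth is the exact sum of the
  noise-free daily curve.
* **Year model**: indicator = mean + trend·t + temp_sens·A_t + N(0, iav_sd),
  with A_t the year's own window-temperature anomaly.
* **Climate**: daily temperature is a fixed seasonal sinusoid (mean 8 °C,
  amplitude 14 °C, peak mid-July) plus the per-year window anomalies
  (SD 1.5 °C) that drive the couplings; precipitation is daily Gamma noise;
  radiation a sinusoid plus noise.  Each constant preseason anomaly extends
  5 days beyond its 30-day window on either side: real anomalies persist
  rather than switching off at a window edge, and the padding keeps coupling
  recovery unbiased when the recovered mean dates anchoring the aggregation
  windows are off by a day or two.  The JJA window is fixed by the calendar
  and needs no padding.
* **Defaults** describe a temperate/boreal pixel: season DOY 120–280, peak
  8 g C m⁻² d⁻¹, 15-year record, couplings −1.9 d °C⁻¹ (start), +1.7 d °C⁻¹
  (end), +0.33 g C m⁻² d⁻¹ °C⁻¹ (peak), indicator IAV 3 d / 3 d /
  0.4 g C m⁻² d⁻¹, observation noise 0.5 g C m⁻² d⁻¹.
* **Not emulated**: spatial autocorrelation between pixels, non-Gaussian
  GPP noise, drought or disturbance years, evergreen (never-dormant)
  seasonal cycles, bimodal seasons.  Passing recovery tests therefore shows
  the estimation machinery is correct and well-calibrated under these
  conditions; it does not validate the indicators against real phenology.

## Recovery experiments

Two standard experiments (`smipp.experiments`) benchmark the chain:

* **Coefficient recovery** — 500 cells × 15 years of anomaly tables with
  generating sensitivities (2.9, 95.9, 2.4), indicator anomaly SDs
  (5 d, 0.5 g C m⁻² d⁻¹, 5 d), and Gaussian noise calibrated analytically so
  per-cell R² ≈ 0.98; per-cell OLS fits are pooled.  Ensemble means agree
  with the generating values to well within 2 Monte-Carlo standard errors.
* **Preseason-coupling recovery** — 20 sites × 15 years (300 site-years) run
  through the *full* daily pipeline (bump generation with couplings
  −1.9/+1.7 d °C⁻¹, observation noise, SSA, extraction, preseason
  aggregation, regression).  Recovered mean slope magnitudes carry a small
  (≲ 3–5 %) systematic imprint of smoothing and day-resolution extraction —
  an honest property of the estimation chain, well inside the experiment's
  Monte-Carlo error.

Problem sizes (500 cells, 300 site-years, 4×4 determinism grids) are the
experiments' standard conditions; they run in seconds on one CPU.

## Numerical choices

* OLS everywhere via `statsmodels` / `scipy.stats.linregress`; SVD via
  `scipy.linalg.svd`.  SSA reconstruction is invariant to singular-vector
  sign ambiguity.
* Degenerate designs raise typed errors naming the offending predictor;
  undefined contributions (all-zero slopes/anomalies) are flagged, not
  raised.
* Run manifests hash the scientific content (resolved config minus output
  locations, content digests of each product, library versions), so a seeded
  run is reproducible by hash.

## Known limitations

* The polynomial smoother biases `GPP_max` low (≈ 8 % on the canonical
  bump: a degree-6 polynomial cannot match a flat-dormant/sharp-peak cycle)
  and its phenology dates by a few days.  These biases are stable across
  years, so anomalies — and everything built on them — are far less
  affected than levels.
* Day-resolution crossings quantise phenology to whole days.
* The IAV share formula credits a component positively within a year when it
  agrees in sign with the total anomaly; a component that is large but
  oscillates against the total can receive a negative share — by design.
* No latitude/area weighting in regional summaries; p-values are reported
  per pixel without multiple-testing control.
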