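# smipp

Phenology/physiology decomposition of annual gross primary productivity
(GPP).

Annual GPP — the yearly carbon uptake of an ecosystem, g C m⁻² yr⁻¹ —
fluctuates both because the growing season shifts (phenology) and because
peak photosynthesis strengthens or weakens (physiology).  `smipp` implements
a complete, tested pipeline that disentangles the two for gridded 8-day GPP
products (satellite-style) and daily site records (flux-tower-style):

1. **Smooth** each year's seasonal curve — a degree-6 polynomial in day of
   year for 8-day composites, singular spectrum analysis (SSA, 120-day
   window, 4 components) for daily series.
2. **Extract indicators** per year: growing-season start and end
   (`GS_start`, `GS_end`: first/last day at or above 10 % of the long-term
   mean peak) and the peak daily GPP (`GPP_max`).
3. **Fit the SMIPP** (Statistical Model of Integrated Phenology and
   Physiology): with anomalies Δ signed so a start *advance* and an end
   *delay* are positive,

   ΔGPP = η_start·ΔGS_start + η_max·ΔGPP_max + η_end·ΔGS_end + ε,

   estimated by OLS per pixel/site.  The η are the sensitivities of annual
   GPP to each indicator; the fit splits every year's anomaly into three
   additive components.
4. **Attribute** the long-term trend and the inter-annual variability (IAV)
   of annual GPP to the three components (signed percentage shares; absolute
   trend shares and signed IAV shares each close to 100 %).
5. **Relate indicators to climate**: correlation, OLS slope and partial
   correlation against preseason (30 days before the mean start/end dates)
   and summer (June–August) temperature, precipitation and radiation.

A synthetic-data generator with bit-defined ground truth (analytic
threshold crossings, exact annual integrals, prescribed trends, IAV and
temperature couplings) drives the test suite and the recovery benchmarks —
no external data are needed.  See `docs/methods.md` for the model details
and design choices.

## Worked example

Run the full daily-site pipeline on a synthetic 15-year record (the default
generator conditions: season DOY 120–280, peak 8 g C m⁻² d⁻¹, temperature
couplings −1.9 d °C⁻¹ on the start and +1.7 d °C⁻¹ on the end):

```python
from smipp import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(mode="site", seed=42, out_dir="demo"))
fit = bundle["result"]["fit"]
print(fit.eta_start, fit.eta_max, fit.eta_end, fit.r_squared)
```

prints (one 15-year site, so sampling noise is visible):

```
eta_start=4.10 eta_max=83.5 eta_end=5.34 r2=0.957
trend shares: 51.7 -37.2 11.1
iav shares:   21.4 81.8 -3.2
indicator     climate      r  slope  p_value  n
 gs_start temperature -0.694 -2.230    0.004 15
  gpp_max temperature  0.923  0.383    0.000 15
   gs_end temperature  0.525  1.412    0.044 15
```

Reading: a 1 g C m⁻² d⁻¹ higher peak adds ≈ 84 g C m⁻² to that year's GPP,
one day of earlier start ≈ 4 g C m⁻², one day of later end ≈ 5 g C m⁻²; the
model explains 96 % of the year-to-year variance, and the peak component
carries ~82 % of it.  The negative `gs_start` slope means the season starts
2.2 days *earlier* per °C of preseason warming; the positive `gs_end` slope
means a later end under autumn warming.

The same analysis runs from the shell:

```sh
smipp run --seed 42 --out demo               # end-to-end with defaults
smipp simulate grid --seed 7 --out sim       # synthetic 8-day grid + truth
smipp indicators --input sim/gpp.nc --out ind.csv
smipp fit --indicators ind.csv --out fits.csv
```

Grid mode writes per-pixel maps (`fits.nc`: η, R², p-values, trends,
trend/IAV contribution shares, climate sensitivities) and every run writes a
`manifest.json` whose hash is reproducible for a fixed seed.

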