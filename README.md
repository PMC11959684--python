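# traitsort

Trait-based analysis of long-term phytoplankton community change: from dated
per-taxon biovolume records and Monod resource-acquisition traits to annual
community compositions, community mean traits, trait–environment trends, and
the standardised-major-axis trade-off fits that reveal **emergent
trade-offs** — trait associations that are weak across a species pool but
strong once each trait combination is weighted by the biomass of the
organisms carrying it.

## The scientific problem

Lakes that eutrophied and then recovered expose their phytoplankton to an
order-of-magnitude swing in phosphorus supply over a few decades.  If
community assembly is driven by resource competition, the biomass-weighted
mean traits of the community should track that swing: nutrient-poor years
select for phosphate affinity, nutrient-rich years (with their denser,
self-shading phytoplankton crops) for light affinity.  `traitsort`
implements the full analysis chain needed to test this on monitoring data,
plus a mechanistic synthetic-data generator so that every stage can be
validated against known ground truth.

The building blocks, in the field's standard notation:

* **Monod growth kinetics.**  Specific growth under phosphate or light
  limitation is

  μ_P = μ_max · P / (μ_max/γ + P),  μ_I = μ_max · I / (μ_max/α + I)

  with maximum growth rate μ_max (d⁻¹), phosphate affinity γ
  (L μmol⁻¹ d⁻¹) and light affinity α (μmol quanta⁻¹ m²).  The
  half-saturation constants are k_P = μ_max/γ and k_I = μ_max/α.
  Missing trait values are imputed as geometric means over the nearest
  measured relatives, walking genus → family → order → class → phylum.

* **Annual compositions.**  Biweekly biovolume records B_it are linearly
  interpolated to a daily series, relative biovolumes b_it = B_it/B_t are
  formed per day, and everything is averaged over the 365/366 days of each
  year, giving B_y, b_iy, class shares g_jy and the long-term average
  shares b̄_i.  Taxa with cell volume < 30 μm³ are excluded (small cells
  were inconsistently identified early in long monitoring series).

* **Community mean traits.**  Because traits are log-distributed,

  CMT_y = exp( Σ_i ln τ_i · b_iy )

  — the biovolume-weighted geometric mean of trait τ across the community.

* **Inference.**  Trait–environment trends use Prais–Winsten regression
  (GLS for AR(1) errors, first observation retained via the √(1−ρ²)
  transform); compositional change is summarised by covariance PCA of the
  year × class share matrix; significance of trait–environment and
  trait–trait associations is additionally assessed by a permutation null
  that reassigns complete trait triples to taxa and recomputes the CMT
  series.

* **SMA trade-off fits.**  Standardised major axis lines
  (slope = sign(r)·SD_y/SD_x) between log traits at three integration
  levels: unweighted unique phenotypes, phenotypes weighted by b̄_i, and
  the across-year CMT series.  Axis scores and biovolume-weighted
  percentiles locate community biomass along the trade-off axis.

## Worked example

```python
import numpy as np
import traitsort as ts

cfg = ts.SyntheticConfig(seed=1)           # 150 taxa, 1966-2007, sorting on
ds = ts.generate_dataset(cfg)

obs, report = ts.filter_small_cells(ds.observations)       # drop cells < 30 um^3
comp = ts.annual_compositions(obs)                         # daily interp -> b_iy
cmt = ts.cmt_series(ds.traits, comp)                       # weighted geometric means

tp = ds.environment.series().loc[comp.years].to_numpy()
fit = ts.prais_winsten(tp, np.log(cmt.values["gamma"].to_numpy()))
print(f"excluded {100*report.fraction_taxa_excluded:.1f}% of taxa "
      f"holding {100*report.mean_biovolume_share:.1f}% of biovolume")
print(f"CMT phosphate affinity vs TP_mix: R_pw = {fit.r_pw:.2f}, "
      f"P_pw = {fit.p_value:.1e}, rho = {fit.rho:.2f}")

levels = ts.sma_three_levels(ds.traits, comp, "gamma", "alpha")
for name, f in levels.items():
    print(f"SMA ln(alpha) ~ ln(gamma) [{name:10s}]  slope = {f.slope:+.2f}  "
          f"R2 = {f.r2:.3f}")
```

prints

```
excluded 7.3% of taxa holding 1.8% of biovolume
CMT phosphate affinity vs TP_mix: R_pw = -0.92, P_pw = 1.6e-17, rho = -0.01
SMA ln(alpha) ~ ln(gamma) [membership]  slope = -1.03  R2 = 0.164
SMA ln(alpha) ~ ln(gamma) [weighted  ]  slope = -1.38  R2 = 0.100
SMA ln(alpha) ~ ln(gamma) [cmt       ]  slope = -1.58  R2 = 0.896
```

Read this as: the community mean phosphate affinity falls sharply in
nutrient-rich years (R_pw = −0.92), and while only 16% of the variance
among pool members links the two affinities, the across-year community
means trade off almost perfectly (R² = 0.90) — the emergent trade-off.

The same chain runs from the shell on CSV inputs:

```bash
traitsort generate --out data/ --seed 1
traitsort run --config run.yaml          # see tests/test_cli.py for the layout
traitsort report --results out/
```

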