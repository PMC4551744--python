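# spatind

Spatial indicators and indicator variography for acoustic-survey fish
density data.

Small pelagic fish (anchovy, sardine) aggregate into patches whose
geometry — where the population sits, how much area it occupies, how
concentrated it is, how much two species overlap — carries information
about stock status beyond the biomass total.  `spatind` implements the
survey-based toolkit used to quantify that geometry from EDSU-resolution
acoustic data (1-nmi Elementary Distance Sampling Units, each with a
density `z` in t/nmi² and an area of influence `s` in nmi²), and the
multivariate stage that links biomass to the resulting suite of spatial
indicators.  It is aimed at fisheries-acoustics and spatial-ecology
practitioners working with georeferenced survey tables.

## What it computes

All quantities weight each sample by its area of influence
(`wᵢ = zᵢsᵢ`, `Q = Σwᵢ`):

| Indicator | Definition | Feature |
|---|---|---|
| Centre of gravity | `Σwᵢ(xᵢ,yᵢ)/Q` | location |
| Inertia / isotropy | `Σwᵢ‖pᵢ−CG‖²/Q`; `√(λ₂/λ₁)` | dispersion |
| Number of major patches | sequential 20-nmi patches holding >10% of `Q` | patchiness |
| Positive area (PA) | `Σsᵢ 1{zᵢ>0}` | occupation |
| Spreading area (SA) | `(2/Q)Σᵢsᵢ(Q−Qᵢ+wᵢ/2)`, ranked by density | aggregation |
| Equivalent area (EA) | `Q²/Σzᵢ²sᵢ` | aggregation |
| Global index of collocation | `1 − ΔCG²/(ΔCG²+I₁+I₂)` | two-species overlap |
| Packing density | `Q/PA` | aggregation |
| Biomass | `Σzᵢsᵢ` (or per-transect means × transect areas) | abundance |

On top of the indicators, the package performs **indicator variography**:
the density cut-off `c80` capturing 80% of total biomass is found from the
ranked cumulative abundance curve, the field is binarized at `z ≥ c80`,
and a nugget + spherical model `γ(h) = c₀ + c₁(1.5h/a − 0.5(h/a)³)` is fit
to the omnidirectional empirical semivariogram — the fitted range `a`
approximates the mean high-density patch size, and the normalized nugget
`100·c₀/(c₀+c₁)` measures small-scale roughness.

The **multivariate stage** divides each indicator by its
(species, sub-area) mean (except patch count and CG), runs
correlation-matrix PCA with standardized biomass and packing density as
supplementary variables, and regresses standardized biomass on the leading
PC scores by forward stepwise OLS (F-to-enter 0.05).

Because raw EDSU tables from real surveys are rarely shareable, the
package ships a **synthetic survey generator**: zero-inflated lognormal
density fields with spherical spatial correlation, sampled on parallel
transects, with recorded ground truth (range, occupancy, biomass, CG) for
parameter-recovery testing.

## Worked example

Simulate a two-area, eight-year panel in which biomass and occupied
fraction rise together, then run the whole chain:

```yaml
# demo.yaml
output: demo_out
seed: 7
simulate:
  years: [2001, 2002, 2003, 2004, 2005, 2006, 2007, 2008]
  base:
    extent: [50.0, 30.0]
    transect_spacing: 5.0
    variogram_range: 10.0
    occupied_fraction: [0.30, 0.34, 0.39, 0.43, 0.47, 0.51, 0.56, 0.60]
    total_biomass: [5000, 5500, 6100, 6700, 7400, 8200, 9050, 10000]
  areas:
    S1: {}
    G1: {variogram_range: 6.0}
```

```sh
$ spatind run --config demo.yaml
[spatind] simulated 16 surveys in 0.1s
[spatind] indicators + variography for 32 slices in 0.2s
[spatind] pooled analyses (4) in 0.1s
[spatind] done in 0.4s -> demo_out
```

`demo_out/indicators.csv` holds one row per species × area × year:

```
species sub_area  year  biomass  positive_area  spreading_area  equivalent_area  n_major_patches  gic  range_nmi  nugget_pct
anchovy       G1  2001   5000.0          335.0          205.26           216.96                2 0.93       4.33       32.65
sardine       G1  2001   5000.0          540.0          281.04           258.65                2 0.93      29.00       53.28
anchovy       G1  2002   5500.0          695.0          401.93           415.95                3 0.99       4.18       33.40
sardine       G1  2002   5500.0          525.0          217.15           177.67                2 0.99       6.97       49.25
```

Reading the first row: in 2001 the anchovy stock in area G1 occupied
335 nmi² but would cover only ~217 nmi² at its mean per-individual density
(EA < PA: the population is concentrated within its area of presence),
formed 2 major patches, overlapped strongly with sardine (GIC 0.93), and
its high-density aggregations had a fitted autocorrelation range of
4.3 nmi.

`demo_out/models/species_anchovy.json` shows the pooled-anchovy stepwise
model of standardized biomass on PC scores:

```json
{"selected": ["PC1"], "coefficients": {"intercept": 1.000, "PC1": 0.0936},
 "r_squared": 0.598, "entry_pvalues": {"PC1": 0.000445}}
```

PC1 — which carries positive loadings for occupation and aggregation
(PA, SA, EA, patch count; see `demo_out/pca/species_anchovy.json`) — enters
with a positive coefficient: years of higher biomass are years of wider
occupation and more, larger patches, which is exactly the coupling the
generator built in.

The same stages are available piecewise (`spatind simulate`,
`spatind indicators`, `spatind variogram`, `spatind pca`,
`spatind regress`) and as library functions (`spatind.indicators`,
`spatind.variogram`, `spatind.multivariate`, `spatind.simulate`).

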