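# Methods

## Scope and data model

`spatind` analyses acoustic-survey fish density at EDSU (Elementary
Distance Sampling Unit, 1 nmi) resolution.  Each record carries a position
(WGS84 lon/lat), a per-species density `z` (t/nmi²) and an area of
influence `s` (nmi²) — the surface the sample represents.  Every spatial
integral in the package is the weighted sum `Σ z·s`, so irregular survey
sectors are handled through the weights, never by resampling.

Coordinates are projected to planar nautical miles with a local
equirectangular projection about the dataset mean position:
`x = (lon − lon₀)·60·cos(lat₀)`, `y = (lat − lat₀)·60`.  One minute of
latitude is one nautical mile by definition; the `cos(lat₀)` factor makes
the x scale locally metric.  At the ≤ 200 nmi extents of shelf surveys the
planar distance agrees with the great-circle distance to well under 1%
(property-tested for pairs ≤ 30 nmi apart at |lat| ≤ 60°).  Origins at
±90° latitude are rejected.  No named geodetic projection is implied by the
indicator definitions themselves; the equirectangular choice is a
documented package assumption, and the inverse transform is exact.

## Spatial indicators

For one (species, sub-area, year) slice with positions `(xᵢ, yᵢ)`,
densities `zᵢ` and weights `sᵢ` (abundance `wᵢ = zᵢsᵢ`, total `Q = Σwᵢ`):

* **Centre of gravity** `CG = Σwᵢ(xᵢ,yᵢ)/Q`; reported both in projected nmi
  and, via the inverse projection, in degrees.  Undefined (raised) when
  `Q = 0` — never silently (0, 0).
* **Inertia** `I = Σwᵢ‖(xᵢ,yᵢ) − CG‖²/Q` (nmi²), and **isotropy**
  `√(λ₂/λ₁)` from the eigenvalues `λ₁ ≥ λ₂` of the weighted covariance of
  positions (`λ₁ + λ₂ = I`).  A point population is defined maximally
  isotropic (isotropy 1).  `λ₂` is clipped to zero when `λ₂ < 10⁻¹² λ₁`:
  for exactly collinear populations the square root would otherwise amplify
  eigenvalue rounding noise to the 1e-9 scale.
* **Positive area** `PA = Σ sᵢ 1{zᵢ > 0}`.  Strict positivity, no density
  floor.
* **Spreading area** `SA = (2/Q)·Σᵢ sᵢ(Q − Qᵢ + wᵢ/2)` over samples ranked
  by decreasing density with cumulative abundance `Qᵢ` — the discrete form
  of `2∫(Q − Q(T))dT/Q` along the area-cumulated abundance curve.
* **Equivalent area** `EA = Q²/Σzᵢ²sᵢ`.
* **Packing density** `Pck = Q/PA`.
* **Patches**: positive samples processed in decreasing density order
  (ties keep input order).  The densest sample founds patch 1; each next
  sample joins the nearest patch centre if within `dlim` (default 20 nmi,
  distance ties to the lowest patch index), else founds a new patch.
  Centres are abundance-weighted and updated incrementally, so membership
  is judged against the centre *at assignment time*; final-centre
  membership could differ, which is why the naive cross-check recomputes
  centres from scratch at every step instead of incrementally.  The major
  patch count retains patches holding strictly more than 10% of `Q`
  (configurable; the strict inequality follows the ">10%" convention).
* **Global index of collocation** between two populations sharing one
  projection: `GIC = 1 − ΔCG²/(ΔCG² + I₁ + I₂)`.  Boundary behaviour: two
  distinct point populations give 0; coincident CGs give 1, including the
  degenerate case ΔCG = I₁ = I₂ = 0 (two coincident point populations),
  defined as 1.
* **Biomass**: `edsu` estimator `Q = Σzᵢsᵢ`, or `transect` estimator
  `Σₜ mean(z in t)·Sₜ` with `Sₜ` the summed member areas; the two coincide
  when EDSU areas are equal within each transect.

Useful ordering facts, enforced in tests: `EA ≤ PA` and `SA ≤ PA` always
(Cauchy–Schwarz / concavity of the cumulated-abundance curve), with
equality exactly for uniform density on the support; `EA ≤ SA` does **not**
hold in general (counterexample `z = {3,1}, s = {1,1}`: EA = 1.6,
SA = 1.5), so it is deliberately not asserted.

## Indicator variography

High-density structure is isolated by the abundance cut-off `c80`: samples
are ranked by decreasing density, abundance is cumulated, and the cut-off
is the density of the first rank at which ≥ 80% of `Q` is captured.
Because the cut-off equals an observed density, indicator membership uses
`z ≥ c80` — a strict inequality would drop the defining sample and capture
less than the target share.  A strict mode is available.

The omnidirectional empirical semivariogram of the binary field uses all
unordered pairs binned by distance only, `γ(h) = Σ(Iᵢ−Iⱼ)²/2N(h)`, with
1-nmi bins (the EDSU spacing) centred at multiples of the width, and a
default maximum lag of half the maximum inter-sample distance.  Pairs are
unweighted: areas of influence weight the indicators, not the pair counts.
Directional variograms are not modelled; anisotropy in the generator is
exercised through directional range checks in the tests instead.

The nugget + spherical model
`γ(h) = c₀ + c₁(1.5h/a − 0.5(h/a)³)` for `h < a`, `c₀ + c₁` beyond, is fit
by pair-count-weighted least squares: a grid over the range `a` at half
lag-width resolution with non-negative linear least squares for `(c₀, c₁)`
at each candidate, followed by bounded scalar refinement.  This is
deterministic and derivative-free, which matters because the objective is
only piecewise-smooth in `a`.  The model is taken as 0 at `h = 0` exactly
(the nugget is the limit from the right); the zero-lag bin holds only
co-located pairs and is normally empty on 1-nmi EDSU tracks.  A flat
variogram fits with `c₁ → 0` and is flagged degenerate with normalized
nugget 100%.  The normalized nugget is `100·c₀/(c₀+c₁)`.

A noiseless model curve is recovered to 1e-6; on simulated spherical
fields (range 10 nmi, no nugget, ~1000 EDSUs on 5-nmi transects) the
fitted indicator range lands within ±30% of truth in ≥ 80% of seeds.  The
indicator transform preserves the range location because the spherical
correlation has compact support — indicator correlation vanishes exactly
where the latent correlation does — though the indicator variogram's shape
near the range differs from spherical, which is the main source of the
remaining scatter.

## Synthetic survey generator

The generator emulates what the indicators respond to in real surveys:

* parallel north–south transects (5 or 10 nmi apart) of 1-nmi EDSUs, each
  with `s = transect_spacing × edsu_spacing` (interior and edge alike);
  the track serpentines like a real vessel, which affects only row order;
* zero inflation: a probit occupancy field `G₂` thresholded at
  `Φ⁻¹(1 − p_occ)` leaves a fraction `p_occ` occupied in expectation;
* right-skewed positive densities: `z = exp(m + σG₁)` on occupied EDSUs;
* spatial autocorrelation: `G₁, G₂` are Gaussian fields with correlation
  `(1−η)·sph(h; a) + η·1{h=0}` on the sample locations, with the x-lag
  scaled by `1/anisotropy_ratio`; the covariance is factorized densely
  (Cholesky with 1e-10 jitter), exact but limited to ≈ 4000 EDSUs;
* per-species substreams at fixed offsets from one seed; a
  `latent_correlation` mixes the white noise of later species with the
  first species' stream before spatial correlation is applied, giving
  cross-species dependence with unchanged marginals; within a species the
  intensity and occupancy fields are independent;
* centre-of-gravity shifts via a linear tilt of the log-mean with slope
  `shift/Var(coordinate)` (the small-tilt approximation of the CG
  displacement); the realized CG is recorded in the ground truth rather
  than forced;
* exact rescaling so `Σz·s` equals the target biomass to 1e-9.

Defaults (60 × 40 nmi extent, 5-nmi transects, range 10 nmi, `σ = 1`,
`p_occ = 0.7`, 10 000 t) sit in the middle of the survey geometries and
patch sizes the indicator suite was designed around.  Multi-year panels
share one layout and reuse the Cholesky factor when correlation parameters
do not change.  `coupled_panel_configs` builds panels in which total
biomass rises geometrically while the occupied fraction rises linearly —
the abundance–occupation coupling that the multivariate stage should
recover — with year order shuffled per area so the coupling is
cross-sectional, not a time trend.

What the generator does **not** emulate: school-level (sub-EDSU)
structure, day/night behaviour, coastline-driven irregular designs
(irregularity can be exercised by masking EDSUs), or non-lognormal density
bodies.  Passing tests therefore demonstrate that the estimators recover
the structure of transformed-Gaussian fields sampled on regular transects;
they do not certify behaviour on survey features outside that model.

## Multivariate stage

Each indicator is divided by its (species, sub-area) mean — so pooled rows
are comparable across stocks of very different absolute scale — except the
number of major patches and the CG coordinates, which stay in natural
units (CG enters in degrees).  Standardized biomass and packing density
are supplementary.

PCA runs on the Pearson correlation matrix of the active columns
(eigenvalue sum = number of variables).  Loadings are variable–score
correlations (`eigenvector·√eigenvalue`); supplementary variables are
projected by correlating them with the scores.  Significance of a loading
or supplementary correlation uses the two-sided correlation t-test with
`n − 2` degrees of freedom at α = 0.05; with 4–9 years per cell, `n` is
small and these tests are indicative, as they are in the source software
conventions for this kind of analysis.  Components are oriented so the
largest-|loading| variable loads positively, making signs reproducible
(they are otherwise arbitrary).  With fewer rows than variables the
trailing eigenvalues are exactly zero; their scores are zero vectors and
are excluded from orthogonality checks.

The regression stage selects the leading axes jointly covering ≥ 85% of
variance (capped at 5) and applies forward stepwise OLS with F-test
p-to-enter 0.05.  Because scores are orthogonal, the selected set equals
the individually significant axes and coefficients equal their univariate
estimates; no removal step is needed.  An intercept-only outcome is valid
and flagged.  Note the familywise property of forward selection under the
null: with K candidate axes the empty-model probability is ≈ 0.95^K.

Pooled analyses run per species (across areas) and per area (across
species); standardization always happens within (species, sub-area) cells
before pooling.  Poolings with fewer than 4 rows are skipped with a
warning.

## Pipeline and reproducibility

`run_pipeline` executes simulate (or CSV ingest) → indicators →
variography → pooled PCA/regression, writing CSV/JSON artifacts plus a
manifest (config echo, seed, row counts, warnings).  A failing slice
(e.g. zero abundance) is logged and skipped, not fatal.  One seed controls
all randomness; per-(area, year) seeds are fixed arithmetic offsets, so
reruns with the same config are bit-identical.  Survey CSVs store the
projected coordinates; on re-read the projection origin is recovered from
them so downstream planar quantities do not shift.

Problem sizes used by the test suite — ~300–1100 EDSUs per survey, 50-seed
Monte-Carlo sweeps, 8-year two-area panels — are desk-scale choices that
keep the full chain exact (dense covariance factorization) while
exercising every stage; the generator documents its ≈ 4000-EDSU dense
limit.

## Known limitations

* The equirectangular projection is inappropriate poleward of ~70° or for
  basin-scale extents; no geodesic computations are provided.
* The empirical-variogram estimator and the spherical fit are one
  reasonable convention (1-nmi bins, pair-count weighting, grid+refine);
  published range/nugget values obtained with other variography software
  need not agree numerically.
* Patch identification is sequential and order-dependent by design; it is
  a hotspot-counting device, not a clustering optimum.
* The stepwise F-to-enter procedure inherits the usual caveats of stepwise
  selection; with orthogonal predictors it reduces to per-axis testing,
  which is the only setting used here.
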