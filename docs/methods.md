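# Methods

`fcp` implements a bottom-up workflow for estimating how much carbon forests
hold today, how much they could hold without human land use, and how the gap
between the two splits into conservation and restoration opportunities. The
whole chain is exercised end-to-end on a synthetic world whose potential
carbon surface and degradation response are known exactly, so every stage has
a quantitative acceptance surface.

## Tree and plot carbon

Individual aboveground dry biomass follows the log–log allometry

    ln W = β0 + β1 ln DBH,

with W in kg and DBH (stem diameter at breast height) in cm. Biome-level
coefficients are obtained by *back-calculation*: each source equation is
evaluated on a fixed pseudo-DBH grid — every 1 cm from 5–25 cm, every 5 cm to
100 cm, every 10 cm to 300 cm (56 points; shared endpoints belong to the
finer bin, a convention this package fixes because range boundaries alone do
not determine ownership) — and an OLS fit of ln W on ln DBH over the pooled
pseudo-data yields the biome equation. Tropical trees can instead use a
wood-density power law `W = a (ρ·DBH²)^b` with configurable coefficients
(default a = 0.0673, b = 0.976); missing densities fall back to a biome
median and are logged.

Plot carbon density (t C ha⁻¹) sums tree biomass over the plot, divides by
plot area, multiplies by a biome wood-carbon fraction (defaults anchored at
the published endpoints: 0.456 tropical, 0.501 temperate, 0.47 elsewhere) and
averages multi-year plots with equal weight per calendar year. Screening
removes densities above 1,867 t C ha⁻¹ (the densest forest on record) and
values outside median ± 2.5 × MAD per biome, computed on ln(x+1)-transformed
densities with the *raw* MAD (no 1.4826 consistency constant — the rule is
stated directly in units of MAD). Low-side outliers are retained in
human-modified non-forest pixels (human-disturbance index > 10%, canopy
< 10%) so that trees outside forests are not discarded. The natural log is
used in the transform; the filter is base-invariant, but a fixed convention
keeps results reproducible.

## Plot → pixel

A plot samples the forested part of its pixel, so pixel-scale carbon is
`C_pixel = C_plot / canopy_plot × canopy_pixel`. Two within-plot canopy
assumptions bound the unknown sampling bias: *upper* (plots sit in the
densest canopy of the pixel → smallest carbon) and *lower* (plots reflect
the mean canopy of the forested, ≥ 10%-cover part → largest carbon). Pixels
without sub-pixel canopy detail use the pixel canopy for both conventions,
which makes them coincide; the synthetic world is in this regime and its
pipeline trains on the lower-convention column. Co-located plots are
averaged per pixel after screening.

## Counterfactual models

Current pixel carbon is regressed on ~40 environmental covariates, 8
human-disturbance covariates (each scaled to [0, 1], 0 = no human impact)
and canopy cover with random-forest ensembles. Two counterfactual designs
estimate potential carbon:

* **type 1** (GS1/SD1): train on everything, then predict with the human
  covariates set to zero;
* **type 2** (GS2/SD2): train only on minimally disturbed pixels, without
  human covariates, and extrapolate.

In both, the canopy covariate is replaced by potential canopy at prediction
time and predictions are masked to potential canopy ≥ 10%. Each ensemble
member is fitted on a spatial bootstrap (one random observation per grid
cell; defaults 0.7° GS1, 0.25° GS2, 1.0° SD2, simple random for SD1) with
hyperparameters chosen per member by the highest tenfold-CV R² over a
12-point grid (trees ∈ {25, 50} × feature fraction ∈ {0.33, 0.6, 1.0} ×
leaf size ∈ {2, 5}); a scaled-down grid keeps the selection logic at desk
cost. Default members: 100; the packaged recovery experiment uses 20, where
the ensemble mean is already stable on a 128×128 world. Ensemble outputs are
per-pixel mean, coefficient of variation (sd/mean), and 5/95% quantiles.

Belowground carbon uses the root mass fraction RMF interpreted as root mass
over total mass, so total living carbon = AGC / (1 − RMF); a
`mode="multiplier"` switch gives AGC × (1 + RMF) for data products that ship
direct multipliers. Stocks integrate density × pixel area with pixel area =
nominal cell area × cos(latitude), reported in Gt C.

## Diagnostics

* **Moran's I** of residuals in great-circle distance bands (binary weights,
  default 20-km bands) with one-sided permutation p-values (199 permutations,
  seeded). Residuals come from a pluggable smooth covariate-only surface
  (default: a B-spline GAM on the top-5 covariates by forest importance).
* **Buffered LOO-CV**: each point predicted by a model trained only on
  points beyond a buffer radius; with buffer 0 it reduces exactly to
  classical LOO. All R² values are computed against the 1:1 line,
  `1 − Σ(o−p)²/Σ(o−ō)²`.
* **PCA convex hulls**: training covariates are standardized, projected on
  the leading components covering ≥ 90% variance, and 2-D hulls built for
  every component pair (19 components → 171 hulls); each prediction pixel
  reports the fraction of hulls containing it (closed-hull convention:
  boundaries count as inside; degenerate zero-area pairs are skipped and
  logged).
* **Disturbance partial regression**: PC1 of the standardized human layers
  (sign-oriented so larger = more disturbed) against carbon, both
  residualized on the environmental controls (Frisch–Waugh). Because naive
  OLS inference is anticonservative when smooth spatial fields confound each
  other, the gridded variant uses a toroidal-shift permutation null
  (circularly shifting the human layers relative to carbon and environment),
  which preserves autocorrelation and holds the nominal test level.

## Pools, partitioning, uncertainty

Dead wood + litter are a forest-class ratio of living carbon — tropical 22%
(15–33), temperate 33% (30–37), boreal 80% (68–94), dryland 21% (2–40) —
with bounds from endpoint products of the ratio and living-carbon ranges.
Soil carbon potential is consumed as a data layer (± absolute error), masked
to potential canopy ≥ 10%; no soil model is implemented.

The pixel deficit `max(potential − current, 0)` splits exactly into
conservation (degradation of standing forest) and restoration (lost canopy):
carbon proportional to the canopy-cover increase goes to restoration; the
excess above the canopy-proportional baseline is distributed across the
total potential canopy, i.e. allocated cc_cur : (cc_pot − cc_cur) to
conservation : restoration — this formalizes a rule stated only in prose,
and the two components always close the deficit to machine precision. When
potential falls short of the proportional baseline, the shortfall shrinks
the restoration term (floored at zero) rather than renormalizing; pixels
with current above potential contribute zero to both components.

Deficits are allocated to land-cover classes in proportion to pixel cover;
the unmapped residual goes to low-human-pressure land in non-forest pixels
(< 10% canopy) and to forest otherwise; water and ice are excluded from
attribution; plantation deficit is tallied as a memo where plantations
exceed 10% of canopy area. The uncertainty budget sums six absolute
half-ranges (model type, input data, bootstrap, roots, dead wood/litter,
soil) *linearly* — the literal published rule — with a quadrature switch
available, and reports per-source shares and the top source per pixel (ties
break in the fixed source order).

## The synthetic world

All layers are Gaussian-filtered white noise (σ = 5 px) on a regular WGS84
lat/lon grid (default 128×128 over 64°×64°). Human layers derive from one
latent pressure field; the least-pressured fifth of the landscape is forced
to zero human impact and becomes the minimal-disturbance mask. The truth is

    potential = biome ceiling × f(env),   current = potential × (1 − H)^γ,

with H a fixed mixture of the eight human layers and γ = 1 by default;
current canopy is potential canopy × (1 − converted fraction), so
degradation acts on both density and cover, as the partitioning stage
requires. ~800 inventory plots (250 m² each) land preferentially in
forested pixels; DBHs follow a Weibull (shape 1.8, scale 14 cm) truncated
at 5 cm, with stem counts scaled so plot biomass under the reference
allometry matches pixel carbon up to ×lognormal(σ = 0.15) noise — making
recomputed plot carbon an unbiased (±15%) estimator of pixel carbon by
construction.

What the world does *not* emulate: realistic climate fields, species
composition, temporal dynamics, disturbance regimes (fire, drought),
sub-pixel canopy structure, or measurement error in the covariates. Passing
recovery tests therefore demonstrates that the *procedure* is consistent —
it recovers a known counterfactual under its own assumptions — not that
real-world biases (sampling, legacy effects, satellite error) are absent.

## Problem sizes and numerical choices

The recovery experiment runs GS1 and GS2 with 20 bootstrap members on the
128×128 world, subsample grids 2.0° (GS1) and 1.0° (GS2) — coarser than the
production defaults because the synthetic pixels are ~0.5° rather than
1 km. The deficit estimate is the mean potential across the fitted designs
minus the full-data (type 1) current prediction, mirroring ensemble
averaging across model designs. Degenerate inputs: zero-tree plots are
valid (density 0); MAD = 0 keeps only median-equal values; all-zero
uncertainty pixels have undefined shares and are masked; empty subsample
tables, sub-50-row training sets, RMF ≥ 1 and negative densities raise
errors. Every random draw descends from a single integer seed via
`numpy.random.Generator` seed sequences, so worlds, ensembles and
permutation tests reproduce bit-for-bit.

## Known limitations

* Type-1 counterfactuals inherit random forests' reluctance to extrapolate
  beyond the training response range; on the synthetic world this appears
  as a few-percent low bias in potential carbon, partly offset by ensemble
  averaging with the type-2 design.
* The canopy-convention split is inert without sub-pixel canopy inputs.
* Land-cover allocation drops deficit mass over water/ice by design.
* The uncertainty budget's linear sum overstates total uncertainty relative
  to quadrature when sources are truly independent; shares are unaffected.
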