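# Methods

This note records the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Chamber fluxes

A closed static chamber of height `H` accumulates gas; the flux is

    f = (M/V₀)(T₀/T)(P/P₀) · H · (dc/dt) · 60,

with `M` the molar mass (44 g/mol N₂O, 16 g/mol CH₄), `V₀ = 0.022414
m³/mol`, `T₀ = 273.15 K`, `P₀ = 101.325 kPa` (the standard ideal-gas
reference state), `T`/`P` chamber conditions, and `dc/dt` the ordinary
least-squares slope of headspace concentration (ppm) on closure minutes
(default closures 0/12/24/36 min).  ppm is treated as a numeric mixing
ratio, so `f` lands in µg m⁻² h⁻¹; 1 kg ha⁻¹ h⁻¹ = 1 × 10⁵ µg m⁻² h⁻¹
bridges the two unit views.  Negative fluxes are legitimate — arable
soils are typically net CH₄ sinks.

No goodness-of-fit rejection is applied by default; an `r2_min` flag
implements the common chamber-QC filter for users who want it.  Only the
linear model is offered; nonlinear (HMR-style) chamber models are out of
scope.

Cumulative emissions use the trapezoid rule over sampling days
(equivalently, exact integration of the piecewise-linear interpolant),
times 24 h/day, giving kg/ha.  Annual values integrate each trial year
separately and average; fallow periods are covered by the same
interpolated series.

**Nitrogen-basis convention.**  Cumulative N₂O is carried as N₂O-N
(kg N/ha, the convention in which field totals are usually reported) and
converted to species mass (×44/28) only at the warming-potential step

    GWP = N₂O × 273 + CH₄ × 27   [kg CO₂-eq],

whose factors are 100-year values including climate–carbon feedbacks.
CH₄ is carried as species mass throughout (consistent with M = 16 in the
flux equation).  This is the only combination under which an 8.9 kg
N₂O-N/ha/yr emission with a 2.0 kg CH₄/ha/yr sink reproduces a GWP near
3.76 t CO₂-eq/ha/yr, the magnitude a heavily fertilized wheat–maize
double crop exhibits; the acceptance suite asserts exactly this
consistency.

## Carbon budget

Indirect (life-cycle) emissions are `CE = Σₖ Dₖ·Cₖ` over the input
inventory (fertilizer N/P/K, diesel, electricity, pesticide, seed,
labor), annualized by cycle years.  Emission factors are data, not code:
the default table (e.g. 8.3 kg CO₂-eq per kg N) carries
literature-magnitude placeholder values and is fully configurable — any
serious application must substitute factors appropriate to its region
and inventory scope.  The system boundary ends at the farm gate.

SOC stocks are fixed-depth sums `Σ conc(g/kg) × BD(g/cm³) × thickness(cm)
× 0.1` in t C/ha over 0–10/10–20/20–30/30–50/50–70/70–90 cm; no
equivalent-soil-mass correction is applied.  The annualized change is

    ΔC = (T₂ − T₁) × 44/12 / n years × 1000   [kg CO₂-eq/ha/yr],

**signed so that positive means sequestration** (end minus start).  The
printed form of this conversion is sometimes written start-minus-end;
that sign would make a carbon-accruing soil a negative "sink" while
being *subtracted* in the net budget, which double-negates.  The
implementation therefore uses end-minus-start, the only sign consistent
with `net = CE + GWP − ΔC` treating ΔC as a sink credit.  The budget
identity holds exactly (not to tolerance) for every plot in every run,
and the offset fraction ΔC/(CE+GWP) is reported alongside.

## Soil health scoring

Each of the ten indicators is scored against the *pooled* distribution
of all plots and both timepoints, so scores are comparable across years:
more-is-better indicators score `100·Φ(z)`, less-is-better `100·(1−Φ(z))`,
and optimum-type indicators (pH, target 7.0 by default) score
`100·(1−|2Φ(z_t)−1|)`, a symmetric penalty around the target.
Cumulative-normal scoring curves are the standard choice where the
published scoring functions are calibrated to regional populations we do
not have; scoring against the trial's own pooled population makes the
procedure self-contained and testable.  Default directions: BD
less-is-better; pH optimum; SWC, TN, SOC, DOC, NO₃-N, AP, MBC, MBN
more-is-better.  AP's direction is genuinely arguable (high available P
can reflect over-fertilization); it is a per-run configuration, not a
hard-coded truth.

Weights come from a PCA of the standardized indicator matrix: components
with eigenvalue > 1 are retained (capped at three), and each indicator's
weight is the sum of its **absolute** loadings on those components —
eigenvector signs are arbitrary, so signed sums would be ill-defined.
The overall score is the weighted mean of indicator scores; it is
invariant to rescaling all weights and bounded in [0, 100].

## Alpha diversity

Rarefaction subsamples each OTU-table column without replacement
(multivariate hypergeometric) to a common depth, by default the minimum
column sum; the seed is recorded in the run manifest.  Indices on the
rarefied counts: richness S; Shannon `H = −Σ pᵢ ln pᵢ` (natural log, the
same convention as the entropy weighting); Gini–Simpson `1 − Σ pᵢ²`
(the raw dominance `Σ pᵢ²` is also emitted so either Simpson convention
is recoverable); Pielou `J = H/ln S`, reported as missing for
single-taxon samples; Chao1 `S + F₁²/2F₂`, switching to the
bias-corrected `S + F₁(F₁−1)/(2(F₂+1))` when no doubletons exist; and
ACE with the standard rare/abundant cutoff of 10 (configurable), falling
back to Chao1 in the degenerate all-singleton case where ACE's sample
coverage is zero.

## Entropy-TOPSIS comprehensive index

The decision matrix holds rotation-level means (over replicates) of the
seven criteria; the biodiversity criterion is the mean of the bacterial
and fungal Shannon indices at the final timepoint.  Normalization is
min–max with direction handling (net GHG is the one cost criterion).
Entropy weighting is computed per *criterion* across the alternatives:
proportions `f = b/Σb` (or the shifted `f = (1+b)/Σ(1+b)` for any column
containing a zero, applied to the whole column so proportions still sum
to one), entropy `H = −Σ f ln f / ln m` with `0·ln 0 := 0` and `m` the
number of alternatives, weights `W = (1−H)/Σ(1−H)`.  Index conventions
in printed formulations of this method often mix row/column subscripts;
per-criterion entropy across alternatives is the only reading that
yields one weight per criterion, and the implementation is pinned to a
from-scratch brute-force oracle at 10⁻¹² on random matrices.

TOPSIS weights the normalized matrix (`z = W·b`; a flag switches to
weighting the entropy proportions `f` instead, another printed
ambiguity), takes column max/min as ideal/anti-ideal vectors, Euclidean
distances `D±`, and `CEI = D⁻/(D⁺+D⁻)`.  Ties in the ranking share a
rank and are flagged.  A criterion constant across alternatives is
degenerate under min–max normalization and raises an error naming the
criterion rather than silently producing NaN.

## Group statistics

One-way ANOVA is computed from the classical sum-of-squares
decomposition; LSD post-hoc pairs use t statistics on the pooled error
mean square, and the compact letter display uses the insert–absorb
algorithm (groups ordered best-first; a significant pair splits every
letter column containing both; subset and duplicate columns are
absorbed), so groups share a letter exactly when not significantly
different at α = 0.05.  Pearson correlation matrices require at least
three observations; constant columns yield missing correlations.

## Synthetic experiment generator

The generator emulates the *statistical structure* of a six-year,
six-rotation × three-replicate randomized complete block trial.  Its
defaults are fixed at the magnitudes such trials report: the wheat–maize
control at 8.9 kg N₂O-N ha⁻¹ yr⁻¹ and a 2.0 kg CH₄ ha⁻¹ yr⁻¹ soil sink,
diversified rotations 30–50 % lower in N₂O and 33–76 % stronger CH₄
sinks; soil C accrual from 0.21 to 2.03 t C ha⁻¹ yr⁻¹ (legume rotations
highest); ~8800 kg CO₂-eq ha⁻¹ yr⁻¹ indirect emissions for the control
and ~34–41 % less for the diversified systems; a +7–10 % Shannon shift
in the rotations with sweet potato and legumes; and a baseline soil
profile whose 0–20 cm layer holds ~51 % of the 0–90 cm stock (67 % to
30 cm, 80 % to 50 cm).

Design choices:

- **Seeding.** One global seed expands to named child streams via
  `SeedSequence([seed, crc32(key…)])`, so any stream (one plot-year's
  fluxes, one OTU table) can be regenerated in isolation and identical
  configs are bit-identical.
- **Fluxes.** Each plot-year's true flux curve is baseline plus
  fertilization pulses decaying exponentially (half-life 5 days, the
  time scale that motivates 3-day post-fertilization sampling), sampled
  weekly plus an extra visit 3 days after each fertilization.  The curve
  is scaled so its trapezoid integral equals the rotation's configured
  annual total — the same integration rule the analysis applies, which
  makes recovery unbiased by construction.  Additive Gaussian noise on
  the flux (SD = 15 % of the mean flux) is truncated only at the point
  where headspace concentrations would go negative, far below any
  realized value.  The flux is then inverted through the chamber
  equation (seasonal chamber temperature, fixed pressure and height) to
  concentration series with small ppm-level measurement noise.
- **Soil.**  Per-plot layer concentrations are baseline plus a plot
  effect (SD 0.25 g/kg) with independent measurement error at each
  timepoint (SD 0.1 g/kg); the configured accrual rate is distributed
  over depth by fixed shares and converted to concentration increments
  with the plot's own bulk density, so the stock-difference estimator is
  exactly unbiased.  Bulk density is measured once per plot.
- **Indicators.** Each indicator is Gaussian around its baseline mean in
  the first year; in the final year the mean shifts by the rotation's
  effect size times a per-indicator response step (BD and pH respond
  downward).  Within-plot variance components are free parameters with
  field-plausible defaults — no published values exist to pin them.
- **OTU tables.** Communities are log-normal species-abundance vectors
  sampled per plot (the standard null model for count tables), turned
  into counts by multinomial draws at ~15 000 (16S) / ~12 000 (ITS)
  reads.  A rotation's diversity shift narrows the log-normal shape σ,
  solved numerically on the deterministic quantile profile so that the
  true Shannon index rises by the configured relative amount; each
  sample's true Shannon is stored in `ground_truth` for recovery tests.
- **Economics.** Prices, costs, protein fractions and a CPI series
  (base 2008) are fixed tables chosen so the control's wheat-equivalent
  yield sits near 13 t ha⁻¹ yr⁻¹ and the sweet-potato rotation gains
  ~38 %; wheat–maize years following a non-cereal crop carry a
  configurable carryover yield boost (~29 %).  All price/CPI tables in
  the default config are synthetic placeholders of realistic magnitude.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: weather and interannual variability,
crop growth and yield–management feedbacks, spatial autocorrelation
between plots, block effects (blocks randomize layout but add no
variance component), diurnal flux cycles and chamber artifacts,
sequencing error, chimeras or compositional biases in OTU tables, and
any covariance between streams (e.g. between SOC accrual and microbial
shifts) beyond what the per-rotation parameters impose.  Tests establish
that the *estimators* are correct and unbiased under the stated model,
not that the model captures field reality.

## Problem sizes and numerics

The default design produces ~48 600 chamber rows (18 plots × 6 years ×
2 gases × ~56 sampling dates × 4 closure minutes), fitted by a
vectorized group-wise OLS; a full pipeline run takes well under a second
after import.  Monte-Carlo recovery tests use a reduced two-rotation
design (2 replicates, 2 years, 60-taxon OTU tables) over 50 seeds,
chosen to give standard errors small enough for 3-SE assertions while
keeping the whole suite in the tens of seconds.  Tolerances: oracle
equivalence for entropy-TOPSIS at 10⁻¹² absolute; trapezoid vs fine-grid
integration at 10⁻¹⁰ relative (the comparison grid must include the
interpolation knots); hand-computed values at the precision quoted.
Degenerate inputs fail loudly by design: constant criteria, zero-SD
indicators, all-zero samples, single alternatives, zero within-group
variance, and missing emission factors or CPI years all raise errors
naming the offending field.

## Known limitations

- Emission factors, prices, and nutrient tables ship as editable
  placeholder data; results are only as good as those tables.
- The nutrition composite (min–max normalized, equal-weight by default)
  is one defensible aggregation among several; weights are configurable
  and the choice matters when nutrient profiles conflict.
- CH₄ is assumed reported as species mass, not CH₄-C.
- Fixed-depth SOC stocks ignore bulk-density change over time
  (equivalent soil mass corrections are not implemented).
- With only two alternatives, min–max normalization makes every
  criterion binary and the CEI collapses toward {0, 1}; the index is
  most informative with several alternatives.
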