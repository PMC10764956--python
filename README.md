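# rotation-impact

Multi-function sustainability assessment of diversified crop rotations.

Long-term rotation trials ask a question no single metric answers: does
replacing a cereal double-crop (winter wheat–summer maize) with rotations
that insert cash crops (sweet potato) or legumes (peanut, soybean) raise
food output and farm income *while* shrinking the greenhouse-gas
footprint and improving the soil?  `rotation-impact` implements the full
quantitative chain such a trial needs, as a tested, reusable library with
a CLI, plus a synthetic-experiment generator so every stage can be
exercised and validated without field data.

## What it computes

**Productivity.** Crops are compared in wheat-equivalent units,
`EY = yield × price / wheat_price`; net income is CPI-deflated,
`EB = yield × price × CPI_j / CPI_base − cost`; protein yield is
`PC = yield × β` with a per-crop protein fraction; a multi-nutrient
composite aggregates min–max-normalized nutrient yields across rotations.
Cycle totals are annualized by cycle length.

**GHG balance.** Static-chamber headspace series are converted to fluxes
with the ideal-gas relation

    f = (M/V₀) · (T₀/T) · (P/P₀) · H · (dc/dt) · 60   [µg m⁻² h⁻¹]

where `dc/dt` is the OLS slope of concentration on closure minutes.
Fluxes are integrated trapezoidally over sampling days (×24 h/day) to
cumulative emissions, and combined as
`GWP = N₂O×273 + CH₄×27` (kg CO₂-eq, species masses, 100-year factors).
Soil organic carbon stocks are `Σ conc × BD × thickness × 0.1` (t C/ha)
over 0–90 cm in six depth increments; their annualized change `ΔC`
(×44/12, positive = sink) closes the budget

    net GHG = CE + GWP(N₂O+CH₄) − ΔC

with `CE = Σ Dₖ·Cₖ` the life-cycle emissions of the input inventory.

**Soil health.** Ten indicators (BD, SWC, pH, TN, SOC, DOC, NO₃⁻-N, AP,
MBC, MBN) are scored 0–100 with cumulative-normal curves against the
pooled sample distribution (more-is-better / less-is-better / optimum),
weighted by the summed absolute loadings of the leading principal
components (Kaiser criterion, ≤3 components), and averaged to an overall
score.

**Microbial diversity.** OTU tables (16S, ITS) are rarefied without
replacement to the minimum sample depth and summarized by six
alpha-diversity indices: richness, Shannon (ln), Gini–Simpson, Pielou,
Chao1, ACE.

**Comprehensive evaluation index.** Rotation means of seven criteria
(equivalent yield, economic benefit, nutrition yield, soil biodiversity,
soil health, C sequestration — benefits; net GHG — cost) are min–max
normalized, weighted by information entropy, and ranked by TOPSIS
closeness `CEI = D⁻/(D⁺+D⁻) ∈ [0,1]`.

**Statistics.** One-way ANOVA with LSD post-hoc compact-letter display,
and Pearson correlation matrices of the rotation-level metrics.

## Worked example

```python
from rotation_impact import default_config, run_pipeline

result = run_pipeline(config=default_config(seed=1))
summary = result.tables["decision_matrix"].set_index("rotation").round(2)
print(summary[["equivalent_yield", "net_ghg", "soil_health", "c_sequestration"]])
print(result.tables["cei"].round(3).sort_values("rank").to_string(index=False))
```

```
          equivalent_yield   net_ghg  soil_health  c_sequestration
rotation
PWM               13733.60   1164.00        66.22             1.90
RSWM              11233.75  10375.96        39.61             0.26
SWM               11777.22    237.42        64.35             2.02
SmWM              10181.06   7106.57        42.75             0.53
SpWM              18299.67   2412.80        49.51             1.41
WM                13493.88   9500.71        44.63             0.83

rotation   cei  rank  d_plus  d_minus
     PWM 0.683     1   0.140    0.302
    SpWM 0.640     2   0.160    0.283
     SWM 0.590     3   0.199    0.286
    RSWM 0.307     4   0.332    0.147
      WM 0.283     5   0.283    0.112
    SmWM 0.156     6   0.342    0.063
```

The default synthetic design is a 6-rotation × 3-replicate randomized
complete block trial over six years.  Reading the table: the
peanut→wheat–maize rotation (PWM) pairs a near-neutral GHG balance
(1164 kg CO₂-eq ha⁻¹ yr⁻¹, versus ~9500 for the wheat–maize control) with
the best soil health score and ~1.9 t C ha⁻¹ yr⁻¹ sequestration, so it
ranks first on the comprehensive index; the cereal-only systems (WM,
SmWM, RSWM) occupy the bottom ranks.  Equivalent yield alone would have
picked the sweet-potato rotation (SpWM) — the index makes that trade-off
explicit.  Currency values are Chinese Yuan ($1 US ≈ 6.95 Yuan).

The same run from a shell:

```bash
rotation-impact simulate --seed 1 --out ds/
rotation-impact run --dataset ds/ --out out/
```

Stage-level subcommands (`flux fit`, `flux integrate`, `budget`,
`soilhealth`, `diversity`, `cei`, `stats`, `productivity`) operate on
plain CSV/TSV tables so each step is independently re-runnable; every
derived output carries the configuration hash and seeds.

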