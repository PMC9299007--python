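# Methods

## Scope and model

The package estimates how much soil organic carbon (SOC) global cropland
could additionally sequester under five improved management measures:
increased inorganic fertilization (M1), increased organic inputs (M2),
reduced tillage (M3), increased crop diversity (M4) and crop residue
incorporation (M5). The chain is: (1) harmonize meta-analytical effect
sizes into annual SOC stock changes with standard errors, (2) pool them
per intervention × climate zone by fixed-effect inverse-variance
weighting, (3) stratify cropland area by its current management and map
each measure to the area where its intervention can still be adopted,
(4) cap organic fertilization by the regional supply of not-yet-recycled
manure carbon, and (5) upscale `area × effect` to Mton C yr⁻¹ with
Monte-Carlo uncertainty and combine measures under complementarity rules.

Key assumptions, stated plainly:

- **Linear accumulation over 20 years.** Total stock changes are divided
  by a fixed 20-year reference duration (the median duration of the
  underlying field studies), ignoring SOC saturation. Short-duration
  studies are therefore diluted and long-duration ones inflated; the
  record's own duration is kept as metadata only.
- **Fixed-effect pooling.** Weights are 1/SE²; the pooled SE is
  (Σw)^(-1/2). No between-study heterogeneity term is estimated and no
  correction is made for overlap of primary studies across meta-analyses,
  so pooled SEs are optimistic.
- **Independent effect cells.** Monte-Carlo draws sample each
  intervention × climate cell independently; no correlation structure
  across cells is assumed because none is identifiable from pooled
  summaries.
- **Additivity within a measure.** Zone potentials are sums over strata;
  interactions between measures are not modelled — the two scenario rules
  (plain sum, 1/rank discount) bracket the complementarity assumption
  instead.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| bulk density ρ_b | 1400 | kg m⁻³ | global topsoil central value (range ~1200–1600); pluggable provider for site-specific lookups |
| reference duration | 20 | yr | median field-study duration; annualization divisor |
| CI → SE divisor | 3.92 | — | full width of a symmetric normal 95% interval in SE units |
| CV inflation | 1.25 | — | penalty applied to the group-average CV when imputing missing SDs |
| fertilization cut-offs | 40, 100 | kg N ha⁻¹ yr⁻¹ | "unfertilized" below 40 (stated); 40–100 vs >100 splits medium/high, matching the narrative that most cropland receives 40–100 kg mineral N |
| manure cut-off | 40 | kg N ha⁻¹ yr⁻¹ | low/high manure input split, mirroring the "<40 kg N from manure" narrative |
| C:N of manure organic fraction | 10 | — | midpoint of slurry (~8) and solid manure (~15); configurable |
| humification coefficient h | 0.5 | — | stable C fraction not decomposed within one year (literature range 0.30–0.75); optimistic by construction |
| Monte-Carlo draws | 1000 | — | matches the reported uncertainty analysis; quantiles at 0.01/0.99 |
| unit conversions | 0.01 t C ha⁻¹ per g C m⁻²; 1 Mton = 10⁹ kg | | centralized constants |

## Design choices where the procedure was open

- **Imputation route.** A record without reported variation gets
  SD = 1.25 × (group CV) × |mean| with CV = |SE·√n / mean| computed per
  record on the harmonized annual scale (CV is scale-invariant, so the
  order of conversion does not matter); zero-mean records are excluded
  from the group average (CV undefined). SE then follows as SD/√n with
  n = 1 when unreported. The global-CV fallback exists but is off by
  default: silently borrowing variance across managements is worse than
  failing loudly.
- **SD takes precedence** over a simultaneously reported CI (it is the
  first-listed rule and closest to the data); asymmetric CIs use half the
  full width — pooling operates on raw mean differences, so no
  log-back-transformation is applied.
- **"Other" climate cell.** The across-zone entry per intervention is the
  inverse-variance combination of the zone-level pooled effects (plus any
  records reported directly as "other"). It doubles as the fallback for
  zones without data (e.g. tillage contrasts in the tropics). Pooling at
  the zone level rather than the study level makes the packaged "other"
  values non-recomputable from the zone cells alone (0.13 vs the printed
  0.14 for IF-NF); the fixture ships the printed values and the pooling
  path is validated on synthetic data instead.
- **Regional manure cap.** The M2 cap is applied per region *before* zone
  aggregation — capping zone totals would let surplus in one country
  offset deficits in another. Within a region the cap scales the region's
  climate sub-potentials proportionally (no within-region allocation rule
  is identifiable). In Monte Carlo the cap is applied inside every draw.
- **Scenario bounds.** Reported scenario bounds are sums of the
  per-measure global bounds (the printed arithmetic); the alternative —
  quantiles of the summed draws, which are tighter under independence —
  is exposed via `all_bounds="draws"` (the default for the per-measure
  "all" row, where the printed bounds are consistent with summed draws
  rather than summed zone quantiles).
- **Rank weighting.** The declining-contribution rule is fixed to 1/k for
  the k-th ranked measure: among simple decline schemes (1/k, 2^-(k-1),
  linear), only 1/k reproduces the printed totals 354, 278 and 432 from
  the global row. Ties are broken by the fixed measure order M1 < … < M5,
  with M2cor occupying M2's slot.
- **Residue eligibility** includes both burned and removed residues
  (whether removal counts is not explicit; burning alone would make M5
  area-limited in a way the printed potentials contradict).

## Synthetic data: what it emulates and what it does not

The generators provide a *stated world* so every stage is testable without
external spatial layers. `generate_cells` matches the global cropland
marginals: total area 1,416,912 kha; climate 30/19/30/21%
(tropical/temperate/subtropical/other); tillage 45% HT, 8% NT, 47% IT;
25% residue burning (removal set to 15%, incorporation 60% — only the
burning share is stated); 72% of rotations without catch crops; and a
joint fertilizer × manure class distribution pinned so that 13% of area is
high–high. Fertilizer class marginals none/medium/high = 0.20/0.55/0.25
are a choice consistent with "most land receives 40–100 kg mineral N";
rates are truncated-lognormal within each class interval so the induced
classes match the marginals exactly. Areas are symmetric-Dirichlet across
cells rescaled to the exact total (conservation is testable to machine
precision). `generate_manure_records` normalizes excretion to
129 Tg N yr⁻¹ with a uniform recycling fraction (default 0.92, keeping
the surplus under the 10% bound). All randomness flows from one seed via
a dedicated sub-stream per table.

What a green test on this world establishes: the arithmetic, unit chain,
classification, capping and uncertainty propagation are correct, and
parameter recovery holds at nominal coverage. What it does not establish:
the realized global potentials — synthetic cells have no spatial
autocorrelation, no real country borders, and attribute independence
(beyond the fertilizer–manure joint), so pipeline outputs on synthetic
defaults agree with the published potentials only in order of magnitude
and ranking (e.g. M3 > M5), never cell by cell.

## Numerical choices

- Percentiles use linear interpolation between order statistics
  (`numpy.quantile` default).
- Zero SEs are rejected in pooling (infinite weight); the noiseless limit
  is exercised with vanishing positive SDs.
- Degenerate inputs: empty record sets and zero total area raise typed
  errors (`NoDataError`); a missing effect cell without an "other"
  fallback raises `NoEffectError`; region mismatches in capping raise
  `AlignmentError`.
- CSV floats are serialized at 6 significant digits; reruns with the same
  seed are byte-identical. Totals are conventionally read in Mton rounded
  to integers; tests compare at ±1 Mton where rounding is involved.
- The pipeline assembles all outputs in memory and writes only after
  every stage succeeds (atomic failure with stage-tagged errors).

## Known limitations

- No random-effects meta-analysis and no correction for non-independence
  between meta-studies; pooled SEs understate true uncertainty.
- The 20-year linearization ignores saturation; potentials are mid-term
  rates, not equilibria.
- Manure-type-specific humification (liquid vs solid) is not modelled;
  the h = 0.5 cap is optimistic and holds only under continued annual
  inputs.
- Equivalent-soil-mass corrections for bulk-density change under reduced
  tillage are not applied (fixed-density conversion).
- The raster/coordinate ingestion layer is out of scope: the core
  operates on tabular cells, and real spatial layers must be reduced to
  that form upstream.
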