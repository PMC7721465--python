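# Methods

`dove` estimates drug-overdose-death (ODD) rates for the current period —
before official mortality data are released — from the same period's
relative web-search volumes.  This note documents the model, its
parameters, the synthetic data used to validate it, and the design choices
made where more than one reasonable option existed.

## Problem setting and data model

The unit of analysis is a (region, period) pair: 51 regions (50 U.S.
states plus the District of Columbia in the real setting) observed yearly
or monthly.  Three inputs:

* **Search panel** — for each region, period and keyword, the keyword's
  query volume divided by total query volume, on a relative 0–100-like
  scale.  Roughly 80 drug-related keywords in the motivating application.
* **Mortality panel** — death count, population and the crude rate
  `count / population × 100 000` per (region, period).  Crude, not
  age-adjusted, rates throughout; monthly rates use the yearly population.
  County counts below 10 are suppressed in public tables.
* **Adjacency list** — symmetric, irreflexive region neighborships;
  regions without neighbors (islands) are allowed.

The *nowcasting contract*: predictors for a target period are that
period's own search rates (available almost immediately), plus at most one
column that reaches back in time — the lagged observed rate.  Observed
mortality at or after the target period never enters training; a hard
leakage guard (`LeakageError`) enforces this in every evaluation.

## Suppressed-count imputation

For each (state, period), the suppressed remainder
`R = state_count − Σ known county counts` is partitioned among the
suppressed counties proportionally to their populations.  Imputed counts
are kept as non-negative reals rather than rounded or capped at 9: the
downstream use is rate estimation, and rounding or capping would break
exact conservation of the state total (which the pipeline guarantees to
1e-9).  An optional cap (`cap=9`) is available; when the proportional
allocation exceeds it, the excess is redistributed proportionally among
the remaining suppressed counties, iteratively, and a warning is logged if
the remainder cannot fit under the cap at all (conservation then yields to
the cap, which is why the cap is off by default).

## MultiSURF keyword scoring (continuous endpoint)

Keywords are ranked by a Relief-family scorer.  Distances between
instances are range-normalized Manhattan: `d(i,j) = mean_f |x_if −
x_jf|/range(f)`, with constant features contributing 0.  MultiSURF's
defining neighborhood rule is a per-instance dead-band: j is *near* i when
`d(i,j) < μ_i − σ_i/2`, where μ_i and σ_i are the mean and (population,
ddof = 0) standard deviation of i's distances to all other instances.

The classical algorithm handles discrete endpoints.  The death rate is
continuous, so this package uses an explicit adaptation: a near pair is a
*hit* when `|y_i − y_j| ≤ endpoint_tolerance × range(y)` and a *miss*
otherwise.  Each feature's score adds `|x_if − x_jf|/range(f)` over miss
pairs and subtracts it over hit pairs, normalized by the total number of
directed near pairs over all instances (a single global normalizer).
Ties in the ranking break by ascending keyword name, so rankings are
deterministic.

`endpoint_tolerance` defaults to 0.05 of the response range.  It is a
documented parameter of this package, not a universal constant: smaller
values make "hit" stricter (fewer negative contributions), larger values
smooth the score.  Correctness is defined by the rule above and checked
against an independent brute-force pair-enumeration oracle (agreement to
1e-10 on random instances).  One non-obvious consequence of the dead-band
rule, confirmed by the oracle: duplicating every instance *changes* the
scores, because each instance acquires a neighbor at distance zero that
shifts its μ_i and σ_i.

## Regression methods

Eight methods run through one fit/predict harness: ordinary least
squares, Bayesian ridge, lasso, AdaBoost, k-nearest neighbors, a single
decision tree, random forest, and extremely randomized trees (ERF, the
headline method — it randomizes both candidate features and split
thresholds and averages the trees).  Estimators are scikit-learn's with
library defaults; hyperparameter overrides (e.g. `n_estimators`) are
configuration recorded in the run manifest, not part of the contract.
Predictions are clipped at 0 (rates cannot be negative) with the clipped
count logged.  Tree ensembles inherit the property that predictions stay
within the training response range; this is tested.

## Walk-forward selection

The tuning grid crosses five parameters:

| parameter | levels | default (reduced) |
|---|---|---|
| method | 8 | OLS, ERF |
| keywords kept | 5–75 step 5 (+ optionally all 80) | 5, 10, 20 |
| training window | previous period only / all available | both |
| lag feature | off / on | both |
| spatial encoding | NONE / DUMMY / NEIGHBOR / POP_WEIGHTED_NEIGHBOR | NONE, NEIGHBOR |

With 16 keyword levels the full grid has 16 × 8 × 2 × 2 × 4 = 2048 cells;
with the 15 levels 5–75 it has 1920.  Both counts circulate for this
design — 15 stated levels vs a printed total of 2048 — so both presets are
provided (`paper_grid(15)`, `paper_grid(16)`); the package takes no
position on which was used originally.

Each config is scored on every feasible target period by training strictly
on earlier periods (keyword ranking included: MultiSURF runs on training
rows only), predicting all regions for the target, and computing **MAE%**
— the *median* over regions of `|predicted − observed|/observed × 100`
(a median absolute percentage error, despite the acronym).  Regions with
observed 0 are excluded and counted in a warning.  Cells that cannot be
built (e.g. a lag model whose only training period has no prior rate) are
skipped and excluded from that config's mean rather than imputed.

Selection is **marginal** by default: for each parameter independently,
the level with the lowest mean MAE% over all configs sharing it wins, and
the final config is assembled from the winners.  **Joint** selection (the
single best cell) is available because the two can disagree under
interactions; ties break by declared level order.  The held-out final
period never enters selection — the chosen config is refit on all working
periods and applied to it exactly once.

## Spatial encodings

All four encodings are indexed by the full fixed region list so training
and prediction matrices align: NONE (no columns), DUMMY (identity),
NEIGHBOR (1 for self and each neighbor), POP_WEIGHTED_NEIGHBOR (1 for
self; each neighbor weighted by its population share of the total
neighboring population, so off-diagonal row sums are exactly 1 for
non-island regions).  Islands get only their self-indicator.  Neighbor
populations for the weighting are taken at the latest training period.

## County disaggregation

Yearly only (monthly county data are almost entirely suppressed in the
real setting).  Per county: share(t) = county count / state count; an OLS
line of share against the period's position in the sorted period axis is
evaluated at the target (the origin choice only shifts the intercept and
is immaterial), clamped to [0, 1] and renormalized within the state.
Counties with one usable period carry their share forward; states whose
total is zero in a period have that period excluded from the fit.  The
predicted state count (`rate × population / 1e5`) is partitioned by these
shares and divided by county populations for rates; county counts sum to
the state count by construction.  Share regressions use counts, not
rates.

## Synthetic data generator

The generator is the package's test bed and defines the conditions under
which its guarantees are demonstrated.  It emulates the *structure* of
the real inputs, not their values:

* latent rate(r, t) = baseline (log-uniform on [5, 50] per 100 000, the
  span of real state-level rates) + region-specific linear trend
  (slope ~ N(0, 0.03 × baseline) per period, scaled by `trend_strength`)
  + AR(1) noise (ρ = 0.5, sd 0.03 × baseline);
* informative keywords: affine in the latent rate (slope uniform on
  [0.5, 2]) plus AR(1) noise with sd = sd(signal)/snr, min-max rescaled to
  [0, 100]; uninformative keywords are independent AR(1) noise on the same
  scale;
* populations log-uniform on [0.5M, 40M]; observed counts are
  Poisson(latent × pop/1e5), so observed rates carry realistic small-state
  sampling noise;
* adjacency: grid graph with 20% of edges deleted (symmetric, possibly
  disconnected);
* counties: Dirichlet(2) base shares per state, drifting linearly at up to
  `share_drift` (default 0.02) per period; integer county counts sum
  exactly to the state count (rounding residue to the largest county);
  counts below the threshold (default 10) are masked.

What it does **not** emulate: keyword semantics and their year-to-year
drift in meaning, cross-keyword correlation structure, search-volume
sampling jitter, age structure, reporting delays, or any calibration to
real mortality surfaces.  Passing tests therefore demonstrate that the
machinery recovers a linear-link signal under realistic noise and
suppression — not that real-data accuracies transfer.

All randomness flows from one integer seed through spawned substreams;
generation is byte-reproducible.

## Problem sizes and defaults used in validation

Recovery checks run at the study's shape — 51 regions, 10 yearly periods,
80 keywords with 5 informative at snr 2 — with the reduced 48-config grid
and ERF at 30 trees, chosen to keep a full walk-forward selection under a
minute per panel.  Under these conditions MultiSURF's top-5 recall of the
informative set averages ≥ 0.8 over 10 seeds and the selected model's
hold-out state MAE% is in the single digits (median over 5 seeds ≤ 10%);
`scripts/acceptance.py` recomputes both, plus the national-total error,
county rank correlation and conservation error, from scratch.

## Known limitations

* The continuous-endpoint hit/miss rule is this package's documented
  adaptation; other Relief implementations may differ in dead-band or
  normalization details, so cross-library score equality is not expected.
* Marginal selection can assemble a configuration that was never the best
  single cell (by design; use `strategy="JOINT"` otherwise).
* County estimates are a partition of the state estimate: within a state
  they carry no information beyond the share trend, and are only
  meaningful for cross-state ranking.
* Imputation distributes the suppressed remainder by population, which is
  exact in aggregate but can misallocate between suppressed counties whose
  true rates differ.
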