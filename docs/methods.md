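# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind the package, in the order the pipeline runs.

## Data model

Observations live in a long (tidy) table, one row per documented cell
(indicator *i*, major ecosystem *j*, spatial unit *k*, year *t*) with the
elicited mean and 25%/75% quartiles, a data-source tag (monitoring /
model / expert judgment) and a variable kind (continuous or count). The
convention for absence is strict: a cell with no row is treated as *not
reported* — it receives documentation flag δ = 0 and contributes neither
value nor weight anywhere. The dense δ lattice is materialised only for
diagnostics; everything else operates on the sparse table.

Reference states are point values per (indicator, ecosystem, unit), valid
for all dates, each tagged with the operational definition used to set it
(carrying capacity, maximum sustainable level, pristine state, ...) and
with the scaling model the expert chose. A documented cell without a
reference state is a hard validation error rather than a silent fallback:
scaling is undefined without it, and guessing a denominator would corrupt
the index unnoticed.

Duplication — one elicited value copied across several localities — is
represented explicitly by a `duplication_group` id rather than inferred
from equal values, so the simulation stage can honour it deterministically.
Rows in one group must carry identical mean and quartiles.

## Distribution fitting

Each elicited triple (mean, q25, q75) is matched to a two-parameter family
by minimising the criterion C = m² + q_l² + q_u², the squared deviations
of the candidate distribution's expectation and quartiles from the
elicited values. The squared (least-squares) combination is symmetric and
smooth; it is isolated in `criterion_c` so an absolute-deviation variant
is a one-line change. Deviations are taken on the indicator's natural
scale: each cell is fitted independently and only compared across families
within the cell, so a scale normalisation would cancel.

Candidate families:

* continuous — normal truncated at 0, Gumbel, log-normal, Weibull, gamma;
* discrete — Poisson (λ), zero-inflated Poisson (π, λ), negative binomial
  (size, prob).

Degenerate elicitations with mean = q25 = q75 become a point mass (C = 0);
equal quartiles with a different mean are fitted normally (C > 0 is then
unavoidable).

Numerics. Continuous families use closed-form moments and quantile
functions (`scipy.special`); C is minimised by Nelder-Mead in a
transformed space (positive parameters on the log scale) from
moment/quantile heuristic starts, plus an exact linear-least-squares start
for the Gumbel (whose mean and quantiles are linear in location and
scale). Discrete families have piecewise-constant quantiles (type-1
convention: smallest k with CDF ≥ p, matching standard tabulations), so C
is minimised by vectorised coarse grids followed by local refinement and a
"mean-exact" polish along the curve where the distribution mean equals the
elicited mean; the negative binomial additionally gets a fine sweep of the
central range because its C surface has several narrow basins. Ties in C
(within 1e-12) resolve by the fixed family order above. The test suite
checks the fitter against an independent dense grid-search oracle built on
`scipy.stats` frozen distributions, on a seeded panel of 50 triples of
both kinds, and re-computes every reported C through that independent
route.

Whole-dataset fitting normalises continuous triples by their mean and
rescales the fitted parameters exactly (all five families are closed under
scaling, with C scaling quadratically), so datasets in which many cells
share one relative quartile spread are fitted essentially once.

## Monte-Carlo replication

Each documented cell receives n = 999 replicates (configurable) drawn from
its fitted family. Draws are exact inverse-CDF samples for the truncated
normal; the Gumbel, whose support extends below zero, is clipped at 0 to
respect the non-negativity of indicator values. Every independent
elicitation has its own RNG substream seeded from (master seed, stable
hash of identity) — the duplication-group id for duplicated cells, the
cell key otherwise. Consequences: identical seeds reproduce bit-identical
vectors; adding or removing a cell never perturbs the draws of other
cells; and all cells of one duplication group carry one identical vector,
mirroring how the duplicated entry was a single elicitation.

Replicates are assembled per cell into whole-dataset replicates; under
independence across cells this is equivalent to drawing whole datasets.

## Scaling

The three models map a non-negative value x and reference r > 0 to [0, 1]:

* minimal: s = min(x/r, 1) — the reference is a low, precautionary level;
* maximal: s = 1 for x ≤ r, r/x above — the reference is a ceiling above
  which effects are detrimental;
* optimal: s = min(minimal, maximal) — any departure degrades; continuous,
  with unique maximum 1 at x = r and hyperbolic decay r/x above.

These piecewise forms satisfy boundedness, the stated monotonicities, and
the identity optimal = min(minimal, maximal) by construction; the three
live behind one dispatch point so alternative shapes (e.g. linear decay
above r truncated at 2r) are swappable without touching callers. A
boundary case worth noting: x = 0 under the maximal model returns 1 (a
proliferating species at zero abundance is below its ceiling); whether
that is ecologically sensible is the indicator designer's call, and the
ecosystem-destruction tests therefore use minimal/optimal indicators.

## Weights

Four multiplicative factors, then renormalisation:

1. *Membership* (base weight): the indicator's membership fraction for the
   ecosystem; fractions sum to 1 over ecosystems per indicator.
2. *Within-slice*: in each documented (ecosystem, unit, date) slice,
   extra-representative indicators jointly receive exactly 0.5 — split
   among themselves by base weight — whenever at least one ordinary
   indicator is documented (the cap doubles as a floor so they "contribute
   significantly without overwhelming"); they take the full share when
   alone. The remaining share is divided equally among the
   trophic/functional groups present among documented ordinary indicators
   (absent groups receive nothing), then within groups by base weight.
3. *Ecosystem equivalence*: factor 1/E per unit, E = ecosystems *present*
   (positive area), not merely documented. A destroyed or undocumented
   ecosystem therefore shows up as a weight deficit that is repaired by
   explicit renormalisation and reported as a diagnostic — keeping the
   property that destroying an ecosystem lowers the cross-ecosystem index
   visible rather than silently renormalised away.
4. *Area*: across units, proportional to total unit area; for a
   single-ecosystem scope, to that ecosystem's area within each unit
   (representativeness of the averaged value for the area it speaks for),
   falling back to total area where no per-ecosystem area is provided.

Thematic sub-indexes apply a binary mask (keep the theme's indicators /
ecosystems / units) and renormalise the surviving weights.

## Aggregation and inference

NI_t(s) = Σ W·s over documented cells, per replicate s, with W
renormalised over documented cells at each date (the sum-to-one condition
cannot hold otherwise under missing data). Summaries are the median and
the 2.5%/97.5% quantiles of the n replicates, with linear interpolation
between order statistics (numpy's default), stated here for
bit-reproducibility. Two dates are compared with independently drawn
replicate vectors — pairing is not assumed — by
p = (#{NI_t1 > NI_t2} + ½·ties)/n, two-sided 2·min(p, 1−p) capped at 1;
the ½-tie convention makes the null p symmetric and gives exactly 0.5 for
identical vectors.

## Synthetic data generator

The generator emulates the elicitation process with known ground truth so
every stage is testable without external data. Truth is parameterised on
the scaled [0, 1] axis per (ecosystem, date) and back-transformed through
the inverse of each cell's scaling model (below-reference branch x = s·r
for minimal/optimal; x = r/s for maximal). Reference values are drawn
uniformly in [20, 200] once per (indicator, ecosystem) and shared across
units, so duplicated elicitations stay coherent with every locality's
reference.

The emulated experts are *statistically calibrated*: the observed mean is
jittered log-normally (mean 1) with relative SD equal to the `noise`
parameter, and the stated quartiles sit at mean·(1 ± 0.6745·noise) — the
quartiles of a normal belief with that same relative SD. Calibration is
the property that makes the simulation-based p-values meaningful: the
error actually committed matches the uncertainty actually stated, so the
null rejection rate at α = 0.05 lands near 0.05. With noise = 0 the
elicitation is exact and the pipeline closes the loop: recovered index =
configured truth, CI width 0.

Defaults (chosen once as the study conditions): 3 ecosystems × 6 units ×
4 dates (1950, 1990, 2000, 2010) with 5 indicators per ecosystem; 8
trophic/functional groups; 15% extra-representative indicators; 20% of
indicators span a second ecosystem with a 0.7/0.3 membership split;
source mix 0.25/0.15/0.60 monitoring/model/expert (expert-dominant);
noise 0.1; duplication and missingness probabilities 0.1; continuous
variables (counts available via `discrete_fraction`); scaling models
half minimal, half optimal (the maximal model's inverse is undefined at
truth 0 and is opted into explicitly).

What the generator does *not* emulate — and hence what passing tests do
not show about real assessments: systematic expert bias (optimism,
anchoring), correlated errors across indicators or neighbouring units,
reference-state uncertainty or disagreement, non-stationary documentation
effort, and real ecosystem area distributions. Recovery results here
certify the arithmetic of the engine, not the reliability of any actual
expert network.

## Problem sizes

The bundled checks run at desk scale: the fitting oracle uses 50 triples;
weight conservation 100 small random datasets; parameter recovery 50
indicators × 20 units × 4 dates (≈ 4,500 cells) at n = 999; null
calibration 200 replicate datasets of 2 ecosystems × 5 units × 6
indicators at two dates. These sizes give Monte-Carlo error comfortably
below the tolerances tested while completing in minutes on one CPU.

## Known limitations

* Reference states are point values; their uncertainty is not propagated.
* Covariance between indicators is ignored (replicates are independent
  across cells), so CIs are exact only under that independence.
* The p-value comparison uses unpaired replicate vectors; if the same
  underlying data informed both dates, the test is conservative.
* The 50% extra-representative share is split by base-weight
  proportionality among multiple extra-representatives; other splits are
  defensible.
* Discrete fitting minimises a piecewise-constant criterion by grid
  refinement; pathological triples far outside the searched ranges could
  in principle find only a local basin (the oracle tests bound this on a
  broad seeded panel).
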