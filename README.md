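# natureindex

A composite biodiversity index engine for national and regional
biodiversity assessment. It turns a sparse table of expert-elicited
indicator observations — each a mean with lower (25%) and upper (75%)
quartiles — into scaled, uncertainty-aware index values that can be
aggregated over indicators, major ecosystems, spatial units (e.g.
municipalities) and assessment years, and compared between dates with
simulation-based p-values.

The intended users are ecologists and environmental agencies running
indicator-based "state of nature" assessments, and methodologists studying
composite-indicator behaviour on synthetic data with known ground truth.

## The method

For indicator *i* in major ecosystem *j*, spatial unit *k* and year *t*,
the observed state *x<sub>ijkt</sub>* is treated as a draw from a
two-parameter distribution *L(a, b)*. The family and parameters are chosen
per cell by minimising

&nbsp;&nbsp;&nbsp;&nbsp;*C = m² + q<sub>l</sub>² + q<sub>u</sub>²*

where *m*, *q<sub>l</sub>*, *q<sub>u</sub>* are the deviations of the
distribution's expectation and quartiles from the elicited mean and
quartiles. Candidates are truncated-normal, Gumbel, log-normal, Weibull
and gamma for continuous variables; Poisson, zero-inflated Poisson and
negative binomial for counts. From the winning fit, *n* = 999 Monte-Carlo
replicates of the data-collection process are drawn (elicitations
duplicated across localities share one simulated vector).

Each replicate is scaled against the cell's reference state
*r<sub>ijk</sub>* — the indicator's expected value in an ecologically
sustainable system — by one of three models: *minimal* (min(x/r, 1),
degradation below the reference), *maximal* (1 below the reference, r/x
above), or *optimal* (their pointwise minimum; any departure degrades).
Scaled states lie in [0, 1] with 1 the reference condition.

The index for replicate *s* is the weighted mean
NI<sub>t</sub>(s) = Σ W<sub>ijkt</sub> · s<sub>ijkt</sub>(s) over
documented cells (undocumented cells carry δ = 0 and weight 0). Weights
implement four rules: ecosystem-membership fractions as base weights;
equal shares for the trophic/functional groups present, with
"extra-representative" indicators jointly capped at 50% of a slice; equal
shares for the ecosystems present in a unit; and area-proportional shares
across units. Weights are renormalised over documented cells at every date.
The index is reported as the median of the replicates with a 95% CI (2.5%
and 97.5% quantiles); dates are compared by the fraction of replicates in
which one exceeds the other (ties counted ½).

## Worked example

```python
from natureindex import GeneratorConfig, generate, nature_index

synth = generate(GeneratorConfig(true_states=0.65, noise=0.1, seed=42))
res = nature_index(synth.dataset, date=1990, n_sim=999, seed=1)
print(res.median, res.ci_low, res.ci_high)
```

Running `python examples/01_generate_and_index.py` prints:

```
dataset: 453 records, 15 indicators, 6 units, 3 ecosystems
index 1990: median 0.645, 95% CI [0.626, 0.664], 113 documented cells
configured truth: 0.650
```

The generator planted a true scaled state of 0.65; the pipeline recovers
it as 0.645 with a CI reflecting the experts' stated uncertainty
(relative spread 0.1). `examples/02_trend_and_comparison.py` shows a
four-date decline from 0.8 to 0.3 recovered as 0.801 → 0.299 with
non-overlapping CIs and a two-sided p below 1/999, and
`examples/03_fit_audit_and_scopes.py` shows the fitted-family audit
table, a single-ecosystem scope restricted to units with ≥ 20% of that
ecosystem's area, and documentation-gap statistics.

A thin CLI mirrors the library:

```bash
natureindex synth --seed 1 --out-dir data/
natureindex index data/ --date 1990 --n-sim 999 --seed 2
natureindex trend data/ --ecosystem eco0
natureindex compare data/ --date1 1950 --date2 2010
```

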