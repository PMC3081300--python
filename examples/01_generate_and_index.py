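"""Generate a synthetic elicitation dataset and compute a composite index.

Builds a small expert-elicitation dataset (3 ecosystems x 6 municipalities
x 4 dates) with a known true scaled state of 0.65, then runs the full
pipeline: per-cell distribution fitting, 999 Monte-Carlo replicates,
reference-state scaling, hierarchical weighting, aggregation.
"""

from natureindex import GeneratorConfig, generate, nature_index

synth = generate(GeneratorConfig(true_states=0.65, noise=0.1, seed=42))
ds = synth.dataset
print(f"dataset: {len(ds.records)} records, {len(ds.indicator_ids)} indicators, "
      f"{len(ds.unit_ids)} units, {len(ds.ecosystem_ids)} ecosystems")

res = nature_index(ds, date=1990, n_sim=999, seed=1)
print(f"index 1990: median {res.median:.3f}, "
      f"95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}], "
      f"{res.n_documented} documented cells")
truth = synth.truth.set_index(["scope", "date"])["true_index"][("country", 1990)]
print(f"configured truth: {truth:.3f}")
# The median should recover the configured true state within the CI; the CI
# width reflects the experts' elicited quartile spread (noise = 0.1).
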