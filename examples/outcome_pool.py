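"""Pool trial-reported outcomes and apply the >6% core-outcome filter.

Simulates 499 trials reporting outcomes with realistic probabilities
(mirroring reporting rates seen across AECOPD herbal-injection trials), then
tallies, filters, and merges with guideline/COS-recommended candidates.
"""

from cosel import pool, synth

records = synth.gen_extraction(
    499,
    reporting_probs={"fev1/fvc": 0.22, "paco2": 0.39, "crp": 0.22,
                     "6-minute walk test": 0.01, "mortality": 0.012},
    domains={"fev1/fvc": "disease progression", "paco2": "laboratory tests",
             "crp": "laboratory tests", "6-minute walk test": "exercise capacity",
             "mortality": "death"},
    seed=11,
)
tally = pool.tally_outcomes(records)
filtered = pool.frequency_filter(tally, total_trials=499, threshold_percent=6.0)
print(filtered.to_string(index=False))

merged = pool.merge_candidates(
    [("COS", [("mortality", "death")]),
     ("guideline", [("mortality", "death"), ("cat score", "quality of life")])],
    tally_core=filtered,
)
print("\n" + merged.to_string(index=False))
print("\nOutcomes reported in strictly more than 6% of trials enter the candidate")
print("pool; each candidate carries the set of sources that proposed it.")
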