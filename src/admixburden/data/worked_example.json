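{
  "description": "Worked excess-case scenario: a carrier allele at frequency 0.01 with odds ratio 1.3 at 1% prevalence yields ~25 heterozygous cases per 100,000 people versus ~20 under no effect, an excess of ~5 cases.",
  "allele_frequency": 0.01,
  "odds_ratio": 1.3,
  "prevalence": 0.01,
  "population_size": 100000,
  "expected_het_cases_null": 20,
  "expected_het_cases_observed": 25,
  "expected_excess": 5
}
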