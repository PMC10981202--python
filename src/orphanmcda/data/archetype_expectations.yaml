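# Predefined concordance expectations for the packaged archetype profiles:
# the curative and highly effective therapies should land above 50 points,
# the two symptomatic therapies below, ranked in the listed order, with at
# least a 40-point spread between the best and worst comparator.
above_50:
  - genetic curative therapy
  - highly effective chronic therapy
below_50:
  - high-quality symptomatic therapy
  - lower-quality symptomatic therapy
expected_order:
  - genetic curative therapy
  - highly effective chronic therapy
  - high-quality symptomatic therapy
  - lower-quality symptomatic therapy
min_spread: 40
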