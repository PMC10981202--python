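# orphanmcda

A config-driven multi-criteria decision analysis (MCDA) engine for assessing
the value of orphan drugs, built for health-technology-assessment (HTA)
committees deciding on reimbursement and procurement. It re-implements the
Emirates MCDA tool for orphan drugs — originally a spreadsheet built from an
eleven-expert consensus session in the UAE — as a reusable Python library and
command-line tool.

## The model

A drug is described by one categorical outcome selection per criterion (e.g.
*disease rarity = "Ultrarare disease"*, *cost-effectiveness = "Between 1-2x
GDP per capita"*). Each criterion `i` has a scoring function mapping its
outcome levels to fractions `f_i ∈ [0, 1]` and a normalized weight `w_i`
(`Σ w_i = 1`). The drug's value is the additive score

```
V = 100 · Σ_i  w_i · f_i        ∈ [0, 100]
```

Weights come from SMART & Swing elicitation: experts rank the criteria by
importance (ties allowed) and state each criterion's percentage importance
increase over the next-ranked one. The lowest-ranked criterion gets an
arbitrary base weight `b`; moving up rank by rank, each group's unnormalized
weight is the group below times `(1 + increase/100)`; normalization to a unit
sum removes `b`. Panel votes on every question are aggregated by arithmetic
mean.

The default criteria set ships with the package: ten criteria (cost-
effectiveness, magnitude of health gain, therapeutic alternative / unmet
need, disease severity, budget impact, disease rarity, clinical evidence,
burden on households, indication uniqueness, patient age), their printed
scoring functions, the consensus ranking with disease rarity and clinical
evidence tied at rank 6, and the weight-increase chain that normalizes to
weights of 25.1% down to 2.6%. The three orphan-specific criteria (rarity,
indication uniqueness, unmet need) jointly carry 23.1% of the weight.

A scored comparison can be validated against predefined expert expectations
with three concordance checks: each drug on the expected side of 50 points,
the expected rank order, and a minimum spread (default 40 points) between the
best and worst comparator.

## Worked example

Score and compare the four packaged archetype profiles (reconstructions of a
genetic curative therapy for an ultrarare disease, a highly effective chronic
therapy, and two symptomatic therapies of differing quality):

```
$ orphanmcda compare --profiles src/orphanmcda/data/archetype_profiles.csv
| rank | drug | total |
| --- | --- | --- |
| 1 | genetic curative therapy | 80.2 |
| 2 | highly effective chronic therapy | 54.4 |
| 3 | high-quality symptomatic therapy | 40.8 |
| 4 | lower-quality symptomatic therapy | 11.6 |
```

Each total is the weighted sum above: the curative therapy earns 80.2 of 100
points because it takes the full fraction on the heavily weighted health-gain
and unmet-need criteria despite a poor cost-effectiveness selection; the
lower-quality symptomatic therapy earns 11.6 because it sits at or near the
bottom level almost everywhere. Validating the same profiles against the
packaged expectations:

```
$ orphanmcda validate --profiles src/orphanmcda/data/archetype_profiles.csv \
    --expectations src/orphanmcda/data/archetype_expectations.yaml
...
**Threshold check: PASS**   (first two above 50, last two below)
**Rank-order check: PASS**
**Spread check: PASS** — observed 68.6 vs minimum 40.0
**Overall: PASS**
```

The same operations are available as library calls
(`orphanmcda.compare_drugs`, `orphanmcda.check_concordance`, …), and
`orphanmcda elicit` turns raw vote CSVs into a ranking, the unnormalized
swing chain, and normalized weights. `orphanmcda export-default` writes the
embedded criteria set to a standalone YAML config you can edit and pass back
via `--config`.

## Layout

- `src/orphanmcda/criteria.py` — domain types and the embedded default set
- `src/orphanmcda/elicitation.py` — vote aggregation and SMART & Swing weights
- `src/orphanmcda/scoring.py` — additive scoring, comparison, numeric classifiers
- `src/orphanmcda/validation.py` — three-part concordance checks
- `src/orphanmcda/config.py`, `reports.py`, `cli.py` — config I/O, report writers, CLI
- `src/orphanmcda/fixtures.py` — synthetic vote panels and archetype profiles
- `docs/methods.md` — modelling choices, parameters, and limitations
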