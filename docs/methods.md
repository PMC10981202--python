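# Methods

## The additive value model

The engine implements a classical additive MCDA value model. A criteria set
defines, for each criterion, an ordered ladder of categorical outcome levels
with fractional scores from 1 (best) to 0 (worst), strictly decreasing and
with the endpoints always attained in the default set. A drug profile selects
exactly one level per criterion; its score is `100 · Σ w_i f_i`, so the
all-best profile scores exactly 100 and the all-worst exactly 0, and raising
any single selection strictly raises the total whenever that criterion's
weight is positive. The model assumes preferential independence between
criteria — each criterion's contribution depends only on its own selection —
which is the standard (and acknowledged) simplification of additive MCDA; any
double counting between overlapping criteria (e.g. cost appearing in both
cost-effectiveness and budget impact) must be handled by the committee when
weighting, not by the engine.

Fractions are stored as proportions in [0, 1]; percent appears only at the
config and report surfaces. Scores are reported to one decimal point; full
precision is kept internally and per-criterion contributions are never
rounded before summation.

## SMART & Swing weights

Weights derive from a ranking (ties allowed, rank numbers contiguous from 1)
and a per-criterion percentage *weight increase* over the next-ranked
criterion. The chain assigns every criterion in the lowest rank group an
arbitrary positive base weight and multiplies upward group by group by
`(1 + increase/100)`; normalization divides by the total, which cancels the
base exactly (property-tested). Two interpretive choices were genuinely open
and are fixed as follows:

- **Tied groups.** Criteria tied at one rank receive identical weight. Within
  a tied group exactly one member carries the group's increase over the next
  rank and the others carry a 0% within-tie increase; the implementation
  therefore climbs by the maximum of the group's entries. This is the only
  reading under which the default set's printed one-decimal weights
  (25.1 … 2.6%) are reproduced exactly, which we verified numerically.
- **The lowest criterion's increase entry.** The lowest-ranked criterion has
  a recorded increase (25% for patient age in the default set) but nothing to
  swing against; the value is carried in the data model and excluded from the
  chain. Including it anywhere would break the exact reproduction above.

Vote aggregation is the plain arithmetic mean for every question — ranks,
increases, and criteria counts — with no trimming or participant weighting.
Mean-rank ties use an absolute tolerance of 1e-9: votes are small integers,
so exact ties are the only intended ties and the tolerance merely absorbs
float noise. The criteria-count vote is decided by plurality with ties going
to the larger count (keeping more criteria is the conservative outcome), and
truncation of a ranking drops whole rank groups from the bottom, refusing to
split a tie.

## Numeric classifiers

The budget-impact and cost-effectiveness criteria are defined by numeric
bands whose printed boundaries overlap ("0.01–0.05%" followed by
"0.05–0.10%"). Both helper classifiers adopt half-open intervals with each
boundary belonging to the band that starts there — budget share in
[0, 0.01), [0.01, 0.05), [0.05, 0.10), [0.10, 0.30), [0.30, ∞) percent of
the annual drug budget, and the ICER-to-GDP-per-capita ratio in [0, 1),
[1, 2), [2, 3), [3, 5), [5, 10), [10, ∞). This yields a total deterministic
rule (no gaps, no overlaps; property-tested). The classifiers are optional
conveniences: the scorer itself consumes categorical selections only, as the
original spreadsheet did, and disease rarity/severity classes are likewise
the assessor's own selections (the ultrarare convention documented in the
default set is roughly 1 per 50,000 population).

## Concordance validation

Three predefined deterministic checks compare scored drugs against prior
expert expectations: (i) each drug strictly above or strictly below 50
points; (ii) the observed descending-score order equals the expected order;
(iii) the spread between the highest and lowest total is at least a minimum
(default 40 points). All comparisons run on totals rounded to one decimal —
the reporting precision — so a spread of 39.7 against a 40-point minimum is
a fail. A total of exactly 50.0 satisfies neither side of the threshold and
is flagged indeterminate. An observed tie fails the rank check unless the
expectation explicitly declares the tie as one tier. No statistical
concordance measure (e.g. kappa) is computed; the procedure is intentionally
three yes/no checks.

## Synthetic fixtures

The synthetic vote generator emulates the structured consensus session the
default set came from: eleven participants by default, each submitting a
complete rank permutation, per-criterion increase votes, and a desired
criteria count. `rank_dispersion` adds Gaussian jitter (in rank positions) to
each ballot before re-sorting; `increase_sd` adds Gaussian noise (percentage
points, clipped at 0) to increase votes; both default to 0, i.e. the panel is
pinned at the consensus. The generator does not emulate features of real
panels such as participant-specific bias, strategic voting, or attrition, so
passing pipeline tests show the machinery is correct, not that any particular
real panel would be well aggregated by the mean.

Because each synthetic ballot is a strict permutation, a seeded *tied*
ranking aggregates to the consensus order with the tie split into adjacent
ranks. For the default set this is harmless: the tied group's within-tie
increase is 0%, so the split ranking produces the identical weight vector —
which is why the zero-dispersion panel reproduces the published weights
end to end.

The four archetype profiles (curative ultrarare gene therapy, highly
effective chronic therapy, high- and lower-quality symptomatic therapies) are
explicit reconstructions: the selections behind the original validation test
cases were never published, so ours are chosen to be clinically plausible and
to meet the qualitative expectations (first two above 50 points, last two
below, in that order). Their exact totals (80.2, 54.4, 40.8, 11.6) are a
property of this reconstruction and are deliberately never asserted against
the originally reported case totals. The archetype ordering is stable under
±1-percentage-point perturbations of any single criterion weight (tested),
so the fixture is not a knife-edge construction.

## Numerical and interface choices

- Weights sum to 1 within 1e-12 after normalization; score totals equal the
  sum of contributions within 1e-9.
- Drug comparisons sort by full-precision total (ties broken by name for
  determinism); *reported* ranks share a rank when totals tie at one-decimal
  precision, consistent with the validation checks.
- Configs are YAML (JSON accepted as the same schema); schema errors carry
  JSON-pointer-style locations. Profile CSVs mirror the original spreadsheet
  layout: criteria as rows, drugs as columns, cells holding level labels.
- Report writers (CSV/JSON/markdown) are byte-deterministic for identical
  inputs; CSV uses RFC 4180 quoting and CRLF line endings.
- The engine accepts any number of drugs in a comparison; the original
  spreadsheet's four-drug limit is not preserved.
- No reimbursement cutoff threshold is implemented: the tool yields a score,
  and where to draw a funding line is a policy question outside its scope.

## Problem sizes

Everything here is desk-scale: ten criteria, panels of order ten
participants, and handfuls of drugs. The full test suite, including the
property suites (50–200 randomized instances each), runs in a few seconds;
the acceptance script in well under a second.
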