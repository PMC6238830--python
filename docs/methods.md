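# Methods

## Data model and conventions

A participant is a pair of records: four nonnegative use counts over the
study window (`glucose_count`, `food_count`, `exercise_count`, and
`generic_count`, constrained to equal the sum of the other three), and a
baseline / 6-month HbA1c pair in percent. The reduction
Δ = baseline − 6-month is derived, never stored, so the sign convention
(positive = improvement) cannot drift; the clinically significant
threshold is Δ ≥ 0.5% (5.5 mmol/mol), inclusive. HbA1c is a 0.1%-precision
measurement, so reductions are rounded to one decimal before the value set
and item labels are formed, and value-set membership is checked to 1e-9
after that rounding.

Cohort construction joins usage to HbA1c records: usage without a matching
HbA1c record is an error naming the participant (silent dropping hides
data corruption), while HbA1c-only participants get an all-zero usage
record — they completed the trial without using the software.

## Discretization

The bin tables encode domain knowledge about plausible tracking cadence
(glucose monitoring up to ~22×/week for poorly controlled patients,
exercise logging rarely above 6×/week) and are deliberately fixed, not
data-driven. Three numerical choices resolve ambiguities in such printed
tables:

* **Touching bounds** (e.g. glucose bins `5–24` then `24–120`) are read as
  half-open `[lower, upper)` with the top bin upper-inclusive; only this
  reading is consistent with the per-week "meaning" column (24–120 uses
  over 24 weeks ⇔ 1–4.9/week). Group 1 of every attribute is exactly {0}.
* **Gaps** (the glucose table has no bin for counts 1–4) are repaired
  upward to the lowest nonzero bin, the semantically nearest, with a
  warning per occurrence.
* **Counts above the top bound raise an error** rather than clamp: the
  generator never produces them, and real data beyond the table almost
  certainly indicates a unit mistake.

Zero counts emit no item. The alternative — an explicit "zero" item per
unused tracker — would make every mined set also describe non-use; the
published per-tracker support tabulations show no zero items, and
suppression keeps item sets interpretable as combinations of trackers
actually used.

## At-least expansion and its redundancy

Expanding Δ into all `a1c6_at_least_a` items with a ≤ Δ makes an ordinal
outcome usable by a set-based miner, at a structural cost: within any
transaction the outcome items form a downward-closed chain, so the support
of any item set containing several chain items equals the support of its
largest threshold alone. Consequently every subset of a frequent chain is
frequent and the unpruned lattice grows as 2^k in the number of frequent
thresholds k. The three pruning rules (drop pure-outcome sets, collapse
chains to their largest threshold, merge the duplicates that collapsing
creates) are applied in that order — collapsing before deduplication is
what makes the duplicate-merge case arise. Duplicate sets with unequal
supports are impossible if the upstream stages are correct, so the
deduplicator treats them as an internal error instead of averaging them.
The pipeline runner additionally caps itemset size at 5 (4 tracker
attributes + 1 outcome item): larger sets are pure expansion redundancy,
yet without the cap they dominate the lattice exponentially. The miner
itself (`MiningConfig`) leaves the size unbounded by default.

Threshold comparison during collapsing is numeric on the parsed value, not
lexicographic on labels (−0.8 < 0.5 although "-0.8" > "0.5" as strings).

## Mining

Support is `100 · |{t : S ⊆ t}| / n` and the floor is converted to a
minimum count with a ceiling: "a minimum of 5%" of 48 participants means
at least 3 supporting transactions, since 2/48 = 4.17% is below the floor.
The miner is the classic level-wise algorithm with prefix-join candidate
generation and subset pruning, over a vertical bitmask representation of
the (small) transaction database. Output order is deterministic — size,
then label-lexicographic — so runs and tests compare stably.

## Exact test

The 2×2 table cross-classifies software users (at least one primary-tracker
event; participants with zero use are excluded) by all-three-trackers
versus fewer and by clinical reduction versus not. Conditional on both
margins the first cell follows Fisher's noncentral hypergeometric law with
odds-ratio parameter ψ. Two estimates are computed:

* the **sample odds ratio** ad/bc, reported for reference;
* the **conditional MLE**, the headline estimate: the conditional mean
  E_ψ[A] is strictly increasing in log ψ, so the likelihood equation
  E_ψ[A] = a is solved by bracketing and bisection on log ψ to a relative
  tolerance of 1e-10, with the boundary cases a = support min → ψ̂ = 0 and
  a = support max → ψ̂ = ∞. This is the estimator standard exact-test
  implementations report, and on the table (6, 6; 23, 4) it rounds to 0.18
  where the sample odds ratio rounds to 0.17.

The two-sided p sums the central (ψ = 1) point probabilities of all tables
with the observed margins that are no more probable than the observed
table, with a relative slack of 1e-7 on the comparison — the standard
guard against floating-point ties flipping a strict inequality. Point
probabilities are computed in log space from log-gamma binomials. A table
with a zero margin is degenerate: p = 1 and the odds ratio is undefined
(flagged, returned as NaN). Tests verify the implementation against direct
integer-arithmetic enumeration, a dense-grid likelihood argmax, and an
independently implemented reference.

## Synthetic cohort

The generator emulates the structure of a 48-completer intervention arm:

| group | n | mean Δ | SD | weekly rates |
|---|---|---|---|---|
| food only | 2 | 1.95 | 1.20 | food 1–3.9 |
| glucose only | 7 | 1.74 | 1.00 | glucose 1–4.9 |
| exercise only | 0 | — | — | — |
| glucose + exercise | 11 | 0.97 | 0.38 | glucose 1–4.9, exercise 0.5–0.9 |
| glucose + food | 3 | 1.07 | 0.45 | glucose 5–7.9, food 1–3.9 |
| food + exercise | 0 | — | — | — |
| all three | 6 | 1.55 | 0.49 | glucose 5–7.9, food 4–6.9, exercise 1–1.9 |
| non-significant users | 10 | 0.1 | 0.3 | 6 all-three, 2 glucose-only, 2 glucose+exercise |
| non-users | 9 | 0.2 | 0.5 | all zero |

Published SDs are treated as sample SDs. The 6/4 split of the ten
non-significant users between all-three and fewer-than-three is forced by
the 2×2 table the test must reproduce (6, 6; 23, 4). Baseline HbA1c is
Normal(8.88, 1.30) floored at 6.0% and rounded to 0.01; the 6-month value
is baseline − Δ.

Design choices where the published description is open:

* **Truncation, not clipping.** Reductions are drawn from normal
  distributions truncated at the 0.5% boundary by rejection sampling
  (≥ 0.5 for the significant groups, < 0.5 after rounding for the
  non-significant ones). Clipping would create an atom exactly at 0.5 that
  distorts the at-least expansion.
* **Mean calibration.** Truncating a Normal(μ, σ) at 0.5 shifts its mean
  (by ≈ +0.08 for the glucose+exercise group), so each truncated group's
  *proposal* mean is found by root-finding so the truncated distribution's
  mean equals the target group mean. The published group means are
  themselves post-selection (groups are defined by Δ ≥ 0.5), so matching
  the truncated mean to them is the faithful emulation. Group SDs are the
  proposal SDs; the realized SD of a truncated draw is somewhat smaller,
  which the tests do not constrain.
* **Uniform usage.** Counts are uniform over the integer range implied by
  the group's weekly-rate interval × 24 weeks (minimum 1 for used
  trackers); no within-group usage distribution is published. Rate ranges
  sit strictly inside single discretization bins, so combination grouping
  recovers the spec's memberships with zero misclassification — a
  structural test, not a statistical one.
* **Uniform timestamps.** Event-level output spreads each count uniformly
  over the 24 weeks from a fixed study start; no temporal pattern is
  modelled.

What the generator does **not** emulate: within-person behavior change over
time, coaching contact, dropout, correlation between usage intensity and
outcome within a group, or measurement error in HbA1c beyond 0.1%
rounding. Passing tests therefore show the pipeline's arithmetic and
algorithms are correct and that group-level structure is recovered; they
do not validate the behavioral claim on real data.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng(seed)`; equal
(spec, seed) gives byte-identical CSV output. The test suite mines at
support floors of 15–40% with size caps of 3–4 on the 48-participant
cohort, checks miner/oracle equivalence on ~100 random instances of up to
12 items, and exact-test/oracle equivalence on 200 random tables with
cells up to 8; distributional recovery uses 100–200 seeds. The full
pipeline at the default 5% floor and size cap 5 mines ~92k frequent sets
(~645 after pruning) in under two seconds.

## Known limitations

* The pipeline reports frequent item sets and supports only; no
  confidence/lift rule derivation, no confidence intervals or covariate
  adjustment around the odds ratio, and no mid-p variant.
* The discretization tables cap plausible use; data from longer windows
  or different apps need a custom YAML table.
* With n = 48, exact-test p-values are discrete and the miner's 5% floor
  equals 3 participants; single-participant idiosyncrasies can clear it.
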