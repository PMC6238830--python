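# trackermine

Association mining of smartphone self-monitoring logs against HbA1c change
in type 2 diabetes.

Patients in mHealth-supported diabetes programs log blood glucose readings,
meals and exercise through smartphone trackers. A recurring clinical
question is which *pattern* of tracker use goes with better glycemic
outcomes: is it better to log everything, or to focus on one or two
behaviors? `trackermine` is a tested pipeline for answering that question
from two flat files — per-participant tracker-use counts (or an event-level
log) over a 24-week window, and baseline / 6-month HbA1c values. It is
aimed at analysts of behavioral-intervention trials and mHealth usage data.

## Method

The pipeline has four stages:

1. **Discretization.** Each use-frequency attribute (`glucose_count`,
   `food_count`, `exercise_count` and their sum `generic_count`) is mapped
   to an ordinal group calibrated to typical weekly use (e.g. a glucose
   count of 120–192 over 24 weeks ≈ 5–7.9 uses/week). Bins are half-open
   `[lower, upper)` with the top bin closed; zero counts emit no item, so
   mined sets describe only trackers actually used.

2. **At-least expansion.** The HbA1c reduction Δ = baseline − 6-month is
   kept at full resolution rather than binned: for the sorted set of
   observed values {a₁ < … < aₘ}, a participant with reduction Δ receives
   every item `a1c6_at_least_a` with a ≤ Δ. The smallest reduction carries
   one item, the largest carries all m.

3. **Frequent-itemset mining and pruning.** An a priori (level-wise) miner
   returns every item set whose support — the percentage of participants
   whose item set contains it — meets a floor (default 5%, i.e. at least
   ⌈0.05·n⌉ participants). Three post-processing rules then remove the
   redundancy the expansion created: sets of only `a1c6_at_least_*` items
   are dropped, chained thresholds collapse to the largest, and the
   resulting duplicates (which must carry equal support) merge.

4. **Exact test.** Software users are cross-classified as (used all three
   trackers vs. fewer) × (clinically significant reduction, Δ ≥ 0.5%,
   vs. not), and the 2×2 table is tested with Fisher's exact test:
   a two-sided p by the point-probability rule, and the odds ratio as the
   conditional maximum-likelihood estimate — the noncentral hypergeometric
   parameter ψ solving E_ψ[A] = a given both margins.

Because raw cohort data of this kind are rarely public, the package ships a
seeded generator (`trackermine.synthetic`) reproducing the structure of a
48-participant intervention cohort: 39 software users, 29 of them with a
clinically significant reduction, spread over tracker combinations with
published per-group mean/SD reductions.

## Worked example

```sh
trackermine simulate --seed 1 --out-dir data/
trackermine analyze --usage data/usage_counts.csv --hba1c data/hba1c.csv \
    --threshold 0.5 --min-support 5 --out report.json
```

prints

```
n=48 users=39 soi=29 OR=0.183738 p=0.042704 -> report.json
```

Of the 48 simulated completers, 39 used the software and 29 of those
achieved a reduction of at least 0.5% HbA1c. The conditional-MLE odds
ratio of 0.18 (two-sided exact p = 0.043) says that users of all three
trackers were *less* likely to achieve the clinical reduction than users
of one or two trackers. `report.json` also carries the per-combination
summaries — e.g. with seed 1 the six users of all three trackers averaged
a 1.65% reduction — the single/dual/triple-tracker shares (31%, 48%, 21%
of the 29), and the mining summary: 92,225 frequent item sets collapse to
645 after the three pruning rules. The same steps are available as library
calls (`generate`, `build_transactions`, `apriori`, `prune`,
`run_pipeline`).

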