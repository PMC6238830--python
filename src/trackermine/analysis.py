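"""Clinical subgroup extraction, tracker-combination summaries and the exact test.

The analysis arm of the pipeline answers the study's headline question:
among participants who actually used the software, is use of all three
trackers (vs. one or two) associated with achieving a clinically
significant HbA1c reduction (>= 0.5%)?  It proceeds in four steps:

* extract the subpopulation of interest (SOI): software users whose
  reduction meets the clinical threshold;
* classify each user by the exact set of trackers used (count >= 1);
* summarise reduction per combination (n, mean, sample SD) and report
  single/dual/triple-tracker shares;
* form the 2x2 table (all three trackers vs. fewer) x (clinical reduction
  vs. not) over all software users and apply Fisher's exact test.

The exact test reports the conditional maximum-likelihood odds ratio — the
noncentral hypergeometric parameter under which the expected first cell
equals the observed one — and a two-sided p-value by the point-probability
rule (sum of all tables, at fixed margins, no more probable than the
observed one).  These are the conventions of the standard exact-test
implementations for count data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .usage import Cohort, UsageRecord, TRACKERS

#: Tracker combinations in canonical (reporting) order, plus "none".
COMBINATIONS: tuple[str, ...] = (
    "food_only",
    "glucose_only",
    "exercise_only",
    "glucose_exercise",
    "glucose_food",
    "food_exercise",
    "all_three",
    "none",
)

CLINICAL_THRESHOLD_DEFAULT = 0.5  # HbA1c % reduction
_TOL = 1e-9

_COMBO_BY_USED: dict[frozenset, str] = {
    frozenset(): "none",
    frozenset({"food"}): "food_only",
    frozenset({"glucose"}): "glucose_only",
    frozenset({"exercise"}): "exercise_only",
    frozenset({"glucose", "exercise"}): "glucose_exercise",
    frozenset({"glucose", "food"}): "glucose_food",
    frozenset({"food", "exercise"}): "food_exercise",
    frozenset(TRACKERS): "all_three",
}

N_TRACKERS: dict[str, int] = {
    "none": 0,
    "food_only": 1,
    "glucose_only": 1,
    "exercise_only": 1,
    "glucose_exercise": 2,
    "glucose_food": 2,
    "food_exercise": 2,
    "all_three": 3,
}


def classify_combination(record: UsageRecord, min_uses: int = 1) -> str:
    """The exact set of trackers used; "used" means count >= ``min_uses``."""
    used = frozenset(t for t in TRACKERS if record.count(t) >= min_uses)
    return _COMBO_BY_USED[used]


def software_users(cohort: Cohort) -> Cohort:
    """Participants with at least one primary-tracker event."""
    return cohort.subset(
        u.participant_id for u, _ in cohort if u.generic_count >= 1
    )


def extract_soi(cohort: Cohort, threshold: float = CLINICAL_THRESHOLD_DEFAULT) -> Cohort:
    """Software users whose HbA1c reduction meets the clinical threshold."""
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return cohort.subset(
        u.participant_id
        for u, h in cohort
        if u.generic_count >= 1 and h.a1c6month_diff >= threshold - _TOL
    )


@dataclass(frozen=True)
class GroupSummary:
    combination: str
    n_users: int
    mean_reduction: float
    sd_reduction: float  # sample SD; 0 when n <= 1


def summarize_groups(soi: Cohort) -> list[GroupSummary]:
    """Per-combination n, mean and sample SD of the HbA1c reduction.

    All seven tracker combinations are reported (empty ones with zeros), in
    the canonical order; participants with no tracker use are excluded.
    """
    by_combo: dict[str, list[float]] = {c: [] for c in COMBINATIONS if c != "none"}
    for u, h in soi:
        combo = classify_combination(u)
        if combo != "none":
            by_combo[combo].append(h.a1c6month_diff)
    out = []
    for combo, diffs in by_combo.items():
        n = len(diffs)
        out.append(
            GroupSummary(
                combo,
                n,
                mean(diffs) if n else 0.0,
                stdev(diffs) if n > 1 else 0.0,
            )
        )
    return out


def tracker_count_shares(summaries: Sequence[GroupSummary]) -> dict[str, dict[str, float]]:
    """Single/dual/triple-tracker user counts and integer-percent shares."""
    total = sum(s.n_users for s in summaries)
    shares = {}
    for label, k in (("single", 1), ("dual", 2), ("triple", 3)):
        n = sum(s.n_users for s in summaries if N_TRACKERS[s.combination] == k)
        shares[label] = {"n": n, "pct": round(100.0 * n / total) if total else 0.0}
    return shares


# ---------------------------------------------------------------------------
# 2x2 table and the exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts: rows = all three trackers / fewer, cols = clinical reduction / not."""

    a: int  # all three & clinical reduction
    b: int  # all three & no clinical reduction
    c: int  # fewer than three & clinical reduction
    d: int  # fewer than three & no clinical reduction

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


def build_2x2(users: Cohort, threshold: float = CLINICAL_THRESHOLD_DEFAULT) -> TwoByTwoTable:
    """Partition software users by (all three trackers) x (clinical reduction)."""
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    for u, h in users:
        if u.generic_count < 1:
            raise ValueError(
                f"participant {u.participant_id} has no tracker use; the 2x2 "
                "covers software users only"
            )
        three = N_TRACKERS[classify_combination(u)] == 3
        reduced = h.a1c6month_diff >= threshold - _TOL
        key = ("a" if reduced else "b") if three else ("c" if reduced else "d")
        cells[key] += 1
    return TwoByTwoTable(**cells)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # conditional MLE; nan when the table is degenerate
    p_two_sided: float
    method: str = "conditional-MLE / point-probability two-sided"
    degenerate: bool = False


def _log_pmf_terms(table: TwoByTwoTable) -> tuple[np.ndarray, np.ndarray]:
    """Support of the first cell given the margins, and log C(r1,k)+log C(r2,c1-k)."""
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return ks, log_comb(r1, ks) + log_comb(r2, c1 - ks)


def _conditional_mean(log_terms: np.ndarray, ks: np.ndarray, log_psi: float) -> float:
    lw = log_terms + ks * log_psi
    w = np.exp(lw - logsumexp(lw))
    return float(np.dot(w, ks))


def fisher_exact(table: TwoByTwoTable) -> FisherResult:
    """Exact test of a 2x2 table conditional on both margins.

    The p-value sums, at odds ratio 1, the central hypergeometric point
    probabilities of every table (with the observed margins) no more
    probable than the observed one, with a relative slack of 1e-7 on the
    comparison to guard against floating-point ties.  The odds ratio is the
    conditional MLE, found by monotone root-finding of the conditional mean
    equation E_psi[A] = a on the log-odds scale.
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1, c2 = table.a + table.c, table.b + table.d
    if min(r1, r2, c1, c2) == 0:
        return FisherResult(math.nan, 1.0, degenerate=True)

    ks, log_terms = _log_pmf_terms(table)
    log_p = log_terms - logsumexp(log_terms)
    p_obs = float(np.exp(log_p[ks == table.a][0]))
    p_value = float(np.exp(log_p)[np.exp(log_p) <= p_obs * (1 + 1e-7)].sum())
    p_value = min(p_value, 1.0)

    # conditional MLE of the odds ratio
    if table.a == ks[0]:
        odds_ratio = 0.0
    elif table.a == ks[-1]:
        odds_ratio = math.inf
    else:
        def f(t: float) -> float:
            return _conditional_mean(log_terms, ks, t) - table.a

        lo, hi = -1.0, 1.0
        while f(lo) > 0:
            lo *= 2
        while f(hi) < 0:
            hi *= 2
        # bisection on log psi; the conditional mean is strictly increasing
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-10 * max(1.0, abs(lo)):
                break
        odds_ratio = math.exp(0.5 * (lo + hi))

    return FisherResult(odds_ratio, p_value)


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------


def run_pipeline(
    cohort: Cohort,
    threshold: float = CLINICAL_THRESHOLD_DEFAULT,
    min_support_pct: float = 5.0,
    mine: bool = True,
    max_itemset_size: int | None = 5,
) -> dict:
    """Run discretize -> mine -> prune -> analyze and collect a JSON-able report.

    The miner itself places no bound on itemset size, but the pipeline caps
    it at 5 by default: a transaction holds at most 4 tracker items, and any
    set with two or more HbA1c threshold items collapses to its largest
    threshold during pruning, so sets beyond 4 tracker items + 1 outcome
    item are pure expansion redundancy.  Without the cap the chain of
    threshold items makes the frequent lattice exponentially large (every
    subset of a frequent chain is frequent) while adding nothing that
    survives pruning.
    """
    from .discretize import build_transactions, sorted_labels
    from .mining import MiningConfig, apriori
    from .pruning import prune

    users = software_users(cohort)
    soi = extract_soi(cohort, threshold)
    summaries = summarize_groups(soi)
    shares = tracker_count_shares(summaries)
    table = build_2x2(users, threshold)
    fisher = fisher_exact(table)

    report: dict = {
        "threshold_pct": threshold,
        "n_total": len(cohort),
        "n_software_users": len(users),
        "n_soi": len(soi),
        "group_summaries": [
            {
                "combination": s.combination,
                "n_users": s.n_users,
                "mean_reduction": round(s.mean_reduction, 4),
                "sd_reduction": round(s.sd_reduction, 4),
            }
            for s in summaries
        ],
        "tracker_count_shares": shares,
        "two_by_two": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "odds_ratio_conditional_mle": round(fisher.odds_ratio, 6)
        if math.isfinite(fisher.odds_ratio)
        else fisher.odds_ratio,
        "odds_ratio_sample": round(table.sample_odds_ratio(), 6),
        "p_two_sided": round(fisher.p_two_sided, 6),
        "fisher_method": fisher.method,
    }
    if mine:
        transactions = build_transactions(cohort)
        frequent = apriori(
            transactions,
            MiningConfig(min_support_pct=min_support_pct, max_itemset_size=max_itemset_size),
        )
        pruned = prune(frequent)
        report["mining"] = {
            "min_support_pct": min_support_pct,
            "n_transactions": len(transactions),
            "n_frequent_itemsets": len(frequent),
            "n_pruned_itemsets": len(pruned.itemsets),
            "removed_only_a1c": pruned.removed_only_a1c,
            "collapsed_a1c": pruned.collapsed_a1c,
            "deduplicated": pruned.deduplicated,
            "top_itemsets": [
                {
                    "items": " ".join(sorted_labels(f.items)),
                    "count": f.count,
                    "support_pct": round(f.support_pct, 1),
                }
                for f in sorted(
                    pruned.itemsets, key=lambda f: (-f.support_pct, len(f.items))
                )[:10]
            ],
        }
    return report
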