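"""Post-mining removal of the redundancies the at-least expansion introduces.

The at-least expansion encodes one ordinal HbA1c value as a chain of
threshold items, which inflates the mined output in three predictable ways.
Three rules, applied in order, undo this:

1. **Drop pure-HbA1c sets.**  A frequent set made only of
   ``a1c6_at_least_*`` items restates the outcome distribution and says
   nothing about tracker use.
2. **Collapse chained thresholds.**  Within one set, a higher threshold
   implies every lower one, so only the largest (numerically, on the parsed
   threshold) is kept.  Support is untouched: the discarded items were
   implied by the kept one in every supporting transaction.
3. **Deduplicate.**  Collapsing can make two sets identical; duplicates
   must then carry identical support (anything else signals an upstream
   bug, and is raised as an internal-consistency error), and one copy is
   kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .discretize import sorted_labels
from .errors import ConsistencyError
from .mining import FrequentItemSet

_SUPPORT_TOL = 1e-9


@dataclass(frozen=True)
class PrunedResult:
    itemsets: list[FrequentItemSet]
    removed_only_a1c: int
    collapsed_a1c: int
    deduplicated: int
    #: provenance per surviving set, aligned with ``itemsets``:
    #: "kept", "collapsed-from:<labels>" or "merged:<k> copies"
    provenance: list[str] = field(default_factory=list)


def drop_pure_a1c(itemsets: Sequence[FrequentItemSet]) -> list[FrequentItemSet]:
    """Remove sets consisting solely of HbA1c threshold items."""
    return [f for f in itemsets if any(not i.is_a1c for i in f.items)]


def collapse_a1c(itemsets: Sequence[FrequentItemSet]) -> list[FrequentItemSet]:
    """Keep only the largest HbA1c threshold item within each set."""
    out = []
    for f in itemsets:
        a1c = [i for i in f.items if i.is_a1c]
        if len(a1c) <= 1:
            out.append(f)
            continue
        top = max(a1c, key=lambda i: i.a1c_threshold)
        kept = frozenset(i for i in f.items if not i.is_a1c) | {top}
        out.append(FrequentItemSet(kept, f.count, f.support_pct))
    return out


def deduplicate(itemsets: Sequence[FrequentItemSet]) -> tuple[list[FrequentItemSet], int]:
    """Merge exact-duplicate sets; duplicate supports must agree exactly."""
    seen: dict[frozenset, FrequentItemSet] = {}
    n_removed = 0
    for f in itemsets:
        prev = seen.get(f.items)
        if prev is None:
            seen[f.items] = f
        else:
            if abs(prev.support_pct - f.support_pct) > _SUPPORT_TOL or prev.count != f.count:
                raise ConsistencyError(
                    f"duplicate item set {{{' '.join(sorted_labels(f.items))}}} with "
                    f"unequal supports {prev.support_pct} vs {f.support_pct}"
                )
            n_removed += 1
    return list(seen.values()), n_removed


def prune(itemsets: Sequence[FrequentItemSet]) -> PrunedResult:
    """Apply the three rules in order and account for every removal."""
    survivors = drop_pure_a1c(itemsets)
    n_dropped = len(itemsets) - len(survivors)

    collapsed = collapse_a1c(survivors)
    n_collapsed = sum(
        1 for before, after in zip(survivors, collapsed) if before.items != after.items
    )
    collapse_note = {
        after.items: f"collapsed-from:{' '.join(sorted_labels(before.items))}"
        for before, after in zip(survivors, collapsed)
        if before.items != after.items
    }

    deduped, n_deduped = deduplicate(collapsed)
    multiplicity: dict[frozenset, int] = {}
    for f in collapsed:
        multiplicity[f.items] = multiplicity.get(f.items, 0) + 1

    provenance = []
    for f in deduped:
        if multiplicity[f.items] > 1:
            provenance.append(f"merged:{multiplicity[f.items]} copies")
        elif f.items in collapse_note:
            provenance.append(collapse_note[f.items])
        else:
            provenance.append("kept")

    return PrunedResult(deduped, n_dropped, n_collapsed, n_deduped, provenance)


def write_pruned(result: PrunedResult, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            (" ".join(sorted_labels(f.items)), f.count, round(f.support_pct, 6), prov)
            for f, prov in zip(result.itemsets, result.provenance)
        ],
        columns=["items", "count", "support_pct", "provenance"],
    )
    df.to_csv(path, index=False)
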