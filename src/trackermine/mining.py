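"""Level-wise (a priori) frequent-itemset mining with a percentage support floor.

Support of an item set is the percentage of transactions (participants)
whose item set contains it.  The miner exploits downward closure: every
subset of a frequent set is frequent, so size-k candidates are generated
only by joining size-(k-1) frequent sets and are pruned if any (k-1)-subset
is infrequent.  With a 5% floor the minimum transaction count is the
ceiling of ``0.05 * n`` — "a minimum of 5%" makes any lower count
inadmissible (2 of 48 is 4.17%, below the floor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .discretize import Item, Transaction, sorted_labels


@dataclass(frozen=True)
class FrequentItemSet:
    items: frozenset[Item]
    count: int
    support_pct: float


@dataclass(frozen=True)
class MiningConfig:
    min_support_pct: float = 5.0
    max_itemset_size: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_support_pct <= 100:
            raise ValueError(f"min_support_pct must be in (0, 100], got {self.min_support_pct}")

    def min_count(self, n_transactions: int) -> int:
        return math.ceil(self.min_support_pct / 100.0 * n_transactions)


def support(items: Iterable[Item], transactions: Sequence[Transaction]) -> float:
    """Percentage of transactions containing every item of ``items``.

    The empty set is contained in every transaction, so its support is 100.
    """
    if len(transactions) == 0:
        raise ValueError("support is undefined over an empty transaction collection")
    query = frozenset(items)
    hits = sum(1 for t in transactions if query <= t.items)
    return 100.0 * hits / len(transactions)


def _sort_key(items: frozenset[Item]) -> tuple[int, tuple[str, ...]]:
    return (len(items), tuple(sorted_labels(items)))


def apriori(
    transactions: Sequence[Transaction], config: MiningConfig | None = None
) -> list[FrequentItemSet]:
    """All item sets whose support meets the floor, sorted by (size, labels)."""
    if config is None:
        config = MiningConfig()
    n = len(transactions)
    if n == 0:
        raise ValueError("apriori requires a nonempty transaction collection")
    min_count = config.min_count(n)

    # vertical representation: per item, a bitmask of supporting transactions
    cover: dict[Item, int] = {}
    for pos, t in enumerate(transactions):
        bit = 1 << pos
        for item in t.items:
            cover[item] = cover.get(item, 0) | bit

    counts: dict[tuple[Item, ...], int] = {}

    # L1; items kept in label order so every itemset is a sorted tuple
    level: dict[tuple[Item, ...], int] = {}
    for item, mask in cover.items():
        c = mask.bit_count()
        if c >= min_count:
            level[(item,)] = mask
            counts[(item,)] = c

    k = 1
    while level and (config.max_itemset_size is None or k < config.max_itemset_size):
        k += 1
        # join step: two size-(k-1) sets sharing their first k-2 items
        by_prefix: dict[tuple[Item, ...], list[tuple[Item, ...]]] = {}
        for tup in sorted(level, key=lambda t: tuple(i.value_label for i in t)):
            by_prefix.setdefault(tup[:-1], []).append(tup)
        next_level: dict[tuple[Item, ...], int] = {}
        for group in by_prefix.values():
            for a, b in combinations(group, 2):
                cand = a + (b[-1],)
                # prune step: all (k-1)-subsets must be frequent
                if any(
                    cand[:j] + cand[j + 1:] not in level for j in range(k - 2)
                ):
                    continue
                mask = level[a] & level[b]
                c = mask.bit_count()
                if c >= min_count:
                    next_level[cand] = mask
                    counts[cand] = c
        level = next_level

    out = [
        FrequentItemSet(frozenset(s), c, 100.0 * c / n)
        for s, c in counts.items()
    ]
    out.sort(key=lambda f: _sort_key(f.items))
    return out
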