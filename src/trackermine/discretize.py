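"""Discretization of tracker-use counts and at-least expansion of HbA1c change.

Two preprocessing steps turn a cohort into transactions for itemset mining:

1.  Each of the four use-frequency attributes is binned into ordinal groups
    calibrated to typical weekly use (e.g. a glucose count of 120-192 over
    24 weeks means 5-7.9 uses per week).  Bins are half-open ``[lower,
    upper)`` with the top bin closed, and group 1 of every attribute is
    exactly {0}.  Zero counts produce no item, so mined item sets describe
    only trackers actually used.

2.  The HbA1c reduction is not binned.  Instead it is expanded into the
    chain of every threshold it meets: a participant whose reduction is
    ``d`` receives one ``a1c6_at_least_a`` item for every distinct observed
    cohort value ``a <= d``.  The participant with the smallest reduction
    therefore carries one such item and the participant with the largest
    carries them all.  This keeps an ordinal outcome mineable by a
    set-based algorithm at the cost of redundancies that are removed after
    mining (see :mod:`trackermine.pruning`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import yaml

from .errors import CsvFormatError, OutOfRangeError, SpecError
from .usage import Cohort

logger = logging.getLogger(__name__)

#: Attribute names, in canonical order.
COUNT_ATTRIBUTES: tuple[str, ...] = (
    "glucose_count",
    "food_count",
    "exercise_count",
    "generic_count",
)

A1C_ATTRIBUTE = "a1c6month_diff"
_A1C_PREFIX = "a1c6_at_least_"

# HbA1c is reported to 0.1%; all reductions are rounded to one decimal
# before the value set is formed and item labels are rendered.
_A1C_DECIMALS = 1
_TOL = 1e-9


@dataclass(frozen=True, order=True)
class Item:
    """One attribute-value pair, e.g. ``glucose_120`` or ``a1c6_at_least_0.5``."""

    attribute: str
    value_label: str

    @property
    def is_a1c(self) -> bool:
        return self.attribute == A1C_ATTRIBUTE

    @property
    def a1c_threshold(self) -> float:
        if not self.is_a1c:
            raise ValueError(f"{self.value_label} is not an HbA1c item")
        return float(self.value_label[len(_A1C_PREFIX):])


@dataclass(frozen=True)
class Transaction:
    """A participant as a set of discrete attribute-value items."""

    participant_id: str
    items: frozenset[Item]


@dataclass(frozen=True)
class Bin:
    group: int
    lower: int
    upper: int
    meaning: str


@dataclass(frozen=True)
class BinAssignment:
    """Result of discretizing one count: which bin, and the item it emits.

    ``item`` is None for group 1 (zero use): unused trackers contribute no
    item to the participant's transaction.
    """

    attribute: str
    bin: Bin
    item: Item | None

    @property
    def group(self) -> int:
        return self.bin.group


class DiscretizationTable:
    """Ordered bin tables for the four use-frequency attributes.

    Group 1 of every attribute must be exactly {0}; later bins are half-open
    ``[lower, upper)`` with the top bin upper-inclusive.  A printed table may
    leave a gap between group 1 and the first nonzero bin (the default
    glucose table has no bin for counts 1-4); such counts are repaired to
    the lowest nonzero group, with a warning per occurrence.
    """

    def __init__(self, bins: dict[str, Sequence[Bin]]):
        for attr, attr_bins in bins.items():
            if not attr_bins:
                raise SpecError(f"{attr}: empty bin list")
            first = attr_bins[0]
            if (first.group, first.lower, first.upper) != (1, 0, 0):
                raise SpecError(f"{attr}: group 1 must be exactly the zero bin (0-0)")
            lowers = [b.lower for b in attr_bins[1:]]
            if lowers != sorted(lowers) or len(set(lowers)) != len(lowers):
                raise SpecError(f"{attr}: lower bounds must be strictly increasing")
        self._bins = {attr: tuple(attr_bins) for attr, attr_bins in bins.items()}

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self._bins)

    def bins(self, attribute: str) -> tuple[Bin, ...]:
        return self._bins[attribute]

    def top_bound(self, attribute: str) -> int:
        return self._bins[attribute][-1].upper

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            attr: [
                {"group": b.group, "lower": b.lower, "upper": b.upper, "meaning": b.meaning}
                for b in attr_bins
            ]
            for attr, attr_bins in self._bins.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DiscretizationTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise CsvFormatError(f"{path}: expected a mapping of attribute -> bin list")
        bins = {
            attr: [Bin(d["group"], d["lower"], d["upper"], d.get("meaning", "")) for d in rows]
            for attr, rows in doc.items()
        }
        return cls(bins)


def default_table() -> DiscretizationTable:
    """The study's bin tables: counts over 24 weeks vs. typical weekly use."""
    return DiscretizationTable(
        {
            "glucose_count": [
                Bin(1, 0, 0, "Zero"),
                Bin(2, 5, 24, "Up to once per week"),
                Bin(3, 24, 120, "1-4.9 times/week"),
                Bin(4, 120, 192, "5-7.9 times/week"),
                Bin(5, 192, 336, "8-13.9 times/week"),
                Bin(6, 336, 520, "14-21.9 times/week"),
            ],
            "exercise_count": [
                Bin(1, 0, 0, "Zero"),
                Bin(2, 0, 5, "Minimal (>0-4)"),
                Bin(3, 5, 12, "Once every other week"),
                Bin(4, 12, 24, "0.5-0.9 time/week"),
                Bin(5, 24, 48, "1-1.9 times/week"),
                Bin(6, 48, 72, "2-2.9 times/week"),
                Bin(7, 72, 96, "3-3.9 times/week"),
                Bin(8, 96, 150, "4-6 times/week"),
            ],
            "food_count": [
                Bin(1, 0, 0, "Zero"),
                Bin(2, 1, 5, ">0-5 over 6 months"),
                Bin(3, 5, 24, "Up to 1 time/week"),
                Bin(4, 24, 96, "1-3.9 times/week"),
                Bin(5, 96, 168, "4-6.9 times/week (1/day)"),
                Bin(6, 168, 336, "7-13.9 times/week (1-1.9/day)"),
                Bin(7, 336, 504, "14-20.9 times/week (2-2.9/day)"),
                Bin(8, 504, 720, "21+ times/week (3+/day)"),
            ],
            "generic_count": [
                Bin(1, 0, 0, "Zero"),
                Bin(2, 0, 24, "1 time/week"),
                Bin(3, 24, 96, "1-3.9 times/week"),
                Bin(4, 96, 168, "4-6.9 times/week (0.5-1/day)"),
                Bin(5, 168, 336, "7-13.9 times/week (1-2/day)"),
                Bin(6, 336, 672, "14-17.9 times/week (2-4/day)"),
                Bin(7, 672, 840, "18-34.9 times/week (4-5/day)"),
                Bin(8, 840, 1200, "35-50 times/week (5-7/day)"),
            ],
        }
    )


def _item_stem(attribute: str) -> str:
    return attribute.removesuffix("_count")


def discretize_count(
    attribute: str, count: int, table: DiscretizationTable
) -> BinAssignment:
    """Map a raw count to its discretization group and item.

    Counts of zero fall in group 1 and emit no item.  A count in a gap of
    the printed table (below the first nonzero bin) is repaired upward to
    the lowest nonzero group.  A count above the top bound is an error, not
    a clamp — real data exceeding the table signals a unit mistake.
    """
    if attribute not in table.attributes:
        raise KeyError(f"attribute {attribute!r} not in discretization table")
    if count < 0:
        raise ValueError(f"{attribute}: count must be nonnegative, got {count}")
    bins = table.bins(attribute)
    if count == 0:
        return BinAssignment(attribute, bins[0], None)
    if count > table.top_bound(attribute):
        raise OutOfRangeError(
            f"{attribute}: count {count} exceeds the table's top bound "
            f"{table.top_bound(attribute)}"
        )
    chosen: Bin | None = None
    for i, b in enumerate(bins[1:]):
        is_top = i == len(bins) - 2
        if b.lower <= count < b.upper or (is_top and count == b.upper):
            chosen = b
            break
    if chosen is None:
        # gap in the printed table between the zero bin and the first
        # nonzero bin: assign the semantically nearest (lowest nonzero) bin
        chosen = bins[1]
        logger.warning(
            "%s: count %d falls in a table gap; repaired to group %d (%s)",
            attribute, count, chosen.group, chosen.meaning,
        )
    item = Item(attribute, f"{_item_stem(attribute)}_{chosen.lower}")
    return BinAssignment(attribute, chosen, item)


# ---------------------------------------------------------------------------
# HbA1c at-least expansion
# ---------------------------------------------------------------------------

def _round_diff(diff: float) -> float:
    # +0.0 so that -0.049..-0.0 renders as "0.0", not "-0.0"
    return round(diff, _A1C_DECIMALS) + 0.0


def a1c_item(threshold: float) -> Item:
    return Item(A1C_ATTRIBUTE, f"{_A1C_PREFIX}{_round_diff(threshold):.1f}")


def a1c_value_set(cohort: Cohort) -> list[float]:
    """Sorted distinct HbA1c reductions observed in the cohort (0.1% grid)."""
    if len(cohort) == 0:
        raise ValueError("value set requires a nonempty cohort")
    return sorted({_round_diff(h.a1c6month_diff) for _, h in cohort})


def expand_a1c(diff: float, value_set: Sequence[float]) -> frozenset[Item]:
    """All ``a1c6_at_least_a`` items with ``a <= diff`` over the cohort values."""
    d = _round_diff(diff)
    if not any(abs(d - a) <= _TOL for a in value_set):
        raise ValueError(
            f"diff {d} not in the cohort value set; the value set must be "
            "built from the same cohort"
        )
    return frozenset(a1c_item(a) for a in value_set if a <= d + _TOL)


def build_transactions(
    cohort: Cohort, table: DiscretizationTable | None = None
) -> list[Transaction]:
    """One transaction per participant: tracker items plus expanded HbA1c items."""
    if table is None:
        table = default_table()
    values = a1c_value_set(cohort)
    transactions = []
    for urec, hrec in cohort:
        items: set[Item] = set()
        for attr in COUNT_ATTRIBUTES:
            assignment = discretize_count(attr, getattr(urec, attr), table)
            if assignment.item is not None:
                items.add(assignment.item)
        items |= expand_a1c(hrec.a1c6month_diff, values)
        transactions.append(Transaction(urec.participant_id, frozenset(items)))
    return transactions


# ---------------------------------------------------------------------------
# Transaction CSV I/O (participant_id, space-separated item labels)
# ---------------------------------------------------------------------------

def item_from_label(label: str) -> Item:
    if label.startswith(_A1C_PREFIX):
        return Item(A1C_ATTRIBUTE, label)
    stem, _, bound = label.rpartition("_")
    if stem in ("glucose", "food", "exercise", "generic") and bound.lstrip("-").isdigit():
        return Item(f"{stem}_count", label)
    raise CsvFormatError(f"unrecognized item label {label!r}")


def sorted_labels(items: Iterable[Item]) -> list[str]:
    return sorted(i.value_label for i in items)


def write_transactions(transactions: Iterable[Transaction], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [(t.participant_id, " ".join(sorted_labels(t.items))) for t in transactions],
        columns=["participant_id", "items"],
    )
    df.to_csv(path, index=False)


def read_transactions(path) -> list[Transaction]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("participant_id", "items"):
        if col not in df.columns:
            raise CsvFormatError(f"{path}: missing required column {col}")
    return [
        Transaction(
            str(row["participant_id"]),
            frozenset(item_from_label(lbl) for lbl in str(row["items"]).split()),
        )
        for _, row in df.iterrows()
    ]
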