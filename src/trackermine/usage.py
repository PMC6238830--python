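"""Core data model and CSV I/O for tracker-usage logs and HbA1c records.

The study cohort is a set of type 2 diabetes patients who carried a
smartphone with three primary self-monitoring trackers — blood glucose,
food intake and exercise — over a 24-week window.  Each participant is
summarised by four use-frequency attributes (``glucose_count``,
``food_count``, ``exercise_count`` and their sum ``generic_count``) and by
the change in glycated hemoglobin between baseline and six months.

Sign convention: ``a1c6month_diff = baseline_pct - sixmonth_pct``, so a
positive value is an improvement (reduction in HbA1c) and a negative value
is a worsening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Iterator

import pandas as pd

from .errors import CohortError, CsvFormatError, RowParseError

logger = logging.getLogger(__name__)

#: The three primary trackers, in canonical order.
TRACKERS: tuple[str, ...] = ("glucose", "food", "exercise")

#: Length of the study window in weeks.
STUDY_WEEKS_DEFAULT = 24


@dataclass(frozen=True)
class UsageEvent:
    """One tracker interaction: a participant used one tracker at one time."""

    participant_id: str
    tracker: str
    timestamp: datetime

    def __post_init__(self) -> None:
        if self.tracker not in TRACKERS:
            raise ValueError(f"unknown tracker {self.tracker!r}; expected one of {TRACKERS}")


@dataclass(frozen=True)
class UsageRecord:
    """Per-participant event counts per tracker over the study window.

    ``generic_count`` is always the sum of the three primary-tracker counts;
    it is stored explicitly because the analysis discretizes it with its own
    bin table, but the constructor enforces the identity.
    """

    participant_id: str
    glucose_count: int
    food_count: int
    exercise_count: int
    generic_count: int = -1  # sentinel: computed when omitted

    def __post_init__(self) -> None:
        for name in ("glucose_count", "food_count", "exercise_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        total = self.glucose_count + self.food_count + self.exercise_count
        if self.generic_count == -1:
            object.__setattr__(self, "generic_count", total)
        elif self.generic_count != total:
            raise ValueError(
                f"generic_count {self.generic_count} != sum of tracker counts {total} "
                f"for participant {self.participant_id}"
            )

    def count(self, tracker: str) -> int:
        return getattr(self, f"{tracker}_count")


@dataclass(frozen=True)
class HbA1cRecord:
    """Baseline and 6-month HbA1c (%) for one participant.

    ``a1c6month_diff`` (baseline minus 6 months) is derived, never supplied:
    positive = reduction (improvement).
    """

    participant_id: str
    baseline_pct: float
    sixmonth_pct: float

    def __post_init__(self) -> None:
        if not self.baseline_pct > 0:
            raise ValueError(f"baseline_pct must be positive, got {self.baseline_pct}")

    @property
    def a1c6month_diff(self) -> float:
        return self.baseline_pct - self.sixmonth_pct


@dataclass
class Cohort:
    """Ordered join of usage records and HbA1c records, keyed by participant.

    Every usage record must match an HbA1c record; participants present only
    in the HbA1c file get an all-zero usage record (they completed the trial
    without touching the software).
    """

    _pairs: dict[str, tuple[UsageRecord, HbA1cRecord]] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, usage: Iterable[UsageRecord], hba1c: Iterable[HbA1cRecord]
    ) -> "Cohort":
        hba1c_by_id: dict[str, HbA1cRecord] = {}
        for rec in hba1c:
            if rec.participant_id in hba1c_by_id:
                raise CohortError(f"duplicate HbA1c record for participant {rec.participant_id}")
            hba1c_by_id[rec.participant_id] = rec
        usage_by_id: dict[str, UsageRecord] = {}
        for rec in usage:
            if rec.participant_id in usage_by_id:
                raise CohortError(f"duplicate usage record for participant {rec.participant_id}")
            if rec.participant_id not in hba1c_by_id:
                raise CohortError(
                    f"usage data for participant {rec.participant_id} has no HbA1c record"
                )
            usage_by_id[rec.participant_id] = rec
        pairs = {}
        for pid, hrec in hba1c_by_id.items():
            urec = usage_by_id.get(pid, UsageRecord(pid, 0, 0, 0))
            pairs[pid] = (urec, hrec)
        return cls(pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[UsageRecord, HbA1cRecord]]:
        return iter(self._pairs.values())

    def __contains__(self, participant_id: str) -> bool:
        return participant_id in self._pairs

    def __getitem__(self, participant_id: str) -> tuple[UsageRecord, HbA1cRecord]:
        return self._pairs[participant_id]

    @property
    def participant_ids(self) -> list[str]:
        return list(self._pairs)

    def subset(self, participant_ids: Iterable[str]) -> "Cohort":
        ids = set(participant_ids)
        return Cohort({pid: pair for pid, pair in self._pairs.items() if pid in ids})

    def usage_records(self) -> list[UsageRecord]:
        return [u for u, _ in self]

    def hba1c_records(self) -> list[HbA1cRecord]:
        return [h for _, h in self]


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["participant_id", "tracker", "timestamp"]
_COUNT_COLUMNS = ["participant_id", "glucose_count", "food_count", "exercise_count", "generic_count"]
_HBA1C_COLUMNS = ["participant_id", "baseline_pct", "sixmonth_pct"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_usage_events(path) -> list[UsageEvent]:
    """Read an event-level usage log (participant_id, tracker, timestamp).

    Rows whose tracker is not one of the three primary trackers (e.g. other
    software features like a weight tracker) are dropped; the number of
    dropped rows is logged.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _EVENT_COLUMNS, path)
    events: list[UsageEvent] = []
    n_other = 0
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        tracker = row["tracker"]
        if tracker not in TRACKERS:
            n_other += 1
            continue
        try:
            ts = datetime.fromisoformat(str(row["timestamp"]))
        except ValueError as exc:
            raise RowParseError(f"{path}, line {line}: bad timestamp {row['timestamp']!r}") from exc
        events.append(UsageEvent(str(row["participant_id"]), tracker, ts))
    if n_other:
        logger.warning("%s: dropped %d row(s) with non-primary trackers", path, n_other)
    return events


def write_usage_events(events: Iterable[UsageEvent], path) -> None:
    df = pd.DataFrame(
        [(e.participant_id, e.tracker, e.timestamp.isoformat()) for e in events],
        columns=_EVENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def aggregate_counts(events: Iterable[UsageEvent]) -> list[UsageRecord]:
    """Collapse an event log to one UsageRecord per participant.

    Counts are plain event tallies per tracker; ``generic_count`` is their
    sum, so total events in equals total generic_count out.
    """
    tallies: dict[str, dict[str, int]] = {}
    for ev in events:
        per = tallies.setdefault(ev.participant_id, {t: 0 for t in TRACKERS})
        per[ev.tracker] += 1
    return [
        UsageRecord(pid, per["glucose"], per["food"], per["exercise"])
        for pid, per in sorted(tallies.items())
    ]


def read_usage_counts(path) -> list[UsageRecord]:
    """Read pre-aggregated per-participant counts."""
    df = pd.read_csv(path)
    _require_columns(df, _COUNT_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                UsageRecord(
                    str(row["participant_id"]),
                    int(row["glucose_count"]),
                    int(row["food_count"]),
                    int(row["exercise_count"]),
                    int(row["generic_count"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise RowParseError(f"{path}, line {idx + 2}: {exc}") from exc
    return records


def write_usage_counts(records: Iterable[UsageRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.participant_id, r.glucose_count, r.food_count, r.exercise_count, r.generic_count)
            for r in records
        ],
        columns=_COUNT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_hba1c(path) -> list[HbA1cRecord]:
    """Read baseline / 6-month HbA1c pairs; the reduction is derived."""
    df = pd.read_csv(path)
    _require_columns(df, _HBA1C_COLUMNS, path)
    dupes = df["participant_id"].astype(str)[df["participant_id"].astype(str).duplicated()]
    if not dupes.empty:
        raise CohortError(f"{path}: duplicate participant_id(s): {', '.join(sorted(set(dupes)))}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                HbA1cRecord(str(row["participant_id"]), float(row["baseline_pct"]), float(row["sixmonth_pct"]))
            )
        except (ValueError, TypeError) as exc:
            raise RowParseError(f"{path}, line {idx + 2}: {exc}") from exc
    return records


def write_hba1c(records: Iterable[HbA1cRecord], path) -> None:
    df = pd.DataFrame(
        [(r.participant_id, r.baseline_pct, r.sixmonth_pct) for r in records],
        columns=_HBA1C_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_cohort(usage_counts_path, hba1c_path) -> Cohort:
    """Convenience join: pre-aggregated counts + HbA1c file -> Cohort."""
    return Cohort.from_records(read_usage_counts(usage_counts_path), read_hba1c(hba1c_path))
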