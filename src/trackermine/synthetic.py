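"""Seeded synthetic cohort generator with the study's statistical structure.

No raw participant data are public, so every downstream stage is exercised
on a simulated cohort that reproduces the published structure: 48 trial
completers, of whom 39 used the software; 29 software users achieved the
clinically significant (>= 0.5%) HbA1c reduction, distributed over tracker
combinations as (food only, glucose only, exercise only, glucose+exercise,
glucose+food, food+exercise, all three) = (2, 7, 0, 11, 3, 0, 6) with the
published per-combination mean/SD reductions; the 10 non-significant
software users split 6 all-three / 4 fewer-than-three so the 2x2 table of
the exact test is reproduced; 9 participants never used the software.

Per-group HbA1c reductions are drawn from truncated normal distributions
(rejection sampling at the 0.5% clinical boundary, keeping the within-group
density smooth rather than piling an atom at the boundary).  Because
truncation shifts the mean of a normal proposal, each truncated group's
proposal mean is calibrated (by root-finding on the truncated-normal mean)
so that the *realized* group mean equals the published one.

Usage counts are drawn uniformly over the integer range implied by the
group's weekly-rate interval times the study length; no within-group usage
distribution or temporal pattern is published, so rates are uniform and
event timestamps (when requested) are spread uniformly over the 24 weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import SpecError
from .usage import Cohort, HbA1cRecord, TRACKERS, UsageEvent, UsageRecord

CLINICAL_THRESHOLD = 0.5  # HbA1c % reduction
_BASELINE_FLOOR = 6.0  # HbA1c % — below this a T2DM trial would not enroll

#: arbitrary but fixed study start, so event output is reproducible
STUDY_START = datetime(2020, 1, 6)


@dataclass(frozen=True)
class GroupSpec:
    """One homogeneous participant group.

    ``rates`` maps tracker name -> (min, max) uses per week; trackers absent
    from the mapping are never used.  ``significant`` controls truncation of
    the reduction draw at the clinical threshold: True keeps draws >= 0.5,
    False keeps draws < 0.5, None leaves them untruncated.
    """

    label: str
    n: int
    mean_reduction: float
    sd_reduction: float
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SpecError(f"{self.label}: n must be nonnegative")
        if self.sd_reduction < 0:
            raise SpecError(f"{self.label}: sd_reduction must be nonnegative")
        for tracker, (lo, hi) in self.rates.items():
            if tracker not in TRACKERS:
                raise SpecError(f"{self.label}: unknown tracker {tracker!r}")
            if lo < 0 or hi < 0:
                raise SpecError(f"{self.label}: weekly rates must be nonnegative")
            if lo > hi:
                raise SpecError(
                    f"{self.label}/{tracker}: infeasible rate range ({lo} > {hi})"
                )
        if self.sd_reduction == 0 and self.n > 0:
            if self.significant is True and self.mean_reduction < CLINICAL_THRESHOLD:
                raise SpecError(f"{self.label}: degenerate draw can never reach threshold")
            if self.significant is False and self.mean_reduction >= CLINICAL_THRESHOLD:
                raise SpecError(f"{self.label}: degenerate draw can never stay below threshold")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    baseline_mean: float = 8.88
    baseline_sd: float = 1.30
    study_weeks: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_weeks <= 0:
            raise SpecError("study_weeks must be positive")

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups)


def default_cohort_spec() -> CohortSpec:
    """The published cohort structure: 48 completers, 39 users, 29 in the SOI."""
    soi = [
        GroupSpec("food_only", 2, 1.95, 1.20, {"food": (1.0, 3.9)}, True),
        GroupSpec("glucose_only", 7, 1.74, 1.00, {"glucose": (1.0, 4.9)}, True),
        GroupSpec("exercise_only", 0, 0.0, 0.0, {"exercise": (1.0, 1.9)}, True),
        GroupSpec(
            "glucose_exercise", 11, 0.97, 0.38,
            {"glucose": (1.0, 4.9), "exercise": (0.5, 0.9)}, True,
        ),
        GroupSpec(
            "glucose_food", 3, 1.07, 0.45,
            {"glucose": (5.0, 7.9), "food": (1.0, 3.9)}, True,
        ),
        GroupSpec(
            "food_exercise", 0, 0.0, 0.0,
            {"food": (1.0, 3.9), "exercise": (0.5, 0.9)}, True,
        ),
        GroupSpec(
            "all_three", 6, 1.55, 0.49,
            {"glucose": (5.0, 7.9), "food": (4.0, 6.9), "exercise": (1.0, 1.9)}, True,
        ),
    ]
    # The 10 software users without a clinically significant reduction split
    # 6 all-three / 4 fewer-than-three, reproducing the published 2x2 table.
    nonsig = [
        GroupSpec(
            "all_three_nonsig", 6, 0.1, 0.3,
            {"glucose": (5.0, 7.9), "food": (4.0, 6.9), "exercise": (1.0, 1.9)}, False,
        ),
        GroupSpec("glucose_only_nonsig", 2, 0.1, 0.3, {"glucose": (1.0, 4.9)}, False),
        GroupSpec(
            "glucose_exercise_nonsig", 2, 0.1, 0.3,
            {"glucose": (1.0, 4.9), "exercise": (0.5, 0.9)}, False,
        ),
    ]
    non_user = [GroupSpec("non_user", 9, 0.2, 0.5, {}, None)]
    return CohortSpec(tuple(soi + nonsig + non_user))


# ---------------------------------------------------------------------------
# truncation calibration
# ---------------------------------------------------------------------------


def _truncated_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.mean(a, b, loc=mu, scale=sd))


def calibrated_proposal_mean(group: GroupSpec, threshold: float = CLINICAL_THRESHOLD) -> float:
    """Proposal mean whose truncated distribution has the group's target mean.

    Rejection at the clinical boundary shifts the realized mean of a normal
    proposal; solving E[X | truncation] = target on the proposal mean keeps
    the simulated group means faithful to the published ones.
    """
    if group.sd_reduction == 0 or group.significant is None:
        return group.mean_reduction
    lo, hi = (threshold, math.inf) if group.significant else (-math.inf, threshold)
    target = group.mean_reduction

    def gap(mu: float) -> float:
        return _truncated_mean(mu, group.sd_reduction, lo, hi) - target

    span = 10 * group.sd_reduction
    return float(brentq(gap, target - span, target + span, xtol=1e-12))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_reduction(rng: np.random.Generator, group: GroupSpec, mu: float) -> float:
    """One HbA1c reduction, rounded to the 0.1% reporting grid."""
    if group.sd_reduction == 0:
        return round(group.mean_reduction, 1)
    for _ in range(100_000):
        raw = rng.normal(mu, group.sd_reduction)
        r = round(raw, 1) + 0.0
        if group.significant is None:
            return r
        if group.significant and raw >= CLINICAL_THRESHOLD:
            return r
        if group.significant is False and r < CLINICAL_THRESHOLD:
            return r
    raise SpecError(f"{group.label}: rejection sampling failed to satisfy truncation")


def _draw_counts(
    rng: np.random.Generator, group: GroupSpec, study_weeks: int
) -> dict[str, int]:
    counts = {t: 0 for t in TRACKERS}
    for tracker, (lo, hi) in group.rates.items():
        cmin = max(1, math.ceil(lo * study_weeks))
        cmax = math.floor(hi * study_weeks)
        if cmin > cmax:
            raise SpecError(
                f"{group.label}/{tracker}: rate range ({lo}, {hi}) admits no "
                f"integer count over {study_weeks} weeks"
            )
        counts[tracker] = int(rng.integers(cmin, cmax + 1))
    return counts


def generate(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Deterministically generate a cohort from a spec and a seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    usage: list[UsageRecord] = []
    hba1c: list[HbA1cRecord] = []
    width = len(str(spec.total_n))
    idx = 0
    for group in spec.groups:
        mu = calibrated_proposal_mean(group)
        for _ in range(group.n):
            idx += 1
            pid = f"P{idx:0{width}d}"
            counts = _draw_counts(rng, group, spec.study_weeks)
            usage.append(
                UsageRecord(pid, counts["glucose"], counts["food"], counts["exercise"])
            )
            reduction = _draw_reduction(rng, group, mu)
            baseline = round(max(_BASELINE_FLOOR, rng.normal(spec.baseline_mean, spec.baseline_sd)), 2)
            hba1c.append(HbA1cRecord(pid, baseline, round(baseline - reduction, 2)))
    return Cohort.from_records(usage, hba1c)


def events_for(
    records: Iterable[UsageRecord], study_weeks: int, seed: int
) -> list[UsageEvent]:
    """Event-level log consistent with the given counts: uniform timestamps."""
    rng = np.random.default_rng(seed)
    horizon = study_weeks * 7 * 24 * 3600  # seconds
    events: list[UsageEvent] = []
    for rec in records:
        for tracker in TRACKERS:
            n = rec.count(tracker)
            if n == 0:
                continue
            offsets = np.sort(rng.integers(0, horizon, size=n))
            events.extend(
                UsageEvent(rec.participant_id, tracker, STUDY_START + timedelta(seconds=int(s)))
                for s in offsets
            )
    return events


# ---------------------------------------------------------------------------
# YAML spec I/O (mirrors CohortSpec field-for-field)
# ---------------------------------------------------------------------------


def spec_to_yaml(spec: CohortSpec, path) -> None:
    doc = {
        "baseline_mean": spec.baseline_mean,
        "baseline_sd": spec.baseline_sd,
        "study_weeks": spec.study_weeks,
        "seed": spec.seed,
        "groups": [
            {
                "label": g.label,
                "n": g.n,
                "mean_reduction": g.mean_reduction,
                "sd_reduction": g.sd_reduction,
                "rates": {t: list(r) for t, r in g.rates.items()},
                "significant": g.significant,
            }
            for g in spec.groups
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> CohortSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        groups = tuple(
            GroupSpec(
                g["label"],
                g["n"],
                g["mean_reduction"],
                g["sd_reduction"],
                {t: (float(r[0]), float(r[1])) for t, r in g.get("rates", {}).items()},
                g.get("significant"),
            )
            for g in doc["groups"]
        )
        return CohortSpec(
            groups,
            baseline_mean=doc.get("baseline_mean", 8.88),
            baseline_sd=doc.get("baseline_sd", 1.30),
            study_weeks=doc.get("study_weeks", 24),
            seed=doc.get("seed", 0),
        )
    except (KeyError, TypeError) as exc:
        raise SpecError(f"{path}: malformed cohort spec ({exc})") from exc
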