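"""Domain types, delimited-table IO and per-male summarisation.

The experimental unit is a small mixed-sex group (a "vial") observed over
several days: one genetically marked *focal* male whose paternity is
assignable, a set of rival males, and a set of females.  Raw data are

* mating events — one row per observed copulation, ordered within each
  group-day;
* paternity records — per female, daughters sired by the focal vs. by
  anyone else (only daughters carry the paternity marker);
* group rosters — who is in each group and the treatment label.

From these we derive, per focal male, the classical components of
reproductive success:

* ``M``  — mating success, the number of unique female mates;
* ``N``  — mate productivity, the arithmetic mean number of daughters
  produced by his mates;
* ``P``  — paternity share, pooled daughters sired divided by total
  daughters produced by his mates;
* ``T``  — reproductive success, total daughters sired.

With the pooled definition of ``P`` the identity ``T = M * N * P`` is exact,
which makes the downstream multiplicative variance decomposition exact as
well.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "group_id",
    "replicate_id",
    "treatment",
    "day",
    "order",
    "male_id",
    "female_id",
]
PATERNITY_COLUMNS = ["group_id", "female_id", "daughters_focal", "daughters_other"]
ROSTER_COLUMNS = ["group_id", "treatment", "replicate_id", "member_id", "sex", "role"]


@dataclass(frozen=True)
class MatingEvent:
    """A single observed copulation."""

    group_id: str
    replicate_id: str
    treatment: str
    day: int
    order: int
    male_id: str
    female_id: str


@dataclass(frozen=True)
class GroupRoster:
    """Membership of one experimental group (vial).

    Exactly one male carries the role ``"focal"``; the remainder are
    ``"rival"``.
    """

    group_id: str
    treatment: str
    males: tuple[tuple[str, str], ...]  # (male_id, role)
    females: tuple[str, ...]
    replicate_id: str = ""

    def __post_init__(self) -> None:
        roles = [role for _, role in self.males]
        if roles.count("focal") != 1:
            raise ValueError(
                f"group {self.group_id!r}: expected exactly one focal male, "
                f"found {roles.count('focal')}"
            )
        ids = [m for m, _ in self.males] + list(self.females)
        if len(set(ids)) != len(ids):
            raise ValueError(f"group {self.group_id!r}: duplicate member ids")

    @property
    def focal_male(self) -> str:
        return next(m for m, role in self.males if role == "focal")

    @property
    def male_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.males)


@dataclass(frozen=True)
class PaternityRecord:
    """Daughters produced by one female, split by sire class."""

    group_id: str
    female_id: str
    daughters_focal: int
    daughters_other: int

    def __post_init__(self) -> None:
        if self.daughters_focal < 0 or self.daughters_other < 0:
            raise ValueError(
                f"paternity record ({self.group_id}, {self.female_id}): "
                "negative daughter count"
            )

    @property
    def total(self) -> int:
        return self.daughters_focal + self.daughters_other


@dataclass
class MaleSummary:
    """Per-focal-male fitness components.

    ``repetitive_rate`` is total copulations divided by unique mates, so 1.0
    means the male never re-mated with the same female.  ``P`` and ``N`` are
    NaN (undefined) for males with ``M == 0``, and ``P`` is NaN when the
    male's mates produced no daughters at all.
    """

    male_id: str
    group_id: str
    treatment: str
    replicate_id: str
    mating_frequency: int
    M: int
    repetitive_rate: float
    N: float
    P: float
    T: int
    group_fecundity: int
    per_female_share: dict[str, float] = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# IO


def _sep_for(path: str | Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_rosters(path: str | Path) -> dict[str, GroupRoster]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    _require_columns(df, ROSTER_COLUMNS[:2] + ROSTER_COLUMNS[3:], path)
    rosters: dict[str, GroupRoster] = {}
    for gid, sub in df.groupby("group_id", sort=True):
        males = tuple(
            (r.member_id, r.role) for r in sub.itertuples() if r.sex == "M"
        )
        females = tuple(r.member_id for r in sub.itertuples() if r.sex == "F")
        treatment = sub["treatment"].iloc[0]
        replicate = (
            sub["replicate_id"].iloc[0] if "replicate_id" in sub.columns else ""
        )
        rosters[gid] = GroupRoster(
            group_id=gid,
            treatment=treatment,
            males=males,
            females=females,
            replicate_id=replicate or "",
        )
    return rosters


def write_rosters(rosters: Mapping[str, GroupRoster], path: str | Path) -> None:
    rows = []
    for roster in rosters.values():
        for male_id, role in roster.males:
            rows.append(
                (roster.group_id, roster.treatment, roster.replicate_id,
                 male_id, "M", role)
            )
        for female_id in roster.females:
            rows.append(
                (roster.group_id, roster.treatment, roster.replicate_id,
                 female_id, "F", "female")
            )
    pd.DataFrame(rows, columns=ROSTER_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_mating_events(
    path: str | Path, rosters: Mapping[str, GroupRoster] | None = None
) -> list[MatingEvent]:
    """Read and validate a mating-event table.

    Rows are returned sorted by (group, day, order).  If ``rosters`` is
    given, every id is checked against the group's roster.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype={c: str for c in EVENT_COLUMNS})
    _require_columns(df, EVENT_COLUMNS, path)
    events = []
    for i, row in enumerate(df.itertuples()):
        try:
            day = int(row.day)
            order = int(row.order)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: row {i}: non-integer day/order") from None
        events.append(
            MatingEvent(
                group_id=row.group_id,
                replicate_id=row.replicate_id,
                treatment=row.treatment,
                day=day,
                order=order,
                male_id=row.male_id,
                female_id=row.female_id,
            )
        )
    return validate_events(events, rosters)


def validate_events(
    events: Iterable[MatingEvent],
    rosters: Mapping[str, GroupRoster] | None = None,
) -> list[MatingEvent]:
    events = sorted(events, key=lambda e: (e.group_id, e.day, e.order))
    seen: set[tuple[str, int, int]] = set()
    for e in events:
        if e.day < 1:
            raise ValueError(f"event {e}: day must be >= 1")
        key = (e.group_id, e.day, e.order)
        if key in seen:
            raise ValueError(
                f"duplicate copulation order {e.order} in group {e.group_id}, "
                f"day {e.day}"
            )
        seen.add(key)
        if rosters is not None:
            if e.group_id not in rosters:
                raise ValueError(f"event {e}: unknown group {e.group_id!r}")
            roster = rosters[e.group_id]
            if e.male_id not in roster.male_ids:
                raise ValueError(
                    f"event {e}: male {e.male_id!r} not on roster of "
                    f"group {e.group_id!r}"
                )
            if e.female_id not in roster.females:
                raise ValueError(
                    f"event {e}: female {e.female_id!r} not on roster of "
                    f"group {e.group_id!r}"
                )
    return events


def events_to_frame(events: Iterable[MatingEvent]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in events], columns=EVENT_COLUMNS)


def write_mating_events(events: Iterable[MatingEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep=_sep_for(path), index=False)


def read_paternity(path: str | Path) -> list[PaternityRecord]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"group_id": str, "female_id": str})
    _require_columns(df, PATERNITY_COLUMNS, path)
    records = []
    seen = set()
    for row in df.itertuples():
        key = (row.group_id, row.female_id)
        if key in seen:
            raise ValueError(f"{path}: duplicate paternity record for {key}")
        seen.add(key)
        records.append(
            PaternityRecord(
                group_id=row.group_id,
                female_id=row.female_id,
                daughters_focal=int(row.daughters_focal),
                daughters_other=int(row.daughters_other),
            )
        )
    return records


def paternity_to_frame(records: Iterable[PaternityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=PATERNITY_COLUMNS
    )


def write_paternity(records: Iterable[PaternityRecord], path: str | Path) -> None:
    paternity_to_frame(records).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Summarisation


def compute_male_summaries(
    events: Iterable[MatingEvent],
    paternity: Iterable[PaternityRecord],
    rosters: Mapping[str, GroupRoster],
) -> list[MaleSummary]:
    """Summarise each focal male's fitness components T, M, P, N.

    ``P`` is the *pooled* share — total daughters sired divided by total
    daughters produced by his mates — so that ``T = M * N * P`` holds
    exactly for every male with ``M >= 1``.

    Raises ``ValueError`` when a paternity record credits the focal male
    with daughters from a female he never mated (a data inconsistency), or
    when one of his mates lacks a paternity record.
    """
    events = validate_events(events, rosters)
    by_group: dict[str, list[MatingEvent]] = {}
    for e in events:
        by_group.setdefault(e.group_id, []).append(e)
    pat_by_group: dict[str, dict[str, PaternityRecord]] = {}
    for rec in paternity:
        if rec.group_id not in rosters:
            raise ValueError(f"paternity record {rec}: unknown group")
        if rec.female_id not in rosters[rec.group_id].females:
            raise ValueError(
                f"paternity record {rec}: female not on roster of group "
                f"{rec.group_id!r}"
            )
        pat_by_group.setdefault(rec.group_id, {})[rec.female_id] = rec

    summaries = []
    for gid in sorted(rosters):
        roster = rosters[gid]
        focal = roster.focal_male
        recs = pat_by_group.get(gid, {})
        group_fecundity = sum(r.total for r in recs.values())
        focal_events = [e for e in by_group.get(gid, []) if e.male_id == focal]
        mate_counts = Counter(e.female_id for e in focal_events)
        mates = sorted(mate_counts)

        for fid, rec in recs.items():
            if rec.daughters_focal > 0 and fid not in mate_counts:
                raise ValueError(
                    f"group {gid!r}: focal male sired daughters with female "
                    f"{fid!r} he was never observed to mate"
                )

        replicate = roster.replicate_id
        if not replicate and by_group.get(gid):
            replicate = by_group[gid][0].replicate_id

        mating_frequency = len(focal_events)
        M = len(mates)
        if M == 0:
            summaries.append(
                MaleSummary(
                    male_id=focal, group_id=gid, treatment=roster.treatment,
                    replicate_id=replicate, mating_frequency=0, M=0,
                    repetitive_rate=float("nan"), N=float("nan"),
                    P=float("nan"), T=0, group_fecundity=group_fecundity,
                )
            )
            continue
        missing = [f for f in mates if f not in recs]
        if missing:
            raise ValueError(
                f"group {gid!r}: focal mates {missing} lack paternity records"
            )
        totals = [recs[f].total for f in mates]
        sired = [recs[f].daughters_focal for f in mates]
        tot = sum(totals)
        T = sum(sired)
        per_female = {
            f: (recs[f].daughters_focal / recs[f].total if recs[f].total else np.nan)
            for f in mates
        }
        summaries.append(
            MaleSummary(
                male_id=focal,
                group_id=gid,
                treatment=roster.treatment,
                replicate_id=replicate,
                mating_frequency=mating_frequency,
                M=M,
                repetitive_rate=mating_frequency / M,
                N=tot / M,
                P=(T / tot) if tot > 0 else float("nan"),
                T=T,
                group_fecundity=group_fecundity,
                per_female_share=per_female,
            )
        )
    return summaries


def summaries_to_frame(summaries: Iterable[MaleSummary]) -> pd.DataFrame:
    """Tidy per-male table used by all downstream statistics."""
    rows = [
        {
            "male_id": s.male_id,
            "group_id": s.group_id,
            "treatment": s.treatment,
            "replicate_id": s.replicate_id,
            "mating_frequency": s.mating_frequency,
            "M": s.M,
            "repetitive_rate": s.repetitive_rate,
            "N": s.N,
            "P": s.P,
            "T": s.T,
            "group_fecundity": s.group_fecundity,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
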