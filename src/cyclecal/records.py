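"""Event logs, cycle derivation, and phase lengths.

A woman's raw record is a list of dated menstruation onsets plus dated
ovulation observations, each ovulation carrying a *basis* label saying
how it was determined (clinical diagnosis, ovulation test kit, or some
other method).  From the onsets we derive menstrual cycles; from an
ovulation falling strictly inside a cycle we derive the follicular
phase length ``f`` (onset to ovulation, in days) and the luteal phase
length ``l`` (day after ovulation through the day before the next
onset), so that ``c = f + l + 1`` exactly.

Cycles are indexed by recency: ``j = 1`` is the most recent cycle, and
a woman's onsets are stored most-recent-first.  The trailing mean
cycle length ``c*_j(k)`` — the mean of the ``k`` cycles immediately
preceding cycle ``j`` — is the predictor used by every calendar method
downstream.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Recognised ovulation-basis labels.
BASES = ("clinical", "test_kit", "other")

#: Bases treated as reliable by default (clinical diagnosis and test kits).
DEFAULT_ALLOWED_BASES = frozenset({"clinical", "test_kit"})

#: Default cycle-length screening window, days (inclusive).
SCREEN_LO = 20
SCREEN_HI = 45

#: Columns of the event CSV dialect.
EVENT_COLUMNS = ("woman_id", "date", "event", "basis")

#: Columns of the derived-cycle CSV.
CYCLE_COLUMNS = ("woman_id", "j", "start_date", "end_date", "c", "f", "l", "basis")


@dataclass(frozen=True)
class MenstruationOnset:
    woman_id: str
    date: dt.date


@dataclass(frozen=True)
class OvulationRecord:
    woman_id: str
    date: dt.date
    basis: str

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise DataError(f"unknown ovulation basis {self.basis!r}; expected one of {BASES}")


@dataclass(frozen=True)
class WomanHistory:
    """One woman's onsets (most recent first) and ovulation records."""

    woman_id: str
    onsets: tuple[dt.date, ...]
    ovulations: tuple[OvulationRecord, ...] = ()

    def __post_init__(self) -> None:
        if len(self.onsets) < 1:
            raise DataError(f"woman {self.woman_id!r}: at least one onset required")
        if len(set(self.onsets)) != len(self.onsets):
            raise DataError(f"woman {self.woman_id!r}: duplicate onset dates")
        ordered = tuple(sorted(self.onsets, reverse=True))
        if ordered != self.onsets:
            object.__setattr__(self, "onsets", ordered)
        for ov in self.ovulations:
            if ov.woman_id != self.woman_id:
                raise DataError(
                    f"ovulation record for {ov.woman_id!r} attached to woman {self.woman_id!r}"
                )

    @property
    def record_length(self) -> int:
        """Number of recorded onsets (one more than derivable cycles)."""
        return len(self.onsets)


@dataclass(frozen=True)
class Cycle:
    """A single inter-menstrual interval.

    ``j`` is the recency index (1 = most recent).  ``f``, ``l`` and
    ``basis`` are present only when a qualifying ovulation record fell
    strictly inside the cycle.
    """

    woman_id: str
    j: int
    start_onset: dt.date
    end_onset: dt.date
    c: int
    f: int | None = None
    l: int | None = None
    basis: str | None = None


@dataclass(frozen=True)
class MeanCycleLength:
    """Trailing mean of the k cycles preceding target cycle j."""

    woman_id: str
    j: int
    k: int
    value: float


def elapsed_days(a: dt.date, b: dt.date) -> int:
    """Whole days elapsed from ``b`` to ``a`` (positive when a is later)."""
    return (a - b).days


def compute_cycles(history: WomanHistory) -> list[Cycle]:
    """Derive cycles from consecutive onsets; cycle j spans onset j+1 → onset j.

    A record with fewer than two onsets yields no cycles.
    """
    onsets = history.onsets
    cycles = []
    for j in range(1, len(onsets)):
        end, start = onsets[j - 1], onsets[j]
        cycles.append(
            Cycle(
                woman_id=history.woman_id,
                j=j,
                start_onset=start,
                end_onset=end,
                c=elapsed_days(end, start),
            )
        )
    return cycles


def screen_cycles(
    cycles: Sequence[Cycle], lo: int = SCREEN_LO, hi: int = SCREEN_HI
) -> list[Cycle]:
    """Keep cycles with lo <= c <= hi (inclusive), preserving order.

    Cycles outside the window are treated as erroneous or defective
    input and dropped; recency indices of the survivors are unchanged,
    so gaps in ``j`` mark removed cycles.
    """
    if lo > hi:
        raise ConfigError(f"screening bounds inverted: lo={lo} > hi={hi}")
    return [cy for cy in cycles if lo <= cy.c <= hi]


def attach_ovulation(
    cycles: Sequence[Cycle],
    ovulations: Iterable[OvulationRecord],
    allowed_bases: frozenset[str] | set[str] = DEFAULT_ALLOWED_BASES,
    duplicate_policy: str = "drop",
) -> list[Cycle]:
    """Annotate cycles with follicular/luteal lengths from ovulation records.

    A record qualifies when its basis is allowed and its date falls
    strictly between the cycle's onsets.  Records dated exactly on an
    onset are inconsistent input and are discarded with a warning.
    When two or more records qualify for one cycle the default policy
    (``"drop"``) leaves the cycle unannotated with a warning;
    ``"earliest"`` keeps the earliest-dated record.

    Cycle lengths are never altered; only ``f``, ``l``, ``basis`` are set.
    """
    if duplicate_policy not in ("drop", "earliest"):
        raise ConfigError(f"unknown duplicate_policy {duplicate_policy!r}")
    records = [ov for ov in ovulations if ov.basis in allowed_bases]
    onset_dates = {d for cy in cycles for d in (cy.start_onset, cy.end_onset)}
    usable = []
    for ov in records:
        if ov.date in onset_dates:
            logger.warning(
                "woman %s: ovulation record on onset date %s discarded", ov.woman_id, ov.date
            )
            continue
        usable.append(ov)

    out: list[Cycle] = []
    for cy in cycles:
        inside = [ov for ov in usable if cy.start_onset < ov.date < cy.end_onset]
        if not inside:
            out.append(cy)
            continue
        if len(inside) > 1:
            if duplicate_policy == "drop":
                logger.warning(
                    "woman %s cycle j=%d: %d qualifying ovulation records; annotation dropped",
                    cy.woman_id,
                    cy.j,
                    len(inside),
                )
                out.append(cy)
                continue
            inside.sort(key=lambda ov: ov.date)
        ov = inside[0]
        f = elapsed_days(ov.date, cy.start_onset)
        out.append(replace(cy, f=f, l=cy.c - f - 1, basis=ov.basis))
    return out


def mean_cycle_length(
    cycles: Sequence[Cycle], j: int, k: int
) -> MeanCycleLength | None:
    """Trailing mean c*_j(k) over one woman's (screened) cycles.

    Requires all k cycles with recency indices j+1 … j+k to be present
    in ``cycles``; returns None when any is missing (removed by
    screening or never recorded), signalling the target cycle is not
    usable for k-past-cycle analyses.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    by_j = {cy.j: cy for cy in cycles}
    woman_ids = {cy.woman_id for cy in cycles}
    if len(woman_ids) > 1:
        raise DataError("mean_cycle_length expects cycles of a single woman")
    past = [by_j.get(t) for t in range(j + 1, j + k + 1)]
    if any(p is None for p in past):
        return None
    value = sum(p.c for p in past) / k  # type: ignore[union-attr]
    return MeanCycleLength(woman_id=next(iter(woman_ids)), j=j, k=k, value=value)


def derive_cycles(
    histories: Iterable[WomanHistory],
    lo: int = SCREEN_LO,
    hi: int = SCREEN_HI,
    allowed_bases: frozenset[str] | set[str] = DEFAULT_ALLOWED_BASES,
    duplicate_policy: str = "drop",
) -> list[Cycle]:
    """Full derivation for a cohort: compute → screen → attach ovulations.

    Screening happens before ovulation attachment; since attachment
    never changes cycle lengths the order does not affect the output.
    """
    out: list[Cycle] = []
    for h in histories:
        cycles = screen_cycles(compute_cycles(h), lo=lo, hi=hi)
        out.extend(attach_ovulation(cycles, h.ovulations, allowed_bases, duplicate_policy))
    return out


# ---------------------------------------------------------------------------
# Tabular views and CSV I/O
# ---------------------------------------------------------------------------

def cycles_to_frame(cycles: Sequence[Cycle]) -> pd.DataFrame:
    """Long-format view of derived cycles (one row per cycle)."""
    rows = [
        {
            "woman_id": cy.woman_id,
            "j": cy.j,
            "start_date": cy.start_onset.isoformat(),
            "end_date": cy.end_onset.isoformat(),
            "c": cy.c,
            "f": cy.f,
            "l": cy.l,
            "basis": cy.basis,
        }
        for cy in cycles
    ]
    df = pd.DataFrame(rows, columns=list(CYCLE_COLUMNS))
    return df


def frame_to_cycles(df: pd.DataFrame) -> list[Cycle]:
    missing = set(CYCLE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"cycle table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        f = None if pd.isna(row.f) else int(row.f)
        l = None if pd.isna(row.l) else int(row.l)
        basis = None if (pd.isna(row.basis) or row.basis == "") else str(row.basis)
        out.append(
            Cycle(
                woman_id=str(row.woman_id),
                j=int(row.j),
                start_onset=dt.date.fromisoformat(str(row.start_date)),
                end_onset=dt.date.fromisoformat(str(row.end_date)),
                c=int(row.c),
                f=f,
                l=l,
                basis=basis,
            )
        )
    return out


def write_cycles_csv(cycles: Sequence[Cycle], path) -> None:
    cycles_to_frame(cycles).to_csv(path, index=False)


def read_cycles_csv(path) -> list[Cycle]:
    return frame_to_cycles(pd.read_csv(path, dtype={"woman_id": str}))


def histories_to_events(histories: Iterable[WomanHistory]) -> pd.DataFrame:
    """Event-log view: one row per onset or ovulation record."""
    rows = []
    for h in histories:
        for d in sorted(h.onsets):
            rows.append({"woman_id": h.woman_id, "date": d.isoformat(), "event": "menses_onset", "basis": ""})
        for ov in sorted(h.ovulations, key=lambda o: o.date):
            rows.append({"woman_id": h.woman_id, "date": ov.date.isoformat(), "event": "ovulation", "basis": ov.basis})
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def events_to_histories(events: pd.DataFrame) -> list[WomanHistory]:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise DataError(f"event log missing columns: {sorted(missing)}")
    bad = set(events["event"].unique()) - {"menses_onset", "ovulation"}
    if bad:
        raise DataError(f"unknown event types: {sorted(bad)}")
    histories = []
    for wid, grp in events.groupby("woman_id", sort=True):
        onsets = tuple(
            dt.date.fromisoformat(str(d))
            for d in grp.loc[grp["event"] == "menses_onset", "date"]
        )
        ovs = tuple(
            OvulationRecord(str(wid), dt.date.fromisoformat(str(r.date)), str(r.basis))
            for r in grp.loc[grp["event"] == "ovulation"].itertuples(index=False)
        )
        if not onsets:
            raise DataError(f"woman {wid!r}: ovulation records but no onsets")
        histories.append(WomanHistory(str(wid), onsets, ovs))
    return histories


def write_event_csv(histories: Iterable[WomanHistory], path) -> None:
    histories_to_events(histories).to_csv(path, index=False)


def read_event_csv(path) -> list[WomanHistory]:
    df = pd.read_csv(path, dtype={"woman_id": str, "basis": str}, keep_default_na=False)
    return events_to_histories(df)


def trailing_mean_frame(cycles: Sequence[Cycle], k: int) -> pd.DataFrame:
    """Per-cycle table of the trailing mean c*_j(k), for cycles where it exists.

    Columns: woman_id, j, c_star, c, f, l, basis.  A cycle appears only
    if its k immediately preceding cycles all survived screening (the
    recency index records gaps).  Input may mix women.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    rows = []
    by_woman: dict[str, dict[int, Cycle]] = {}
    for cy in cycles:
        by_woman.setdefault(cy.woman_id, {})[cy.j] = cy
    for wid in sorted(by_woman):
        jmap = by_woman[wid]
        for j, cy in sorted(jmap.items()):
            past = [jmap.get(t) for t in range(j + 1, j + k + 1)]
            if any(p is None for p in past):
                continue
            c_star = sum(p.c for p in past) / k  # type: ignore[union-attr]
            rows.append(
                {
                    "woman_id": wid,
                    "j": j,
                    "c_star": c_star,
                    "c": cy.c,
                    "f": cy.f,
                    "l": cy.l,
                    "basis": cy.basis,
                }
            )
    return pd.DataFrame(rows, columns=["woman_id", "j", "c_star", "c", "f", "l", "basis"])
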