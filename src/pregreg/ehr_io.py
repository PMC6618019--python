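"""Record schemas, delimited-text readers/writers and follow-up windows.

All dates are calendar dates (no time of day), serialised ISO-8601.
Intervals are closed ``[start, end]`` and durations are whole days.

The patient metadata supplies year of birth only; the k-th birthday is
represented as January 1 of (year_of_birth + k).  An infant's month of
birth resolves to the 15th of that month, which minimises the maximum
error of the 60-day mother-baby link rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

ENTITY_DATA_FIELDS = [f"data{i}" for i in range(1, 9)]


@dataclass(frozen=True)
class ClinicalEvent:
    patient_id: str
    event_date: date
    code: str


@dataclass(frozen=True)
class EntityRecord:
    """A structured record: an entity code plus up to eight data fields.

    Data fields are kept as raw strings; each entity rule knows whether to
    read a field as a date, a week count or a day count.
    """

    patient_id: str
    event_date: date
    entity_code: int
    data: tuple[str, ...] = ("",) * 8

    def field(self, i: int) -> str:
        """1-based data field access; empty string when absent."""
        return self.data[i - 1] if 1 <= i <= len(self.data) else ""


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    year_of_birth: int
    registration_start: date
    registration_end: date | None = None
    death_date: date | None = None
    practice_uts: date | None = None
    practice_last_collection: date | None = None

    def birthday(self, k: int) -> date:
        """k-th birthday under the January-1 convention."""
        return date(self.year_of_birth + k, 1, 1)

    def censor_date(self) -> date | None:
        """Earliest of leaving the practice, death, last collection."""
        cands = [d for d in (self.registration_end, self.death_date,
                             self.practice_last_collection) if d is not None]
        return min(cands) if cands else None


@dataclass(frozen=True)
class FollowUpWindow:
    patient_id: str
    start: date
    end: date
    flavour: str = "unrestricted"

    @property
    def empty(self) -> bool:
        return self.start > self.end

    @property
    def days(self) -> int:
        """Person-time in days (closed interval); 0 when empty."""
        return 0 if self.empty else (self.end - self.start).days + 1

    def contains(self, d: date) -> bool:
        return not self.empty and self.start <= d <= self.end


@dataclass(frozen=True)
class MotherBabyCandidate:
    mother_id: str
    infant_id: str
    infant_birth_month: tuple[int, int]  # (year, month)

    @property
    def representative_birth_date(self) -> date:
        y, m = self.infant_birth_month
        return date(y, m, 15)


# ---------------------------------------------------------------------------
# Follow-up eligibility
# ---------------------------------------------------------------------------

#: flavour -> (age floor, age ceiling, years added to registration start)
_FLAVOURS = {
    "internal_validation": (11, 49, 0),
    "external_validation": (15, 44, 1),
    "unrestricted": (0, 200, 0),
}


def follow_up_window(
    meta: PatientMeta,
    flavour: str,
    coverage_start: date,
    coverage_end: date,
) -> FollowUpWindow:
    """Per-patient eligible observation interval.

    Follow-up starts at the latest of the age-floor birthday, the (possibly
    one-year-deferred) registration start, the practice up-to-standard date
    and the coverage start; it ends at the earliest of the age-ceiling
    birthday, registration end, death, the practice's last collection date
    and the coverage end.  The window may be empty (start > end), in which
    case the patient contributes no person-time.
    """
    try:
        age_lo, age_hi, reg_defer_years = _FLAVOURS[flavour]
    except KeyError:
        raise ValueError(f"unknown follow-up flavour {flavour!r}") from None

    reg = meta.registration_start
    if reg_defer_years:
        try:
            reg = reg.replace(year=reg.year + reg_defer_years)
        except ValueError:  # Feb 29
            reg = reg.replace(year=reg.year + reg_defer_years, day=28)

    starts = [meta.birthday(age_lo), reg, coverage_start]
    if meta.practice_uts is not None:
        starts.append(meta.practice_uts)
    ends = [meta.birthday(age_hi), coverage_end]
    for d in (meta.registration_end, meta.death_date, meta.practice_last_collection):
        if d is not None:
            ends.append(d)
    return FollowUpWindow(
        patient_id=meta.patient_id, start=max(starts), end=min(ends), flavour=flavour
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


@dataclass
class ReadReport:
    """Counts of rows dropped for unparseable dates, per file."""

    n_rows: int = 0
    n_dropped: int = 0


def _read_table(path: str | Path, mandatory: list[str]) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    return df


def _parse_date(s: str) -> date | None:
    if not s:
        return None
    ts = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    if pd.isna(ts):
        ts = pd.to_datetime(s, dayfirst=True, errors="coerce")
    return None if pd.isna(ts) else ts.date()


def read_events(path: str | Path, report: ReadReport | None = None) -> list[ClinicalEvent]:
    df = _read_table(path, ["patient_id", "event_date", "code"])
    out: list[ClinicalEvent] = []
    dropped = 0
    for row in df.itertuples(index=False):
        d = _parse_date(row.event_date)
        if d is None or not row.patient_id:
            dropped += 1
            continue
        out.append(ClinicalEvent(str(row.patient_id), d, str(row.code)))
    if dropped:
        log.warning("read_events(%s): dropped %d rows with invalid dates", path, dropped)
    if report is not None:
        report.n_rows += len(df)
        report.n_dropped += dropped
    out.sort(key=lambda e: (e.patient_id, e.event_date, e.code))
    return out


def read_entities(path: str | Path, report: ReadReport | None = None) -> list[EntityRecord]:
    df = _read_table(path, ["patient_id", "event_date", "entity_code"])
    for c in ENTITY_DATA_FIELDS:
        if c not in df.columns:
            df[c] = ""
    out: list[EntityRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        d = _parse_date(row.event_date)
        try:
            ecode = int(row.entity_code)
        except (TypeError, ValueError):
            ecode = -1
        if d is None or ecode < 0 or not row.patient_id:
            dropped += 1
            continue
        data = tuple(str(getattr(row, c)) for c in ENTITY_DATA_FIELDS)
        out.append(EntityRecord(str(row.patient_id), d, ecode, data))
    if dropped:
        log.warning("read_entities(%s): dropped %d malformed rows", path, dropped)
    if report is not None:
        report.n_rows += len(df)
        report.n_dropped += dropped
    out.sort(key=lambda e: (e.patient_id, e.event_date, e.entity_code))
    return out


def read_patients(path: str | Path, report: ReadReport | None = None) -> list[PatientMeta]:
    df = _read_table(path, ["patient_id", "year_of_birth", "reg_start"])
    out: list[PatientMeta] = []
    dropped = 0
    for row in df.itertuples(index=False):
        reg_start = _parse_date(row.reg_start)
        try:
            yob = int(row.year_of_birth)
        except (TypeError, ValueError):
            yob = -1
        if reg_start is None or yob < 0 or not row.patient_id:
            dropped += 1
            continue
        get = lambda c: _parse_date(getattr(row, c)) if hasattr(row, c) else None
        out.append(
            PatientMeta(
                patient_id=str(row.patient_id),
                year_of_birth=yob,
                registration_start=reg_start,
                registration_end=get("reg_end"),
                death_date=get("death_date"),
                practice_uts=get("uts"),
                practice_last_collection=get("last_collection"),
            )
        )
    if dropped:
        log.warning("read_patients(%s): dropped %d malformed rows", path, dropped)
    if report is not None:
        report.n_rows += len(df)
        report.n_dropped += dropped
    out.sort(key=lambda p: p.patient_id)
    return out


def read_links(path: str | Path, report: ReadReport | None = None) -> list[MotherBabyCandidate]:
    df = _read_table(path, ["mother_id", "infant_id", "birth_month"])
    out: list[MotherBabyCandidate] = []
    dropped = 0
    for row in df.itertuples(index=False):
        try:
            y, m = str(row.birth_month).split("-")[:2]
            ym = (int(y), int(m))
            date(ym[0], ym[1], 15)
        except (ValueError, IndexError):
            dropped += 1
            continue
        out.append(MotherBabyCandidate(str(row.mother_id), str(row.infant_id), ym))
    if dropped:
        log.warning("read_links(%s): dropped %d malformed rows", path, dropped)
    if report is not None:
        report.n_rows += len(df)
        report.n_dropped += dropped
    out.sort(key=lambda l: (l.mother_id, l.infant_id))
    return out


def events_from_frame(df: pd.DataFrame) -> list[ClinicalEvent]:
    """In-memory counterpart of read_events for an events table."""
    out = [
        ClinicalEvent(str(r.patient_id), date.fromisoformat(str(r.event_date)),
                      str(r.code))
        for r in df.itertuples(index=False)
    ]
    out.sort(key=lambda e: (e.patient_id, e.event_date, e.code))
    return out


def entities_from_frame(df: pd.DataFrame) -> list[EntityRecord]:
    out = [
        EntityRecord(
            str(r.patient_id), date.fromisoformat(str(r.event_date)),
            int(r.entity_code),
            tuple(str(getattr(r, c, "")) for c in ENTITY_DATA_FIELDS),
        )
        for r in df.itertuples(index=False)
    ]
    out.sort(key=lambda e: (e.patient_id, e.event_date, e.entity_code))
    return out


def patients_from_frame(df: pd.DataFrame) -> list[PatientMeta]:
    def opt(v) -> date | None:
        s = str(v).strip()
        return date.fromisoformat(s) if s else None

    out = [
        PatientMeta(
            patient_id=str(r.patient_id),
            year_of_birth=int(r.year_of_birth),
            registration_start=date.fromisoformat(str(r.reg_start)),
            registration_end=opt(getattr(r, "reg_end", "")),
            death_date=opt(getattr(r, "death_date", "")),
            practice_uts=opt(getattr(r, "uts", "")),
            practice_last_collection=opt(getattr(r, "last_collection", "")),
        )
        for r in df.itertuples(index=False)
    ]
    out.sort(key=lambda p: p.patient_id)
    return out


def links_from_frame(df: pd.DataFrame) -> list[MotherBabyCandidate]:
    out = []
    for r in df.itertuples(index=False):
        y, m = str(r.birth_month).split("-")[:2]
        out.append(MotherBabyCandidate(str(r.mother_id), str(r.infant_id),
                                       (int(y), int(m))))
    out.sort(key=lambda l: (l.mother_id, l.infant_id))
    return out


def person_time_days(windows: list[FollowUpWindow]) -> int:
    return sum(w.days for w in windows)


def clip_window(w: FollowUpWindow, lo: date, hi: date) -> FollowUpWindow:
    """Intersect a follow-up window with a calendar period."""
    return FollowUpWindow(w.patient_id, max(w.start, lo), min(w.end, hi), w.flavour)
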