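"""Pregnancy episode delineation: the core register-building algorithm.

One patient's coded history goes in; a set of dated, classified pregnancy
episodes comes out.  The stages, run in order per patient:

1.  tag every pregnancy-related clinical event and known entity record;
2.  cluster outcome evidence into distinct delivery and loss episodes
    (the two outcome streams are never merged — apparent overlaps are
    flagged, not resolved);
3.  resolve each cluster's end date from its candidate dates;
4.  estimate each episode's start date from dating evidence using a fixed
    priority hierarchy (EDD > EDC > LMP > antenatal gestational age >
    gestational age at birth), imputing a type-specific duration when no
    dating evidence is available;
5.  attach remaining antenatal-type records to the episode they fall in;
6.  cluster still-unattached records into outcome-unknown episodes;
7.  classify outcomes, derive trimester dates, set flags;
8.  link infants from mother-baby candidate pairs.

The pregnancy start is the onset of the last menstrual period (gestational
day 0); trimester 2 begins at day 91 (completed week 13) and trimester 3
at day 182 (week 27).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codelists import (
    CodeDictionary,
    END_ENTITY_RULES,
    LOSS_EVIDENCE,
    NON_DATING_CATEGORIES,
    START_ENTITY_RULES,
)
from .ehr_io import ClinicalEvent, EntityRecord, MotherBabyCandidate, PatientMeta

DAY = timedelta(days=1)

#: Register outcome classes.
OUTCOMES = (
    "live_birth", "stillbirth", "live_and_stillbirth",
    "miscarriage", "top", "probable_top", "ectopic", "molar",
    "blighted_ovum", "unspecified_loss",
    "delivery_third_trimester", "delivery_late_pregnancy",
    "outcome_unknown",
)

DELIVERY_OUTCOMES = frozenset({
    "live_birth", "stillbirth", "live_and_stillbirth",
    "delivery_third_trimester", "delivery_late_pregnancy",
})
LOSS_OUTCOMES = frozenset({
    "miscarriage", "top", "probable_top", "ectopic", "molar",
    "blighted_ovum", "unspecified_loss",
})

#: When a loss cluster holds mixed loss codes, the most specific diagnosis
#: wins, in this order.
LOSS_PRECEDENCE = (
    "ectopic", "molar", "blighted_ovum", "top", "miscarriage",
    "probable_top", "unspecified_loss",
)

REGISTER_COLUMNS = [
    "patient_id", "episode_id", "start_date", "end_date", "start_source",
    "end_source", "outcome", "gestation_days", "trimester2_start",
    "trimester3_start", "preterm_flag", "postterm_flag", "multiple_flag",
    "conflict_flag", "ongoing_flag", "infant_ids",
]


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable windows and defaults of the episode builder (days)."""

    delivery_merge_days: int = 56      # outcome dates closer than this merge
    loss_merge_days: int = 28
    max_gestation_days: int = 294      # 42-week cap on gestation-week arithmetic
    postnatal_offset_max_days: int = 56
    postnatal_default_backdate_days: int = 42
    attribution_slack_days: int = 22   # dating window = (end-280-slack, end]
    birth_gestation_window_days: int = 56
    unknown_gap_days: int = 280        # one pregnancy cannot span more than a term
    impute_delivery_days: int = 280
    impute_loss_days: int = 84
    impute_ectopic_days: int = 56
    impute_unknown_lead_days: int = 53  # typical gestation at first antenatal record
    ongoing_threshold_days: int = 266   # 38 weeks
    mother_baby_max_gap_days: int = 60

    @property
    def dating_window_days(self) -> int:
        return 280 + self.attribution_slack_days


@dataclass(frozen=True)
class PregnancyRecord:
    """One dated, category-tagged evidence item for one patient."""

    patient_id: str
    source: str                       # "clinical" | "entity"
    event_date: date
    categories: frozenset[str] = frozenset()
    entity_code: int | None = None
    payload: tuple[str, ...] = ()
    scan_flag: bool = False

    def field(self, i: int) -> str:
        return self.payload[i - 1] if 1 <= i <= len(self.payload) else ""

    def sort_key(self):
        return (self.event_date, self.source,
                self.entity_code if self.entity_code is not None else -1,
                tuple(sorted(self.categories)))


@dataclass
class PregnancyEpisode:
    patient_id: str
    episode_id: str = ""
    start_date: date | None = None
    end_date: date | None = None
    start_source: str = ""            # edd|edc|lmp|antenatal_gestation|gestation_at_birth|imputed
    end_source: str = ""              # outcome_event|entity_rule|postnatal_backdate|""
    outcome: str = "outcome_unknown"
    trimester2_start: date | None = None
    trimester3_start: date | None = None
    preterm_flag: bool = False
    postterm_flag: bool = False
    multiple_flag: bool = False
    conflict_flag: bool = False
    ongoing_flag: bool = False
    infant_ids: list[str] = field(default_factory=list)
    contributing_records: list[PregnancyRecord] = field(default_factory=list)

    @property
    def gestation_days(self) -> int | None:
        if self.start_date is None or self.end_date is None:
            return None
        return (self.end_date - self.start_date).days

    @property
    def last_record_date(self) -> date | None:
        if not self.contributing_records:
            return None
        return max(r.event_date for r in self.contributing_records)

    @property
    def earliest_record_date(self) -> date | None:
        if not self.contributing_records:
            return None
        return min(r.event_date for r in self.contributing_records)

    def interval(self) -> tuple[date, date] | None:
        """Closed interval for overlap checks; unknown episodes run from
        start to their last record date."""
        if self.start_date is None:
            return None
        end = self.end_date if self.end_date is not None else self.last_record_date
        if end is None or end < self.start_date:
            end = self.start_date
        return (self.start_date, end)


# ---------------------------------------------------------------------------
# Field parsing helpers
# ---------------------------------------------------------------------------


def _parse_field_date(s: str) -> date | None:
    s = s.strip()
    if not s:
        return None
    ts = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    if pd.isna(ts):
        ts = pd.to_datetime(s, dayfirst=True, errors="coerce")
    return None if pd.isna(ts) else ts.date()


def _parse_weeks(s: str) -> int | None:
    """A gestation-week count: bare integer or '12w'/'12 weeks'."""
    s = s.strip().lower()
    if not s:
        return None
    for suffix in ("weeks", "week", "wk", "w"):
        if s.endswith(suffix):
            s = s[: -len(suffix)].strip()
            break
    try:
        v = int(float(s))
    except ValueError:
        return None
    return v if v >= 0 else None


def _parse_offset_days(s: str, max_days: int) -> int | None:
    """Postnatal offset in data fields: 'Nd' days, 'Nw' weeks, or a bare
    integer read as weeks when <= 8 and days otherwise; capped at max_days."""
    s = s.strip().lower()
    if not s:
        return None
    unit = None
    for suffix, u in (("days", "d"), ("day", "d"), ("d", "d"),
                      ("weeks", "w"), ("week", "w"), ("wk", "w"), ("w", "w")):
        if s.endswith(suffix):
            s = s[: -len(suffix)].strip()
            unit = u
            break
    try:
        v = int(float(s))
    except ValueError:
        return None
    if v < 0:
        return None
    if unit == "w" or (unit is None and v <= 8):
        v *= 7
    return min(v, max_days)


# ---------------------------------------------------------------------------
# Stage 1: tagging
# ---------------------------------------------------------------------------


def tag_records(
    events: Iterable[ClinicalEvent],
    entities: Iterable[EntityRecord],
    cdict: CodeDictionary,
    scan_codes: frozenset[str] = frozenset(),
) -> list[PregnancyRecord]:
    """Turn a patient's raw events into tagged pregnancy records.

    Clinical events whose code is in the dictionary, and entity records
    whose entity code appears in the rule tables, each become one record;
    everything else is discarded.
    """
    out: list[PregnancyRecord] = []
    for ev in events:
        cats = cdict.categories_of(ev.code)
        if cats:
            out.append(PregnancyRecord(
                patient_id=ev.patient_id, source="clinical",
                event_date=ev.event_date, categories=cats,
                payload=(ev.code,), scan_flag=ev.code in scan_codes,
            ))
    known = set(START_ENTITY_RULES) | set(END_ENTITY_RULES)
    for en in entities:
        if en.entity_code in known:
            out.append(PregnancyRecord(
                patient_id=en.patient_id, source="entity",
                event_date=en.event_date, entity_code=en.entity_code,
                payload=en.data, scan_flag=en.entity_code == 284,
            ))
    out.sort(key=PregnancyRecord.sort_key)
    return out


def record_code(rec: PregnancyRecord) -> str | None:
    return rec.payload[0] if rec.source == "clinical" and rec.payload else None


# ---------------------------------------------------------------------------
# Stage 2/3: outcome candidates, clustering, end dates
# ---------------------------------------------------------------------------

# end-candidate precedence classes, best first
_CLS_ENTITY_DIRECT = 0   # entity delivery-detail records carrying the event date
_CLS_CLINICAL = 1        # dated outcome clinical codes
_CLS_BACKDATE = 2        # back-dated postnatal / CHS / discharge rules

_END_SOURCE = {
    _CLS_ENTITY_DIRECT: "entity_rule",
    _CLS_CLINICAL: "outcome_event",
    _CLS_BACKDATE: "postnatal_backdate",
}


@dataclass(frozen=True)
class EndCandidate:
    record: PregnancyRecord
    group: str          # "delivery" | "loss"
    end_date: date
    cls: int


def _entity_end_candidate(rec: PregnancyRecord, cfg: AlgorithmConfig) -> EndCandidate | None:
    rule = END_ENTITY_RULES.get(rec.entity_code or -1)
    if rule is None:
        return None
    ev = rec.event_date
    group = "delivery"
    if rule == "event_date":
        return EndCandidate(rec, group, ev, _CLS_ENTITY_DIRECT)
    if rule == "event_minus_42":
        return EndCandidate(rec, group, ev - 42 * DAY, _CLS_BACKDATE)
    if rule == "event_minus_7":
        return EndCandidate(rec, group, ev - 7 * DAY, _CLS_BACKDATE)
    if rule == "chs_stage":
        stage = rec.field(2).strip().lower().replace(" ", "")
        if stage == "birth":
            return EndCandidate(rec, group, ev, _CLS_BACKDATE)
        if stage in {"6wk", "6w", "6weeks", "6week"}:
            return EndCandidate(rec, group, ev - 42 * DAY, _CLS_BACKDATE)
        return None  # used only if CHS stage specifies birth or 6 weeks
    if rule == "event_minus_offset_d2":
        off = _parse_offset_days(rec.field(2), cfg.postnatal_offset_max_days)
        if off is None:
            off = cfg.postnatal_default_backdate_days
        return EndCandidate(rec, group, ev - off * DAY, _CLS_BACKDATE)
    if rule == "discharge_d1_minus_2":
        d = _parse_field_date(rec.field(1))
        if d is None:
            return None
        if rec.field(2).strip().lower() == "loss":
            group = "loss"
        return EndCandidate(rec, group, d - 2 * DAY, _CLS_BACKDATE)
    raise AssertionError(f"unhandled end rule {rule}")


def _clinical_end_candidates(rec: PregnancyRecord, cfg: AlgorithmConfig) -> list[EndCandidate]:
    out = []
    cats = rec.categories
    if cats & {"delivery", "stillbirth", "preterm", "postterm"}:
        out.append(EndCandidate(rec, "delivery", rec.event_date, _CLS_CLINICAL))
    elif cats & {"third_trimester", "late_pregnancy"}:
        out.append(EndCandidate(rec, "delivery", rec.event_date, _CLS_BACKDATE))
    elif "postnatal" in cats:
        out.append(EndCandidate(
            rec, "delivery",
            rec.event_date - cfg.postnatal_default_backdate_days * DAY,
            _CLS_BACKDATE,
        ))
    if cats & LOSS_EVIDENCE:
        out.append(EndCandidate(rec, "loss", rec.event_date, _CLS_CLINICAL))
    return out


def outcome_candidates(
    records: Iterable[PregnancyRecord], cfg: AlgorithmConfig
) -> list[EndCandidate]:
    """All (record, provisional end date) outcome candidates, both groups.

    A record spanning both evidence groups yields one candidate in each
    stream; the streams are clustered independently.
    """
    out: list[EndCandidate] = []
    for rec in records:
        if rec.source == "entity":
            c = _entity_end_candidate(rec, cfg)
            if c is not None:
                out.append(c)
        else:
            out.extend(_clinical_end_candidates(rec, cfg))
    out.sort(key=lambda c: (c.end_date, c.cls, c.record.sort_key()))
    return out


def cluster_outcomes(
    records: Iterable[PregnancyRecord], cfg: AlgorithmConfig
) -> tuple[list[list[EndCandidate]], list[list[EndCandidate]]]:
    """Group outcome candidates into distinct pregnancy episodes.

    Within each evidence stream, candidates sorted by provisional end date
    chain into one cluster while consecutive dates are no more than the
    stream's merge window apart; a larger gap starts a new episode.
    Delivery and loss streams are never merged.
    """
    cands = outcome_candidates(records, cfg)
    windows = {"delivery": cfg.delivery_merge_days, "loss": cfg.loss_merge_days}
    clusters: dict[str, list[list[EndCandidate]]] = {"delivery": [], "loss": []}
    for group in ("delivery", "loss"):
        window = windows[group]
        prev: date | None = None
        for c in (c for c in cands if c.group == group):
            if prev is None or (c.end_date - prev).days > window:
                clusters[group].append([])
            clusters[group][-1].append(c)
            prev = c.end_date
    return clusters["delivery"], clusters["loss"]


def estimate_end_date(cluster: Sequence[EndCandidate]) -> tuple[date, str]:
    """Resolve one cluster's end date.

    Entity delivery-detail records (which carry the event date directly)
    outrank dated outcome clinical codes, which outrank back-dated
    postnatal/CHS/discharge approximations; ties within the winning class
    break to the earliest candidate date.
    """
    if not cluster:
        raise ValueError("empty cluster")
    best_cls = min(c.cls for c in cluster)
    end = min(c.end_date for c in cluster if c.cls == best_cls)
    return end, _END_SOURCE[best_cls]


# ---------------------------------------------------------------------------
# Stage 4: start dates
# ---------------------------------------------------------------------------

#: start-source priority levels, best first
START_LEVELS = ("edd", "edc", "lmp", "antenatal_gestation", "gestation_at_birth")


@dataclass(frozen=True)
class StartCandidate:
    record: PregnancyRecord
    level: str
    start_date: date
    scan: bool = False


def _capped_weeks_back(anchor: date, weeks: int, cfg: AlgorithmConfig) -> date:
    return anchor - min(weeks * 7, cfg.max_gestation_days) * DAY


def start_candidates_for_record(
    rec: PregnancyRecord,
    end_date: date | None,
    cfg: AlgorithmConfig,
    gestation_weeks_map: Mapping[str, int] | None = None,
    birth_gestation_map: Mapping[str, int] | None = None,
) -> list[StartCandidate]:
    """Start-date candidates a single record contributes.

    ``end_date`` anchors gestation-at-birth arithmetic and may be None for
    outcome-unknown episodes (in which case those rules yield nothing).
    """
    out: list[StartCandidate] = []
    ev = rec.event_date
    if rec.source == "entity":
        rule = START_ENTITY_RULES.get(rec.entity_code or -1)
        if rule is None:
            return out
        if rule == "edd_d2_minus_280":
            edd = _parse_field_date(rec.field(2))
            if edd is not None:
                out.append(StartCandidate(rec, "edd", edd - 280 * DAY, scan=False))
        elif rule == "edd_d8_or_weeks_d2":
            edd = _parse_field_date(rec.field(8))
            if edd is not None:
                out.append(StartCandidate(rec, "edd", edd - 280 * DAY, scan=True))
            else:
                w = _parse_weeks(rec.field(2))
                if w is not None:
                    out.append(StartCandidate(
                        rec, "edd", _capped_weeks_back(ev, w, cfg), scan=True))
        elif rule == "event_minus_weeks_d1":
            w = _parse_weeks(rec.field(1))
            if w is not None:
                out.append(StartCandidate(
                    rec, "antenatal_gestation", _capped_weeks_back(ev, w, cfg)))
        elif rule == "event_minus_weeks_d8":
            w = _parse_weeks(rec.field(8))
            if w is not None:
                out.append(StartCandidate(
                    rec, "antenatal_gestation", _capped_weeks_back(ev, w, cfg)))
        elif rule == "end_minus_weeks_d1":
            w = _parse_weeks(rec.field(1))
            if w is not None and end_date is not None:
                out.append(StartCandidate(
                    rec, "gestation_at_birth", _capped_weeks_back(end_date, w, cfg)))
        return out

    cats = rec.categories
    code = record_code(rec)
    # The event date of an LMP record is the LMP itself; likewise for EDC.
    # Clinical EDD codes carry no machine-readable delivery date in this
    # schema, so the EDD level is fed by entity records only.
    if "edc" in cats:
        out.append(StartCandidate(rec, "edc", ev))
    if "lmp" in cats:
        out.append(StartCandidate(rec, "lmp", ev))
    if gestation_weeks_map and code in gestation_weeks_map:
        w = gestation_weeks_map[code]
        out.append(StartCandidate(
            rec, "antenatal_gestation", _capped_weeks_back(ev, w, cfg)))
    if birth_gestation_map and code in birth_gestation_map and end_date is not None:
        w = birth_gestation_map[code]
        out.append(StartCandidate(
            rec, "gestation_at_birth", _capped_weeks_back(end_date, w, cfg)))
    return out


def estimate_start_date(
    end_date: date | None,
    candidates: Iterable[StartCandidate],
    impute_days: int | None,
) -> tuple[date | None, str]:
    """Pick the start date from candidates via the priority hierarchy.

    The first priority level holding a valid candidate (start strictly
    before the end date) wins.  Within a level the most recently recorded
    candidate is used, except that scan-derived EDD evidence outranks
    non-scan EDD regardless of recency.  With no valid candidate the start
    is imputed as ``end - impute_days``.
    """
    by_level: dict[str, list[StartCandidate]] = {lv: [] for lv in START_LEVELS}
    for c in candidates:
        by_level[c.level].append(c)
    for level in START_LEVELS:
        pool = by_level[level]
        if level == "edd":
            pool = sorted(pool, key=lambda c: (not c.scan, -c.record.event_date.toordinal(),
                                               c.record.sort_key()))
        else:
            pool = sorted(pool, key=lambda c: (-c.record.event_date.toordinal(),
                                               c.record.sort_key()))
        for c in pool:
            if end_date is None or c.start_date < end_date:
                return c.start_date, level
    if end_date is not None and impute_days is not None:
        return end_date - impute_days * DAY, "imputed"
    return None, "imputed"


# ---------------------------------------------------------------------------
# Stage 7 helpers: classification, trimesters, flags
# ---------------------------------------------------------------------------


def classify_outcome(
    records: Sequence[PregnancyRecord],
    group: str,
    live_birth_codes: frozenset[str] = frozenset(),
) -> str:
    """Outcome class of one cluster's records.

    Delivery clusters: stillbirth evidence alone (even alongside generic
    delivery codes) classifies as stillbirth; explicit live-birth evidence
    together with stillbirth evidence classifies as live_and_stillbirth;
    otherwise delivery-type evidence defaults to live birth, falling back
    to the third-trimester then late-pregnancy/postnatal classes when only
    such indirect evidence exists.  Loss clusters take the most specific
    loss diagnosis present.
    """
    cats: set[str] = set()
    has_live_specific = False
    for r in records:
        cats |= r.categories
        if record_code(r) in live_birth_codes:
            has_live_specific = True
    if group == "delivery":
        has_still = "stillbirth" in cats
        # entity delivery-detail records are direct evidence of a birth
        has_delivery = bool(cats & {"delivery", "preterm", "postterm"}) or any(
            r.source == "entity" for r in records)
        if has_still:
            return "live_and_stillbirth" if has_live_specific else "stillbirth"
        if has_delivery:
            return "live_birth"
        if "third_trimester" in cats:
            return "delivery_third_trimester"
        return "delivery_late_pregnancy"
    for label in LOSS_PRECEDENCE:
        if label in cats:
            return label
    return "unspecified_loss"


def compute_trimesters(ep: PregnancyEpisode) -> PregnancyEpisode:
    """Trimester 2 starts at gestational day 91, trimester 3 at day 182;
    a boundary at or past the end date is dropped."""
    ep.trimester2_start = None
    ep.trimester3_start = None
    if ep.start_date is None:
        return ep
    t2 = ep.start_date + 91 * DAY
    t3 = ep.start_date + 182 * DAY
    if ep.end_date is None or t2 < ep.end_date:
        ep.trimester2_start = t2
    if ep.end_date is None or t3 < ep.end_date:
        ep.trimester3_start = t3
    return ep


def flag_attributes(ep: PregnancyEpisode) -> PregnancyEpisode:
    cats: set[str] = set()
    for r in ep.contributing_records:
        cats |= r.categories
    ep.preterm_flag = "preterm" in cats
    ep.postterm_flag = "postterm" in cats and not ep.preterm_flag
    ep.multiple_flag = "multiple" in cats
    return ep


def flag_conflicts(episodes: Sequence[PregnancyEpisode]) -> None:
    """Flag every pair of a patient's episodes whose intervals intersect.

    Conflicting episodes are never altered or removed; the flag simply
    surfaces them for the analyst.
    """
    ivs = [ep.interval() for ep in episodes]
    for i in range(len(episodes)):
        for j in range(i + 1, len(episodes)):
            a, b = ivs[i], ivs[j]
            if a is None or b is None:
                continue
            if a[0] <= b[1] and b[0] <= a[1]:
                episodes[i].conflict_flag = True
                episodes[j].conflict_flag = True


def flag_ongoing(ep: PregnancyEpisode, censor_date: date | None,
                 cfg: AlgorithmConfig) -> PregnancyEpisode:
    """An outcome-unknown episode is potentially ongoing when its earliest
    record is less than 38 weeks before the censoring date."""
    ep.ongoing_flag = False
    if ep.outcome != "outcome_unknown" or censor_date is None:
        return ep
    first = ep.earliest_record_date
    if first is not None and (censor_date - first).days < cfg.ongoing_threshold_days:
        ep.ongoing_flag = True
    return ep


def link_infants(
    episodes: Sequence[PregnancyEpisode],
    candidates: Iterable[MotherBabyCandidate],
    cfg: AlgorithmConfig,
) -> None:
    """Attach infants to the delivery episode nearest their birth month.

    Each infant links to at most one episode, the one minimising the gap
    between the episode's delivery date and the infant's representative
    birth date (15th of the birth month), provided the gap is at most
    60 days.  Stillbirth-only episodes are not linkable.
    """
    linkable = [
        ep for ep in episodes
        if ep.outcome in DELIVERY_OUTCOMES - {"stillbirth"} and ep.end_date is not None
    ]
    for cand in sorted(candidates, key=lambda c: (c.infant_id, c.mother_id)):
        best: tuple[int, date, PregnancyEpisode] | None = None
        for ep in linkable:
            gap = abs((ep.end_date - cand.representative_birth_date).days)
            if gap > cfg.mother_baby_max_gap_days:
                continue
            key = (gap, ep.end_date)
            if best is None or key < (best[0], best[1]):
                best = (gap, ep.end_date, ep)
        if best is not None:
            best[2].infant_ids.append(cand.infant_id)


# ---------------------------------------------------------------------------
# Stages 5/6: antenatal attachment and unknown episodes
# ---------------------------------------------------------------------------


def attach_antenatal(
    episodes: Sequence[PregnancyEpisode],
    leftover: Iterable[PregnancyRecord],
) -> list[PregnancyRecord]:
    """Attach antenatal-type records falling inside a dated episode.

    A record inside more than one (overlapping) episode attaches to the
    episode whose end is nearest.  Returns the records that attached to no
    episode (candidates for outcome-unknown episodes).
    """
    unattached: list[PregnancyRecord] = []
    for rec in leftover:
        best: PregnancyEpisode | None = None
        best_gap: int | None = None
        for ep in episodes:
            iv = ep.interval()
            if iv is None or not (iv[0] <= rec.event_date <= iv[1]):
                continue
            gap = (iv[1] - rec.event_date).days
            if best_gap is None or gap < best_gap:
                best, best_gap = ep, gap
        if best is not None:
            best.contributing_records.append(rec)
        else:
            unattached.append(rec)
    return unattached


def build_unknown_episodes(
    unattached: Sequence[PregnancyRecord],
    cfg: AlgorithmConfig,
    gestation_weeks_map: Mapping[str, int] | None = None,
) -> list[PregnancyEpisode]:
    """Cluster unattached dating/antenatal records into outcome-unknown
    episodes.

    Records whose categories are exclusively non-dating (timing-uncertain
    or other-postnatal) never seed an episode.  Successive records no more
    than one full term (280 days) apart form one episode; a single
    antenatal code suffices.  The start is estimated with the usual
    hierarchy; lacking any dating evidence it falls back to the earliest
    record minus the typical gestation at a first antenatal record.
    """
    seeds = [
        r for r in unattached
        if r.categories - NON_DATING_CATEGORIES or r.source == "entity"
    ]
    seeds.sort(key=PregnancyRecord.sort_key)
    clusters: list[list[PregnancyRecord]] = []
    prev: date | None = None
    for rec in seeds:
        if prev is None or (rec.event_date - prev).days > cfg.unknown_gap_days:
            clusters.append([])
        clusters[-1].append(rec)
        prev = rec.event_date
    episodes = []
    for cl in clusters:
        cands: list[StartCandidate] = []
        for rec in cl:
            cands.extend(start_candidates_for_record(
                rec, None, cfg, gestation_weeks_map=gestation_weeks_map))
        start, source = estimate_start_date(None, cands, None)
        ep = PregnancyEpisode(
            patient_id=cl[0].patient_id,
            outcome="outcome_unknown",
            contributing_records=list(cl),
        )
        if start is None:
            start = min(r.event_date for r in cl) - cfg.impute_unknown_lead_days * DAY
            source = "imputed"
        ep.start_date, ep.start_source = start, source
        compute_trimesters(ep)
        episodes.append(ep)
    return episodes


# ---------------------------------------------------------------------------
# Per-patient assembly and register construction
# ---------------------------------------------------------------------------


def build_patient_episodes(
    records: Sequence[PregnancyRecord],
    cfg: AlgorithmConfig | None = None,
    censor_date: date | None = None,
    links: Iterable[MotherBabyCandidate] = (),
    gestation_weeks_map: Mapping[str, int] | None = None,
    birth_gestation_map: Mapping[str, int] | None = None,
    live_birth_codes: frozenset[str] = frozenset(),
) -> list[PregnancyEpisode]:
    """Run all stages for one patient's tagged records."""
    cfg = cfg or AlgorithmConfig()
    delivery_clusters, loss_clusters = cluster_outcomes(records, cfg)

    outcome_record_ids = {
        id(c.record)
        for cl in delivery_clusters + loss_clusters
        for c in cl
    }

    episodes: list[PregnancyEpisode] = []
    pending: list[tuple[PregnancyEpisode, list[PregnancyRecord], str]] = []
    for group, clusters in (("delivery", delivery_clusters), ("loss", loss_clusters)):
        for cl in clusters:
            end, end_source = estimate_end_date(cl)
            recs = []
            seen = set()
            for c in cl:
                if id(c.record) not in seen:
                    seen.add(id(c.record))
                    recs.append(c.record)
            ep = PregnancyEpisode(
                patient_id=recs[0].patient_id,
                end_date=end, end_source=end_source,
                outcome=classify_outcome(recs, group, live_birth_codes),
                contributing_records=recs,
            )
            pending.append((ep, recs, group))
            episodes.append(ep)

    # Dating records: anything not consumed as outcome evidence.
    dating_pool = [r for r in records if id(r) not in outcome_record_ids]

    # Attribute each dating record to the episode with the nearest end among
    # those whose dating window contains it, then run the start hierarchy.
    assigned: dict[int, list[PregnancyRecord]] = {id(ep): [] for ep, _, _ in pending}
    used_ids: set[int] = set()
    window = cfg.dating_window_days
    for rec in dating_pool:
        best_ep = None
        best_gap = None
        for ep, _, _ in pending:
            gap = (ep.end_date - rec.event_date).days
            if 0 <= gap < window:
                if best_gap is None or gap < best_gap:
                    best_ep, best_gap = ep, gap
        if best_ep is not None:
            assigned[id(best_ep)].append(rec)
            used_ids.add(id(rec))

    impute = {
        **{o: cfg.impute_delivery_days for o in DELIVERY_OUTCOMES},
        **{o: cfg.impute_loss_days for o in LOSS_OUTCOMES},
        "ectopic": cfg.impute_ectopic_days,
    }
    for ep, recs, group in pending:
        cands: list[StartCandidate] = []
        for rec in assigned[id(ep)] + recs:
            cands.extend(start_candidates_for_record(
                rec, ep.end_date, cfg,
                gestation_weeks_map=gestation_weeks_map,
                birth_gestation_map=birth_gestation_map,
            ))
        # gestation-at-birth evidence must sit close to the delivery
        cands = [
            c for c in cands
            if c.level != "gestation_at_birth"
            or 0 <= (c.record.event_date - ep.end_date).days <= cfg.birth_gestation_window_days
        ]
        ep.start_date, ep.start_source = estimate_start_date(
            ep.end_date, cands, impute[ep.outcome])
        for rec in assigned[id(ep)]:
            ep.contributing_records.append(rec)

    # Stage 5: attach remaining antenatal-type records to dated episodes.
    leftover = [r for r in dating_pool if id(r) not in used_ids]
    unattached = attach_antenatal(episodes, leftover)

    # Stage 6: outcome-unknown episodes from what is left.
    episodes.extend(build_unknown_episodes(
        unattached, cfg, gestation_weeks_map=gestation_weeks_map))

    # Stage 7: trimesters, flags.
    for ep in episodes:
        compute_trimesters(ep)
        flag_attributes(ep)
        flag_ongoing(ep, censor_date, cfg)
    flag_conflicts(episodes)

    # Stage 8: infant linkage.
    link_infants(episodes, links, cfg)

    episodes.sort(key=lambda e: (
        e.start_date or date.min,
        e.end_date or date.max,
        e.outcome,
    ))
    return episodes


def build_register(
    events: Iterable[ClinicalEvent],
    entities: Iterable[EntityRecord],
    patients: Iterable[PatientMeta],
    links: Iterable[MotherBabyCandidate],
    cdict: CodeDictionary,
    cfg: AlgorithmConfig | None = None,
    default_censor: date | None = None,
    gestation_weeks_map: Mapping[str, int] | None = None,
    birth_gestation_map: Mapping[str, int] | None = None,
    live_birth_codes: frozenset[str] = frozenset(),
    scan_codes: frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Build the full register: one row per pregnancy episode.

    Output is sorted by (patient_id, start_date) with patient-scoped
    sequential episode ids, and is identical for any input row ordering.
    """
    cfg = cfg or AlgorithmConfig()
    ev_by_pat: dict[str, list[ClinicalEvent]] = {}
    for ev in events:
        ev_by_pat.setdefault(ev.patient_id, []).append(ev)
    en_by_pat: dict[str, list[EntityRecord]] = {}
    for en in entities:
        en_by_pat.setdefault(en.patient_id, []).append(en)
    link_by_pat: dict[str, list[MotherBabyCandidate]] = {}
    for lk in links:
        link_by_pat.setdefault(lk.mother_id, []).append(lk)
    meta_by_pat = {m.patient_id: m for m in patients}

    all_pids = sorted(set(ev_by_pat) | set(en_by_pat))
    rows = []
    for pid in all_pids:
        meta = meta_by_pat.get(pid)
        censor = meta.censor_date() if meta is not None else None
        if censor is None:
            censor = default_censor
        records = tag_records(
            ev_by_pat.get(pid, ()), en_by_pat.get(pid, ()), cdict,
            scan_codes=scan_codes,
        )
        eps = build_patient_episodes(
            records, cfg, censor_date=censor,
            links=link_by_pat.get(pid, ()),
            gestation_weeks_map=gestation_weeks_map,
            birth_gestation_map=birth_gestation_map,
            live_birth_codes=live_birth_codes,
        )
        for k, ep in enumerate(eps, start=1):
            ep.episode_id = f"{pid}:{k}"
            rows.append({
                "patient_id": ep.patient_id,
                "episode_id": ep.episode_id,
                "start_date": ep.start_date.isoformat() if ep.start_date else "",
                "end_date": ep.end_date.isoformat() if ep.end_date else "",
                "start_source": ep.start_source,
                "end_source": ep.end_source,
                "outcome": ep.outcome,
                "gestation_days": ep.gestation_days if ep.gestation_days is not None else "",
                "trimester2_start": ep.trimester2_start.isoformat() if ep.trimester2_start else "",
                "trimester3_start": ep.trimester3_start.isoformat() if ep.trimester3_start else "",
                "preterm_flag": ep.preterm_flag,
                "postterm_flag": ep.postterm_flag,
                "multiple_flag": ep.multiple_flag,
                "conflict_flag": ep.conflict_flag,
                "ongoing_flag": ep.ongoing_flag,
                "infant_ids": ";".join(ep.infant_ids),
            })
    return pd.DataFrame(rows, columns=REGISTER_COLUMNS)
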