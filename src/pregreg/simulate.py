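"""Synthetic cohort generator: ground-truth pregnancies plus the coded
tables a primary-care extract would contain.

The generator draws a cohort of women with registration metadata, places
pregnancies along each woman's fertile, observed time with configurable
outcome mix and gestation distributions, then *emits* the six input
tables (clinical events, entity records, patient metadata, mother-baby
candidates, reference outcome episodes, and the truth table itself)
under a recording model: per-record-type emission probabilities,
recording delay, retrospective coding of pre-registration pregnancies,
and date jitter.  With all probabilities at 1 and no delay or jitter the
emitted record is information-complete and the register builder recovers
every truth pregnancy exactly.

Everything is reproducible from (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ehr_io import ENTITY_DATA_FIELDS, PatientMeta

DAY = timedelta(days=1)

#: clinical code emitted for each truth outcome class
OUTCOME_CODES = {
    "live_birth": "L20..11",
    "stillbirth": "Q4z..15",
    "miscarriage": "L04..00",
    "top": "L052.11",
    "probable_top": "L05..12",
    "ectopic": "L03..00",
    "molar": "L002.00",
    "blighted_ovum": "L010.00",
    "unspecified_loss": "L0z..00",
    "delivery_third_trimester": "62N8.00",
    "delivery_late_pregnancy": "L281.00",
}

ANTENATAL_CODE = "62...00"
LMP_CODE = "1513.00"
POSTNATAL_CODE = "62S7.00"
PRETERM_CODE = "L142.11"
POSTTERM_CODE = "L150.00"
MULTIPLE_CODE = "L210.00"

DELIVERY_TRUTH_OUTCOMES = frozenset({
    "live_birth", "stillbirth", "live_and_stillbirth",
    "delivery_third_trimester", "delivery_late_pregnancy",
})


@dataclass(frozen=True)
class TruthPregnancy:
    patient_id: str
    preg_index: int
    true_start: date
    true_end: date
    true_outcome: str
    gestation_days: int
    is_preterm: bool = False
    is_postterm: bool = False
    is_multiple: bool = False
    infant_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort and pregnancy-process parameters.

    Defaults give a dynamic cohort observed 2005-2015 with a realistic
    outcome mix (live birth dominant, stillbirth rare, losses mostly
    first-trimester) and term deliveries centred on 280 days.
    """

    coverage_start: date = date(2005, 1, 1)
    coverage_end: date = date(2015, 12, 31)
    birth_year_range: tuple[int, int] = (1966, 1998)
    pregnancy_rate_per_year: float = 0.12
    fertile_age_range: tuple[int, int] = (16, 44)
    historical_lookback_years: int = 8      # pregnancies may pre-date registration
    transfer_out_p: float = 0.10
    death_p: float = 0.002
    delivery_gestation_mean: float = 280.0
    delivery_gestation_sd: float = 9.0
    delivery_gestation_bounds: tuple[int, int] = (154, 300)
    loss_gestation_bounds: tuple[int, int] = (35, 140)
    postterm_threshold_days: int = 294
    preterm_threshold_days: int = 259
    twin_p: float = 0.015
    min_gap_after_loss: int = 28
    min_gap_after_delivery: int = 150
    outcome_mix: dict = field(default_factory=lambda: {
        "live_birth": 0.625,
        "stillbirth": 0.003,
        "miscarriage": 0.105,
        "top": 0.015,
        "probable_top": 0.090,
        "ectopic": 0.009,
        "molar": 0.001,
        "blighted_ovum": 0.001,
        "unspecified_loss": 0.011,
        "delivery_third_trimester": 0.016,
        "delivery_late_pregnancy": 0.018,
    })


@dataclass(frozen=True)
class RecordingModel:
    """How completely and how promptly the GP record captures each truth
    pregnancy.  Probabilities in [0, 1]; delays and jitter in days."""

    lmp_p: float = 0.25
    edd_p: float = 0.60
    booking_p: float = 0.70
    antenatal_visit_rate: float = 0.15      # per-week emission probability
    outcome_code_p: float = 0.95
    postnatal_p: float = 0.60
    entity_detail_p: float = 0.70
    hospital_emit_p: float = 0.95
    recording_delay_mean_days: float = 0.0  # Poisson mean delay on outcome codes
    historical_recording_p: float = 0.20    # retro-coding of pre-registration pregnancies
    historical_offset_days: tuple[int, int] = (7, 90)
    date_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lmp_p", "edd_p", "booking_p", "outcome_code_p",
                     "postnatal_p", "entity_detail_p", "hospital_emit_p",
                     "historical_recording_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.antenatal_visit_rate < 0 or self.recording_delay_mean_days < 0:
            raise ValueError("rates must be non-negative")

    @classmethod
    def full(cls) -> "RecordingModel":
        """Complete, instantaneous, noise-free recording."""
        return cls(lmp_p=1.0, edd_p=1.0, booking_p=1.0, antenatal_visit_rate=0.25,
                   outcome_code_p=1.0, postnatal_p=1.0, entity_detail_p=1.0,
                   hospital_emit_p=1.0, recording_delay_mean_days=0.0,
                   historical_recording_p=0.0, date_jitter_sd=0.0)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _rand_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    span = (hi - lo).days
    return lo + int(rng.integers(0, max(span, 0) + 1)) * DAY


def simulate_cohort(
    n_patients: int,
    seed: int,
    config: SimulationConfig | None = None,
) -> tuple[list[TruthPregnancy], list[PatientMeta]]:
    """Draw a cohort of women and their ground-truth pregnancy histories.

    Pregnancy onsets follow a per-woman Poisson process over her fertile,
    simulated time (which may begin before she registers, producing
    historical pregnancies), with enforced recovery gaps after each
    outcome (28 days after a loss, 150 after a delivery).
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    outcomes = sorted(cfg.outcome_mix)
    weights = np.array([cfg.outcome_mix[o] for o in outcomes], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("outcome_mix must have positive total weight")
    weights = weights / weights.sum()

    truths: list[TruthPregnancy] = []
    metas: list[PatientMeta] = []
    infant_counter = 0
    for i in range(n_patients):
        pid = f"P{i:06d}"
        yob = int(rng.integers(cfg.birth_year_range[0], cfg.birth_year_range[1] + 1))
        reg_lo = cfg.coverage_start
        reg_hi = cfg.coverage_end - 365 * DAY
        reg_start = _rand_date(rng, reg_lo, reg_hi)
        reg_end = None
        if rng.random() < cfg.transfer_out_p:
            reg_end = _rand_date(rng, reg_start + 365 * DAY, cfg.coverage_end)
        death = None
        if rng.random() < cfg.death_p:
            death = _rand_date(rng, reg_start, cfg.coverage_end)
        meta = PatientMeta(
            patient_id=pid, year_of_birth=yob,
            registration_start=reg_start, registration_end=reg_end,
            death_date=death, practice_uts=cfg.coverage_start,
            practice_last_collection=cfg.coverage_end,
        )
        metas.append(meta)

        fert_lo = max(date(yob + cfg.fertile_age_range[0], 1, 1),
                      reg_start - cfg.historical_lookback_years * 365 * DAY)
        censor = meta.censor_date() or cfg.coverage_end
        fert_hi = min(date(yob + cfg.fertile_age_range[1], 1, 1), censor)
        if cfg.pregnancy_rate_per_year <= 0 or fert_lo >= fert_hi:
            continue

        t = fert_lo
        k = 0
        while True:
            wait_days = rng.exponential(365.25 / cfg.pregnancy_rate_per_year)
            start = t + int(round(wait_days)) * DAY
            if start >= fert_hi:
                break
            outcome = str(rng.choice(outcomes, p=weights))
            if outcome in DELIVERY_TRUTH_OUTCOMES:
                g = int(round(rng.normal(cfg.delivery_gestation_mean,
                                         cfg.delivery_gestation_sd)))
                g = int(np.clip(g, *cfg.delivery_gestation_bounds))
            else:
                g = int(rng.integers(cfg.loss_gestation_bounds[0],
                                     cfg.loss_gestation_bounds[1] + 1))
            end = start + g * DAY
            if end > fert_hi:
                break  # would be censored mid-pregnancy; truth table omits it
            is_del = outcome in DELIVERY_TRUTH_OUTCOMES
            is_preterm = is_del and g < cfg.preterm_threshold_days
            is_postterm = is_del and g >= cfg.postterm_threshold_days
            infants: tuple[str, ...] = ()
            is_multiple = False
            if outcome == "live_birth":
                n_babies = 2 if rng.random() < cfg.twin_p else 1
                is_multiple = n_babies > 1
                infants = tuple(
                    f"B{infant_counter + j:06d}" for j in range(n_babies))
                infant_counter += n_babies
            k += 1
            truths.append(TruthPregnancy(
                patient_id=pid, preg_index=k, true_start=start, true_end=end,
                true_outcome=outcome, gestation_days=g,
                is_preterm=is_preterm, is_postterm=is_postterm,
                is_multiple=is_multiple, infant_ids=infants,
            ))
            gap = cfg.min_gap_after_delivery if is_del else cfg.min_gap_after_loss
            t = end + gap * DAY
    return truths, metas


# ---------------------------------------------------------------------------
# Record emission
# ---------------------------------------------------------------------------


@dataclass
class EmittedTables:
    events: pd.DataFrame
    entities: pd.DataFrame
    patients: pd.DataFrame
    links: pd.DataFrame
    reference: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("events", "entities", "patients", "links", "reference", "truth"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def patients_frame(metas: Sequence[PatientMeta]) -> pd.DataFrame:
    iso = lambda d: d.isoformat() if d is not None else ""
    return pd.DataFrame(
        [{
            "patient_id": m.patient_id,
            "year_of_birth": m.year_of_birth,
            "reg_start": iso(m.registration_start),
            "reg_end": iso(m.registration_end),
            "death_date": iso(m.death_date),
            "uts": iso(m.practice_uts),
            "last_collection": iso(m.practice_last_collection),
        } for m in metas]
    )


def truth_frame(truths: Sequence[TruthPregnancy]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "patient_id": t.patient_id,
            "preg_index": t.preg_index,
            "true_start": t.true_start.isoformat(),
            "true_end": t.true_end.isoformat(),
            "true_outcome": t.true_outcome,
            "gestation_days": t.gestation_days,
            "is_preterm": t.is_preterm,
            "is_postterm": t.is_postterm,
            "is_multiple": t.is_multiple,
            "infant_ids": ";".join(t.infant_ids),
        } for t in truths]
    )


def emit_records(
    truths: Sequence[TruthPregnancy],
    metas: Sequence[PatientMeta],
    model: RecordingModel | None = None,
    seed: int = 0,
) -> EmittedTables:
    """Emit the coded tables implied by the truth under a recording model.

    For each pregnancy observed during registration the generator may
    emit: an LMP code at the true start; an antenatal booking (entity 60,
    10 weeks' gestation) at start+70 d; a pregnancy-dates record (entity
    129) carrying the true EDD; scheduled antenatal visit codes; outcome
    clinical codes at the true end (plus any recording delay); a
    delivery-detail entity record (78) or a loss pregnancy-outcome record
    (114); a postnatal check at end+42 d; a hospital reference episode;
    and mother-baby candidates for live births.  Pre-registration
    pregnancies are, with some probability, retro-coded after
    registration with the *recording* date (not the true outcome date),
    reproducing the retrospective-recording artefact of real extracts.
    """
    model = model or RecordingModel()
    rng = np.random.default_rng(seed)
    meta_by_pid = {m.patient_id: m for m in metas}

    events: list[dict] = []
    entities: list[dict] = []
    links: list[dict] = []
    reference: list[dict] = []

    def jit(d: date) -> date:
        if model.date_jitter_sd > 0:
            return d + int(round(rng.normal(0.0, model.date_jitter_sd))) * DAY
        return d

    def delay(d: date) -> date:
        if model.recording_delay_mean_days > 0:
            return d + int(rng.poisson(model.recording_delay_mean_days)) * DAY
        return d

    def ev(pid: str, d: date, code: str) -> None:
        events.append({"patient_id": pid, "event_date": d.isoformat(), "code": code})

    def en(pid: str, d: date, code: int, **data: str) -> None:
        row = {"patient_id": pid, "event_date": d.isoformat(), "entity_code": code}
        for f in ENTITY_DATA_FIELDS:
            row[f] = data.get(f, "")
        entities.append(row)

    for t in sorted(truths, key=lambda t: (t.patient_id, t.preg_index)):
        pid = t.patient_id
        meta = meta_by_pid[pid]
        start, end = t.true_start, t.true_end

        if end < meta.registration_start:
            # historical pregnancy: optionally retro-coded with the
            # consultation date rather than the true outcome date
            if rng.random() < model.historical_recording_p:
                lo, hi = model.historical_offset_days
                rec_date = meta.registration_start + int(rng.integers(lo, hi + 1)) * DAY
                code = OUTCOME_CODES.get(t.true_outcome)
                if code is not None:
                    ev(pid, rec_date, code)
            continue

        if rng.random() < model.lmp_p:
            ev(pid, jit(start), LMP_CODE)
        if rng.random() < model.booking_p and start + 70 * DAY < end:
            en(pid, jit(start + 70 * DAY), 60, data1="10")
        if rng.random() < model.edd_p:
            scan_date = min(start + 84 * DAY, end - DAY)
            en(pid, jit(scan_date), 129, data2=(start + 280 * DAY).isoformat())
        wk = 6
        while start + wk * 7 * DAY < end:
            if rng.random() < model.antenatal_visit_rate:
                ev(pid, jit(start + wk * 7 * DAY), ANTENATAL_CODE)
            wk += 1

        outcome_date = delay(jit(end))
        if rng.random() < model.outcome_code_p:
            code = OUTCOME_CODES.get(t.true_outcome)
            if code is not None:
                ev(pid, outcome_date, code)
            # preterm/postterm/multiple markers accompany explicit
            # delivery records only
            if t.true_outcome in ("live_birth", "stillbirth"):
                if t.is_preterm:
                    ev(pid, outcome_date, PRETERM_CODE)
                if t.is_postterm:
                    ev(pid, outcome_date, POSTTERM_CODE)
                if t.is_multiple:
                    ev(pid, outcome_date, MULTIPLE_CODE)

        if rng.random() < model.entity_detail_p:
            if t.true_outcome in ("live_birth", "stillbirth"):
                en(pid, outcome_date, 78)
            elif t.true_outcome not in DELIVERY_TRUTH_OUTCOMES:
                # discharge two days after the loss; the rule backs this out
                en(pid, outcome_date + 2 * DAY, 114,
                   data1=(outcome_date + 2 * DAY).isoformat(), data2="loss")

        if (t.true_outcome in DELIVERY_TRUTH_OUTCOMES
                and rng.random() < model.postnatal_p):
            ev(pid, jit(end + 42 * DAY), POSTNATAL_CODE)

        if rng.random() < model.hospital_emit_p:
            reference.append({
                "patient_id": pid,
                "outcome_date": end.isoformat(),
                "outcome_group": ("delivery" if t.true_outcome in DELIVERY_TRUTH_OUTCOMES
                                  else "loss"),
                "gestation_weeks": (t.gestation_days // 7
                                    if t.true_outcome in DELIVERY_TRUTH_OUTCOMES else ""),
            })

        for infant in t.infant_ids:
            links.append({
                "mother_id": pid, "infant_id": infant,
                "birth_month": f"{end.year}-{end.month:02d}",
            })

    ev_cols = ["patient_id", "event_date", "code"]
    en_cols = ["patient_id", "event_date", "entity_code", *ENTITY_DATA_FIELDS]
    return EmittedTables(
        events=pd.DataFrame(events, columns=ev_cols),
        entities=pd.DataFrame(entities, columns=en_cols),
        patients=patients_frame(metas),
        links=pd.DataFrame(links, columns=["mother_id", "infant_id", "birth_month"]),
        reference=pd.DataFrame(
            reference,
            columns=["patient_id", "outcome_date", "outcome_group", "gestation_weeks"]),
        truth=truth_frame(truths),
    )
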