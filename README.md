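# pregreg

Delineate, date and validate **pregnancy episodes** from coded
primary-care electronic health records.

UK primary-care databases (CPRD GOLD-style extracts) record pregnancies
as scattered coded fragments: antenatal visit codes, last-menstrual-
period (LMP) and expected-delivery-date (EDD) records, structured
"entity" records carrying gestation weeks or discharge dates, and
outcome codes for deliveries and early pregnancy losses. Researchers
studying medicine safety in pregnancy, vaccine uptake, or reproductive
outcomes need those fragments resolved into a **pregnancy register**:
one row per pregnancy, with a start date (LMP onset, gestational day 0),
an end date, trimester boundaries, an outcome class, and quality flags.
`pregreg` implements that resolution as a deterministic per-patient
algorithm, together with the two ways such a register is validated:

- **internal validation** against a hospital-style reference source —
  one-to-one matching of outcome dates within 12 weeks, giving a
  potential positive predictive value (PPV), sensitivity, and
  date/gestation agreement, with sensitivity-analysis variants for
  delayed and retrospective recording;
- **external validation** via population-style rates: live births and
  terminations per 1000 women-years, miscarriages per 100 known-outcome
  pregnancies, prematurity (< 259 days, i.e. < 37 weeks) per 100 births.

A synthetic-data generator emits ground-truth cohorts and their coded
tables under configurable recording completeness, delay and
retrospective-coding behaviour, so the entire pipeline runs, converges
and is tested without any confidential data.

## The algorithm in brief

Per patient: (1) tag pregnancy-related records using a categorised code
list (21 non-exclusive categories) and an entity-code rule table;
(2) cluster outcome evidence into episodes — delivery and loss evidence
stream separately and are never merged, so competing outcomes surface as
*conflict* flags rather than being resolved away; provisional outcome
dates chain within a 56-day window (deliveries) or 28-day window
(losses); (3) resolve each episode's end date (entity delivery-detail
records ≻ dated outcome codes ≻ back-dated postnatal/CHS rules);
(4) estimate the start date through a fixed hierarchy

&nbsp;&nbsp;&nbsp;&nbsp;EDD ≻ EDC ≻ LMP ≻ antenatal gestational age ≻ gestational age at birth,

scan-derived EDD preferred, each gestation-week rule capped at 42 weeks,
falling back to imputation (280 d deliveries / 84 d losses / 56 d
ectopic) recorded in a `start_source` field; (5) attach remaining
antenatal records; (6) build *outcome-unknown* episodes from unattached
evidence — a single antenatal code suffices — flagged *ongoing* when the
earliest record is under 38 weeks before censoring; (7) classify
outcomes (13 classes) and set preterm/postterm/multiple/conflict flags;
(8) link infants whose birth month lies within 60 days of a delivery.

## Worked example

```python
from datetime import date
from pregreg import ClinicalEvent, EntityRecord, build_register, example_codelist

events = [
    ClinicalEvent("w1", date(2010, 1, 1), "1513.00"),   # LMP - first day
    ClinicalEvent("w1", date(2010, 3, 5), "62...00"),   # patient pregnant
    ClinicalEvent("w1", date(2010, 10, 8), "L20..11"),  # spontaneous vaginal delivery
    ClinicalEvent("w1", date(2012, 4, 2), "L04..00"),   # spontaneous abortion
]
entities = [
    # antenatal booking at 10 weeks' gestation
    EntityRecord("w1", date(2010, 3, 12), 60, ("10", "", "", "", "", "", "", "")),
    # stages of labour on the delivery day
    EntityRecord("w1", date(2010, 10, 8), 78, ("",) * 8),
]
register = build_register(events, entities, [], [], example_codelist())
print(register[["episode_id", "start_date", "end_date", "start_source",
                "outcome", "gestation_days", "trimester2_start"]].to_string(index=False))
```

prints

```
episode_id start_date   end_date start_source     outcome  gestation_days trimester2_start
      w1:1 2010-01-01 2010-10-08          lmp  live_birth             280       2010-04-02
      w1:2 2012-01-09 2012-04-02      imputed miscarriage              84
```

The first pregnancy is dated from its LMP record (the booking record at
10 weeks agrees) and ends on the delivery-detail entity date; trimester
2 begins at gestational day 91. The second has an outcome code but no
dating evidence, so its start is imputed 84 days (the loss default)
before the end, and `start_source` says so.

The same pipeline is scriptable from the shell via the `pregreg` console
command (`simulate`, `build-register`, `validate`, `rates`), driven by a
YAML configuration naming paths, coverage dates and any algorithm
parameter overrides.

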