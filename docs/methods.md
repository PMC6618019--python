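# Methods

`pregreg` re-implements, as a reusable and fully testable pipeline, an
algorithm for delineating pregnancy episodes from coded UK primary-care
records (CPRD GOLD-style data): clinical events carrying read-style code
tokens, structured "entity" records carrying typed data fields, patient
and practice registration metadata, and mother–baby candidate links. It
also implements the two validation exercises such a register is judged
by — outcome-level agreement with a hospital-style reference source, and
population-style outcome rates — plus a synthetic-data generator so the
whole pipeline runs and is tested without access to any confidential
data.

## The vocabulary layer

Clinical codes are opaque tokens tagged with one or more of 21
non-mutually-exclusive pregnancy categories (antenatal, late pregnancy,
third trimester, delivery, stillbirth, ectopic, termination (TOP),
miscarriage, probable TOP, molar, unspecified loss, blighted ovum,
postnatal, other postnatal, preterm, postterm, multiple, LMP, EDD, EDC,
pregnancy-related of uncertain timing). Code matching is exact-string:
production code lists arrive pre-expanded, so no hierarchy or wildcard
logic is applied. The package ships a 22-code miniature list (one
example code per category plus one deliberately dual-category
delivery+preterm code) used by tests and the simulator; full lists are
input data, not embedded constants.

Two categories — *other postnatal* and *pregnancy-related (timing
uncertain)* — are never date-determining: they can attach to an existing
episode but never seed one and never contribute candidate dates, because
it is unknowable which phase of pregnancy they refer to.

Entity codes map to a fixed rule table. Start-of-pregnancy rules:
antenatal booking/consultation (60, 61) and alpha-fetoprotein (154)
subtract the recorded gestation weeks from the event date (max 42
weeks); gestation-at-outcome records (119, 120) subtract the recorded
weeks from the episode's *end* date; pregnancy-dates (129) and
ultrasound-scan (284) records subtract 280 days from the recorded
expected delivery date, the scan record falling back to
event-minus-weeks when no EDD is present. End-of-pregnancy rules:
six-week checks (35, 80, 84) subtract 42 days; the CHS examination (63)
uses the event date at stage "birth" and event − 42 d at stage "6 wk"
and is ignored at any other stage; postnatal examination/visit (69, 150)
subtract the recorded offset capped at 56 days (bare values ≤ 8 are read
as weeks, larger ones as days; a missing offset defaults to 42 days, the
six-week-check norm); delivery-detail records (78, 93, 112, 115, 119,
120, 126, 128, 144, 145) use the event date; perinatal problems (100)
subtract 7 days; pregnancy outcome (114) uses the discharge date in
data 1 minus 2 days, and is the one entity record that can describe an
early loss rather than a delivery (the outcome read from data 2,
defaulting to delivery).

## Episode delineation

Per patient, the stages run in a fixed order:

1. **Tag** every clinical event whose code is in the dictionary and
   every entity record with a known entity code.
2. **Cluster outcomes.** Each outcome record contributes a provisional
   end date via its rule. Delivery evidence (delivery, stillbirth, late
   pregnancy, third trimester, postnatal, preterm, postterm categories;
   delivery-type entity records) and loss evidence (ectopic, TOP,
   miscarriage, probable TOP, molar, unspecified loss, blighted ovum;
   loss-type entity-114 records) stream separately and are never merged:
   an apparent loss inside a delivery surfaces later as a *conflict*,
   never as a choice between outcomes. Within a stream, provisional
   dates sorted ascending chain into one cluster while consecutive gaps
   stay within the merge window — 56 days for deliveries (a true
   inter-delivery interval cannot be shorter, and postnatal codes span
   at most 8 weeks), 28 days for losses (loss management rarely spans
   longer, and a shorter window preserves distinct consecutive losses).
   Chain clustering makes the partition unique, which is what the
   brute-force partition-enumeration oracle in the tests verifies.
3. **End dates.** Within a cluster, entity delivery-detail records
   (which carry the delivery date directly) outrank dated outcome
   clinical codes, which outrank back-dated postnatal/CHS/discharge
   approximations; ties break to the earliest candidate. Clinical codes
   that only imply a delivery are back-dated analogously to the entity
   rules: postnatal codes by 42 days (midpoint of their ≤ 8-week
   window); late-pregnancy and third-trimester codes use their event
   date.
4. **Start dates.** Dating evidence is attributed to the episode whose
   end is nearest among those whose window — (end − 302 d, end], one
   term plus 22 days' slack — contains the record
   (gestation-at-birth records must instead lie within 56 days after
   the end). The hierarchy is EDD > EDC > LMP > antenatal gestational
   age > gestational age at birth; the first level holding a valid
   candidate (start strictly before end) wins; within a level the most
   recently recorded candidate is used, except that scan-derived EDD
   evidence outranks non-scan EDD regardless of recency. An LMP or EDC
   record's event date is taken as the LMP/conception date itself.
   Clinical EDD codes carry no machine-readable delivery date in this
   schema, so the EDD level is fed by entity records only; clinical
   codes that do encode gestational age can be supplied through an
   optional code→weeks map. With no usable evidence, the start is
   imputed as end minus a type-specific default: 280 days for
   deliveries, 84 for early losses, 56 for ectopic pregnancies (which
   end earlier clinically); all configurable.
5. **Attach antenatal records.** Remaining antenatal/dating-type records
   falling inside exactly one episode's interval attach to it; inside
   overlapping episodes they attach to the episode ending soonest.
6. **Outcome-unknown episodes.** Still-unattached records (excluding the
   two never-dating categories) chain into episodes while consecutive
   gaps stay within 280 days — one pregnancy cannot span more than a
   term. A single antenatal code suffices. The start uses the same
   hierarchy; failing that it is imputed as the earliest record minus
   53 days, the typical gestation at a first antenatal contact. These
   episodes have no end date.
7. **Classify and flag.** Delivery clusters: stillbirth evidence alone
   (even with generic delivery codes) → stillbirth; explicit live-birth
   evidence (an optional live-birth-specific code set, since the 21
   categories cannot distinguish "live birth" from generic "delivery"
   codes) together with stillbirth evidence → live birth and stillbirth;
   otherwise delivery evidence → live birth, then third-trimester-only →
   delivery by third-trimester code, then late-pregnancy/postnatal-only
   → delivery by late-pregnancy code. Loss clusters take the most
   specific diagnosis: ectopic > molar > blighted ovum > TOP >
   miscarriage > probable TOP > unspecified loss. Trimester 2 starts at
   gestational day 91 (13 completed weeks) and trimester 3 at day 182
   (week 27), dropped when at or past the end. Preterm/postterm/multiple
   flags are purely code-based (the gestation-under-259-days widening is
   a rate-estimator choice, not stored in the flag). Episodes whose
   intervals intersect are both conflict-flagged and left untouched. An
   outcome-unknown episode is *potentially ongoing* when its earliest
   record is less than 38 weeks (266 days) before the censoring date
   (earliest of leaving the practice, death, last data collection).
8. **Infant linkage.** Each candidate infant links to at most one
   live-birth-capable episode, the one minimising the gap between the
   delivery date and the infant's representative birth date, provided
   the gap is ≤ 60 days. A month of birth resolves to the 15th, which
   minimises the worst-case error of the 60-day rule.

All arithmetic is on whole days. Because the patient metadata supplies a
year of birth only, the k-th birthday is represented as January 1 of
(birth year + k) — a deterministic, conservative convention.

## Follow-up windows and validation

Follow-up starts at the latest of the age-floor birthday, registration
start (deferred one year in the external-validation flavour, to avoid
ascertaining historical pregnancies), the practice up-to-standard date
and coverage start; it ends at the earliest of the age-ceiling birthday,
registration end, death, last collection and coverage end. The internal
flavour uses ages 11–49; the external flavour 15–44. Windows are closed
intervals; an empty window contributes no person-time.

Outcome matching is per patient and per outcome group (the reference
source cannot reliably subtype early losses, so its outcome group is
binary). Pairs match greedily in ascending absolute date difference,
strictly below 12 weeks (84 days), ties broken by earlier reference then
earlier register date; matching is one-to-one. Potential PPV is the
share of register outcomes with a reference match ("potential" because
some true outcomes — home births, private care — cannot appear in the
reference); sensitivity is the share of reference outcomes captured.
Greedy matching can in principle miss the optimal assignment when two
distinct outcomes of one woman fall closer than twice the match window
with large date errors; the oracle test therefore covers the regime real
consecutive pregnancies occupy (spacing ≥ 168 days), where greedy is
provably optimal. Sensitivity-analysis variants drop register outcomes
in the first 183 days of follow-up, reference outcomes in the last 183
days, or register outcomes within 365 days of registration ("6 months"
and "1 year" operationalised as fixed day counts).

Rates: live births and terminations per 1000 women-years of eligible
external-flavour follow-up intersected with the calendar period (days /
365.25); miscarriages per 100 pregnancies with a known outcome;
prematurity per 100 births (live births and stillbirths), primary
definition flag-based, broad definition adding deliveries with estimated
gestation < 259 days and a non-imputed start. Broad termination adds
probable TOP and unspecified loss; broad miscarriage adds unspecified
loss. Confidence intervals are exact (Poisson for counts, Clopper–
Pearson for proportions) below 100 events and normal approximations
above — a documented package choice.

## The synthetic-data generator

`simulate_cohort` draws women (birth years 1966–1998, coverage
2005–2015, registration uniform within coverage, 10% transferring out,
rare deaths) and places pregnancy onsets as a per-woman Poisson process
(default 0.12/year) over her fertile (ages 16–44), simulated time —
which begins up to 8 years before registration, producing historical
pregnancies. Outcomes follow a realistic mix (live birth dominant at
62.5%, stillbirth 0.3%, the loss classes together ≈ 23%, third-
trimester/late-pregnancy-coded deliveries ≈ 3.4%); delivery gestations
are Normal(280, 9) truncated to [154, 300] days, losses Uniform(35, 140)
days; preterm means delivery gestation < 259 days and postterm ≥ 294;
1.5% of live births are twins; recovery gaps of 28 days after a loss and
150 after a delivery are enforced.

`emit_records` then produces the coded tables under a `RecordingModel`:
emission probabilities per record type (LMP code, entity-60 booking at
start + 70 d with 10 weeks recorded, entity-129 carrying the true EDD,
weekly antenatal visit codes, outcome codes, entity delivery-detail/
loss-outcome records, postnatal checks at end + 42 d, hospital reference
episodes, mother–baby candidates), a Poisson recording delay on outcome
codes, Gaussian date jitter, and retrospective coding: a pre-
registration pregnancy is, with some probability, coded after
registration *with the recording date*, reproducing the
historical-recording artefact that motivates the first-year-of-
registration exclusion. Defaults model moderately complete recording
(e.g. outcome codes 95%, EDD 60%, LMP 25%, hospital capture 95%);
`RecordingModel.full()` is the information-complete, noise-free setting
under which the register builder provably recovers every observable
truth pregnancy exactly — the calibration the end-to-end tests and the
acceptance script rely on.

What the generator does **not** emulate: demographically realistic
fertility (age-specific rates, seasonality), practice-level clustering,
free-text recovery, code-list breadth (it uses the 22-code fixture
list), miscoding (wrong outcome class), or reference-source date error.
Passing tests therefore demonstrate the algorithm's correctness given
its rules and the recording model's imperfection modes — not the
clinical completeness of any particular production code list.

## Numerical and design choices

- Chain (single-linkage) clustering with per-stream windows makes the
  outcome partition unique and order-independent; the register is
  byte-identical under input shuffling.
- Ties everywhere break on explicit deterministic keys (dates, then
  source, then code), never on input order.
- Unparseable dates in input rows are dropped with a logged count;
  unknown codes/entities are silently not pregnancy-related; unknown
  category labels or missing columns are hard errors.
- Problem sizes in the test suite and acceptance script (cohorts of
  500–5000 women) were chosen so binomial/Poisson standard errors are
  small enough for ±3 s.e. assertions to discriminate while every run
  stays interactive.

## Known limitations

- Conflicting (overlapping) episodes are flagged, never resolved, by
  design.
- The 42-week cap applies to gestation-week arithmetic, not to LMP- or
  EDC-derived starts; with the 302-day attribution window this permits
  gestations up to 301 days from an extreme LMP record.
- Clinical EDD codes cannot date a pregnancy without an accompanying
  entity record; in data dialects where the EDD value is recoverable it
  should be mapped onto entity 129/284 records upstream.
- Greedy matching is not globally optimal for pathological loss
  spacings (distinct losses < 168 days apart with large date errors);
  see above.
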