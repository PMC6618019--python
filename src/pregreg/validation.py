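"""Register validation: two-source outcome matching and population rates.

Internal validation compares register outcomes against a reference
(hospital-style) outcome source: per patient and per outcome group
(deliveries and early losses are analysed separately), outcome dates are
matched one-to-one when less than 12 weeks apart, giving a potential PPV
(not all true outcomes reach hospital), a sensitivity, and date/gestation
agreement summaries, with sensitivity-analysis variants that drop episodes
near the follow-up boundaries or in the first year of registration.

External validation estimates population-style rates (live birth and
termination per 1000 women-years, miscarriage per 100 known-outcome
pregnancies, prematurity per 100 births) with 95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ehr_io import FollowUpWindow, clip_window
from .episodes import DELIVERY_OUTCOMES

DAY = timedelta(days=1)
DAYS_PER_YEAR = 365.25

MATCH_WINDOW_DAYS = 84          # strict: |difference| < 12 weeks
HALF_YEAR_DAYS = 183
ONE_YEAR_DAYS = 365

VARIANTS = ("primary", "drop_first_6m", "drop_last_6m", "drop_first_year")

BIRTH_OUTCOMES = frozenset({"live_birth", "stillbirth", "live_and_stillbirth"})
LIVE_BIRTH_OUTCOMES = frozenset({"live_birth", "live_and_stillbirth"})


@dataclass(frozen=True)
class ReferenceEpisode:
    """One outcome in the reference source.  The reference cannot reliably
    subtype early losses, so the outcome group is binary."""

    patient_id: str
    outcome_date: date
    outcome_group: str              # "delivery" | "loss"
    gestation_weeks: int | None = None


@dataclass(frozen=True)
class RegisterOutcome:
    """A register episode reduced to what matching needs."""

    patient_id: str
    episode_id: str
    outcome_date: date              # the episode's end date
    outcome_group: str
    gestation_weeks: int | None = None


@dataclass(frozen=True)
class MatchResult:
    patient_id: str
    outcome_group: str
    register: RegisterOutcome | None = None
    reference: ReferenceEpisode | None = None

    @property
    def matched(self) -> bool:
        return self.register is not None and self.reference is not None

    @property
    def date_diff_days(self) -> int | None:
        if not self.matched:
            return None
        return (self.register.outcome_date - self.reference.outcome_date).days

    @property
    def gestation_diff_weeks(self) -> int | None:
        if (not self.matched or self.register.gestation_weeks is None
                or self.reference.gestation_weeks is None):
            return None
        return self.register.gestation_weeks - self.reference.gestation_weeks


@dataclass
class ValidationReport:
    outcome_group: str
    analysis_variant: str
    n_register: int
    n_reference: int
    n_matched: int
    ppv: float | None
    sensitivity: float | None
    date_diff_median: float | None = None
    date_diff_iqr: tuple[float, float] | None = None
    share_within_2d: float | None = None
    share_same_day: float | None = None
    gestation_diff_median: float | None = None
    gestation_diff_iqr: tuple[float, float] | None = None
    gestation_diff_mean: float | None = None


def read_reference(path: str | Path) -> list[ReferenceEpisode]:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"patient_id", "outcome_date", "outcome_group"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = pd.to_datetime(row.outcome_date, errors="coerce")
        if pd.isna(d) or row.outcome_group not in {"delivery", "loss"}:
            continue
        gw = None
        if hasattr(row, "gestation_weeks") and str(row.gestation_weeks).strip():
            try:
                gw = int(float(row.gestation_weeks))
            except ValueError:
                gw = None
        out.append(ReferenceEpisode(str(row.patient_id), d.date(),
                                    row.outcome_group, gw))
    out.sort(key=lambda r: (r.patient_id, r.outcome_date, r.outcome_group))
    return out


def register_outcomes(register: pd.DataFrame) -> list[RegisterOutcome]:
    """Project register rows with a known outcome onto match inputs."""
    out: list[RegisterOutcome] = []
    for row in register.itertuples(index=False):
        if row.outcome == "outcome_unknown" or not row.end_date:
            continue
        group = "delivery" if row.outcome in DELIVERY_OUTCOMES else "loss"
        gw = None
        if row.gestation_days not in ("", None) and not (
                isinstance(row.gestation_days, float) and math.isnan(row.gestation_days)):
            gw = int(row.gestation_days) // 7
        out.append(RegisterOutcome(
            patient_id=str(row.patient_id),
            episode_id=str(row.episode_id),
            outcome_date=date.fromisoformat(str(row.end_date)),
            outcome_group=group,
            gestation_weeks=gw,
        ))
    out.sort(key=lambda r: (r.patient_id, r.outcome_date, r.episode_id))
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def match(
    register: Sequence[RegisterOutcome],
    reference: Sequence[ReferenceEpisode],
    window_days: int = MATCH_WINDOW_DAYS,
) -> list[MatchResult]:
    """One-to-one matching of register vs reference outcomes.

    Within each (patient, outcome group), candidate pairs are taken
    greedily in ascending absolute date difference (strictly below the
    12-week window), ties broken by the earlier reference date and then
    the earlier register date.  Unmatched outcomes on either side appear
    as unmatched results.
    """
    results: list[MatchResult] = []
    keys = sorted(
        {(r.patient_id, r.outcome_group) for r in register}
        | {(r.patient_id, r.outcome_group) for r in reference}
    )
    reg_by_key: dict[tuple[str, str], list[RegisterOutcome]] = {}
    for r in register:
        reg_by_key.setdefault((r.patient_id, r.outcome_group), []).append(r)
    ref_by_key: dict[tuple[str, str], list[ReferenceEpisode]] = {}
    for r in reference:
        ref_by_key.setdefault((r.patient_id, r.outcome_group), []).append(r)

    for key in keys:
        regs = reg_by_key.get(key, [])
        refs = ref_by_key.get(key, [])
        pairs = []
        for i, rg in enumerate(regs):
            for j, rf in enumerate(refs):
                diff = abs((rg.outcome_date - rf.outcome_date).days)
                if diff < window_days:
                    pairs.append((diff, rf.outcome_date, rg.outcome_date, i, j))
        pairs.sort()
        used_reg: set[int] = set()
        used_ref: set[int] = set()
        for diff, _, _, i, j in pairs:
            if i in used_reg or j in used_ref:
                continue
            used_reg.add(i)
            used_ref.add(j)
            results.append(MatchResult(key[0], key[1], regs[i], refs[j]))
        for i, rg in enumerate(regs):
            if i not in used_reg:
                results.append(MatchResult(key[0], key[1], register=rg))
        for j, rf in enumerate(refs):
            if j not in used_ref:
                results.append(MatchResult(key[0], key[1], reference=rf))
    return results


def ppv(results: Iterable[MatchResult]) -> float | None:
    """Share of register outcomes confirmed in the reference source."""
    n_reg = sum(1 for r in results if r.register is not None)
    n_matched = sum(1 for r in results if r.matched)
    return None if n_reg == 0 else n_matched / n_reg


def sensitivity(results: Iterable[MatchResult]) -> float | None:
    """Share of reference outcomes captured by the register."""
    results = list(results)
    n_ref = sum(1 for r in results if r.reference is not None)
    n_matched = sum(1 for r in results if r.matched)
    return None if n_ref == 0 else n_matched / n_ref


def date_agreement(results: Iterable[MatchResult]) -> dict:
    """Summaries of signed date differences over matched pairs."""
    diffs = np.array([r.date_diff_days for r in results if r.matched], dtype=float)
    if diffs.size == 0:
        return {"median": None, "iqr": None, "share_within_2d": None,
                "share_same_day": None, "n": 0}
    q1, med, q3 = np.percentile(diffs, [25, 50, 75])
    return {
        "median": float(med),
        "iqr": (float(q1), float(q3)),
        "share_within_2d": float(np.mean(np.abs(diffs) <= 2)),
        "share_same_day": float(np.mean(diffs == 0)),
        "n": int(diffs.size),
    }


def gestation_agreement(results: Iterable[MatchResult]) -> dict:
    diffs = np.array(
        [r.gestation_diff_weeks for r in results
         if r.matched and r.gestation_diff_weeks is not None],
        dtype=float,
    )
    if diffs.size == 0:
        return {"median": None, "iqr": None, "mean": None, "n": 0}
    q1, med, q3 = np.percentile(diffs, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q1), float(q3)),
            "mean": float(np.mean(diffs)), "n": int(diffs.size)}


# ---------------------------------------------------------------------------
# Analysis variants and window restriction
# ---------------------------------------------------------------------------


def restrict_to_windows(
    register: Sequence[RegisterOutcome],
    reference: Sequence[ReferenceEpisode],
    windows: Mapping[str, FollowUpWindow],
) -> tuple[list[RegisterOutcome], list[ReferenceEpisode]]:
    """Keep only outcomes dated inside the owning patient's follow-up."""
    reg = [r for r in register
           if r.patient_id in windows and windows[r.patient_id].contains(r.outcome_date)]
    ref = [r for r in reference
           if r.patient_id in windows and windows[r.patient_id].contains(r.outcome_date)]
    return reg, ref


def apply_variant(
    register: Sequence[RegisterOutcome],
    reference: Sequence[ReferenceEpisode],
    windows: Mapping[str, FollowUpWindow],
    variant: str,
    registration_starts: Mapping[str, date] | None = None,
) -> tuple[list[RegisterOutcome], list[ReferenceEpisode]]:
    """Sensitivity-analysis filters around the follow-up boundaries.

    drop_first_6m removes register outcomes in the first 183 days of
    follow-up (delayed GP recording of historical hospital events);
    drop_last_6m removes reference outcomes in the last 183 days
    (outcomes the GP has not yet recorded); drop_first_year removes
    register outcomes within 365 days of joining the practice
    (retrospective recording of past pregnancies).
    """
    if variant == "primary":
        return list(register), list(reference)
    if variant == "drop_first_6m":
        reg = [r for r in register
               if r.patient_id not in windows
               or r.outcome_date >= windows[r.patient_id].start + HALF_YEAR_DAYS * DAY]
        return reg, list(reference)
    if variant == "drop_last_6m":
        ref = [r for r in reference
               if r.patient_id not in windows
               or r.outcome_date <= windows[r.patient_id].end - HALF_YEAR_DAYS * DAY]
        return list(register), ref
    if variant == "drop_first_year":
        if registration_starts is None:
            raise ValueError("drop_first_year requires registration start dates")
        reg = [r for r in register
               if r.patient_id not in registration_starts
               or r.outcome_date >= registration_starts[r.patient_id] + ONE_YEAR_DAYS * DAY]
        return reg, list(reference)
    raise ValueError(f"unknown analysis variant {variant!r}")


def validation_report(
    register: Sequence[RegisterOutcome],
    reference: Sequence[ReferenceEpisode],
    windows: Mapping[str, FollowUpWindow],
    variant: str = "primary",
    registration_starts: Mapping[str, date] | None = None,
    window_days: int = MATCH_WINDOW_DAYS,
) -> dict[str, ValidationReport]:
    """Full internal-validation summary, one report per outcome group."""
    reg, ref = restrict_to_windows(register, reference, windows)
    reg, ref = apply_variant(reg, ref, windows, variant, registration_starts)
    reports = {}
    for group in ("delivery", "loss"):
        res = match([r for r in reg if r.outcome_group == group],
                    [r for r in ref if r.outcome_group == group],
                    window_days=window_days)
        agree = date_agreement(res)
        gest = gestation_agreement(res)
        reports[group] = ValidationReport(
            outcome_group=group,
            analysis_variant=variant,
            n_register=sum(1 for r in res if r.register is not None),
            n_reference=sum(1 for r in res if r.reference is not None),
            n_matched=sum(1 for r in res if r.matched),
            ppv=ppv(res),
            sensitivity=sensitivity(res),
            date_diff_median=agree["median"],
            date_diff_iqr=agree["iqr"],
            share_within_2d=agree["share_within_2d"],
            share_same_day=agree["share_same_day"],
            gestation_diff_median=gest["median"],
            gestation_diff_iqr=gest["iqr"],
            gestation_diff_mean=gest["mean"],
        )
    return reports


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

RATE_KINDS = (
    "live_birth", "termination", "termination_broad",
    "miscarriage", "miscarriage_broad",
    "prematurity", "prematurity_broad",
)


@dataclass(frozen=True)
class RateResult:
    kind: str
    value: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: float
    scale: str                   # "per_1000_women_years" | "per_100"


def _poisson_ci(n: int) -> tuple[float, float]:
    """95% CI for a Poisson count: exact below 100 events, else normal."""
    if n < 100:
        lo = 0.0 if n == 0 else stats.chi2.ppf(0.025, 2 * n) / 2
        hi = stats.chi2.ppf(0.975, 2 * n + 2) / 2
        return lo, hi
    half = 1.959963984540054 * math.sqrt(n)
    return n - half, n + half


def _binomial_ci(k: int, n: int) -> tuple[float, float]:
    """95% CI for a proportion: Clopper-Pearson below 100 events, else normal."""
    if n == 0:
        return 0.0, 0.0
    p = k / n
    if k < 100:
        lo = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
        return lo, hi
    half = 1.959963984540054 * math.sqrt(p * (1 - p) / n)
    return p - half, p + half


def _register_frame(register: pd.DataFrame) -> pd.DataFrame:
    df = register.copy()
    df["end"] = pd.to_datetime(df["end_date"], errors="coerce")
    df["gest"] = pd.to_numeric(df["gestation_days"], errors="coerce")
    return df


def person_years(
    windows: Mapping[str, FollowUpWindow], period: tuple[date, date]
) -> float:
    """Person-time in women-years over the calendar period."""
    days = 0
    for w in windows.values():
        days += clip_window(w, period[0], period[1]).days
    return days / DAYS_PER_YEAR


def rates(
    register: pd.DataFrame,
    windows: Mapping[str, FollowUpWindow],
    period: tuple[date, date],
    which: str,
) -> RateResult:
    """Population-style outcome rates over a calendar period.

    Live birth and termination counts per 1000 women-years of eligible
    follow-up; miscarriage per 100 pregnancies with a known outcome;
    prematurity per 100 births (live births and stillbirths).  The broad
    variants widen the numerator: termination_broad adds probable
    terminations and unspecified losses, miscarriage_broad adds
    unspecified losses, prematurity_broad adds deliveries with estimated
    gestation under 259 days and a non-imputed start.
    """
    if which not in RATE_KINDS:
        raise ValueError(f"unknown rate kind {which!r}")
    df = _register_frame(register)
    lo, hi = period
    in_period = df["end"].notna() & (df["end"] >= pd.Timestamp(lo)) & (
        df["end"] <= pd.Timestamp(hi))
    in_window = df.apply(
        lambda row: row["patient_id"] in windows
        and pd.notna(row["end"])
        and windows[row["patient_id"]].contains(row["end"].date()),
        axis=1,
    ) if len(df) else pd.Series([], dtype=bool)
    eligible = df[in_period & in_window]

    if which in ("live_birth", "termination", "termination_broad"):
        if which == "live_birth":
            num = eligible["outcome"].isin(LIVE_BIRTH_OUTCOMES).sum()
        elif which == "termination":
            num = (eligible["outcome"] == "top").sum()
        else:
            num = eligible["outcome"].isin(
                {"top", "probable_top", "unspecified_loss"}).sum()
        wy = person_years(windows, period)
        if wy <= 0:
            return RateResult(which, None, None, None, int(num), 0.0,
                              "per_1000_women_years")
        n_lo, n_hi = _poisson_ci(int(num))
        per = 1000.0 / wy
        return RateResult(which, float(num) * per, n_lo * per, n_hi * per,
                          int(num), wy, "per_1000_women_years")

    if which in ("miscarriage", "miscarriage_broad"):
        known = eligible[eligible["outcome"] != "outcome_unknown"]
        denom = len(known)
        cats = {"miscarriage"} if which == "miscarriage" else {
            "miscarriage", "unspecified_loss"}
        num = int(known["outcome"].isin(cats).sum())
    else:  # prematurity
        births = eligible[eligible["outcome"].isin(BIRTH_OUTCOMES)]
        denom = len(births)
        preterm = births["preterm_flag"].astype(bool)
        if which == "prematurity_broad":
            preterm = preterm | (
                (births["gest"] < 259) & (births["start_source"] != "imputed"))
        num = int(preterm.sum())

    if denom == 0:
        return RateResult(which, None, None, None, num, 0.0, "per_100")
    p_lo, p_hi = _binomial_ci(num, denom)
    return RateResult(which, 100.0 * num / denom, 100.0 * p_lo, 100.0 * p_hi,
                      num, float(denom), "per_100")
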