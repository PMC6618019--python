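"""Categorised pregnancy code lists: the algorithm's vocabulary layer.

Clinical codes are opaque string tokens tagged with one or more of 21
pregnancy categories (categories are not mutually exclusive).  Structured
"entity" records are tagged with integer entity codes; a fixed rule table
maps each known entity code to the arithmetic used to derive a pregnancy
start or end date from its event date and data fields.

Code matching is exact-string on the token; lists are expected to be
pre-expanded (no hierarchy/prefix search here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: The 21 pregnancy code categories.
CATEGORIES: frozenset[str] = frozenset({
    "antenatal",
    "late_pregnancy",      # code implies <=3 wk before delivery
    "third_trimester",
    "delivery",
    "stillbirth",
    "ectopic",
    "top",
    "miscarriage",
    "probable_top",
    "molar",
    "unspecified_loss",
    "blighted_ovum",
    "postnatal",           # code implies <=8 wk after delivery
    "other_postnatal",
    "preterm",
    "postterm",
    "multiple",
    "lmp",
    "edd",
    "edc",
    "pregnancy_related_uncertain",
})

#: Categories whose presence means a delivery occurred.
DELIVERY_EVIDENCE: frozenset[str] = frozenset({
    "delivery", "stillbirth", "late_pregnancy", "third_trimester",
    "postnatal", "preterm", "postterm",
})

#: Categories whose presence means an early pregnancy loss occurred.
LOSS_EVIDENCE: frozenset[str] = frozenset({
    "ectopic", "top", "miscarriage", "probable_top", "molar",
    "unspecified_loss", "blighted_ovum",
})

#: Categories that never determine pregnancy start/end dates and never
#: seed episodes on their own (timing too uncertain).
NON_DATING_CATEGORIES: frozenset[str] = frozenset({
    "other_postnatal", "pregnancy_related_uncertain",
})

# ---------------------------------------------------------------------------
# Entity-code rule table: how each known entity code converts to a pregnancy
# start or end date.  Rule identifiers are interpreted by the episode builder.
# ---------------------------------------------------------------------------

#: entity code -> rule for deriving a pregnancy *start* date.
START_ENTITY_RULES: Mapping[int, str] = {
    60: "event_minus_weeks_d1",    # ante-natal booking, gestation weeks in data1
    61: "event_minus_weeks_d1",    # ante-natal consultation
    154: "event_minus_weeks_d8",   # alpha fetoprotein, gestation weeks in data8
    119: "end_minus_weeks_d1",     # gestation at maternity outcome (weeks in data1)
    120: "end_minus_weeks_d1",     # gestational age of baby
    129: "edd_d2_minus_280",       # pregnancy dates: expected delivery date in data2
    284: "edd_d8_or_weeks_d2",     # maternity ultrasound scan: EDD in data8,
                                   # else event minus weeks in data2
}

#: entity code -> rule for deriving a pregnancy *end* date.
END_ENTITY_RULES: Mapping[int, str] = {
    35: "event_minus_42",          # hearing test at 6 wk
    80: "event_minus_42",          # muscle tone at 6 wk (CHS)
    84: "event_minus_42",          # vision at 6 wk (CHS)
    63: "chs_stage",               # CHS examination: birth -> event; 6wk -> event-42
    69: "event_minus_offset_d2",   # postnatal examination, offset in data2 (max 56 d)
    150: "event_minus_offset_d2",  # postnatal visit
    78: "event_date",              # stages of labour
    93: "event_date",              # delivery details
    112: "event_date",             # CHS Apgar at 1 min
    115: "event_date",             # delivery details (CHS)
    119: "event_date",             # gestation - maternity outcome
    120: "event_date",             # gestational age of baby
    126: "event_date",             # maternity infant details
    128: "event_date",             # perineum
    144: "event_date",             # maternity outcome placenta
    145: "event_date",             # CHS Apgar at 5 min
    100: "event_minus_7",          # perinatal problems
    114: "discharge_d1_minus_2",   # pregnancy outcome: discharge date in data1
}

KNOWN_ENTITY_CODES: frozenset[int] = frozenset(START_ENTITY_RULES) | frozenset(
    END_ENTITY_RULES
)

#: End-rule identifiers that read the delivery event directly (highest
#: precedence when resolving a cluster's end date).
DIRECT_END_RULES: frozenset[str] = frozenset({"event_date"})


@dataclass(frozen=True)
class CodeEntry:
    """One clinical code with its description and category tags."""

    code: str
    description: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"code {self.code!r} has no categories")
        unknown = self.categories - CATEGORIES
        if unknown:
            raise ValueError(f"code {self.code!r}: unknown categories {sorted(unknown)}")


@dataclass
class CodeDictionary:
    """Lookup table from clinical code token to its pregnancy categories.

    Unknown codes are simply "not pregnancy-related": lookups return an
    empty set and never raise.
    """

    entries: dict[str, CodeEntry] = field(default_factory=dict)
    entity_rules: Mapping[int, str] = field(default_factory=lambda: dict(END_ENTITY_RULES))

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def categories_of(self, code: str) -> frozenset[str]:
        entry = self.entries.get(code)
        return entry.categories if entry is not None else frozenset()

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in sorted(CATEGORIES)}
        for entry in self.entries.values():
            for cat in entry.categories:
                counts[cat] += 1
        return counts

    def codes_in(self, category: str) -> set[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return {c for c, e in self.entries.items() if category in e.categories}

    def to_frame(self) -> pd.DataFrame:
        """Serialise back to the one-row-per-(code, category) table layout."""
        rows = [
            {"code": e.code, "description": e.description, "category": cat}
            for e in self.entries.values()
            for cat in sorted(e.categories)
        ]
        return (
            pd.DataFrame(rows, columns=["code", "description", "category"])
            .sort_values(["code", "category"], kind="stable")
            .reset_index(drop=True)
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_codelist(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> CodeDictionary:
    """Load a categorised code list from delimited text.

    The file holds one row per (code, category) pair with columns
    ``code, description, category``; ``dialect`` maps these canonical names
    to the file's actual column names.  Duplicate (code, category) rows are
    deduplicated; multiple rows for one code union their categories.

    Raises
    ------
    ValueError
        If the file is empty, a mandatory column is missing, or a row
        carries an unrecognised category label.
    """
    dialect = dialect or {}
    colmap = {dialect.get(k, k): k for k in ("code", "description", "category")}
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).rename(columns=colmap)
    missing = {"code", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"code list {path}: missing columns {sorted(missing)}")
    if "description" not in df.columns:
        df["description"] = ""
    if df.empty:
        raise ValueError(f"code list {path} contains no rows")

    bad = df.loc[~df["category"].isin(CATEGORIES)]
    if not bad.empty:
        i = bad.index[0]
        raise ValueError(
            f"code list {path} row {i + 2}: unknown category "
            f"{bad['category'].iloc[0]!r} for code {bad['code'].iloc[0]!r}"
        )

    entries: dict[str, CodeEntry] = {}
    for code, grp in df.groupby("code", sort=False):
        desc = grp["description"].dropna().iloc[0] if grp["description"].notna().any() else ""
        entries[str(code)] = CodeEntry(
            code=str(code),
            description=str(desc),
            categories=frozenset(grp["category"]),
        )
    return CodeDictionary(entries=entries)


def example_codelist() -> CodeDictionary:
    """The miniature code list shipped with the package (one example code
    per category, plus one dual-category code), for tests and simulation."""
    with resources.as_file(
        resources.files("pregreg.data").joinpath("pregnancy_codes.csv")
    ) as p:
        return load_codelist(p)


def categories_of(cdict: CodeDictionary, code: str) -> frozenset[str]:
    """Categories of ``code``; empty set when not pregnancy-related."""
    return cdict.categories_of(code)


def outcome_group(categories: Iterable[str]) -> str:
    """Classify a category set as outcome evidence.

    Returns one of ``delivery_evidence``, ``loss_evidence``, ``both`` or
    ``none``.  Delivery records and early-loss records are handled by
    separate episode streams downstream, so a code spanning both groups is
    reported as ``both``.
    """
    cats = frozenset(categories)
    has_del = bool(cats & DELIVERY_EVIDENCE)
    has_loss = bool(cats & LOSS_EVIDENCE)
    if has_del and has_loss:
        return "both"
    if has_del:
        return "delivery_evidence"
    if has_loss:
        return "loss_evidence"
    return "none"
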