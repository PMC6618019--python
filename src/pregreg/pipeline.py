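"""Convenience composition: emitted (or loaded) tables straight through the
register builder, plus truth-vs-register comparison used in calibration
checks."""

from __future__ import annotations

from datetime import date

import pandas as pd

from .codelists import CodeDictionary, example_codelist
from .ehr_io import (
    entities_from_frame,
    events_from_frame,
    links_from_frame,
    patients_from_frame,
)
from .episodes import AlgorithmConfig, build_register
from .simulate import EmittedTables


def register_from_tables(
    tables: EmittedTables,
    cdict: CodeDictionary | None = None,
    cfg: AlgorithmConfig | None = None,
    default_censor: date | None = None,
) -> pd.DataFrame:
    """Build a register directly from in-memory emitted tables."""
    return build_register(
        events_from_frame(tables.events),
        entities_from_frame(tables.entities),
        patients_from_frame(tables.patients),
        links_from_frame(tables.links),
        cdict or example_codelist(),
        cfg=cfg,
        default_censor=default_censor,
    )


def recovery_summary(truth: pd.DataFrame, register: pd.DataFrame,
                     patients: pd.DataFrame) -> dict:
    """Fraction of observed truth pregnancies recovered with exact start,
    end and outcome class.  Only truth pregnancies ending on or after the
    woman's registration start are observable in her coded record."""
    reg_start = {str(r.patient_id): str(r.reg_start)
                 for r in patients.itertuples(index=False)}
    observed = {
        (str(t.patient_id), str(t.true_start), str(t.true_end), str(t.true_outcome))
        for t in truth.itertuples(index=False)
        if str(t.true_end) >= reg_start.get(str(t.patient_id), "9999")
    }
    got = {
        (str(r.patient_id), str(r.start_date), str(r.end_date), str(r.outcome))
        for r in register.itertuples(index=False)
        if r.outcome != "outcome_unknown"
    }
    n_truth = len(observed)
    n_exact = len(observed & got)
    return {
        "n_truth": n_truth,
        "n_exact": n_exact,
        "n_spurious": len(got - observed),
        "recovery": n_exact / n_truth if n_truth else None,
    }
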