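from __future__ import annotations

from datetime import date

import pytest

from pregreg.codelists import example_codelist
from pregreg.ehr_io import ClinicalEvent, EntityRecord
from pregreg.episodes import AlgorithmConfig, tag_records


@pytest.fixture(scope="session")
def cdict():
    return example_codelist()


@pytest.fixture(scope="session")
def cfg():
    return AlgorithmConfig()


@pytest.fixture
def tagger(cdict):
    """Build tagged records for one patient from (date, code) clinical
    events and (date, entity_code, data...) entity tuples."""

    def make(clinical=(), entity=(), pid="p1"):
        events = [ClinicalEvent(pid, d, code) for d, code in clinical]
        ents = []
        for item in entity:
            d, code = item[0], item[1]
            data = list(item[2:]) + [""] * (8 - len(item[2:]))
            ents.append(EntityRecord(pid, d, code, tuple(data)))
        return tag_records(events, ents, cdict=make.cdict)

    make.cdict = cdict
    return make


def d(iso: str) -> date:
    return date.fromisoformat(iso)
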