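from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from injurychain.records import COLUMNS, Provenance, RecordSet

settings.register_profile("default", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("default")

_DEFAULTS = {
    "player_id": "P1",
    "injury_date": "2015-09-01",
    "season_label": "",
    "body_part": "Thigh",
    "side": "left",
    "nature": "muscle",
    "category": "Hamstring Muscle Injury",
    "onset": "sudden",
    "severity_days": 5,
    "contact": "no",
    "context": "match",
    "recurrence_class": "index",
}


def make_recordset(rows: list[dict]) -> RecordSet:
    """RecordSet from partial row dicts, filling unspecified fields."""
    full = [{**_DEFAULTS, **row} for row in rows]
    frame = pd.DataFrame(full, columns=list(COLUMNS))
    frame["injury_date"] = pd.to_datetime(frame["injury_date"])
    return RecordSet(frame, Provenance(rows_read=len(rows), rows_accepted=len(rows)))


@pytest.fixture
def rs_factory():
    return make_recordset
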