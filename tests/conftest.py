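"""Shared fixtures: small hand-built datasets and random dataset factories."""

from __future__ import annotations

import numpy as np
import pytest

from vocalgate.core import (
    GateSpec,
    ParticipantProfile,
    ResponseDataset,
    ResponseRecord,
    StimulusItem,
)

GATES = ("G200", "G400", "G500", "G600", "GFULL")


def make_dataset(
    rows: list[tuple],
    items: dict[str, tuple] | None = None,
    gate_spec: GateSpec | None = None,
) -> ResponseDataset:
    """Build a dataset from (participant, group, item, gate, response[, conf]) rows.

    ``items`` maps item_id -> (event_type, language, emotion, full_ms);
    unknown items default to a 1448 ms anger vocalization.
    """
    ds = ResponseDataset(gate_spec=gate_spec or GateSpec())
    items = items or {}
    for row in rows:
        pid, group, item_id, gate, response = row[:5]
        conf = row[5] if len(row) > 5 else None
        if pid not in ds.participants:
            ds.participants[pid] = ParticipantProfile(participant_id=pid, group=group)
        if item_id not in ds.items:
            ev, lang, emo, full = items.get(item_id, ("vocalization", "none", "anger", 1448.0))
            # speaker_id stays empty: it is not part of the canonical
            # response-table schema, so round-trips preserve it as ""
            ds.items[item_id] = StimulusItem(
                item_id=item_id,
                event_type=ev,
                language=lang,
                emotion=emo,
                speaker_id="",
                full_duration_ms=full,
            )
        ds.records.append(
            ResponseRecord(
                participant_id=pid,
                item_id=item_id,
                gate_label=gate,
                response=response,
                confidence=conf,
            )
        )
    return ds


def random_dataset(rng: np.random.Generator, n_participants: int = 3, n_items: int = 4) -> ResponseDataset:
    """Small random-but-valid dataset for round-trip and invariance checks."""
    labels = ("anger", "happiness", "fear", "sadness", "neutral")
    emotions = ("anger", "fear", "sadness", "happiness_amusement")
    rows = []
    items = {}
    for i in range(n_items):
        emo = emotions[i % len(emotions)]
        items[f"it{i}"] = ("vocalization", "none", emo, float(rng.integers(715, 2376)))
    for p in range(n_participants):
        group = "chinese" if p % 2 == 0 else "arab"
        for i in range(n_items):
            for g in GATES:
                conf = int(rng.integers(1, 8)) if rng.random() > 0.2 else None
                rows.append(
                    (f"p{p}", group, f"it{i}", g, labels[rng.integers(0, 5)], conf)
                )
    return make_dataset(rows, items=items)


@pytest.fixture
def perfect_dataset() -> ResponseDataset:
    """Two participants who always give the target response at every gate."""
    items = {
        "v_ang": ("vocalization", "none", "anger", 1448.0),
        "v_sad": ("vocalization", "none", "sadness", 900.0),
        "p_fear": ("prosody", "mandarin", "fear", 1500.0),
    }
    rows = []
    for pid, group in (("p1", "chinese"), ("p2", "arab")):
        for item_id, (_, _, emo, _) in items.items():
            target = "happiness" if emo.startswith("happiness") else emo
            for g in GATES:
                rows.append((pid, group, item_id, g, target, 7))
    return make_dataset(rows, items=items)
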