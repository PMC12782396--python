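"""Canonical data types, validation, and delimited-text I/O for gating studies.

The pipeline works on long-format trial-response tables from a forced-choice
auditory gating experiment: listeners hear truncated excerpts ("gates") of a
vocal emotion expression in blocks of increasing duration and pick one of five
labels (anger, happiness, fear, sadness, neutral), optionally rating their
confidence on a 7-point scale.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "LANGUAGES",
    "STIMULUS_EMOTIONS",
    "RESPONSE_LABELS",
    "CANONICAL_COLUMNS",
    "SchemaError",
    "ValidationError",
    "DuplicationError",
    "GateSpec",
    "StimulusItem",
    "TrialDefinition",
    "ParticipantProfile",
    "ResponseRecord",
    "ResponseDataset",
    "Violation",
    "target_response",
    "validate_dataset",
    "read_response_table",
    "write_response_table",
]

EVENT_TYPES = frozenset({"vocalization", "prosody"})
LANGUAGES = frozenset({"arabic", "mandarin", "english", "none"})
STIMULUS_EMOTIONS = frozenset(
    {"anger", "fear", "sadness", "happiness", "happiness_amusement", "happiness_pleasure"}
)
#: The five response options on the forced-choice screen. Neutral is a response
#: label only — no neutral stimuli exist.
RESPONSE_LABELS = ("anger", "happiness", "fear", "sadness", "neutral")

#: Happiness sub-categories exist only for vocalizations (laughter vs. pleasure
#: sounds); both map onto the single "happiness" response option.
_VOCAL_ONLY_EMOTIONS = frozenset({"happiness_amusement", "happiness_pleasure"})

CANONICAL_COLUMNS = [
    "participant",
    "group",
    "event_type",
    "language",
    "emotion",
    "item",
    "gate",
    "response",
    "confidence",
    "full_duration_ms",
]


class SchemaError(ValueError):
    """A required column is missing or the header cannot be mapped."""


class ValidationError(ValueError):
    """A row carries an unknown label or violates a field constraint."""


class DuplicationError(ValueError):
    """More than one record for the same participant x item x gate."""


def target_response(emotion: str) -> str:
    """Response label counted as correct for a stimulus emotion.

    Both happiness sub-categories share the single "happiness" response
    option offered on the 5-label screen.
    """
    if emotion not in STIMULUS_EMOTIONS:
        raise ValueError(f"unknown stimulus emotion: {emotion!r}")
    if emotion in _VOCAL_ONLY_EMOTIONS:
        return "happiness"
    return emotion


@dataclass(frozen=True)
class GateSpec:
    """Ordered gate durations plus the ungated full stimulus.

    Defaults follow the common G200/G400/G500/G600/GFull design.
    """

    finite_gates_ms: tuple[int, ...] = (200, 400, 500, 600)
    include_full: bool = True

    def __post_init__(self) -> None:
        gates = tuple(int(g) for g in self.finite_gates_ms)
        object.__setattr__(self, "finite_gates_ms", gates)
        if not gates and not self.include_full:
            raise ValueError("gate spec must define at least one gate")
        if any(g <= 0 for g in gates):
            raise ValueError("gate durations must be positive")
        if any(b <= a for a, b in zip(gates, gates[1:])):
            raise ValueError("finite gates must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        finite = tuple(f"G{g}" for g in self.finite_gates_ms)
        return finite + (("GFULL",) if self.include_full else ())

    def gate_duration(self, label: str, full_duration_ms: float) -> float:
        """Playable duration for a gate label of an item with the given length."""
        if label == "GFULL":
            if not self.include_full:
                raise ValueError("GFULL not part of this gate spec")
            return float(full_duration_ms)
        try:
            ms = int(label.lstrip("G"))
        except ValueError as exc:
            raise ValueError(f"malformed gate label: {label!r}") from exc
        if ms not in self.finite_gates_ms:
            raise ValueError(f"gate label {label!r} not in spec {self.labels}")
        return float(ms)

    def order_key(self, label: str) -> int:
        """Sort key placing gates in ascending-duration presentation order."""
        return self.labels.index(label)


@dataclass(frozen=True)
class StimulusItem:
    """One recorded vocal expression prior to gating."""

    item_id: str
    event_type: str
    language: str
    emotion: str
    speaker_id: str
    full_duration_ms: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type: {self.event_type!r}")
        if self.language not in LANGUAGES:
            raise ValueError(f"unknown language: {self.language!r}")
        if self.emotion not in STIMULUS_EMOTIONS:
            raise ValueError(f"unknown emotion: {self.emotion!r}")
        if self.event_type == "prosody" and self.language == "none":
            raise ValueError(f"prosody item {self.item_id} must carry a language")
        if self.event_type == "prosody" and self.emotion in _VOCAL_ONLY_EMOTIONS:
            raise ValueError(
                f"{self.emotion} is a vocalization-only category (item {self.item_id})"
            )
        if not self.full_duration_ms > 0:
            raise ValueError(f"non-positive duration for item {self.item_id}")


@dataclass(frozen=True)
class TrialDefinition:
    """One gated presentation: an item cut to a gate duration."""

    item_id: str
    gate_label: str
    playable_duration_ms: float


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    group: str
    native_language: str = ""
    l2_proficiency: float | None = None


@dataclass(frozen=True)
class ResponseRecord:
    """One judgment: participant x gated item -> chosen label (+ confidence)."""

    participant_id: str
    item_id: str
    gate_label: str
    response: str
    confidence: int | None = None

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_LABELS:
            raise ValueError(f"unknown response label: {self.response!r}")
        if self.confidence is not None and not 1 <= int(self.confidence) <= 7:
            raise ValueError(f"confidence out of 1-7 range: {self.confidence}")


@dataclass(frozen=True)
class Violation:
    """One invariant breach found by :func:`validate_dataset`."""

    kind: str
    message: str


@dataclass
class ResponseDataset:
    """A full trial-response dataset: participants, items, judgments."""

    participants: dict[str, ParticipantProfile] = field(default_factory=dict)
    items: dict[str, StimulusItem] = field(default_factory=dict)
    records: list[ResponseRecord] = field(default_factory=list)
    gate_spec: GateSpec = field(default_factory=GateSpec)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseDataset):
            return NotImplemented
        key = lambda r: (r.participant_id, r.item_id, r.gate_label)
        return (
            self.participants == other.participants
            and self.items == other.items
            and sorted(self.records, key=key) == sorted(other.records, key=key)
            and self.gate_spec == other.gate_spec
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table joining records with item and participant metadata.

        Rows are sorted by (participant, item, gate order); this is the
        canonical analysis and serialization layout.
        """
        rows = []
        for r in self.records:
            item = self.items.get(r.item_id)
            part = self.participants.get(r.participant_id)
            rows.append(
                {
                    "participant": r.participant_id,
                    "group": part.group if part else "",
                    "event_type": item.event_type if item else "",
                    "language": item.language if item else "",
                    "emotion": item.emotion if item else "",
                    "item": r.item_id,
                    "gate": r.gate_label,
                    "response": r.response,
                    "confidence": r.confidence,
                    "full_duration_ms": item.full_duration_ms if item else float("nan"),
                }
            )
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        if len(df):
            order = {lab: i for i, lab in enumerate(self.gate_spec.labels)}
            df = df.sort_values(
                ["participant", "item", "gate"],
                key=lambda s: s.map(order) if s.name == "gate" else s,
                kind="stable",
            ).reset_index(drop=True)
        df["confidence"] = df["confidence"].astype("Int64")
        return df


def validate_dataset(dataset: ResponseDataset) -> list[Violation]:
    """Check referential and structural invariants; violations are data, not errors."""
    out: list[Violation] = []
    labels = set(dataset.gate_spec.labels)
    max_finite = max(dataset.gate_spec.finite_gates_ms, default=0)

    for item in dataset.items.values():
        if item.full_duration_ms <= max_finite:
            out.append(
                Violation(
                    "item_too_short",
                    f"item {item.item_id} lasts {item.full_duration_ms} ms, not "
                    f"longer than the largest finite gate ({max_finite} ms)",
                )
            )

    seen: set[tuple[str, str, str]] = set()
    for r in dataset.records:
        if r.participant_id not in dataset.participants:
            out.append(
                Violation("unknown_participant", f"record references unknown participant {r.participant_id!r}")
            )
        if r.item_id not in dataset.items:
            out.append(Violation("unknown_item", f"record references unknown item {r.item_id!r}"))
        if r.gate_label not in labels:
            out.append(Violation("unknown_gate", f"record carries unknown gate {r.gate_label!r}"))
        key = (r.participant_id, r.item_id, r.gate_label)
        if key in seen:
            out.append(Violation("duplicate_record", f"duplicate record for {key}"))
        seen.add(key)
    return out


def _coerce_confidence(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
        return None
    if value == "" or (isinstance(value, str) and not value.strip()):
        return None
    return int(float(value))


def read_response_table(
    path: str | Path | _io.TextIOBase,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
    gate_spec: GateSpec | None = None,
) -> ResponseDataset:
    """Read a long-format response table into a validated dataset.

    Parameters
    ----------
    path
        Delimited text file (comma default, tab accepted) with a header row.
    dialect
        Optional column-rename mapping ``{external_name: canonical_name}``
        bridging an external deposit's layout to the canonical schema.
    sep
        Field separator; autodetected between comma and tab when omitted.
    gate_spec
        Gate design; inferred from the gate labels present when omitted.

    Raises
    ------
    SchemaError
        A canonical column is missing after renaming.
    ValidationError
        Unknown gate / response / emotion label, with the offending row index.
    DuplicationError
        Repeated participant x item x gate combination.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    if gate_spec is None:
        finite = sorted(
            {int(g.lstrip("G")) for g in df["gate"].dropna().unique() if g != "GFULL"}
        )
        gate_spec = GateSpec(
            finite_gates_ms=tuple(finite) or (200, 400, 500, 600),
            include_full="GFULL" in set(df["gate"]) or finite == [],
        )

    ds = ResponseDataset(gate_spec=gate_spec)
    valid_gates = set(gate_spec.labels)
    seen: set[tuple[str, str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        gate = row["gate"]
        if gate not in valid_gates:
            raise ValidationError(f"row {idx}: unknown gate label {gate!r}")
        if row["response"] not in RESPONSE_LABELS:
            raise ValidationError(f"row {idx}: unknown response label {row['response']!r}")
        try:
            item = StimulusItem(
                item_id=row["item"],
                event_type=row["event_type"],
                language=row["language"] if pd.notna(row["language"]) else "none",
                emotion=row["emotion"],
                speaker_id="",
                full_duration_ms=float(row["full_duration_ms"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        prev = ds.items.get(item.item_id)
        if prev is not None and prev != item:
            raise ValidationError(f"row {idx}: item {item.item_id!r} redefined inconsistently")
        ds.items[item.item_id] = item
        pid = row["participant"]
        if pid not in ds.participants:
            ds.participants[pid] = ParticipantProfile(participant_id=pid, group=row["group"])
        key = (pid, item.item_id, gate)
        if key in seen:
            raise DuplicationError(f"row {idx}: duplicate record for {key}")
        seen.add(key)
        try:
            ds.records.append(
                ResponseRecord(
                    participant_id=pid,
                    item_id=item.item_id,
                    gate_label=gate,
                    response=row["response"],
                    confidence=_coerce_confidence(row["confidence"]),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
    return ds


def write_response_table(dataset: ResponseDataset, path: str | Path, sep: str = ",") -> None:
    """Write the canonical long-format table (header always present)."""
    df = dataset.to_frame()
    df.to_csv(path, sep=sep, index=False)
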