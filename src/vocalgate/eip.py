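"""Emotion Identification Points: latency of stable emotion recognition.

The EIP of one participant x item is the earliest gate at which the listener
gives the target response and never deviates from it at any longer exposure
of the same item, expressed in milliseconds: the finite gate duration, or the
item's full duration when recognition only stabilizes at the ungated
stimulus. Items never stably recognized by GFull are scored as errors and
excluded from latency means; sequences with a missing gate are flagged
incomplete and excluded from both frequencies and errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core import GateSpec, ResponseDataset, target_response

__all__ = [
    "EIPRecord",
    "identify_point",
    "eip_table",
    "gate_frequency_table",
    "cumulative_percent",
    "round_half_up",
    "records_frame",
    "eip_summary",
]


@dataclass(frozen=True)
class EIPRecord:
    """Outcome of the stability scan for one participant x item."""

    participant_id: str
    item_id: str
    status: str  # identified | error | incomplete
    identification_gate: str | None = None
    eip_ms: float | None = None
    # metadata carried for grouping and the duration covariate
    group: str = ""
    event_type: str = ""
    language: str = ""
    emotion: str = ""
    full_duration_ms: float = float("nan")

    def __post_init__(self) -> None:
        if self.status not in ("identified", "error", "incomplete"):
            raise ValueError(f"unknown status: {self.status!r}")
        if (self.status == "identified") != (self.eip_ms is not None):
            raise ValueError("eip_ms must be set exactly when status is 'identified'")


def identify_point(
    responses: list[tuple[str, str | None]],
    target: str,
    full_duration_ms: float,
    gate_spec: GateSpec | None = None,
) -> EIPRecord:
    """Apply the stability rule to one ordered per-gate response sequence.

    ``responses`` holds (gate_label, response) pairs in ascending gate order;
    a ``None`` response marks a missing trial. The identification gate is the
    earliest gate whose response and every later response equal ``target``.
    Any non-target response — another emotion or neutral — breaks stability
    equally. No such gate by GFull means an error.
    """
    spec = gate_spec or GateSpec()
    labels = [g for g, _ in responses]
    keys = [spec.order_key(g) for g in labels]  # raises on unknown labels
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate gate labels in response sequence")
    if keys != sorted(keys):
        raise ValueError("responses must be ordered by ascending gate duration")

    expected = set(spec.labels)
    present = {g: r for g, r in responses}
    if expected - set(labels) or any(r is None for _, r in responses):
        return EIPRecord("", "", "incomplete", full_duration_ms=full_duration_ms)

    seq = [present[g] for g in spec.labels]
    gate = None
    for i in range(len(seq)):
        if all(r == target for r in seq[i:]):
            gate = spec.labels[i]
            break
    if gate is None:
        return EIPRecord("", "", "error", full_duration_ms=full_duration_ms)
    return EIPRecord(
        "",
        "",
        "identified",
        identification_gate=gate,
        eip_ms=spec.gate_duration(gate, full_duration_ms),
        full_duration_ms=full_duration_ms,
    )


def eip_table(
    dataset: ResponseDataset, include_categories: tuple[str, ...] | None = None
) -> list[EIPRecord]:
    """One EIPRecord per participant x item.

    ``include_categories`` restricts to a subset of stimulus emotions (all by
    default). happiness_pleasure records are produced like any other — the
    conventional exclusion of that category from latency *summaries* is
    handled downstream by :func:`eip_summary`.
    """
    spec = dataset.gate_spec
    df = dataset.to_frame()
    records: list[EIPRecord] = []
    if df.empty:
        return records
    if include_categories is not None:
        df = df[df["emotion"].isin(include_categories)]
        if df.empty:
            return records

    # Wide layout (participant x item rows, gates as columns) lets the
    # stability scan run as array ops; identify_point is the scalar
    # reference implementation of the same rule.
    wide = df.pivot(index=["participant", "item"], columns="gate", values="response")
    wide = wide.reindex(columns=list(spec.labels))
    meta = (
        df.groupby(["participant", "item"], sort=True)[
            ["group", "event_type", "language", "emotion", "full_duration_ms"]
        ]
        .first()
        .reindex(wide.index)
    )
    arr = wide.to_numpy(dtype=object)
    targets = meta["emotion"].map(target_response).to_numpy(dtype=object)
    missing = pd.isna(arr).any(axis=1)
    correct = arr == targets[:, None]
    # stable from gate i onward <=> every response from i to GFull is correct
    stable = np.logical_and.accumulate(correct[:, ::-1], axis=1)[:, ::-1]
    any_stable = stable.any(axis=1)
    first_gate = stable.argmax(axis=1)

    finite = np.array([*spec.finite_gates_ms, 0.0], dtype=float)[: len(spec.labels)]
    fulls = meta["full_duration_ms"].to_numpy(dtype=float)
    for row, ((pid, item_id), m) in enumerate(meta.iterrows()):
        if missing[row]:
            status, gate, ms = "incomplete", None, None
        elif any_stable[row]:
            status = "identified"
            gate = spec.labels[first_gate[row]]
            ms = fulls[row] if gate == "GFULL" else float(finite[first_gate[row]])
        else:
            status, gate, ms = "error", None, None
        records.append(
            EIPRecord(
                participant_id=pid,
                item_id=item_id,
                status=status,
                identification_gate=gate,
                eip_ms=ms,
                group=m["group"],
                event_type=m["event_type"],
                language=m["language"],
                emotion=m["emotion"],
                full_duration_ms=fulls[row],
            )
        )
    return records


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves upward (2.5 -> 3)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def cumulative_percent(counts: list[int] | tuple[int, ...], total: int) -> list[int]:
    """Cumulative identified percentages from per-gate counts, round-half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    cum = np.cumsum(counts)
    return [round_half_up(100.0 * c / total) for c in cum]


def records_frame(records: list[EIPRecord]) -> pd.DataFrame:
    """EIP records as a tidy DataFrame (one row per participant x item)."""
    return pd.DataFrame(
        [
            {
                "participant": r.participant_id,
                "item": r.item_id,
                "group": r.group,
                "event_type": r.event_type,
                "language": r.language,
                "emotion": r.emotion,
                "status": r.status,
                "identification_gate": r.identification_gate,
                "eip_ms": r.eip_ms,
                "full_duration_ms": r.full_duration_ms,
            }
            for r in records
        ],
        columns=[
            "participant",
            "item",
            "group",
            "event_type",
            "language",
            "emotion",
            "status",
            "identification_gate",
            "eip_ms",
            "full_duration_ms",
        ],
    )


def gate_frequency_table(
    records: list[EIPRecord],
    grouping: tuple[str, ...] = ("group", "event_type", "language", "emotion"),
    gate_spec: GateSpec | None = None,
) -> pd.DataFrame:
    """Per-cell gate frequencies, cumulative percents, errors, and latency.

    For each grouping cell: the count of items first stably identified at
    each gate, the cumulative percentage of the cell total at each gate
    (round-half-up), the error count/percent (never identified by GFull),
    and the mean and sample SD of the identified latencies in ms. Incomplete
    sequences are excluded from the cell total.
    """
    spec = gate_spec or GateSpec()
    df = records_frame(records)
    df = df[df["status"] != "incomplete"]
    rows = []
    for key, sub in df.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        total = len(sub)
        ident = sub[sub["status"] == "identified"]
        counts = [int((ident["identification_gate"] == g).sum()) for g in spec.labels]
        cum = cumulative_percent(counts, total)
        n_err = int((sub["status"] == "error").sum())
        lat = ident["eip_ms"].astype(float)
        row = dict(zip(grouping, key))
        for g, c, p in zip(spec.labels, counts, cum):
            row[f"n_{g}"] = c
            row[f"cum_pct_{g}"] = p
        row["n_errors"] = n_err
        row["n_total"] = total
        row["error_pct"] = round_half_up(100.0 * n_err / total)
        row["eip_mean_ms"] = float(lat.mean()) if len(lat) else float("nan")
        row["eip_sd_ms"] = float(lat.std(ddof=1)) if len(lat) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def eip_summary(
    records: list[EIPRecord],
    grouping: tuple[str, ...] = ("group", "event_type", "language", "emotion"),
    exclude_categories: tuple[str, ...] = ("happiness_pleasure",),
) -> pd.DataFrame:
    """Mean/SD identified latency per cell, with the duration covariate.

    happiness_pleasure is excluded by default (the category is tabulated in
    frequency tables but conventionally dropped from latency models because
    it is not reliably recognized); pass ``exclude_categories=()`` to keep it.
    Cells with no identified records are reported with NaN latency.
    """
    df = records_frame(records)
    if exclude_categories:
        df = df[~df["emotion"].isin(exclude_categories)]
    rows = []
    for key, sub in df.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        ident = sub[sub["status"] == "identified"]
        lat = ident["eip_ms"].astype(float)
        rows.append(
            dict(zip(grouping, key))
            | {
                "n_identified": len(ident),
                "eip_mean_ms": float(lat.mean()) if len(lat) else float("nan"),
                "eip_sd_ms": float(lat.std(ddof=1)) if len(lat) > 1 else float("nan"),
                "mean_full_duration_ms": float(ident["full_duration_ms"].mean())
                if len(ident)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
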