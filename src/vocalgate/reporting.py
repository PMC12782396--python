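"""Publication-style tables, descriptive contrasts, and model-ready export.

Inferential modeling (mixed-effects fits, post hoc contrasts) is deliberately
delegated to external statistics tooling: this module exports a long-format,
model-ready table with the factor columns such tools expect (Group,
EventType, Emotion, Gate, Familiarity, GFullDuration) and offers a
participant-level bootstrap for simple descriptive group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GateSpec
from .eip import EIPRecord, records_frame

__all__ = [
    "FAMILIARITY_MAP",
    "accuracy_trajectory_table",
    "relabel_familiarity",
    "familiarity_to_language",
    "bootstrap_group_contrast",
    "ContrastEstimate",
    "export_model_table",
    "read_model_table",
]

#: (group, stimulus language) -> familiarity of that language to the group.
#: Each listener group hears its own language natively, English as the shared
#: second language, and the other group's language as fully foreign.
FAMILIARITY_MAP = {
    ("chinese", "mandarin"): "native",
    ("chinese", "english"): "L2",
    ("chinese", "arabic"): "foreign",
    ("arab", "arabic"): "native",
    ("arab", "english"): "L2",
    ("arab", "mandarin"): "foreign",
}

_INVERSE_FAMILIARITY = {
    (group, fam): lang for (group, lang), fam in FAMILIARITY_MAP.items()
}


def relabel_familiarity(table: pd.DataFrame) -> pd.DataFrame:
    """Add a familiarity column derived from group x language.

    Vocalization rows (language "none") get an empty familiarity: the factor
    is undefined for nonverbal stimuli, which enter models as their own
    event-type level. Unknown group/language pairings raise.
    """
    for col in ("group", "language"):
        if col not in table.columns:
            raise KeyError(f"column {col!r} required")
    out = table.copy()

    def _fam(row) -> str:
        if row["language"] in ("none", "", None):
            return ""
        key = (row["group"], row["language"])
        if key not in FAMILIARITY_MAP:
            raise ValueError(f"unknown group/language pairing: {key}")
        return FAMILIARITY_MAP[key]

    out["familiarity"] = out.apply(_fam, axis=1)
    return out


def familiarity_to_language(group: str, familiarity: str) -> str:
    """Inverse of the familiarity relabeling for one group."""
    key = (group, familiarity)
    if key not in _INVERSE_FAMILIARITY:
        raise ValueError(f"unknown group/familiarity pairing: {key}")
    return _INVERSE_FAMILIARITY[key]


def accuracy_trajectory_table(
    hu: pd.DataFrame, gate_spec: GateSpec | None = None
) -> pd.DataFrame:
    """Participant-mean Hu per condition x emotion, gates as columns.

    Input is the long per-participant Hu table; output mirrors the
    publication layout: one row per group x event type x language x emotion,
    one column per gate, values averaged over participants.
    """
    if hu.empty:
        raise ValueError("empty Hu table")
    spec = gate_spec or GateSpec()
    wide = (
        hu.groupby(["group", "event_type", "language", "emotion", "gate"], sort=True)["hu"]
        .mean()
        .unstack("gate")
    )
    present = [g for g in spec.labels if g in wide.columns]
    return wide[present]


@dataclass(frozen=True)
class ContrastEstimate:
    """Difference of cell means with a percentile bootstrap interval."""

    difference: float
    ci_low: float
    ci_high: float
    replicates: int


def bootstrap_group_contrast(
    table: pd.DataFrame,
    cell_a: dict[str, object],
    cell_b: dict[str, object],
    value_col: str,
    replicates: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ContrastEstimate:
    """Bootstrap the difference of two cell means, resampling participants.

    Participants — not trials — are the exchangeable unit, matching the
    random-effect structure of repeated-measures designs: each replicate
    redraws participants with replacement within each cell and takes the
    mean of their per-participant means.
    """
    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")

    def _cell(sel: dict[str, object]) -> pd.DataFrame:
        mask = np.ones(len(table), dtype=bool)
        for col, val in sel.items():
            mask &= (table[col] == val).to_numpy()
        sub = table[mask]
        if sub.empty:
            raise ValueError(f"empty cell for selector {sel}")
        return sub

    def _part_means(sub: pd.DataFrame) -> np.ndarray:
        return sub.groupby("participant")[value_col].mean().to_numpy(dtype=float)

    means_a = _part_means(_cell(cell_a))
    means_b = _part_means(_cell(cell_b))
    diff = float(means_a.mean() - means_b.mean())

    rng = np.random.default_rng(seed)
    boots = np.empty(replicates)
    for i in range(replicates):
        ra = means_a[rng.integers(0, means_a.size, means_a.size)]
        rb = means_b[rng.integers(0, means_b.size, means_b.size)]
        boots[i] = ra.mean() - rb.mean()
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ContrastEstimate(diff, float(lo), float(hi), replicates)


_MODEL_COLUMNS = [
    "Participant",
    "Group",
    "EventType",
    "Language",
    "Familiarity",
    "Emotion",
    "Gate",
    "Measure",
    "Value",
    "GFullDuration",
]


def export_model_table(
    hu: pd.DataFrame, eips: list[EIPRecord], path: str | Path
) -> pd.DataFrame:
    """Write the long model-ready table combining Hu scores and EIP latencies.

    One row per Hu entry (Measure = "hu") and one per identified EIP record
    (Measure = "eip_ms"), with the familiarity factor derived from group x
    language and the full stimulus duration carried as a covariate for
    latency models. Returns the table as written.
    """
    rows = []
    if len(hu):
        fam = relabel_familiarity(hu)
        for r in fam.itertuples(index=False):
            rows.append(
                {
                    "Participant": r.participant,
                    "Group": r.group,
                    "EventType": r.event_type,
                    "Language": r.language,
                    "Familiarity": r.familiarity,
                    "Emotion": r.emotion,
                    "Gate": r.gate,
                    "Measure": "hu",
                    "Value": r.hu,
                    "GFullDuration": "",
                }
            )
    if eips:
        ef = relabel_familiarity(records_frame(eips))
        ef = ef[ef["status"] == "identified"]
        for r in ef.itertuples(index=False):
            rows.append(
                {
                    "Participant": r.participant,
                    "Group": r.group,
                    "EventType": r.event_type,
                    "Language": r.language,
                    "Familiarity": r.familiarity,
                    "Emotion": r.emotion,
                    "Gate": r.identification_gate,
                    "Measure": "eip_ms",
                    "Value": r.eip_ms,
                    "GFullDuration": r.full_duration_ms,
                }
            )
    df = pd.DataFrame(rows, columns=_MODEL_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_model_table(path: str | Path) -> pd.DataFrame:
    """Read back a model-ready export (round-trip companion)."""
    df = pd.read_csv(path, dtype={"Familiarity": str}, keep_default_na=False, na_values=[])
    missing = [c for c in _MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"model table missing column(s): {missing}")
    df["Value"] = pd.to_numeric(df["Value"])
    df["GFullDuration"] = pd.to_numeric(df["GFullDuration"].mask(df["GFullDuration"] == ""))
    return df
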