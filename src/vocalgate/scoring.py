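"""Accuracy scoring for forced-choice emotion judgments.

The central statistic is Wagner's unbiased hit rate (Hu),

    Hu = A^2 / (B * C)

where, within a stratum (e.g. one participant x event condition x gate),
A is the number of correct target responses to an emotion's stimuli, B the
number of presentations of that emotion, and C the total number of times the
target response label was used. Hu is the product of the hit rate (A/B) and
the precision of the response label (A/C), so it discounts both category
frequency and a rater's bias toward particular labels. Hu = 1 only for a
perfect, unconfused responder; Hu = 0 whenever the target label never meets
the target stimuli (A = 0).

Neutral is a response column only: the paradigm presents no neutral stimuli
but offers the label because brief emotional voices are often heard as
neutral.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd

from .core import RESPONSE_LABELS, ResponseDataset, target_response

__all__ = [
    "confusion_matrix",
    "hu_score",
    "hu_table",
    "neutral_proportion",
    "confidence_summary",
]

#: Default stratum for per-participant Hu scoring: one score per participant,
#: event condition (event type x language) and gate.
DEFAULT_STRATIFIERS = ("participant", "group", "event_type", "language", "gate")


def confusion_matrix(
    dataset: ResponseDataset, stratifiers: tuple[str, ...] = DEFAULT_STRATIFIERS
) -> "OrderedDict[tuple, pd.DataFrame]":
    """Stimulus-emotion x response-label count matrices per stratum.

    Each matrix has one row per stimulus emotion present in the stratum and
    the five response labels as columns; cell sums equal the stratum's record
    count. Empty strata simply do not appear.
    """
    df = dataset.to_frame()
    bad = [s for s in stratifiers if s not in df.columns]
    if bad:
        raise KeyError(f"unknown stratifier field(s): {bad}")
    out: "OrderedDict[tuple, pd.DataFrame]" = OrderedDict()
    if df.empty:
        return out
    for key, sub in df.groupby(list(stratifiers), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        mat = (
            sub.groupby(["emotion", "response"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(RESPONSE_LABELS), fill_value=0)
        )
        mat.columns.name = "response"
        out[key] = mat
    return out


def hu_score(matrix: pd.DataFrame, emotion: str) -> float:
    """Unbiased hit rate A^2/(B*C) for one stimulus emotion in one stratum.

    C counts every use of the emotion's target response label across the
    whole stratum (all stimulus rows), which is what makes the measure
    sensitive to label-usage bias. Returns 0.0 when the target label never
    met the emotion's stimuli (A = 0, including the C = 0 case).
    """
    if emotion not in matrix.index:
        raise KeyError(f"emotion {emotion!r} is not a row of this matrix")
    target = target_response(emotion)
    a = float(matrix.loc[emotion, target])
    b = float(matrix.loc[emotion].sum())
    if b == 0:
        raise ValueError(f"no presentations of {emotion!r} in this stratum (B = 0)")
    c = float(matrix[target].sum())
    if a == 0.0:
        return 0.0
    return a * a / (b * c)


def hu_table(
    dataset: ResponseDataset, stratifiers: tuple[str, ...] = DEFAULT_STRATIFIERS
) -> pd.DataFrame:
    """Hu score per stratum x stimulus emotion, long format.

    With the default stratifiers this yields one score per participant x
    event condition x gate x emotion; averaging over participants gives the
    publication-style accuracy trajectory layout.
    """
    df = dataset.to_frame()
    cols = [*stratifiers, "emotion", "hu"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    bad = [s for s in stratifiers if s not in df.columns]
    if bad:
        raise KeyError(f"unknown stratifier field(s): {bad}")
    strat = list(stratifiers)
    df = df.assign(target=df["emotion"].map(target_response))

    b = df.groupby(strat + ["emotion"], sort=True).size().rename("b")
    a = (
        df[df["response"] == df["target"]]
        .groupby(strat + ["emotion"], sort=True)
        .size()
        .reindex(b.index, fill_value=0)
        .rename("a")
    )
    usage = df.groupby(strat + ["response"], sort=True).size().rename("c")

    out = pd.concat([a, b], axis=1).reset_index()
    out["target"] = out["emotion"].map(target_response)
    out = out.merge(
        usage.reset_index().rename(columns={"response": "target"}),
        on=strat + ["target"],
        how="left",
    )
    out["c"] = out["c"].fillna(0).astype(int)
    denom = (out["b"] * out["c"]).to_numpy(dtype=float)
    a_np = out["a"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hu = np.where(a_np == 0.0, 0.0, a_np * a_np / denom)
    out["hu"] = hu
    return out[cols]


def neutral_proportion(
    dataset: ResponseDataset,
    grouping: tuple[str, ...] = ("group", "event_type", "language", "emotion", "gate"),
) -> pd.DataFrame:
    """Proportion of 'neutral' responses per stratum (supplementary summary)."""
    df = dataset.to_frame()
    if df.empty:
        return pd.DataFrame(columns=[*grouping, "neutral_proportion"])
    out = (
        df.assign(is_neutral=df["response"].eq("neutral"))
        .groupby(list(grouping), sort=True)["is_neutral"]
        .mean()
        .rename("neutral_proportion")
        .reset_index()
    )
    return out


def confidence_summary(
    dataset: ResponseDataset,
    grouping: tuple[str, ...] = ("group", "event_type", "language", "emotion", "gate"),
) -> pd.DataFrame:
    """Mean 1-7 confidence per stratum; missing ratings excluded, empty strata NaN."""
    df = dataset.to_frame()
    if df.empty:
        return pd.DataFrame(columns=[*grouping, "mean_confidence", "n_rated"])
    conf = df["confidence"].astype("Float64")
    out = (
        df.assign(confidence=conf)
        .groupby(list(grouping), sort=True)["confidence"]
        .agg(mean_confidence="mean", n_rated="count")
        .reset_index()
    )
    out["mean_confidence"] = out["mean_confidence"].astype(float)
    out.loc[out["n_rated"] == 0, "mean_confidence"] = np.nan
    return out
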