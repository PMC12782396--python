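"""Gated-stimulus construction and blocked presentation scheduling.

A gating study cuts each stimulus from its acoustic onset into excerpts of
fixed duration (e.g. 200/400/500/600 ms) plus the unedited full recording, and
presents them in blocks of strictly increasing duration so that short-gate
judgments are never contaminated by prior exposure to longer excerpts.

Audio here is mono PCM; peak normalization targets a digital dBFS level (a
file property), which is distinct from the playback sound-pressure level an
experimenter calibrates on hardware. Cut points get a short linear fade-out
to suppress truncation clicks.
"""

from __future__ import annotations

import math
import wave as _wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import GateSpec, StimulusItem, TrialDefinition

__all__ = [
    "Waveform",
    "Block",
    "BlockSchedule",
    "read_wav",
    "write_wav",
    "cut_segment",
    "normalize_peak",
    "plan_gates",
    "build_trial_inventory",
    "build_block_schedule",
]


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples in [-1, 1] at a fixed rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("waveform must be a non-empty 1-D sample sequence")
        if np.max(np.abs(samples)) > 1.0 + 1e-12:
            raise ValueError("sample amplitudes must lie in [-1, 1]")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate_hz


def _ms_to_samples(duration_ms: float, rate: int) -> int:
    # round-half-up, so e.g. 0.5 samples -> 1
    return int(math.floor(duration_ms * rate / 1000.0 + 0.5))


def read_wav(path: str | Path) -> Waveform:
    """Read a mono 16-bit PCM WAV file. Stereo input is rejected."""
    with _wave.open(str(path), "rb") as fh:
        if fh.getnchannels() != 1:
            raise ValueError(f"{path}: expected mono audio, got {fh.getnchannels()} channels")
        if fh.getsampwidth() != 2:
            raise ValueError(f"{path}: only 16-bit PCM supported, got {8 * fh.getsampwidth()}-bit")
        rate = fh.getframerate()
        raw = fh.readframes(fh.getnframes())
    data = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32768.0
    return Waveform(samples=data, sample_rate_hz=rate)


def write_wav(audio: Waveform, path: str | Path) -> None:
    """Write mono 16-bit PCM."""
    pcm = np.clip(np.round(audio.samples * 32768.0), -32768, 32767).astype("<i2")
    with _wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(audio.sample_rate_hz)
        fh.writeframes(pcm.tobytes())


def cut_segment(audio: Waveform, duration_ms: float, fade_ms: float = 5.0) -> Waveform:
    """Cut the initial `duration_ms` from acoustic onset, with a linear fade-out.

    The fade (default 5 ms) ramps the final samples linearly to zero to avoid
    truncation clicks. When the requested duration covers the whole recording
    the input is returned unchanged (no fade: the natural offset needs none).
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if fade_ms < 0:
        raise ValueError("fade_ms must be non-negative")
    if fade_ms > duration_ms:
        raise ValueError("fade_ms cannot exceed duration_ms")
    n = _ms_to_samples(duration_ms, audio.sample_rate_hz)
    if n >= audio.samples.size:
        return audio
    out = audio.samples[:n].copy()
    n_fade = _ms_to_samples(fade_ms, audio.sample_rate_hz)
    if n_fade > 0:
        n_fade = min(n_fade, n)
        # linear ramp from 1 down to 0 across the final n_fade samples
        out[n - n_fade :] *= np.linspace(1.0, 0.0, n_fade)
    return Waveform(samples=out, sample_rate_hz=audio.sample_rate_hz)


def normalize_peak(audio: Waveform, target: float = -3.0, dbfs: bool = True) -> Waveform:
    """Scale so the peak magnitude hits the target level.

    `target` is a dBFS level by default (0 dBFS = full scale); pass
    ``dbfs=False`` to give a linear amplitude ratio in (0, 1].
    """
    peak = float(np.max(np.abs(audio.samples)))
    if peak == 0.0:
        raise ValueError("cannot normalize silent (all-zero) audio")
    level = 10.0 ** (target / 20.0) if dbfs else float(target)
    if not 0.0 < level <= 1.0:
        raise ValueError("target level must resolve to an amplitude in (0, 1]")
    return Waveform(samples=audio.samples * (level / peak), sample_rate_hz=audio.sample_rate_hz)


def plan_gates(item: StimulusItem, spec: GateSpec | None = None) -> list[TrialDefinition]:
    """One trial per gate for an item; items too brief for gating are rejected."""
    spec = spec or GateSpec()
    max_finite = max(spec.finite_gates_ms, default=0)
    if item.full_duration_ms <= max_finite:
        raise ValueError(
            f"item {item.item_id!r} ({item.full_duration_ms} ms) is too brief for "
            f"gating at {max_finite} ms"
        )
    trials = [
        TrialDefinition(item.item_id, f"G{g}", float(g)) for g in spec.finite_gates_ms
    ]
    if spec.include_full:
        trials.append(TrialDefinition(item.item_id, "GFULL", float(item.full_duration_ms)))
    return trials


def build_trial_inventory(
    items: list[StimulusItem] | tuple[StimulusItem, ...], spec: GateSpec | None = None
) -> list[TrialDefinition]:
    """Concatenate per-item gate plans: |inventory| = n_items x n_gates."""
    spec = spec or GateSpec()
    inventory: list[TrialDefinition] = []
    for item in items:
        inventory.extend(plan_gates(item, spec))
    return inventory


@dataclass(frozen=True)
class Block:
    """One presentation sub-block: a single gate x a single event type."""

    gate_label: str
    event_type: str
    trials: tuple[TrialDefinition, ...]
    practice_trials: int = 5


@dataclass
class BlockSchedule:
    """Blocks in ascending gate-duration order, event types never intermixed."""

    blocks: list[Block] = field(default_factory=list)


def build_block_schedule(
    trials: list[TrialDefinition],
    items: dict[str, StimulusItem],
    order_policy: str = "vocal_first",
    practice_per_block: int = 5,
    seed: int = 0,
    spec: GateSpec | None = None,
) -> BlockSchedule:
    """Arrange trials into the blocked ascending-duration presentation order.

    Blocks run from the shortest gate to GFull. Within each gate duration,
    speech and vocalization trials form separate sub-blocks ordered by
    `order_policy` (the counterbalancing lever: half of a participant pool
    gets each policy). Item order within a sub-block is a seed-determined
    permutation; speech sub-blocks intermix all languages.
    """
    if order_policy not in ("speech_first", "vocal_first"):
        raise ValueError(f"unknown order policy: {order_policy!r}")
    spec = spec or GateSpec()
    rng = np.random.default_rng(seed)
    event_order = (
        ("prosody", "vocalization") if order_policy == "speech_first" else ("vocalization", "prosody")
    )
    blocks: list[Block] = []
    for gate in spec.labels:
        at_gate = [t for t in trials if t.gate_label == gate]
        if not at_gate:
            continue
        for ev in event_order:
            sub = [t for t in at_gate if items[t.item_id].event_type == ev]
            if not sub:
                continue
            sub.sort(key=lambda t: t.item_id)  # stable base order before shuffling
            perm = rng.permutation(len(sub))
            blocks.append(
                Block(
                    gate_label=gate,
                    event_type=ev,
                    trials=tuple(sub[i] for i in perm),
                    practice_trials=practice_per_block,
                )
            )
    return BlockSchedule(blocks=blocks)
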