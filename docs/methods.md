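# Methods

## The measurement problem

In an auditory gating experiment, listeners judge the emotion of a vocal
stimulus — a nonverbal vocalization (laugh, sob, shout) or an emotionally
inflected pseudo-utterance — from excerpts that always grow in duration:
first the initial 200 ms of every stimulus, then 400, 500, 600 ms, and
finally the full recording (G200…GFull). Blocks run strictly from shortest
to longest so that a short-gate judgment is never contaminated by prior
exposure to a longer excerpt of the same item. On each trial the listener
picks one of five labels (anger, happiness, fear, sadness, neutral) and
optionally rates confidence on a 7-point scale. The pipeline turns these
long-format trial tables into two dependent measures:

**Accuracy — the unbiased hit rate (Hu).** Within a stratum (by default one
participant × event condition × gate), for a stimulus emotion with A correct
target responses out of B presentations, where the target label was used C
times in total across the stratum,

    Hu = A² / (B · C) = (A/B) · (A/C),

i.e. hit rate × precision. Hu discounts both unequal category sizes and a
rater's bias toward particular labels; Hu = 1 only for a perfect, unconfused
responder, and Hu = 0 whenever A = 0 (we define the C = 0 case as 0 as
well). No variance-stabilizing transform is applied; the raw proportions are
exported. Because the response screen offers a single "happiness" option,
the two vocalization sub-categories (happiness-amusement = laughter,
happiness-pleasure = contentment sounds) are separate stimulus rows that
share one response column, and C is counted over the stratum as a whole.

**Latency — the Emotion Identification Point (EIP).** For one participant ×
item, the EIP is the earliest gate whose response and every later response
equal the target, expressed in milliseconds: the finite gate duration, or
the item's full duration when recognition only stabilizes at the ungated
stimulus. Any non-target response breaks stability — a neutral response and
a wrong emotion count identically, since the stability rule only asks
whether the listener has settled on the target. Items never stably
recognized by GFull are errors and are excluded from latency means.
Sequences with any missing gate are reported as a third status,
`incomplete`, and excluded from both the identified frequencies and the
error counts, so missing trials can never silently inflate error rates.

The per-pair scan exists twice on purpose: `identify_point` is the scalar
reference implementation, and `eip_table` re-derives the same rule as a
vectorized suffix-conjunction over a wide (participant × item) × gate array.
A test enumerates all 5⁵ = 3,125 possible 5-gate response patterns against a
brute-force oracle, and another checks the two routes against each other on
simulated data.

## Tables and rounding

The gate-frequency table reports, per group × event condition × emotion:
counts of items first identified at each gate, cumulative percentages of the
cell total, error counts and percentages, and the mean (sample SD, ddof = 1)
of identified latencies. Percentages use round-half-up to integers
(`Decimal` rounding, not banker's rounding), which reproduces arithmetically
self-consistent published-style rows exactly; two invariants hold by
construction: cumulative percentages are non-decreasing, and the GFull
cumulative percentage plus the error percentage equals 100 within ±1
rounding unit.

The familiarity factor recodes stimulus language relative to the listener
group: each group hears its own language natively, English as the shared
second language (L2), and the other group's language as foreign. The map is
a bijection per group and is inverted by `familiarity_to_language`. For
vocalizations the factor is undefined (language "none") and is exported
blank rather than inventing a level — nonverbal stimuli enter models as
their own event-type level.

Mixed-effects model fitting is deliberately out of scope:
`export_model_table` writes a long model-ready table (Participant, Group,
EventType, Language, Familiarity, Emotion, Gate, Measure, Value,
GFullDuration) for external tooling such as lme4, with the full stimulus
duration carried as a covariate for latency models. The in-package
inferential companion is a participant-level percentile bootstrap:
participants, not trials, are resampled, matching the exchangeability
structure of a repeated-measures design with a by-subject random intercept.

## The synthetic-listener generator

The generator emulates the structure of a two-group cross-cultural gating
study so the whole pipeline is testable without human data: 2 groups × 25
participants; 50 vocalizations (10 items each for anger, fear, sadness,
happiness-amusement, happiness-pleasure; full durations uniform on
715–2376 ms) and 144 pseudo-utterances (3 languages × 4 emotions × 12 items;
834–2900 ms); gates G200/G400/G500/G600/GFull; every participant judges
every item at every gate.

Each condition carries a latent psychometric model. At exposure duration d
(ms), the probability of recognizing the target is a logistic in
log-duration,

    p(d) = 1 / (1 + exp(−slope · (log d − log t50_eff))),

with `t50_ms` the duration of 50% recognition and
`t50_eff = t50 · exp(u_participant + u_item)`, the random effects being
independent normals on the log scale (defaults 0.15 and 0.20 SD). The log
scale gives Weber-like behavior over the wide range of full durations and
keeps p strictly inside (0, 1). One response draw is a mixture:

1. with probability `lapse` (default 0.05), a uniform pick among the 5
   labels — full inattention, which overrides every other mechanism, so
   lapse = 1 degenerates to exact uniform guessing (target rate 1/5);
2. otherwise, if the previous gate's response to this item was the target,
   repeat it with probability `stickiness` (default 0.9). Stickiness directly
   models the response stability the EIP quantifies; it applies only after a
   *target* response (no non-target perseveration), and it is a modeling
   invention of this package — the generator makes no claim that human
   stability arises this way;
3. otherwise the target with probability p(d); failing that, "neutral" with
   probability `neutral_bias · exp(−d / neutral_decay_ms)` (defaults 0.6 and
   400 ms), emulating the tendency to hear brief emotional voices as
   neutral; the remainder spreads uniformly over the three non-target
   emotion labels.

`response_kernel_probs` exposes this distribution analytically (stickiness
aside) and unit tests verify it sums to one and that p(d) is non-decreasing
in d for all valid parameters.

Default thresholds were fixed once to reproduce the qualitative structure of
cross-cultural gating results — anger vocalizations near-immediate
(t50 = 180 ms), other vocalizations within ~300–400 ms, pleasure sounds poor
and late (1600 ms), prosody slower overall (500–1100 ms) with happiness
slowest — with a common slope of 2. The generator does not emulate group
differences, ingroup advantages, item-level acoustic structure, confidence
criteria, fatigue, or real response-time behavior; confidence is a noisy
monotone function of p(d). Passing tests therefore certify the *pipeline
arithmetic and its statistical conventions*, not any claim about human
listeners.

All randomness flows from the config's single integer seed through one
`numpy` Generator in a fixed traversal order (conditions in declaration
order, gates ascending), so equal configs give byte-identical datasets.

## Parameter recovery

`recovery_study` runs simulate → EIP extraction → latency summary (and Hu
scoring) for each config in a grid and correlates the generating t50 with
the recovered mean identified latency. At study size (50 participants × 194
items), a 5-point t50 grid (250/400/600/900/1400 ms) over 10 replicates
yields per-replicate strictly monotone mean EIPs and a Spearman correlation
≥ 0.9 — the package's internal validity check that the latency measure
tracks the latent threshold. These sizes were chosen as the design the
generator emulates; the vectorized sampler and wide-array EIP scan keep a
full grid × replicate sweep around a minute on one core.

## Audio conventions

Gates are cut from acoustic onset (sample 0); millisecond→sample conversion
rounds half-up. De-clicking is automated as a linear fade-out (default 5 ms)
at the cut point instead of manual waveform editing, for reproducibility; no
fade is applied when the gate covers the whole recording. Peak
normalization targets a digital level (default −3 dBFS): a "75 dB" playback
level is a sound-pressure calibration of hardware, not a file property, and
is out of scope, as is loudness-model (LUFS) normalization. WAV I/O is mono
16-bit PCM (scale 32768, clipped at full scale); stereo files are rejected
with a clear error.

## Degenerate inputs and edge conventions

- `hu_score` with B = 0 (no presentations) raises; A = 0 returns 0.0.
- Empty strata are omitted from confusion matrices (not zero-filled rows);
  strata with no confidence ratings report missing, not zero.
- `cut_segment` rejects a fade longer than the cut; `normalize_peak` rejects
  silent audio (scale undefined); `Waveform` rejects empty or out-of-range
  samples.
- `plan_gates` rejects items not strictly longer than the largest finite
  gate, naming the item.
- Bootstrap contrasts require ≥ 100 replicates and non-empty cells.

## Known limitations

- The stickiness mechanism is the simplest model that exercises the EIP
  stability rule; it has no empirical calibration.
- The generator's conditions are group-symmetric, so cross-group contrasts
  on synthetic data estimate a true difference of zero by design.
- The canonical response-table schema does not serialize speaker identity;
  round-trips preserve it as empty.
- Import of external deposits requires a user-supplied column-rename mapping
  (`dialect`); the pipeline does not guess foreign layouts.
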