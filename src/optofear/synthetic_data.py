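"""Synthetic stimulation protocols, spike populations, and freezing tables.

The generators reproduce the structure of the acute optogenetic experiment
(20 Hz pulse trains of 0.5/1/5/15 s after a 5-min baseline, 30-s inter-train
gaps) and of the fear-renewal behavioural designs (ABA/ABCA/contextual), so
that every downstream stage of the pipeline can be exercised with known
ground truth. All generators are pure functions of (parameters, seed).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import InvalidParameterError, SpikeTrain, StimProtocol

log = logging.getLogger("optofear")

#: Train durations (s) used in the acute stimulation experiment, each
#: presented once per trial in random order.
DEFAULT_TRAIN_DURATIONS = (0.5, 1.0, 5.0, 15.0)

#: Stage vocabularies of the behavioural protocols. "CS_1_4" stages are the
#: mean over the first four tone presentations of an extinction session.
STAGE_VOCAB = {
    "ABA": (
        "conditioning",
        "extinction_first_CS1_4",
        "extinction_last_CS1_4",
        "baseline_laser",
        "CS",
        "post_CS",
    ),
    "ABCA": (
        "conditioning",
        "extinction_first_CS1_4",
        "extinction_last_CS1_4",
        "baseline_laser_C",
        "CS_C",
        "baseline_laser_A",
        "CS_A",
    ),
    "contextual": (
        "baseline",
        "ITI",
        "recall_minute_1",
        "recall_minute_2",
        "recall_minute_3",
        "recall_minute_4",
        "recall_minute_5",
        "recall_minute_6",
    ),
}

#: Stages during which the laser is ON (where the ChR2 group effect applies).
LASER_STAGES = {
    "ABA": ("baseline_laser",),
    "ABCA": ("baseline_laser_C", "baseline_laser_A"),
    # laser covers the first 4 minutes of the contextual recall test
    "contextual": tuple(f"recall_minute_{m}" for m in range(1, 5)),
}

#: Plausible group-level freezing means (%) for control animals per stage.
DEFAULT_STAGE_MEANS = {
    "ABA": {
        "conditioning": 65.0,
        "extinction_first_CS1_4": 75.0,
        "extinction_last_CS1_4": 40.0,
        "baseline_laser": 55.0,
        "CS": 60.0,
        "post_CS": 45.0,
    },
    "ABCA": {
        "conditioning": 65.0,
        "extinction_first_CS1_4": 75.0,
        "extinction_last_CS1_4": 40.0,
        "baseline_laser_C": 45.0,
        "CS_C": 55.0,
        "baseline_laser_A": 60.0,
        "CS_A": 60.0,
    },
    "contextual": {
        "baseline": 10.0,
        "ITI": 40.0,
        "recall_minute_1": 60.0,
        "recall_minute_2": 55.0,
        "recall_minute_3": 50.0,
        "recall_minute_4": 45.0,
        "recall_minute_5": 40.0,
        "recall_minute_6": 35.0,
    },
}


@dataclass(frozen=True)
class GroundTruthUnit:
    """What was injected into one synthetic unit, for scoring detectors."""

    unit_id: str
    klass: str = "none"                 # "none" | "excited" | "inhibited_rebound"
    response_latency: float = 0.0015    # s; excited: from onset, rebound: from offset
    per_pulse_response_prob: float = 0.0
    suppression_factor: float = 1.0     # within-pulse rate multiplier in [0, 1]
    background_rate: float = 5.0        # Hz
    isi_shape: float = 1.0              # gamma renewal shape; 1 = Poisson, <1 bursty

    def __post_init__(self) -> None:
        if self.klass not in ("none", "excited", "inhibited_rebound"):
            raise InvalidParameterError(f"unknown unit class {self.klass!r}")
        if not 0.0 <= self.per_pulse_response_prob <= 1.0:
            raise InvalidParameterError("per_pulse_response_prob must be in [0, 1]")
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise InvalidParameterError("suppression_factor must be in [0, 1]")
        if self.klass == "none" and (
            self.per_pulse_response_prob != 0.0 or self.suppression_factor != 1.0
        ):
            raise InvalidParameterError(
                "class 'none' requires response_prob 0 and suppression_factor 1"
            )
        if self.background_rate < 0 or self.isi_shape <= 0:
            raise InvalidParameterError("background_rate >= 0 and isi_shape > 0 required")


@dataclass(frozen=True)
class BackgroundParams:
    """Population heterogeneity of background firing.

    Rates are drawn log-uniformly over ``rate_range`` (cortical firing rates
    are roughly log-normal), ISI shapes uniformly over ``isi_shape_range``
    (shape < 1 produces bursty trains, 1 is Poisson).
    """

    rate_range: tuple = (1.0, 10.0)      # Hz
    isi_shape_range: tuple = (0.5, 1.5)

    def __post_init__(self) -> None:
        lo, hi = self.rate_range
        if not 0 < lo <= hi:
            raise InvalidParameterError("rate_range must satisfy 0 < lo <= hi")
        lo, hi = self.isi_shape_range
        if not 0 < lo <= hi:
            raise InvalidParameterError("isi_shape_range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class FreezingEffectSpec:
    """Group structure of a synthetic freezing experiment.

    The two control groups (GFP virus, and ChR2 without laser) share
    identical stage means by construction; the ChR2 group's mean is lowered
    by ``laser_stage_delta`` percentage points at laser-on stages only.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"ChR2": 10, "control_GFP": 9, "control_nolaser": 9}
    )
    stage_means: dict | None = None      # control means per stage; None = defaults
    stage_sd: float = 10.0               # between-animal SD, percent
    laser_stage_delta: float = 20.0      # percent reduction in ChR2 at laser stages
    seed: int = 0

    def __post_init__(self) -> None:
        required = {"ChR2", "control_GFP", "control_nolaser"}
        if set(self.group_sizes) != required:
            raise InvalidParameterError(f"group_sizes must have keys {sorted(required)}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise InvalidParameterError("group sizes must be non-negative")
        if self.stage_sd < 0:
            raise InvalidParameterError("stage_sd must be non-negative")


def gen_protocol(
    train_spec=None,
    pulse_rate: float = 20.0,
    pulse_width: float = 0.010,
    inter_train_gap: float = 30.0,
    baseline_s: float = 300.0,
    n_trials: int = 1,
    seed: int = 0,
) -> StimProtocol:
    """Build a pulse-train stimulation protocol.

    Each trial presents every entry of ``train_spec`` once, in a
    seed-determined random order, separated by ``inter_train_gap`` seconds,
    after a ``baseline_s`` silent period. A train of duration ``d`` at rate
    ``r`` contains ``round(d * r)`` pulses spaced exactly ``1/r`` apart.
    """
    if train_spec is None:
        train_spec = [(d, "11mW") for d in DEFAULT_TRAIN_DURATIONS]
    train_spec = tuple((float(d), str(label)) for d, label in train_spec)
    if any(d <= 0 for d, _ in train_spec):
        raise InvalidParameterError("train durations must be positive")
    if pulse_rate <= 0:
        raise InvalidParameterError("pulse_rate must be positive")
    if not 0 < pulse_width < 1.0 / pulse_rate:
        raise InvalidParameterError("pulse_width must lie in (0, 1/pulse_rate)")
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")

    rng = np.random.default_rng(seed)
    onsets, train_ids = [], []
    cursor = 0.0
    train_counter = 0
    for _ in range(n_trials):
        cursor += baseline_s
        order = rng.permutation(len(train_spec))
        for j in order:
            duration = train_spec[j][0]
            n_pulses = int(round(duration * pulse_rate))
            onsets.append(cursor + np.arange(n_pulses) / pulse_rate)
            train_ids.append(np.full(n_pulses, train_counter))
            train_counter += 1
            cursor += duration + inter_train_gap
    onsets = np.concatenate(onsets)
    train_ids = np.concatenate(train_ids)
    return StimProtocol(
        pulse_onsets=onsets,
        pulse_width=pulse_width,
        pulse_rate=pulse_rate,
        train_spec=train_spec,
        inter_train_gap=inter_train_gap,
        baseline_s=baseline_s,
        total_duration=cursor,
        train_ids=train_ids,
    )


def gen_background_train(
    rate: float,
    duration: float,
    isi_shape: float = 1.0,
    seed=0,
    unit_id: str = "unit0",
) -> SpikeTrain:
    """Gamma renewal process: ISIs ~ Gamma(isi_shape, mean 1/rate).

    ``isi_shape = 1`` gives a Poisson process; shapes below 1 give bursty
    trains with an ISI coefficient of variation ``1/sqrt(isi_shape)``.
    The process starts counting intervals from t = 0 (ordinary, not
    equilibrium, renewal process — negligible at the durations used here).
    """
    if rate < 0:
        raise InvalidParameterError("rate must be non-negative")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if isi_shape <= 0:
        raise InvalidParameterError("isi_shape must be positive")
    if rate == 0:
        return SpikeTrain(unit_id, np.empty(0), duration)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = 1.0 / (rate * isi_shape)
    times = []
    t = 0.0
    expected = int(rate * duration)
    while t < duration:
        isis = rng.gamma(isi_shape, scale, size=max(expected, 64) + 64)
        chunk = t + np.cumsum(isis)
        times.append(chunk)
        t = chunk[-1]
    times = np.concatenate(times)
    times = times[times < duration]
    return SpikeTrain(unit_id, times, duration)


def inject_responses(
    train: SpikeTrain,
    protocol: StimProtocol,
    ground_truth: GroundTruthUnit,
    seed=0,
    latency_sd: float = 0.0002,
    rebound_span: float = 0.002,
) -> SpikeTrain:
    """Add stimulus-locked structure to a background train.

    excited: with ``per_pulse_response_prob``, one extra spike at
    onset + latency + Normal(0, latency_sd) (truncated so the realised
    latency stays positive). inhibited_rebound: background spikes inside
    each pulse are deleted with probability ``1 - suppression_factor``, and
    with ``per_pulse_response_prob`` one rebound spike is added uniformly
    within ``rebound_span`` after pulse offset.
    """
    gt = ground_truth
    if gt.klass == "none":
        return train
    if gt.response_latency >= protocol.pulse_period:
        raise InvalidParameterError("response latency must be below the pulse period")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onsets = protocol.pulse_onsets
    spikes = train.spike_times

    if gt.klass == "excited":
        hit = rng.random(onsets.size) < gt.per_pulse_response_prob
        noise = rng.normal(0.0, latency_sd, size=int(hit.sum()))
        lat = np.maximum(gt.response_latency + noise, 1e-6)
        extra = onsets[hit] + lat
        merged = np.sort(np.concatenate([spikes, extra]))
        return SpikeTrain(train.unit_id, merged, train.duration)

    # inhibited_rebound
    offset = protocol.pulse_width
    lo = np.searchsorted(spikes, onsets, side="left")
    hi = np.searchsorted(spikes, onsets + offset, side="left")
    in_pulse = np.zeros(spikes.size, dtype=bool)
    for a, b in zip(lo, hi):
        in_pulse[a:b] = True
    drop = in_pulse & (rng.random(spikes.size) < (1.0 - gt.suppression_factor))
    kept = spikes[~drop]
    hit = rng.random(onsets.size) < gt.per_pulse_response_prob
    rebound = onsets[hit] + offset + rng.uniform(0.0, rebound_span, size=int(hit.sum()))
    merged = np.sort(np.concatenate([kept, rebound]))
    return SpikeTrain(train.unit_id, merged, train.duration)


def gen_population(
    n_units: int,
    frac_excited: float,
    frac_inhibited: float,
    protocol: StimProtocol,
    background: BackgroundParams | None = None,
    response_prob: float = 0.3,
    excited_latency: float = 0.0015,
    suppression_factor: float = 0.1,
    seed: int = 0,
):
    """Generate a population with exact injected-class counts.

    Returns ``(trains, ground_truths)``. Class counts are
    ``round(frac * n_units)``; which units carry a response is a
    seed-determined random assignment.
    """
    if not (0.0 <= frac_excited <= 1.0 and 0.0 <= frac_inhibited <= 1.0):
        raise InvalidParameterError("class fractions must lie in [0, 1]")
    if frac_excited + frac_inhibited > 1.0:
        raise InvalidParameterError("class fractions must sum to at most 1")
    if n_units < 1:
        raise InvalidParameterError("n_units must be positive")
    background = background or BackgroundParams()

    n_exc = int(round(frac_excited * n_units))
    n_inh = int(round(frac_inhibited * n_units))
    classes = np.array(
        ["excited"] * n_exc + ["inhibited_rebound"] * n_inh
        + ["none"] * (n_units - n_exc - n_inh)
    )
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    classes = classes[rng.permutation(n_units)]

    lo, hi = background.rate_range
    rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_units))
    shapes = rng.uniform(*background.isi_shape_range, size=n_units)

    trains, gts = [], []
    for i, child in enumerate(ss.spawn(n_units)):
        unit_rng = np.random.default_rng(child)
        uid = f"u{i:04d}"
        klass = classes[i]
        gt = GroundTruthUnit(
            unit_id=uid,
            klass=klass,
            response_latency=excited_latency if klass == "excited" else 0.0015,
            per_pulse_response_prob=0.0 if klass == "none" else response_prob,
            suppression_factor=1.0 if klass != "inhibited_rebound" else suppression_factor,
            background_rate=float(rates[i]),
            isi_shape=float(shapes[i]),
        )
        bg = gen_background_train(
            gt.background_rate, protocol.total_duration, gt.isi_shape,
            seed=unit_rng, unit_id=uid,
        )
        trains.append(inject_responses(bg, protocol, gt, seed=unit_rng))
        gts.append(gt)
    return trains, gts


def gen_freezing_dataset(spec: FreezingEffectSpec, protocol_name: str) -> pd.DataFrame:
    """Per-animal, per-stage percent-freezing table for one protocol.

    Values are Normal(group stage mean, stage_sd) clipped to [0, 100]; the
    ChR2 group mean is lowered by ``laser_stage_delta`` at laser-on stages.
    """
    if protocol_name not in STAGE_VOCAB:
        raise InvalidParameterError(
            f"unknown protocol {protocol_name!r}; valid: {sorted(STAGE_VOCAB)}"
        )
    stages = STAGE_VOCAB[protocol_name]
    laser_stages = set(LASER_STAGES[protocol_name])
    means = dict(DEFAULT_STAGE_MEANS[protocol_name])
    if spec.stage_means is not None:
        unknown = set(spec.stage_means) - set(stages)
        if unknown:
            raise InvalidParameterError(f"stages not in {protocol_name} vocabulary: {sorted(unknown)}")
        means.update(spec.stage_means)

    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in ("ChR2", "control_GFP", "control_nolaser"):
        for i in range(spec.group_sizes[group]):
            animal = f"{group}_{i:02d}"
            for stage in stages:
                mu = means[stage]
                if group == "ChR2" and stage in laser_stages:
                    mu = mu - spec.laser_stage_delta
                value = float(np.clip(rng.normal(mu, spec.stage_sd), 0.0, 100.0))
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "session": protocol_name,
                        "stage": stage,
                        "percent_freezing": value,
                    }
                )
    return pd.DataFrame(rows)
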