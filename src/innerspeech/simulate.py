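"""Synthetic sessions with known ground truth.

Emulates the statistical structure of the word-production task: each unit
fires as an inhomogeneous Poisson process whose rate is piecewise constant
within trial phases — a baseline plus an additive, word- and phase-specific
gain.  Two unit archetypes are provided:

* SMG-like: word-selective gains in designated active phases (cue,
  internal, speech), so word identity is linearly decodable there.
* S1-like: word-agnostic gain restricted to the vocalized-speech phase
  (speech production modulates these units, but word identity does not).

Additive gains keep effect sizes directly interpretable against the
baseline in spikes/s; rates are clipped at zero and clip events counted.
Auditory-cue trials draw an audio onset uniformly from the config range and
the cue-phase gain begins at audio onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .session import (
    SessionValidationError,
    SpikeData,
    TaskConfig,
    make_trial_table,
)

ACTIVE_PHASES_DEFAULT = {"cue": 0.5, "internal": 0.5, "speech": 0.6}


@dataclass
class UnitGroundTruth:
    """Generative parameters of one simulated unit.

    ``gain[word][phase]`` is the additive rate change (spikes/s) applied
    during that phase for that word; ``modality_gain`` applies during the
    cue phase only; ``latency`` delays the response onset within a phase.
    """

    unit_id: str
    area: str
    baseline_rate: float
    gain: dict[str, dict[str, float]] = field(default_factory=dict)
    modality_gain: dict[str, float] = field(default_factory=dict)
    latency: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise SessionValidationError("baseline_rate: must be >= 0")
        if self.area == "S1":
            for w, by_phase in self.gain.items():
                for p, g in by_phase.items():
                    if p != "speech" and g != 0:
                        raise SessionValidationError(
                            "S1 units: gain must be nonzero only in speech phase"
                        )
            speech = {by.get("speech", 0.0) for by in self.gain.values()}
            if len(speech) > 1:
                raise SessionValidationError(
                    "S1 units: gain must be constant across words"
                )

    def gain_at(self, word: str, phase: str) -> float:
        return self.gain.get(word, {}).get(phase, 0.0)

    def tuned_phases(self) -> set[str]:
        """Phases in which this unit has nonzero gain for >=1 word."""
        return {
            p
            for by_phase in self.gain.values()
            for p, g in by_phase.items()
            if g != 0.0
        }

    def to_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "area": self.area,
            "baseline_rate": self.baseline_rate,
            "gain": self.gain,
            "modality_gain": self.modality_gain,
            "latency": self.latency,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "UnitGroundTruth":
        return cls(
            unit_id=d["unit_id"],
            area=d["area"],
            baseline_rate=float(d["baseline_rate"]),
            gain={w: {p: float(g) for p, g in by.items()} for w, by in d["gain"].items()},
            modality_gain={m: float(g) for m, g in d.get("modality_gain", {}).items()},
            latency=float(d.get("latency", 0.0)),
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a simulated unit population.

    ``tuned_fraction`` maps phase name -> fraction of units with
    word-selective gain in that phase (SMG) or, for S1, the fraction with a
    word-agnostic speech-phase gain.  ``effect_mean``/``effect_sd``
    parameterize the magnitude distribution |N(mean, sd)| of gains in
    spikes/s; baselines are Gamma(shape, scale) distributed.

    ``word_code`` controls whether a unit reuses one per-word gain profile
    in every phase it is tuned in ("shared", the default: word codes
    generalize across cue, internal and vocalized speech, and tuning is
    preserved between phases) or draws fresh gains per phase
    ("independent": phase codes are orthogonal and cross-phase decoding
    stays at chance).
    """

    n_units: int = 32
    area: str = "SMG"
    tuned_fraction: Mapping[str, float] | None = None
    effect_mean: float = 5.0
    effect_sd: float = 2.0
    baseline_shape: float = 2.0
    baseline_scale: float = 4.0
    modality_effect: float = 0.0
    latency: float = 0.0
    word_code: str = "shared"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise SessionValidationError("n_units: must be >= 1")
        for p, f in (self.tuned_fraction or {}).items():
            if not 0 <= f <= 1:
                raise SessionValidationError(f"tuned_fraction[{p!r}]: must be in [0,1]")
        if self.area not in ("SMG", "S1"):
            raise SessionValidationError("area: must be SMG or S1")
        if self.word_code not in ("shared", "independent"):
            raise SessionValidationError("word_code: must be shared or independent")

    def fractions(self) -> dict[str, float]:
        if self.tuned_fraction is not None:
            return dict(self.tuned_fraction)
        if self.area == "S1":
            return {"speech": 1.0}
        return dict(ACTIVE_PHASES_DEFAULT)


def sample_population(
    spec: PopulationSpec, config: TaskConfig | None = None
) -> list[UnitGroundTruth]:
    """Draw a reproducible population of ground-truth units.

    For each phase with tuned fraction ``f``, exactly ``round(f * n_units)``
    units receive nonzero gain in that phase.  Tuned SMG units get an
    independent per-word gain magnitude; S1 units get one shared magnitude
    in the speech phase.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(spec.seed)
    baselines = rng.gamma(spec.baseline_shape, spec.baseline_scale, size=spec.n_units)
    units = [
        UnitGroundTruth(
            unit_id=f"{spec.area}_{i:03d}",
            area=spec.area,
            baseline_rate=float(baselines[i]),
            latency=spec.latency,
        )
        for i in range(spec.n_units)
    ]
    profiles: dict[int, np.ndarray] = {}  # per-unit word-gain profile (shared code)
    for phase, frac in spec.fractions().items():
        n_tuned = int(round(frac * spec.n_units))
        chosen = rng.choice(spec.n_units, size=n_tuned, replace=False)
        for i in chosen:
            u = units[i]
            if spec.area == "S1":
                g = float(abs(rng.normal(spec.effect_mean, spec.effect_sd)))
                g = max(g, 0.1 * spec.effect_mean) if spec.effect_mean > 0 else g
                for w in config.words:
                    u.gain.setdefault(w, {})["speech"] = g
                continue
            if spec.word_code == "shared" and i in profiles:
                mags = profiles[i]
            else:
                mags = np.abs(rng.normal(spec.effect_mean, spec.effect_sd, config.n_words))
                if spec.effect_mean > 0 and mags.max() < 1e-6:
                    mags[int(np.argmax(mags))] = spec.effect_mean
                profiles[i] = mags
            for w, g in zip(config.words, mags):
                u.gain.setdefault(w, {})[phase] = float(g)
    if spec.modality_effect > 0 and spec.area == "SMG":
        for u in units:
            for m in config.cue_modalities:
                u.modality_gain[m] = float(rng.normal(0.0, spec.modality_effect))
    return units


def _sample_piecewise_poisson(
    segments: Sequence[tuple[float, float, float]], rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Sample one spike train from a piecewise-constant-rate Poisson process.

    ``segments`` are (start, stop, rate) triples; negative rates are clipped
    at zero and counted.  Returns sorted spike times and the clip count.
    """
    times = []
    clipped = 0
    for start, stop, rate in segments:
        dur = stop - start
        if dur <= 0:
            continue
        if rate < 0:
            rate = 0.0
            clipped += 1
        if rate == 0:
            continue
        n = rng.poisson(rate * dur)
        if n:
            times.append(start + dur * rng.random(n))
    if not times:
        return np.empty(0), clipped
    return np.sort(np.concatenate(times)), clipped


def _trial_segments(
    unit: UnitGroundTruth,
    word: str,
    modality: str,
    audio_onset: float | None,
    config: TaskConfig,
) -> list[tuple[float, float, float]]:
    """Piecewise-constant rate profile of one unit over one trial."""
    boundaries = {0.0, config.trial_duration}
    intervals = config.phase_intervals
    events: list[tuple[float, float, float]] = []  # (start, stop, delta rate)
    for phase, (a, b) in intervals.items():
        g = unit.gain_at(word, phase)
        if phase == "cue":
            g += unit.modality_gain.get(modality, 0.0)
        if g == 0.0:
            continue
        start = a + unit.latency
        if phase == "cue" and modality == "auditory" and audio_onset is not None:
            start = a + audio_onset + unit.latency
        start = min(start, b)
        events.append((start, b, g))
        boundaries.update((start, b))
    cuts = sorted(boundaries)
    segments = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        rate = unit.baseline_rate
        for a, b, g in events:
            if a <= s and e <= b:
                rate += g
        segments.append((s, e, rate))
    return segments


def simulate_session(
    population: Sequence[UnitGroundTruth],
    config: TaskConfig,
    n_reps: int = 8,
    cue_modalities: Sequence[str] | None = None,
    seed: int = 0,
    session_id: str = "sim-000",
) -> tuple[pd.DataFrame, SpikeData, dict]:
    """Simulate one session: ``n_reps x W x |modalities|`` randomized trials.

    Returns the trial table, spike data and a ground-truth dict (population
    parameters, spec echo, clip count) suitable for a JSON sidecar.
    """
    if n_reps < 1:
        raise SessionValidationError("n_reps: must be >= 1")
    cue_modalities = tuple(cue_modalities or config.cue_modalities)
    rng = np.random.default_rng(seed)
    conditions = [(w, m) for m in cue_modalities for w in config.words for _ in range(n_reps)]
    order = rng.permutation(len(conditions))
    onsets = config.phase_onsets
    lo, hi = config.audio_onset_range
    rows = []
    for tid, idx in enumerate(order):
        word, modality = conditions[idx]
        row = {
            "trial_id": tid,
            "session_id": session_id,
            "word": word,
            "cue_modality": modality,
            "audio_onset": rng.uniform(lo, hi) if modality == "auditory" else np.nan,
            "error_kind": "none",
        }
        row.update({f"onset_{p}": onsets[p] for p in config.phase_names})
        rows.append(row)
    trials = make_trial_table(rows)

    trains: dict[tuple[str, int], np.ndarray] = {}
    n_clipped = 0
    for unit in population:
        for row in rows:
            audio = row["audio_onset"]
            segs = _trial_segments(
                unit,
                row["word"],
                row["cue_modality"],
                None if np.isnan(audio) else float(audio),
                config,
            )
            spikes, clipped = _sample_piecewise_poisson(segs, rng)
            n_clipped += clipped
            trains[(unit.unit_id, row["trial_id"])] = spikes
    units = pd.DataFrame(
        [{"unit_id": u.unit_id, "area": u.area} for u in population]
    ).sort_values("unit_id").reset_index(drop=True)
    ground_truth = {
        "session_id": session_id,
        "seed": int(seed),
        "n_reps": int(n_reps),
        "cue_modalities": list(cue_modalities),
        "clipped_segments": int(n_clipped),
        "population": [u.to_dict() for u in population],
    }
    return trials, SpikeData(units=units, trains=trains), ground_truth


def inject_errors(
    trials: pd.DataFrame,
    p_spoke_during_internal: float = 0.0,
    p_wrong_word_vocalized: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag error trials by independent Bernoulli draws (reproducible).

    If both kinds fire on a trial, spoke_during_internal takes precedence
    (it occurs earlier in the trial).
    """
    for p in (p_spoke_during_internal, p_wrong_word_vocalized):
        if not 0 <= p <= 1:
            raise SessionValidationError("error probabilities must be in [0,1]")
    rng = np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    spoke = rng.random(n) < p_spoke_during_internal
    wrong = rng.random(n) < p_wrong_word_vocalized
    kind = np.where(spoke, "spoke_during_internal", np.where(wrong, "wrong_word_vocalized", "none"))
    out["error_kind"] = kind
    return out
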