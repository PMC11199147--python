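"""Canonical data model for one recording (or simulated) session.

A session consists of a :class:`TaskConfig` describing the word list and
trial structure, a trial table (one row per trial), and per-unit, per-trial
spike timestamps.  All times are in seconds, trial-relative, with 0 at ITI
onset; intervals are half-open ``[onset, offset)``.

The six task phases are, in order: ITI (inter-trial interval), cue
(auditory or written word presentation), D1 (delay), internal (silent
production of the cued word), D2 (delay), speech (vocalized production).

On-disk format is a single HDF5 archive (``/config`` JSON attribute,
``/trials`` columnar table, ``/units/<id>/spikes/<trial_id>`` datasets).
A plain-text fallback dialect is available via :func:`export_trials_csv`
and :func:`export_config_json` (one CSV trial table with columns
``trial_id, session_id, word, cue_modality, onset_<phase>..., audio_onset,
error_kind`` plus one JSON config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

PHASES = ("ITI", "cue", "D1", "internal", "D2", "speech")
#: Rest/action pairing used for phase-comparison statistics.
REST_PHASES = ("ITI", "D1", "D2")
ACTION_PHASES = ("cue", "internal", "speech")

DEFAULT_WORDS = (
    "battlefield",
    "cowboy",
    "python",
    "spoon",
    "swimming",
    "telephone",
    "bindip",
    "nifzig",
)

DEFAULT_PHASE_DURATIONS = (2.0, 1.5, 0.5, 1.5, 0.5, 1.5)

ERROR_KINDS = ("none", "spoke_during_internal", "wrong_word_vocalized")

TRIAL_COLUMNS = (
    "trial_id",
    "session_id",
    "word",
    "cue_modality",
    *[f"onset_{p}" for p in PHASES],
    "audio_onset",
    "error_kind",
)


class SessionValidationError(ValueError):
    """Raised when a session object violates a documented invariant."""


@dataclass(frozen=True)
class TaskConfig:
    """Word list, phase timing and rate-estimation parameters for a task.

    Defaults reproduce the eight-word, six-phase task: six lexical words
    plus two pseudowords, phases of (2.0, 1.5, 0.5, 1.5, 0.5, 1.5) s,
    50-ms rate bins and a 50-ms Gaussian smoothing kernel, and auditory
    cue onsets 200-650 ms into the cue phase.
    """

    words: tuple[str, ...] = DEFAULT_WORDS
    phase_names: tuple[str, ...] = PHASES
    phase_durations: tuple[float, ...] = DEFAULT_PHASE_DURATIONS
    cue_modalities: tuple[str, ...] = ("auditory", "written")
    bin_width: float = 0.05
    kernel_width: float = 0.05
    audio_onset_range: tuple[float, float] = (0.200, 0.650)

    def __post_init__(self) -> None:
        if len(self.words) < 2:
            raise SessionValidationError("words: need at least 2 word labels")
        if len(set(self.words)) != len(self.words):
            raise SessionValidationError("words: labels must be unique")
        if len(self.phase_names) != len(self.phase_durations):
            raise SessionValidationError(
                "phase_durations: length must match phase_names"
            )
        if any(d <= 0 for d in self.phase_durations):
            raise SessionValidationError("phase_durations: must be > 0")
        if self.bin_width <= 0:
            raise SessionValidationError("bin_width: must be > 0")
        if self.kernel_width <= 0:
            raise SessionValidationError("kernel_width: must be > 0")
        lo, hi = self.audio_onset_range
        if not (0 <= lo <= hi):
            raise SessionValidationError("audio_onset_range: need 0 <= min <= max")
        for name, dur in zip(self.phase_names, self.phase_durations):
            # bin_width must divide each phase to within one bin: every phase
            # needs at least one full bin of coverage.
            if dur / self.bin_width < 1 - 1e-9:
                raise SessionValidationError(
                    f"bin_width larger than phase {name!r} duration"
                )
        if not set(self.cue_modalities) <= {"auditory", "written"}:
            raise SessionValidationError(
                "cue_modalities: must be a subset of {auditory, written}"
            )

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def trial_duration(self) -> float:
        return float(sum(self.phase_durations))

    @property
    def phase_onsets(self) -> dict[str, float]:
        """Phase onset times (s) relative to trial start."""
        onsets = {}
        t = 0.0
        for name, dur in zip(self.phase_names, self.phase_durations):
            onsets[name] = t
            t += dur
        return onsets

    @property
    def phase_intervals(self) -> dict[str, tuple[float, float]]:
        onsets = self.phase_onsets
        return {
            name: (onsets[name], onsets[name] + dur)
            for name, dur in zip(self.phase_names, self.phase_durations)
        }

    @property
    def n_bins(self) -> int:
        return int(round(self.trial_duration / self.bin_width))

    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    def phase_bin_slices(self) -> dict[str, slice]:
        """Bins per phase: every bin whose left edge lies in [onset, offset)."""
        edges = self.bin_edges()[:-1]
        out = {}
        for name, (a, b) in self.phase_intervals.items():
            inside = (edges >= a - 1e-9) & (edges < b - 1e-9)
            idx = np.nonzero(inside)[0]
            out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "words": list(self.words),
            "phase_names": list(self.phase_names),
            "phase_durations": list(self.phase_durations),
            "cue_modalities": list(self.cue_modalities),
            "bin_width": self.bin_width,
            "kernel_width": self.kernel_width,
            "audio_onset_range": list(self.audio_onset_range),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskConfig":
        version = d.get("schema_version", SCHEMA_VERSION)
        if str(version) != SCHEMA_VERSION:
            raise SessionValidationError(
                f"schema_version mismatch: archive {version!r}, expected {SCHEMA_VERSION!r}"
            )
        return cls(
            words=tuple(d["words"]),
            phase_names=tuple(d["phase_names"]),
            phase_durations=tuple(float(x) for x in d["phase_durations"]),
            cue_modalities=tuple(d["cue_modalities"]),
            bin_width=float(d["bin_width"]),
            kernel_width=float(d["kernel_width"]),
            audio_onset_range=tuple(float(x) for x in d["audio_onset_range"]),
        )


def make_trial_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Build a trial table DataFrame with the canonical column order."""
    df = pd.DataFrame(list(rows))
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            if col == "audio_onset":
                df[col] = np.nan
            elif col == "error_kind":
                df[col] = "none"
            else:
                raise SessionValidationError(f"trial table missing column {col!r}")
    return df[list(TRIAL_COLUMNS)].reset_index(drop=True)


def validate_trials(trials: pd.DataFrame, config: TaskConfig) -> None:
    """Check trial-table invariants against a config; raise on violation."""
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise SessionValidationError(f"trial table missing column {col!r}")
    bad_words = set(trials["word"]) - set(config.words)
    if bad_words:
        raise SessionValidationError(
            f"word: labels not in config.words: {sorted(bad_words)}"
        )
    bad_mod = set(trials["cue_modality"]) - set(config.cue_modalities)
    if bad_mod:
        raise SessionValidationError(
            f"cue_modality: labels not in config.cue_modalities: {sorted(bad_mod)}"
        )
    bad_err = set(trials["error_kind"]) - set(ERROR_KINDS)
    if bad_err:
        raise SessionValidationError(f"error_kind: unknown kinds {sorted(bad_err)}")
    if trials["trial_id"].duplicated().any():
        raise SessionValidationError("trial_id: duplicated trial ids")
    onset_cols = [f"onset_{p}" for p in config.phase_names]
    onsets = trials[onset_cols].to_numpy(float)
    if not (np.diff(onsets, axis=1) > 0).all():
        raise SessionValidationError("phase_onsets: must be strictly increasing")
    aud = trials["cue_modality"] == "auditory"
    if aud.any() and trials.loc[aud, "audio_onset"].isna().any():
        raise SessionValidationError("audio_onset: missing on an auditory trial")


def repetition_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Repetition count per (session_id, word, cue_modality)."""
    return (
        trials.groupby(["session_id", "word", "cue_modality"], sort=True)
        .size()
        .rename("n_reps")
        .reset_index()
    )


@dataclass
class SpikeData:
    """Per-unit, per-trial spike timestamps (seconds, trial-relative).

    ``units`` carries one row per unit (``unit_id``, ``area``); ``trains``
    maps ``(unit_id, trial_id)`` to a sorted float array of spike times.
    The unit roster is identical across trials of a session.
    """

    units: pd.DataFrame
    trains: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units["unit_id"])

    def spike_times(self, unit_id: str, trial_id: int) -> np.ndarray:
        return self.trains[(unit_id, int(trial_id))]

    def validate(self, trials: pd.DataFrame, config: TaskConfig) -> None:
        dur = config.trial_duration
        trial_ids = list(trials["trial_id"])
        for uid in self.unit_ids:
            for tid in trial_ids:
                key = (uid, int(tid))
                if key not in self.trains:
                    raise SessionValidationError(
                        f"spike_times: missing train for unit {uid!r} trial {tid}"
                    )
                t = np.asarray(self.trains[key], float)
                if t.size and (np.diff(t) < 0).any():
                    raise SessionValidationError(
                        f"spike_times: unsorted for unit {uid!r} trial {tid}"
                    )
                if t.size and (t[0] < 0 or t[-1] > dur + 1e-9):
                    raise SessionValidationError(
                        f"spike_times: outside [0, {dur}] for unit {uid!r} trial {tid}"
                    )

    def subset_trials(self, trial_ids: Iterable[int]) -> "SpikeData":
        keep = {int(t) for t in trial_ids}
        trains = {k: v for k, v in self.trains.items() if k[1] in keep}
        return SpikeData(units=self.units.copy(), trains=trains)


def write_session(
    path,
    config: TaskConfig,
    trials: pd.DataFrame,
    spikes: SpikeData,
    ground_truth: dict | None = None,
) -> None:
    """Write a validated session to a self-describing HDF5 archive.

    Integers and labels round-trip bit-exactly; times at full float64
    precision.  ``ground_truth`` (a JSON-serializable dict, e.g. simulator
    output) is stored alongside for parameter-recovery tests.
    """
    validate_trials(trials, config)
    spikes.validate(trials, config)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config_json"] = json.dumps(config.to_dict())
        if ground_truth is not None:
            f.attrs["ground_truth_json"] = json.dumps(ground_truth)
        g = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            vals = trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                as_str = np.array([str(v) for v in vals], dtype=object)
                g.create_dataset(col, data=as_str, dtype=str_dt)
            else:
                g.create_dataset(col, data=vals)
        gu = f.create_group("units")
        for _, row in spikes.units.iterrows():
            uid = str(row["unit_id"])
            grp = gu.create_group(uid)
            grp.attrs["area"] = str(row["area"])
            gs = grp.create_group("spikes")
            for tid in trials["trial_id"]:
                gs.create_dataset(
                    str(int(tid)),
                    data=np.asarray(spikes.trains[(uid, int(tid))], float),
                )


def read_session(path) -> tuple[TaskConfig, pd.DataFrame, SpikeData, dict | None]:
    """Read and validate a session archive written by :func:`write_session`.

    Returns ``(config, trials, spikes, ground_truth)`` where ground truth is
    ``None`` unless a simulator sidecar was stored.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if str(version) != SCHEMA_VERSION:
            raise SessionValidationError(
                f"schema_version mismatch: archive {version!r}, expected {SCHEMA_VERSION!r}"
            )
        config = TaskConfig.from_dict(json.loads(f.attrs["config_json"]))
        gt = None
        if "ground_truth_json" in f.attrs:
            gt = json.loads(f.attrs["ground_truth_json"])
        g = f["trials"]
        data = {}
        for col in TRIAL_COLUMNS:
            if col not in g:
                raise SessionValidationError(f"archive missing column {col!r}")
            vals = g[col][()]
            if vals.dtype.kind in "OS":
                vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
            data[col] = vals
        trials = pd.DataFrame(data)[list(TRIAL_COLUMNS)]
        trials["trial_id"] = trials["trial_id"].astype(int)
        units_rows = []
        trains: dict[tuple[str, int], np.ndarray] = {}
        for uid in f["units"]:
            grp = f["units"][uid]
            units_rows.append({"unit_id": uid, "area": str(grp.attrs["area"])})
            for tid in grp["spikes"]:
                trains[(uid, int(tid))] = grp["spikes"][tid][()].astype(float)
        units = pd.DataFrame(units_rows).sort_values("unit_id").reset_index(drop=True)
        spikes = SpikeData(units=units, trains=trains)
    validate_trials(trials, config)
    spikes.validate(trials, config)
    return config, trials, spikes, gt


def exclude_error_trials(
    trials: pd.DataFrame, spikes: SpikeData | None = None
) -> tuple[pd.DataFrame, SpikeData | None, dict]:
    """Drop error trials (kept in archives, removed only at analysis time).

    Returns the retained trials, consistently filtered spikes, and a report
    with per-kind exclusion counts.  Idempotent; an empty result is allowed
    and flagged in the report.
    """
    counts = trials.loc[trials["error_kind"] != "none", "error_kind"].value_counts()
    keep = trials["error_kind"] == "none"
    kept = trials.loc[keep].reset_index(drop=True)
    report = {
        "n_input": int(len(trials)),
        "n_retained": int(len(kept)),
        "excluded": {str(k): int(v) for k, v in counts.items()},
        "empty_result": bool(len(kept) == 0),
    }
    missing_words = set(trials["word"]) - set(kept["word"])
    if missing_words:
        report["words_lost"] = sorted(missing_words)
    out_spikes = spikes.subset_trials(kept["trial_id"]) if spikes is not None else None
    return kept, out_spikes, report


def export_trials_csv(trials: pd.DataFrame, path) -> None:
    """CSV fallback dialect for the trial table."""
    trials[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def export_config_json(config: TaskConfig, path) -> None:
    """JSON fallback dialect for the task config."""
    with open(path, "w") as f:
        json.dump(config.to_dict(), f, indent=2)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SessionValidationError(f"trial CSV missing columns {missing}")
    return df[list(TRIAL_COLUMNS)]
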