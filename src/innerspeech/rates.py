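"""Firing-rate estimation: binned counts, Gaussian smoothing, alignment,
and per-phase averages.

Instantaneous rates are spike counts in fixed-width bins (default 50 ms)
divided by the bin width, optionally smoothed with a Gaussian kernel whose
width (default 50 ms) is interpreted as the standard deviation, truncated
at +/-4 sigma and renormalized.  Edge handling is reflection padding so
constant signals stay constant at trial boundaries.  Smoothing is applied
across the whole trial before any phase slicing or alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .session import SessionValidationError, SpikeData, TaskConfig


@dataclass
class RateTensor:
    """Trials x units x time-bins firing rates (spikes/s) with bin metadata."""

    values: np.ndarray
    bin_edges: np.ndarray
    trial_ids: np.ndarray
    unit_ids: list[str]
    alignment: str = "trial_start"
    smoothed: bool = False
    kernel_width: float | None = None
    #: seconds of cue phase covered for every trial after audio alignment
    common_coverage: float | None = None

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def trial_index(self, trial_id: int) -> int:
        idx = np.nonzero(self.trial_ids == trial_id)[0]
        if idx.size == 0:
            raise KeyError(f"trial_id {trial_id} not in tensor")
        return int(idx[0])


@dataclass
class PhaseRates:
    """Per-phase trial x unit mean rates with trial labels carried alongside.

    ``rates[phase]`` has shape (n_trials, n_units); ``labels`` has one row
    per trial (same order in every phase) with word and cue modality.
    """

    rates: dict[str, np.ndarray]
    labels: pd.DataFrame
    unit_ids: list[str]

    @property
    def phases(self) -> list[str]:
        return list(self.rates)

    def matrix(self, phase: str) -> np.ndarray:
        return self.rates[phase]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (trial, unit, phase)."""
        rows = []
        for phase, mat in self.rates.items():
            for i, (_, lab) in enumerate(self.labels.iterrows()):
                for j, uid in enumerate(self.unit_ids):
                    rows.append(
                        {
                            "trial_id": lab["trial_id"],
                            "unit_id": uid,
                            "phase": phase,
                            "rate": mat[i, j],
                        }
                    )
        return pd.DataFrame(rows)


def bin_spike_counts(
    spikes: SpikeData, trials: pd.DataFrame, config: TaskConfig
) -> RateTensor:
    """Bin spike counts: ``values[t,u,b] = #spikes in [edge_b, edge_b+1) / width``."""
    edges = config.bin_edges()
    trial_ids = trials["trial_id"].to_numpy(int)
    unit_ids = spikes.unit_ids
    values = np.zeros((len(trial_ids), len(unit_ids), len(edges) - 1))
    dur = config.trial_duration
    for i, tid in enumerate(trial_ids):
        for j, uid in enumerate(unit_ids):
            t = spikes.trains[(uid, int(tid))]
            if t.size and (t.min() < 0 or t.max() > dur + 1e-9):
                raise SessionValidationError(
                    f"spike outside trial bounds: unit {uid!r} trial {tid}"
                )
            counts, _ = np.histogram(t, edges)
            values[i, j] = counts / config.bin_width
    return RateTensor(
        values=values,
        bin_edges=edges,
        trial_ids=trial_ids,
        unit_ids=list(unit_ids),
    )


def smooth_rates(rates: RateTensor, kernel_width: float | None = None) -> RateTensor:
    """Smooth along time with a normalized Gaussian (sigma = kernel_width).

    Mass-preserving for interior impulses; reflection padding at the trial
    boundaries keeps constant signals exactly constant.
    """
    if rates.smoothed:
        raise SessionValidationError("rates already smoothed")
    width = kernel_width if kernel_width is not None else 0.05
    if width <= 0:
        raise SessionValidationError("kernel_width: must be > 0")
    sigma = width / rates.bin_width
    smoothed = gaussian_filter1d(
        rates.values, sigma=sigma, axis=2, mode="reflect", truncate=4.0
    )
    return replace(rates, values=smoothed, smoothed=True, kernel_width=width)


def align_to_audio_onset(
    rates: RateTensor, trials: pd.DataFrame, config: TaskConfig
) -> RateTensor:
    """Re-index cue-phase bins of auditory trials so bin 0 starts at audio onset.

    The audio onset is rounded to the nearest bin edge; the shifted cue block
    reads real bins from the following delay, so the tensor keeps uniform
    edges.  Non-auditory trials pass through unchanged.  ``common_coverage``
    on the result gives the seconds of cue phase observed for every trial
    (cue duration minus the largest shift); bins past it mix phases.
    """
    sl = config.phase_bin_slices()["cue"]
    bw = rates.bin_width
    values = rates.values.copy()
    max_shift = 0
    tid_to_row = {int(r["trial_id"]): r for _, r in trials.iterrows()}
    for i, tid in enumerate(rates.trial_ids):
        row = tid_to_row[int(tid)]
        if row["cue_modality"] != "auditory":
            continue
        audio = row["audio_onset"]
        if pd.isna(audio):
            raise SessionValidationError(
                f"audio_onset: missing on auditory trial {tid}"
            )
        shift = int(round(float(audio) / bw))
        if shift == 0:
            continue
        if sl.stop + shift > rates.n_bins:
            raise SessionValidationError(
                f"audio_onset shift exceeds trial bounds on trial {tid}"
            )
        max_shift = max(max_shift, shift)
        values[i, :, sl] = rates.values[i, :, sl.start + shift : sl.stop + shift]
    cue_duration = (sl.stop - sl.start) * bw
    return replace(
        rates,
        values=values,
        alignment="audio_onset",
        common_coverage=cue_duration - max_shift * bw,
    )


def phase_average(
    rates: RateTensor, trials: pd.DataFrame, config: TaskConfig
) -> PhaseRates:
    """Mean rate over each phase's bins, per trial and unit."""
    slices = config.phase_bin_slices()
    out = {}
    for phase, sl in slices.items():
        if sl.stop - sl.start == 0:
            raise SessionValidationError(f"phase {phase!r} has zero bins")
        out[phase] = rates.values[:, :, sl].mean(axis=2)
    order = {int(t): i for i, t in enumerate(rates.trial_ids)}
    labels = trials.copy()
    labels = labels.sort_values("trial_id", key=lambda s: s.map(order)).reset_index(drop=True)
    labels = labels[["trial_id", "word", "cue_modality"]]
    return PhaseRates(rates=out, labels=labels, unit_ids=list(rates.unit_ids))


def rate_tensor_to_hdf5(rates: RateTensor, path) -> None:
    """Export a RateTensor with dimension labels to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=rates.values)
        f.create_dataset("bin_edges", data=rates.bin_edges)
        f.create_dataset("trial_ids", data=rates.trial_ids)
        f.create_dataset(
            "unit_ids",
            data=np.array(rates.unit_ids, dtype=object),
            dtype=h5py.string_dtype("utf-8"),
        )
        f.attrs["alignment"] = rates.alignment
        f.attrs["smoothed"] = rates.smoothed
        f.attrs["dims"] = "trial,unit,bin"
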