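"""Filtering, epoching, variance-based rejection, homogeneous field
correction and radial-channel selection."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .forward import SensorArray
from .synth import Recording, TrialSet

log = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "RejectionReport",
    "bandpass",
    "narrowband",
    "segment_trials",
    "reject_bad_trials",
    "reject_bad_channels",
    "hfc_projector",
    "hfc",
    "select_radial",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase (two-pass) Butterworth band-pass."""

    low: float = 1.0
    high: float = 40.0
    order: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high < fs / 2:
            raise ValueError(f"band ({self.low}, {self.high}) invalid for fs={fs}")


def _apply_sos(data, spec: FilterSpec, fs: float):
    sos = signal.butter(spec.order, [spec.low, spec.high], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (spec.order + 1)
    return signal.sosfiltfilt(sos, data, axis=-1, padtype="odd", padlen=padlen)


def bandpass(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Forward-backward Butterworth filter (zero net phase shift)."""
    spec.validate(recording.fs)
    return recording.copy_with(_apply_sos(recording.data, spec, recording.fs))


def narrowband(recording: Recording, f0: float) -> Recording:
    """4 Hz-wide band around a stimulation frequency: [f0−2, f0+2] Hz."""
    if f0 <= 2.0:
        raise ValueError("narrowband centre frequency must exceed 2 Hz")
    return bandpass(recording, FilterSpec(f0 - 2.0, f0 + 2.0))


def segment_trials(recording: Recording, window: float) -> TrialSet:
    """Epoch [0, window) s after each event; truncated trials are dropped."""
    n_win = int(round(window * recording.fs))
    trials, conditions, dropped = [], [], 0
    for s0, code in recording.events:
        if s0 + n_win > recording.n_samples:
            dropped += 1
            continue
        trials.append(recording.data[:, s0 : s0 + n_win])
        conditions.append(code)
    if dropped:
        log.warning("dropped %d truncated trial(s) at recording end", dropped)
    if not trials:
        raise ValueError("no complete trials in recording")
    return TrialSet(np.stack(trials), conditions, recording.fs, np.arange(n_win) / recording.fs)


@dataclass
class RejectionReport:
    removed_trials: list = field(default_factory=list)
    removed_channels: list = field(default_factory=list)
    trial_variances: list = field(default_factory=list)
    threshold: float = float("nan")

    def to_json(self, path=None):
        d = dict(
            removed_trials=[int(i) for i in self.removed_trials],
            removed_channels=[str(c) for c in self.removed_channels],
            trial_variances=[float(v) for v in self.trial_variances],
            threshold=float(self.threshold),
        )
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def reject_bad_trials(trials: TrialSet):
    """Drop trials whose pooled variance exceeds mean + 3·sd of trial variances.

    The variance is pooled over channels and samples (one scalar per trial);
    the rule is applied in a single pass.
    """
    if trials.n_trials < 3:
        raise ValueError("need at least 3 trials for variance-based rejection")
    v = trials.data.var(axis=(1, 2))
    thr = v.mean() + 3.0 * v.std()
    bad = np.flatnonzero(v > thr)
    if len(bad) == trials.n_trials:
        raise ValueError("variance criterion removed every trial")
    keep = np.setdiff1d(np.arange(trials.n_trials), bad)
    report = RejectionReport(
        removed_trials=bad.tolist(), trial_variances=v.tolist(), threshold=float(thr)
    )
    out = TrialSet(
        trials.data[keep], [trials.conditions[i] for i in keep], trials.fs, trials.time
    )
    return out, report


def reject_bad_channels(trials: TrialSet, labels=None):
    """Same 3-sd variance rule applied across channels instead of trials."""
    v = trials.data.var(axis=(0, 2))
    thr = v.mean() + 3.0 * v.std()
    bad = np.flatnonzero(v > thr)
    keep = np.setdiff1d(np.arange(trials.data.shape[1]), bad)
    names = [labels[i] if labels else int(i) for i in bad]
    report = RejectionReport(removed_channels=names, threshold=float(thr))
    return TrialSet(trials.data[:, keep], trials.conditions, trials.fs, trials.time), report


def hfc_projector(array: SensorArray) -> np.ndarray:
    """Orthogonal projector removing any spatially uniform field.

    With N the channels×3 matrix of sensitive-axis unit vectors, a uniform
    field B appears as N·B across channels; the projector I − N·N⁺ annihilates
    that subspace exactly and leaves everything orthogonal to it untouched.
    """
    N = array.channel_axes
    if N.shape[0] < 4:
        raise ValueError("homogeneous field correction needs at least 4 channels")
    rank = np.linalg.matrix_rank(N)
    if rank < 3:
        warnings.warn(
            f"channel axes span only {rank} direction(s); projecting onto available rank",
            stacklevel=2,
        )
    return np.eye(N.shape[0]) - N @ np.linalg.pinv(N)


def hfc(data: np.ndarray, array: SensorArray) -> np.ndarray:
    """Apply homogeneous field correction to (n_channels, n_samples) data."""
    return hfc_projector(array) @ data


def select_radial(array: SensorArray, data: np.ndarray | None = None):
    """Keep, per site, the channel most nearly radial to the scalp.

    The outward scalp normal is the unit vector from the sphere centre
    (origin) to the site; the kept axis maximises |ô·n̂|.  Idempotent: a
    radial array is returned unchanged.
    """
    if array.n_axes == 1:
        return (array, data) if data is not None else (array, None)
    normals = array.site_positions / np.linalg.norm(array.site_positions, axis=1, keepdims=True)
    cosines = np.abs(np.einsum("sai,si->sa", array.site_triads, normals))
    best = cosines.argmax(axis=1)
    keep_axes = array.site_triads[np.arange(array.n_sites), best][:, None, :]
    idx = np.arange(array.n_sites) * array.n_axes + best
    sub = SensorArray(
        array.site_positions,
        keep_axes,
        system_tag=array.system_tag.replace("triaxial", "radial"),
        scalp_offset=array.scalp_offset,
        labels=tuple(array.labels[i] for i in idx),
    )
    return (sub, data[idx] if data is not None else None)
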