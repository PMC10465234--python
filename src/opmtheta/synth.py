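"""Synthetic multi-subject MEG sessions with known ground truth.

Generates everything the analysis pipeline consumes: helmet sensor arrays
(wearable triaxial magnetometer and cryogenic radial-gradiometer-like
layouts), current-dipole sources driving a steady-state visual paradigm and a
working-memory frontal-theta paradigm, sensor noise with a low-frequency
excess, spatially uniform interference, and movement artefact from rigid-body
head motion inside a static background field.

The defaults reproduce the study conditions: 58-site triaxial helmet (174
channels) and a 275-channel radial array; 1200 Hz sampling; 4/6/8 Hz visual
stimulation 2 s on / 2 s off, 40 trials per frequency; 20 s on / 20 s off
2-back blocks, 25 trials (1000 s); an empty-room noise floor averaging
16.5 fT/√Hz in theta (4–8 Hz) and 13.6 fT/√Hz in beta (13–30 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import DipoleSource, HeadModel, SensorArray, dipole_leadfield
from .nulling import StaticFieldModel

__all__ = [
    "Recording",
    "TrialSet",
    "MotionTrace",
    "NoiseSpec",
    "SessionTruth",
    "build_array",
    "gen_visual_source",
    "gen_nback_source",
    "gen_sensor_noise",
    "gen_uniform_interference",
    "gen_motion_trace",
    "gen_movement_artifact",
    "simulate_session",
    "gen_cohort",
]

#: fixed source placements (head frame, metres)
OCCIPITAL_POS = np.array([0.0, -0.06, 0.02])
FRONTAL_POS = np.array([0.0, 0.055, 0.035])

#: sensor-noise defaults; the OPM floor/knee are calibrated so that the
#: band-mean amplitude spectral density is 16.5 fT/√Hz over 4–8 Hz and
#: 13.6 fT/√Hz over 13–30 Hz.
OPM_NOISE_FLOOR_FT = 12.2589
OPM_NOISE_KNEE_HZ = 4.7039
SQUID_NOISE_FLOOR_FT = 8.0


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor-noise amplitude spectral density: floor·sqrt(1 + (knee/f)^exp)."""

    floor_fT: float = OPM_NOISE_FLOOR_FT
    knee_hz: float = OPM_NOISE_KNEE_HZ
    exponent: float = 1.0
    per_channel_independent: bool = True

    def __post_init__(self):
        if self.floor_fT <= 0:
            raise ValueError("noise floor must be positive")
        if self.knee_hz < 0:
            raise ValueError("knee frequency must be non-negative")

    def asd_tesla(self, f):
        """Target ASD in tesla/√Hz; the 1/f term is capped below 0.05 Hz."""
        f = np.maximum(np.asarray(f, float), 0.05)
        return self.floor_fT * 1e-15 * np.sqrt(1.0 + (self.knee_hz / f) ** self.exponent)

    @classmethod
    def opm_default(cls) -> "NoiseSpec":
        return cls()

    @classmethod
    def squid_default(cls) -> "NoiseSpec":
        return cls(floor_fT=SQUID_NOISE_FLOOR_FT, knee_hz=0.0)


@dataclass
class Recording:
    """Continuous sensor recording: (n_channels, n_samples) in tesla."""

    data: np.ndarray
    fs: float
    events: list  # [(sample_index, condition_code), ...]
    array: SensorArray

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        n = self.data.shape[1]
        for s, _c in self.events:
            if not 0 <= s < n:
                raise ValueError("event sample index out of range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data) -> "Recording":
        return Recording(data, self.fs, list(self.events), self.array)

    def save(self, prefix) -> None:
        np.save(f"{prefix}.npy", self.data)
        meta = dict(
            fs=self.fs,
            events=[[int(s), str(c)] for s, c in self.events],
            system_tag=self.array.system_tag,
            labels=list(self.array.labels),
        )
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh)
        pd.DataFrame(
            [(int(s), str(c)) for s, c in self.events], columns=["sample", "code"]
        ).to_csv(f"{prefix}_events.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, prefix) -> "Recording":
        data = np.load(f"{prefix}.npy")
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        array = build_array(meta["system_tag"])
        events = [(int(s), str(c)) for s, c in meta["events"]]
        return cls(data, meta["fs"], events, array)


@dataclass
class TrialSet:
    """Epoched data: (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    conditions: list
    fs: float
    time: np.ndarray  # seconds, relative to trial onset

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("trial data must be (n_trials, n_channels, n_samples)")
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("one condition per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class MotionTrace:
    """Rigid-body pose per sample: rotation matrices and translations."""

    rotations: np.ndarray  # (n_samples, 3, 3)
    translations: np.ndarray  # (n_samples, 3), metres
    fs: float

    def __post_init__(self):
        R = np.asarray(self.rotations, float)
        gram = np.einsum("tij,tik->tjk", R, R)
        if np.max(np.abs(gram - np.eye(3))) > 1e-10:
            raise ValueError("rotations must be orthonormal")
        if np.max(np.abs(R[0] - np.eye(3))) > 1e-10 or np.max(np.abs(self.translations[0])) > 0:
            raise ValueError("pose at t=0 must be the identity")
        self.rotations = R
        self.translations = np.asarray(self.translations, float)

    @property
    def n_samples(self) -> int:
        return self.rotations.shape[0]


def build_array(
    mode: str,
    n_sites: int | None = None,
    scalp_offset: float | None = None,
    scalp_radius: float = 0.09,
    seed=None,
) -> SensorArray:
    """Quasi-uniform helmet array on the upper part of a sphere.

    Sites are placed by a Fibonacci lattice over the spherical cap covering
    the upper ~65 % of the sphere of radius ``scalp_radius + scalp_offset``;
    triaxial mode emits a radial plus two tangential axes per site.  The
    layout is deterministic; ``seed`` is accepted for interface uniformity.
    """
    defaults = {
        "opm_triaxial": (58, 0.0065, 3),
        "opm_radial": (58, 0.0065, 1),
        "squid_radial": (275, 0.04, 1),
    }
    if mode not in defaults:
        raise ValueError(f"unknown array mode: {mode!r}")
    d_sites, d_off, n_axes = defaults[mode]
    n_sites = d_sites if n_sites is None else int(n_sites)
    scalp_offset = d_off if scalp_offset is None else float(scalp_offset)
    if n_sites < 4:
        raise ValueError("need at least 4 sites")
    radius = scalp_radius + scalp_offset

    i = np.arange(n_sites)
    cap = 0.65  # fraction of the sphere's area covered, from the +z pole down
    z = 1.0 - (i + 0.5) / n_sites * 2.0 * cap
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    normals = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    positions = radius * normals

    zhat = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(np.broadcast_to(zhat, normals.shape), normals)
    small = np.linalg.norm(t1, axis=1) < 1e-8
    t1[small] = [1.0, 0.0, 0.0]
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)
    if n_axes == 3:
        triads = np.stack([normals, t1, t2], axis=1)
    else:
        triads = normals[:, None, :]
    return SensorArray(positions, triads, system_tag=mode, scalp_offset=scalp_offset)


def _tangential_unit(position) -> np.ndarray:
    n = np.asarray(position, float)
    n = n / np.linalg.norm(n)
    t = np.cross([0.0, 0.0, 1.0], n)
    if np.linalg.norm(t) < 1e-8:
        t = np.array([1.0, 0.0, 0.0])
    return t / np.linalg.norm(t)


def gen_visual_source(
    fs: float = 1200.0,
    n_trials_per_freq: int = 40,
    freqs=(4.0, 6.0, 8.0),
    on: float = 2.0,
    off: float = 2.0,
    amplitude_nAm: float = 8.0,
    harmonic_weights=(1.0, 0.25),
    position=OCCIPITAL_POS,
    orientation=None,
    seed=None,
):
    """Steady-state visual dipole: harmonic series at the trial frequency,
    gated on during the on-window; trials in pseudorandom order.

    Returns ``(DipoleSource, events)`` with one event (onset sample, "f<freq>")
    per trial.
    """
    rng = np.random.default_rng(seed)
    for f0 in freqs:
        if f0 >= fs / 2:
            raise ValueError("stimulation frequency must be below Nyquist")
    order = np.repeat(np.asarray(freqs, float), n_trials_per_freq)
    rng.shuffle(order)
    trial_len = int(round((on + off) * fs))
    on_len = int(round(on * fs))
    n_total = trial_len * len(order)
    moment = np.zeros(n_total)
    events = []
    t_on = np.arange(on_len) / fs
    for k, f0 in enumerate(order):
        s0 = k * trial_len
        wave = np.zeros(on_len)
        for h, w in enumerate(harmonic_weights, start=1):
            wave += w * np.sin(2 * np.pi * h * f0 * t_on)
        moment[s0 : s0 + on_len] = amplitude_nAm * wave
        events.append((s0, f"f{f0:g}"))
    ori = _tangential_unit(position) if orientation is None else orientation
    src = DipoleSource(position, ori, moment, fs)
    return src, events


def _bandlimited_noise(rng, n, fs, band):
    """Unit-variance Gaussian noise with spectral support exactly in ``band``."""
    lo, hi = band
    x = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, 1 / fs)
    spec = np.fft.rfft(x)
    spec[(f < lo) | (f > hi)] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def gen_nback_source(
    fs: float = 1200.0,
    n_trials: int = 25,
    on: float = 20.0,
    off: float = 20.0,
    band=(4.0, 8.0),
    rel_amplitude_increase: float = 0.5,
    subject_scale: float = 1.0,
    amplitude_nAm: float = 3.0,
    position=FRONTAL_POS,
    orientation=None,
    seed=None,
):
    """Frontal-midline theta dipole: band-limited 4–8 Hz noise whose envelope
    is (1 + rel_amplitude_increase) during task blocks.

    Returns ``(DipoleSource, events)``; events mark task onsets, and the trial
    window is [0, on+off) so the task occupies [0, on) and rest [on, on+off).
    """
    if rel_amplitude_increase < 0:
        raise ValueError("rel_amplitude_increase must be non-negative")
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError("theta band must lie inside (0, fs/2)")
    rng = np.random.default_rng(seed)
    trial_len = int(round((on + off) * fs))
    on_len = int(round(on * fs))
    n_total = trial_len * n_trials
    carrier = _bandlimited_noise(rng, n_total, fs, band)
    envelope = np.ones(n_total)
    events = []
    for k in range(n_trials):
        s0 = k * trial_len
        envelope[s0 : s0 + on_len] = 1.0 + rel_amplitude_increase
        events.append((s0, "nback"))
    moment = amplitude_nAm * subject_scale * carrier * envelope
    ori = _tangential_unit(position) if orientation is None else orientation
    src = DipoleSource(position, ori, moment, fs)
    return src, events


def gen_sensor_noise(array: SensorArray, fs, duration, spec: NoiseSpec, seed=None):
    """Independent per-channel noise shaped to the spec's ASD (tesla)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    white = rng.standard_normal((array.n_channels, n))
    f = np.fft.rfftfreq(n, 1 / fs)
    # unit-variance white noise has one-sided ASD sqrt(2/fs)
    gain = spec.asd_tesla(f) / np.sqrt(2.0 / fs)
    gain[0] = 0.0
    spec_w = np.fft.rfft(white, axis=1) * gain
    return np.fft.irfft(spec_w, n=n, axis=1)


def gen_uniform_interference(
    array: SensorArray,
    fs,
    duration,
    drift_asd_fT: float = 1000.0,
    cutoff: float = 3.0,
    broadband_asd_fT: float = 5.0,
    seed=None,
):
    """Spatially uniform interference field projected on each channel's axis.

    A single 3-vector time series B(t) gives channel i the value ô_i·B(t);
    channels sharing an axis direction therefore receive identical
    interference, and the channel vector always lies in the 3-dimensional
    span of the axis matrix.  The spectrum has two parts: strong slow drifts
    (``drift_asd_fT`` per component below ``cutoff``, e.g. passing vehicles)
    and a small broadband spatially-uniform floor (``broadband_asd_fT``)
    standing for remnant shielded-room interference; at the defaults well
    over 99 % of the power sits below the cutoff.
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    white = rng.standard_normal((3, n))
    f = np.fft.rfftfreq(n, 1 / fs)
    asd = np.where(f <= cutoff, drift_asd_fT, broadband_asd_fT) * 1e-15
    gain = asd / np.sqrt(2.0 / fs)
    gain[0] = 0.0
    B = np.fft.irfft(np.fft.rfft(white, axis=1) * gain, n=n, axis=1)  # (3, n)
    return array.channel_axes @ B


def gen_motion_trace(
    fs,
    duration,
    rot_rms_deg: float = 2.0,
    trans_rms_m: float = 0.005,
    cutoff_hz: float = 1.0,
    seed=None,
) -> MotionTrace:
    """Smooth random rigid-body motion, identity pose at t = 0."""
    from scipy.spatial.transform import Rotation

    from .nulling import _smooth_traces

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    ang = _smooth_traces(rng, 3, n, fs, cutoff_hz, np.deg2rad(rot_rms_deg), mode="rms")
    trans = _smooth_traces(rng, 3, n, fs, cutoff_hz, trans_rms_m, mode="rms")
    R = Rotation.from_euler("xyz", ang.T).as_matrix()
    return MotionTrace(R, trans.T, fs)


def gen_movement_artifact(
    array: SensorArray, field: StaticFieldModel, motion: MotionTrace, chunk: int = 100_000
):
    """Sensor signal caused by rigid motion through a static field.

    Channel i at time t measures (R(t)ô_i)·B(R(t)p_i + d(t)) − ô_i·B(p_i)
    with B(p) = B0 + G·p; the static term at the reference pose is subtracted
    so the artefact is zero for the identity pose.
    """
    P = array.channel_positions
    O = array.channel_axes
    static = np.einsum("ci,ci->c", O, field.field_at(P))
    n = motion.n_samples
    out = np.empty((array.n_channels, n))
    for s0 in range(0, n, chunk):
        s1 = min(n, s0 + chunk)
        R = motion.rotations[s0:s1]
        d = motion.translations[s0:s1]
        RP = np.einsum("tij,cj->tci", R, P) + d[:, None, :]
        RO = np.einsum("tij,cj->tci", R, O)
        B = field.B0 + RP @ field.G.T
        out[:, s0:s1] = (np.einsum("tci,tci->tc", RO, B) - static[None, :]).T
    return out


@dataclass
class SessionTruth:
    """Everything that determines a synthetic session, given the seed."""

    fs: float = 1200.0
    sources: list = field(default_factory=list)  # [(DipoleSource, events), ...]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    interference_asd_fT: float = 1000.0
    interference_cutoff_hz: float = 3.0
    interference_broadband_fT: float = 5.0
    static_field: StaticFieldModel | None = None
    motion: dict | None = None  # kwargs for gen_motion_trace, or None for a fixed head
    seed: int = 0

    @property
    def duration(self) -> float:
        if not self.sources:
            raise ValueError("session has no sources")
        return max(len(src.moment) for src, _e in self.sources) / self.fs


def simulate_session(truth: SessionTruth, head: HeadModel, array: SensorArray):
    """Forward-project sources and add noise, interference and movement.

    Returns ``(recording, empty_room)``: the empty-room twin shares the noise
    and interference specification (independent realisation) but omits the
    sources and the movement artefact.  Both are fully reproducible from
    ``truth.seed``.
    """
    for src, _ev in truth.sources:
        if src.fs != truth.fs:
            raise ValueError("source sampled at a different rate than the session")
    n = int(round(truth.duration * truth.fs))
    ss = np.random.SeedSequence(truth.seed)
    s_noise, s_intf, s_motion, s_noise_er, s_intf_er = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(5)
    ]

    data = np.zeros((array.n_channels, n))
    events = []
    for src, ev in truth.sources:
        lf = dipole_leadfield(head, array, src.position) @ src.orientation  # (n_ch,)
        m = src.moment
        data[:, : len(m)] += np.outer(lf, m)
        events.extend(ev)
    events.sort(key=lambda e: e[0])

    data += gen_sensor_noise(array, truth.fs, n / truth.fs, truth.noise, seed=s_noise)
    if truth.interference_asd_fT > 0:
        data += gen_uniform_interference(
            array,
            truth.fs,
            n / truth.fs,
            truth.interference_asd_fT,
            truth.interference_cutoff_hz,
            truth.interference_broadband_fT,
            seed=s_intf,
        )
    if truth.motion is not None and truth.static_field is not None:
        trace = gen_motion_trace(truth.fs, n / truth.fs, seed=s_motion, **truth.motion)
        data += gen_movement_artifact(array, truth.static_field, trace)

    empty = gen_sensor_noise(array, truth.fs, n / truth.fs, truth.noise, seed=s_noise_er)
    if truth.interference_asd_fT > 0:
        empty += gen_uniform_interference(
            array,
            truth.fs,
            n / truth.fs,
            truth.interference_asd_fT,
            truth.interference_cutoff_hz,
            truth.interference_broadband_fT,
            seed=s_intf_er,
        )
    return Recording(data, truth.fs, events, array), Recording(empty, truth.fs, [], array)


def subject_seed(master_seed: int, subject: int, stream: str) -> int:
    """Stable per-subject, per-stream seed below 2**31."""
    import zlib

    key = f"{master_seed}:{subject}:{stream}".encode()
    return zlib.crc32(key) % (2**31 - 1)


def gen_cohort(
    n_subjects: int = 14,
    task: str = "nback",
    master_seed: int = 0,
    position_jitter_m: float = 0.005,
    rel_increase_median: float = 0.5,
    rel_increase_sigma: float = 0.4,
    head: HeadModel | None = None,
    **task_kwargs,
):
    """Paired OPM/SQUID session truths for a synthetic cohort.

    Each subject's dipole geometry — position jittered around the canonical
    site and orientation drawn uniformly in the local tangent plane (cortical
    folding varies between people) — is shared between that subject's two
    sessions, giving fingerprinting a recoverable signature; for the theta
    task the task-related amplitude increase is drawn log-normal.
    Noise is independent per session; the SQUID twin uses the 275-channel
    radial array with a lower flat noise floor and a fixed head.
    """
    head = head or HeadModel()
    rng = np.random.default_rng(subject_seed(master_seed, 0, "cohort"))
    base_pos = FRONTAL_POS if task == "nback" else OCCIPITAL_POS
    subjects = []
    for s in range(n_subjects):
        jitter = rng.standard_normal(3) * position_jitter_m
        pos = base_pos + jitter
        r = np.linalg.norm(pos - head.centre)
        if r >= head.source_radius_max - 0.002:
            pos = head.centre + (pos - head.centre) * (head.source_radius_max - 0.002) / r
        rel = float(rel_increase_median * np.exp(rng.standard_normal() * rel_increase_sigma))
        t1 = _tangential_unit(pos)
        radial = (pos - head.centre) / np.linalg.norm(pos - head.centre)
        t2 = np.cross(radial, t1)
        ang = rng.uniform(0.0, 2 * np.pi)
        ori = np.cos(ang) * t1 + np.sin(ang) * t2
        ori /= np.linalg.norm(ori)
        sessions = {}
        for system, noise, motion in [
            ("opm", NoiseSpec.opm_default(), dict(rot_rms_deg=2.0)),
            ("squid", NoiseSpec.squid_default(), None),
        ]:
            seed = subject_seed(master_seed, s, system)
            src_seed = subject_seed(master_seed, s, f"source-{system}")
            if task == "nback":
                src, ev = gen_nback_source(
                    position=pos,
                    orientation=ori,
                    rel_amplitude_increase=rel,
                    seed=src_seed,
                    **task_kwargs,
                )
            else:
                src, ev = gen_visual_source(
                    position=pos, orientation=ori, seed=src_seed, **task_kwargs
                )
            sessions[system] = SessionTruth(
                fs=src.fs,
                sources=[(src, ev)],
                noise=noise,
                # the cryogenic reference is modelled as interference-clean
                # (its synthetic gradiometry is out of scope)
                interference_asd_fT=1000.0 if system == "opm" else 0.0,
                static_field=StaticFieldModel.from_nT([0.2, 0.1, 0.2]) if motion else None,
                motion=motion,
                seed=seed,
            )
        subjects.append(
            dict(subject=s, position=pos, orientation=ori, rel_increase=rel, sessions=sessions)
        )
    return subjects
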