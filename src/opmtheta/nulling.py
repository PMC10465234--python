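"""Static background-field estimation and iterative nulling.

Inside a magnetically shielded enclosure the remnant static field near the
head is well described by a first-order spherical-harmonic expansion: three
uniform components plus five independent linear gradients (the gradient
tensor of a source-free static field is symmetric and traceless).  A
bi-planar coil set can generate exactly these eight patterns, so estimating
them from measurements taken by tracked, moving sensors and driving the coils
with the negated estimate nulls the field; iterating improves the residual.

All fields are stored in tesla (gradients in tesla/metre); constructors and
reports in nT are provided for convenience.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StaticFieldModel",
    "NullingLog",
    "fit_static_field",
    "null_iteration",
    "run_nulling",
    "rotation_artifact",
]

_PARAM_NAMES = ("B0x", "B0y", "B0z", "Gxx", "Gyy", "Gxy", "Gxz", "Gyz")


@dataclass(frozen=True)
class StaticFieldModel:
    """Uniform field B0 (tesla) plus linear gradient tensor G (tesla/m).

    G is symmetric and traceless, so it carries five independent components
    (Gxx, Gyy, Gxy, Gxz, Gyz) with Gzz = −Gxx − Gyy.
    """

    B0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    G: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self):
        B0 = np.asarray(self.B0, float)
        G = np.asarray(self.G, float)
        if np.max(np.abs(G - G.T)) > 1e-15 * max(1.0, np.max(np.abs(G))):
            raise ValueError("gradient tensor must be symmetric")
        if abs(np.trace(G)) > 1e-12 * max(1.0, np.max(np.abs(G))):
            raise ValueError("gradient tensor must be traceless")
        object.__setattr__(self, "B0", B0)
        object.__setattr__(self, "G", G)

    @classmethod
    def from_params(cls, params) -> "StaticFieldModel":
        """Build from the 8-vector (B0x, B0y, B0z, Gxx, Gyy, Gxy, Gxz, Gyz)."""
        b = np.asarray(params, float)
        B0 = b[:3]
        gxx, gyy, gxy, gxz, gyz = b[3:]
        G = np.array([[gxx, gxy, gxz], [gxy, gyy, gyz], [gxz, gyz, -gxx - gyy]])
        return cls(B0, G)

    @classmethod
    def from_nT(cls, B0_nT, G_nT_per_m=None) -> "StaticFieldModel":
        G = np.zeros((3, 3)) if G_nT_per_m is None else np.asarray(G_nT_per_m, float) * 1e-9
        return cls(np.asarray(B0_nT, float) * 1e-9, G)

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [*self.B0, self.G[0, 0], self.G[1, 1], self.G[0, 1], self.G[0, 2], self.G[1, 2]]
        )

    def field_at(self, points) -> np.ndarray:
        """B(p) = B0 + G·p at one or many points (tesla)."""
        points = np.asarray(points, float)
        return self.B0 + points @ self.G.T

    @property
    def magnitude(self) -> float:
        """|B0| in tesla (the uniform-component magnitude)."""
        return float(np.linalg.norm(self.B0))

    @property
    def gradient_norm(self) -> float:
        return float(np.linalg.norm(self.G))

    def __sub__(self, other) -> "StaticFieldModel":
        return StaticFieldModel(self.B0 - other.B0, self.G - other.G)


def design_matrix(positions, orientations) -> np.ndarray:
    """Rows of the linear model m = ô·(B0 + G·p) over the 8 free parameters."""
    p = np.atleast_2d(np.asarray(positions, float))
    o = np.atleast_2d(np.asarray(orientations, float))
    ox, oy, oz = o[:, 0], o[:, 1], o[:, 2]
    px, py, pz = p[:, 0], p[:, 1], p[:, 2]
    return np.column_stack(
        [
            ox,
            oy,
            oz,
            ox * px - oz * pz,
            oy * py - oz * pz,
            ox * py + oy * px,
            ox * pz + oz * px,
            oy * pz + oz * py,
        ]
    )


def fit_static_field(positions, orientations, measurements):
    """Least-squares fit of the 8-parameter static field model.

    Parameters are flattened observations: ``positions``/``orientations``
    (n_obs, 3) give each sensor's tracked location and sensitive axis at the
    time of each scalar field ``measurement`` (tesla).

    Returns ``(model, residual_rms)``.  Raises if the pose diversity is
    insufficient (design matrix rank < 8), naming the deficient directions.
    """
    A = design_matrix(positions, orientations)
    m = np.asarray(measurements, float).ravel()
    if A.shape[0] < 8:
        raise ValueError("need at least 8 observations to fit the static field")
    if not np.any(m):
        return StaticFieldModel(), 0.0
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    tol = s[0] * max(A.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank < 8:
        null = vt[rank:]
        bad = [_PARAM_NAMES[i] for i in np.unique(np.argmax(np.abs(null), axis=1))]
        raise ValueError(
            "rank-deficient design (insufficient motion); "
            f"unconstrained directions involve: {', '.join(bad)}"
        )
    coef = vt.T @ ((u.T @ m) / s)
    resid = m - A @ coef
    return StaticFieldModel.from_params(coef), float(np.sqrt(np.mean(resid**2)))


@dataclass
class NullingLog:
    """Per-iteration record of the simulated nulling procedure."""

    entries: list = field(default_factory=list)

    def append(self, iteration, fitted, residual, fit_rms):
        self.entries.append(
            dict(
                iteration=iteration,
                fitted_B0_nT=list(fitted.B0 * 1e9),
                residual_B0_nT=list(residual.B0 * 1e9),
                residual_magnitude_nT=residual.magnitude * 1e9,
                residual_gradient_nT_per_m=residual.gradient_norm * 1e9,
                fit_residual_rms_fT=fit_rms * 1e15,
            )
        )

    def to_json(self, path=None):
        s = json.dumps(self.entries, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


# -- simulated nulling ------------------------------------------------------

#: default simulation knobs (see docs/methods.md for rationale)
DEFAULTS = dict(
    n_sites=5,
    duration=30.0,
    fs=1200.0,
    fit_decimate=10,
    rot_amplitude_deg=10.0,
    trans_amplitude_m=0.05,
    motion_cutoff_hz=1.0,
    measurement_noise_fT_rtHz=15.0,
    tracking_pos_rms_m=1e-4,
    tracking_ang_rms_deg=0.1,
    site_radius=0.1,
)


def _smooth_traces(rng, n_axes, n_samples, fs, cutoff, amplitude, mode="peak"):
    """Low-pass random trajectories anchored at zero at t = 0."""
    white = rng.standard_normal((n_axes, n_samples))
    f = np.fft.rfftfreq(n_samples, 1 / fs)
    spec = np.fft.rfft(white, axis=1)
    spec[:, f > cutoff] = 0.0
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    scale = np.max(np.abs(x), axis=1) if mode == "peak" else np.sqrt(np.mean(x**2, axis=1))
    scale[scale == 0] = 1.0
    x = x * (amplitude / scale)[:, None]
    return x - x[:, :1]


def _simulate_fit(field: StaticFieldModel, rng, cfg) -> StaticFieldModel:
    """One fit: moving tracked triaxial sensors measuring ``field``."""
    n = int(round(cfg["duration"] * cfg["fs"]))
    step = cfg["fit_decimate"]
    ang = np.deg2rad(
        _smooth_traces(rng, 3, n, cfg["fs"], cfg["motion_cutoff_hz"], cfg["rot_amplitude_deg"])
    )[:, ::step].T
    trans = _smooth_traces(
        rng, 3, n, cfg["fs"], cfg["motion_cutoff_hz"], cfg["trans_amplitude_m"]
    )[:, ::step].T
    n_fit = ang.shape[0]
    R = Rotation.from_euler("xyz", ang).as_matrix()  # (n_fit, 3, 3)

    # reference sensor layout: triaxial sites on a ring around the helmet
    k = cfg["n_sites"]
    phis = 2 * np.pi * np.arange(k) / k
    sites = cfg["site_radius"] * np.column_stack(
        [np.cos(phis), np.sin(phis), 0.4 * np.ones(k)]
    )
    triads = np.tile(np.eye(3), (k, 1, 1))

    pos = np.einsum("tij,sj->tsi", R, sites) + trans[:, None, :]  # (n_fit, k, 3)
    ori = np.einsum("tij,saj->tsai", R, triads)  # (n_fit, k, 3, 3)
    # field at each site position, projected on each axis
    B = field.field_at(pos.reshape(-1, 3)).reshape(n_fit, k, 3)
    true_meas = np.einsum("tsai,tsi->tsa", ori, B)

    fs_fit = cfg["fs"] / step
    sigma = cfg["measurement_noise_fT_rtHz"] * 1e-15 * np.sqrt(fs_fit / 2.0)
    meas = true_meas + rng.standard_normal(true_meas.shape) * sigma

    # tracking noise corrupts the poses used in the fit, not the measurements
    pos_tr = pos + rng.standard_normal(pos.shape) * cfg["tracking_pos_rms_m"]
    dang = rng.standard_normal((n_fit, k, 3)) * np.deg2rad(cfg["tracking_ang_rms_deg"])
    Rerr = Rotation.from_rotvec(dang.reshape(-1, 3)).as_matrix().reshape(n_fit, k, 3, 3)
    ori_tr = np.einsum("tsij,tsaj->tsai", Rerr, ori)

    positions = np.repeat(pos_tr, 3, axis=1).reshape(-1, 3)
    orientations = ori_tr.reshape(-1, 3)
    est, _rms = fit_static_field(positions, orientations, meas.reshape(-1))
    return est, _rms


def null_iteration(true_field: StaticFieldModel, seed=None, **overrides):
    """Estimate the current field from simulated moving-sensor data and
    subtract the estimate; returns ``(residual_field, log_entry)``."""
    cfg = {**DEFAULTS, **overrides}
    rng = np.random.default_rng(seed)
    if cfg.get("noiseless"):
        cfg = {
            **cfg,
            "measurement_noise_fT_rtHz": 0.0,
            "tracking_pos_rms_m": 0.0,
            "tracking_ang_rms_deg": 0.0,
        }
    est, rms = _simulate_fit(true_field, rng, cfg)
    residual = true_field - est
    return residual, (est, rms)


def run_nulling(
    start_field: StaticFieldModel, n_iterations: int = 2, seed=None, **overrides
) -> NullingLog:
    """Iterated estimate-and-compensate loop; the residual feeds forward."""
    rng = np.random.default_rng(seed)
    log = NullingLog()
    current = start_field
    for it in range(1, n_iterations + 1):
        sub = int(rng.integers(0, 2**31 - 1))
        current, (est, rms) = null_iteration(current, seed=sub, **overrides)
        log.append(it, est, current, rms)
    return log


def random_start_field(rng, magnitude_nT=0.9, gradient_nT_per_m=2.0) -> StaticFieldModel:
    """Random uniform field of given magnitude plus random traceless gradients."""
    b = rng.standard_normal(3)
    b *= magnitude_nT * 1e-9 / np.linalg.norm(b)
    g5 = rng.standard_normal(5) * gradient_nT_per_m * 1e-9 / np.sqrt(5)
    return StaticFieldModel.from_params(np.concatenate([b, g5]))


def rotation_artifact(field_magnitude: float, angle_deg: float) -> float:
    """Worst-case shift of a measured field component for a sensitive-axis
    rotation by ``angle_deg`` in a uniform field of ``field_magnitude``.

    The measured component is ô·B; rotating ô on the unit sphere changes it by
    at most 2·|B|·sin(θ/2) (the chord length of the rotation).  The result is
    returned in the units of ``field_magnitude``.
    """
    if field_magnitude < 0:
        raise ValueError("field magnitude must be non-negative")
    return 2.0 * field_magnitude * float(np.sin(np.deg2rad(angle_deg) / 2.0))
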