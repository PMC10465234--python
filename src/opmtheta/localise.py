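"""LCMV beamforming and pseudo-T source imaging.

The linearly constrained minimum variance (LCMV) beamformer builds, per grid
voxel θ, a spatial filter w_θ minimising projected variance subject to unit
gain on the voxel's lead field.  Source orientation is optimised per voxel as
the direction of largest beamformer-projected power, which in closed form is
the eigenvector of the smallest eigenvalue of Lᵀ·C⁻¹·L.  Task-related power
changes are expressed as the pseudo-T contrast

    T = (wᵀ·C_on·w − wᵀ·C_off·w) / (2·wᵀ·C_off·w)

between active and control data covariance windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import LeadFieldGrid
from .synth import TrialSet

__all__ = [
    "Covariance",
    "BeamformerWeights",
    "PseudoTImage",
    "VirtualElectrode",
    "compute_covariance",
    "regularise",
    "lcmv_weights",
    "compute_weights_grid",
    "pseudo_t",
    "pseudo_t_image",
    "find_peak",
    "region_mask",
    "virtual_electrode",
    "project_empty_room",
    "image_to_nifti",
]


@dataclass
class Covariance:
    matrix: np.ndarray
    window: tuple | None = None
    n_samples: int = 0

    def __post_init__(self):
        C = np.asarray(self.matrix, float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("covariance must be square")
        if np.max(np.abs(C - C.T)) > 1e-12 * max(1.0, np.max(np.abs(C))):
            raise ValueError("covariance must be symmetric")
        ev = np.linalg.eigvalsh(C)
        if ev.size and ev[0] < -1e-12 * max(ev[-1], 0.0):
            raise ValueError("covariance must be positive semi-definite (to tolerance)")
        self.matrix = C


def _window_samples(trials: TrialSet, window):
    t0, t1 = window
    sel = (trials.time >= t0) & (trials.time < t1)
    # concatenate the window across trials: (n_channels, n_trials*n_sel)
    return trials.data[:, :, sel].transpose(1, 0, 2).reshape(trials.data.shape[1], -1)


def compute_covariance(data, window=None) -> Covariance:
    """Sample covariance, mean removed per channel.

    ``data`` is either a continuous (n_channels, n_samples) array, or a
    :class:`TrialSet` with ``window=(t0, t1)`` seconds relative to trial onset
    (the window's samples are concatenated across retained trials).
    """
    if isinstance(data, TrialSet):
        X = _window_samples(data, window) if window is not None else data.data.transpose(
            1, 0, 2
        ).reshape(data.data.shape[1], -1)
    else:
        X = np.asarray(data, float)
        if window is not None:
            raise ValueError("a window requires epoched (TrialSet) input")
    if X.size == 0:
        raise ValueError("empty covariance window")
    n_ch, n = X.shape
    if n <= n_ch:
        warnings.warn(
            f"covariance estimated from {n} samples for {n_ch} channels", stacklevel=2
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = max(n - 1, 1)
    return Covariance(Xc @ Xc.T / denom, window=window, n_samples=n)


def regularise(C: Covariance, fraction: float = 0.02) -> Covariance:
    """Tikhonov regularisation: add ``fraction``·λmax to the diagonal."""
    lam = np.linalg.eigvalsh(C.matrix)[-1]
    return Covariance(C.matrix + fraction * lam * np.eye(C.matrix.shape[0]), C.window, C.n_samples)


_REF = np.array([0.0, 0.0, 1.0])


def _fix_sign(eta):
    d = eta @ _REF
    if d < 0 or (d == 0 and (eta[0] < 0 or (eta[0] == 0 and eta[1] < 0))):
        return -eta
    return eta


def lcmv_weights(C_reg: Covariance, L: np.ndarray):
    """Unit-gain LCMV weights and power-maximising orientation for one voxel.

    In a spherical conductor the radial dipole component is externally silent,
    so L has (at most) rank 2; the orientation search is restricted to the
    column space of Lᵀ, where the power-maximising direction is the
    eigenvector of the smallest eigenvalue of the reduced Lᵀ·C⁻¹·L.

    Returns ``(w, eta)`` with wᵀ·(L·η) = 1.  Raises if L is (numerically)
    zero, e.g. at the sphere centre.
    """
    _u, s, vt = np.linalg.svd(L, full_matrices=False)
    if s[0] <= 0 or s[1] <= s[0] * 1e-10:
        raise np.linalg.LinAlgError("lead field rank < 2 at voxel")
    V = vt[:2].T  # (3, 2) basis of the sensed orientation subspace
    Ci = np.linalg.inv(C_reg.matrix)
    A = Ci @ L  # (n_ch, 3)
    M = L.T @ A  # (3, 3)
    Mr = V.T @ M @ V
    evals, evecs = np.linalg.eigh(Mr)
    if evals[0] <= evals[-1] * 1e-14:
        raise np.linalg.LinAlgError("singular orientation matrix at voxel")
    eta = _fix_sign(V @ evecs[:, 0])
    denom = eta @ M @ eta
    w = A @ eta / denom
    return w, eta


@dataclass
class BeamformerWeights:
    """Per-voxel LCMV filters on a grid."""

    weights: np.ndarray  # (n_vox, n_channels)
    orientations: np.ndarray  # (n_vox, 3)
    voxel_centres: np.ndarray
    spacing: float
    valid: np.ndarray  # bool per voxel


def compute_weights_grid(
    grid: LeadFieldGrid, C_reg: Covariance, projector: np.ndarray | None = None
) -> BeamformerWeights:
    """Vectorised LCMV weights for every grid voxel.

    If the data were cleaned with the homogeneous-field-correction projector,
    pass the same ``projector`` so the lead fields see the identical
    measurement model.
    """
    L = grid.leadfields  # (n_vox, n_ch, 3)
    if projector is not None:
        L = np.einsum("dc,vci->vdi", projector, L)
    # restrict orientations to the (rank-2) column space of each Lᵀ
    _u, s, vt = np.linalg.svd(L, full_matrices=False)
    valid = s[:, 1] > s[:, 0] * 1e-10
    V = vt[:, :2, :].transpose(0, 2, 1)  # (n_vox, 3, 2)
    Ci = np.linalg.inv(C_reg.matrix)
    A = np.einsum("dc,vci->vdi", Ci, L)  # C⁻¹ L
    M = np.einsum("vci,vcj->vij", L, A)
    Mr = np.einsum("via,vij,vjb->vab", V, M, V)
    evals, evecs = np.linalg.eigh(Mr)
    valid &= evals[:, 0] > evals[:, -1] * 1e-14
    eta = np.einsum("via,va->vi", V, evecs[:, :, 0])
    flip = eta @ _REF < 0
    eta[flip] *= -1.0
    denom = np.einsum("vi,vij,vj->v", eta, M, eta)
    bad = ~valid | (denom == 0)
    denom[bad] = 1.0
    W = np.einsum("vdi,vi->vd", A, eta) / denom[:, None]
    W[bad] = 0.0
    valid = ~bad
    if not np.all(valid):
        warnings.warn(f"{np.sum(~valid)} voxel(s) with singular orientation matrix excluded")
    return BeamformerWeights(W, eta, grid.voxel_centres, grid.spacing, valid)


def pseudo_t(w: np.ndarray, C_on: Covariance, C_off: Covariance) -> float:
    """Active-vs-control projected-power contrast for one voxel."""
    p_on = w @ C_on.matrix @ w
    p_off = w @ C_off.matrix @ w
    if p_off == 0:
        raise ZeroDivisionError("control-window projected power is zero")
    return float((p_on - p_off) / (2.0 * p_off))


@dataclass
class PseudoTImage:
    values: np.ndarray  # (n_vox,)
    voxel_centres: np.ndarray
    spacing: float
    valid: np.ndarray
    windows: tuple | None = None

    def to_tsv(self, path):
        import pandas as pd

        pd.DataFrame(
            dict(
                x=self.voxel_centres[:, 0],
                y=self.voxel_centres[:, 1],
                z=self.voxel_centres[:, 2],
                T=self.values,
            )
        ).to_csv(path, sep="\t", index=False)


def pseudo_t_image(
    weights: BeamformerWeights, C_on: Covariance, C_off: Covariance, windows=None
) -> PseudoTImage:
    W = weights.weights
    p_on = np.einsum("vc,cd,vd->v", W, C_on.matrix, W)
    p_off = np.einsum("vc,cd,vd->v", W, C_off.matrix, W)
    vals = np.zeros(W.shape[0])
    ok = weights.valid & (p_off > 0)
    vals[ok] = (p_on[ok] - p_off[ok]) / (2.0 * p_off[ok])
    return PseudoTImage(vals, weights.voxel_centres, weights.spacing, ok, windows)


def region_mask(voxel_centres, region: str, source_radius: float = 0.08) -> np.ndarray:
    """Synthetic stand-ins for anatomical lobes on the source sphere:
    'frontal' = anterior third (y ≥ R/3), 'visual' = posterior third."""
    y = np.asarray(voxel_centres)[:, 1]
    if region == "frontal":
        return y >= source_radius / 3.0
    if region == "visual":
        return y <= -source_radius / 3.0
    if region == "all":
        return np.ones(len(y), bool)
    raise ValueError(f"unknown region {region!r}")


def find_peak(image: PseudoTImage, mask=None) -> int:
    """Index of the maximal-T voxel inside the mask (ties → lowest index)."""
    mask = np.ones(image.values.shape, bool) if mask is None else np.asarray(mask, bool)
    mask = mask & image.valid
    if not mask.any():
        raise ValueError("empty peak-search mask")
    idx = np.flatnonzero(mask)
    return int(idx[np.argmax(image.values[idx])])


def refine_peak(
    head,
    array,
    C_reg: Covariance,
    C_on: Covariance,
    C_off: Covariance,
    coarse_position,
    projector=None,
    spacing: float = 0.004,
    half_extent: float = 0.008,
):
    """Re-evaluate the pseudo-T contrast on a fine local grid around a coarse
    peak and return the refined peak position.

    Used with a coarse whole-volume scan (e.g. 8 mm) followed by a ``spacing``
    (default 4 mm) lattice within ``half_extent`` of the coarse peak.
    """
    from .forward import LeadFieldGrid, _leadfields_at

    coarse_position = np.asarray(coarse_position, float)
    k = int(round(half_extent / spacing))
    offs = np.arange(-k, k + 1) * spacing
    zz, yy, xx = np.meshgrid(offs, offs, offs, indexing="ij")
    pts = coarse_position + np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    r = np.linalg.norm(pts - head.centre, axis=1)
    pts = pts[(r < head.source_radius_max) & (r > 1e-3)]
    lf = _leadfields_at(head, array, pts)
    local = LeadFieldGrid(pts, lf, spacing, head, array.system_tag)
    w = compute_weights_grid(local, C_reg, projector=projector)
    img = pseudo_t_image(w, C_on, C_off)
    return pts[find_peak(img)], img


@dataclass
class VirtualElectrode:
    timecourse: np.ndarray
    location: np.ndarray
    normalised: bool = False


def virtual_electrode(w, data, location=None, normalise=False) -> VirtualElectrode:
    """Project sensor data through one voxel's weights: VE(t) = wᵀ·data(t)."""
    ve = np.asarray(w) @ np.asarray(data, float)
    if normalise:
        sd = ve.std()
        if sd > 0:
            ve = ve / sd
    return VirtualElectrode(ve, None if location is None else np.asarray(location), normalise)


def project_empty_room(w, empty_recording, location=None) -> VirtualElectrode:
    """Reuse task-derived weights, unchanged, on the empty-room recording."""
    if empty_recording.data.shape[0] != len(w):
        raise ValueError("empty-room channel count does not match the weights")
    return virtual_electrode(w, empty_recording.data, location=location)


def image_to_nifti(image: PseudoTImage):
    """Pack the voxel list back onto its regular lattice as a NIfTI volume."""
    import nibabel as nib

    c = image.voxel_centres
    sp = image.spacing
    ijk = np.round((c - c.min(axis=0)) / sp).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.full(shape, np.nan)
    vol[tuple(ijk.T)] = image.values
    affine = np.diag([sp * 1e3, sp * 1e3, sp * 1e3, 1.0])
    affine[:3, 3] = c.min(axis=0) * 1e3  # mm, head frame
    return nib.Nifti1Image(vol, affine)
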