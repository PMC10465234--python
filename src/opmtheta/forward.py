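"""Dipole-in-sphere forward model and sensor-array geometry.

The magnetic field outside a spherically symmetric volume conductor due to a
current dipole has a closed analytic form (the classic sphere solution): the
field depends only on the primary current, not on the conductivity profile,
and purely radial dipoles are externally silent.  Synthetic heads here are
spheres, so this solution is exact and serves as the forward model for
beamforming.

Units are SI throughout (tesla, metre, second); dipole moments are expressed
in nA·m, so lead fields carry units of tesla per nA·m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MU0_OVER_4PI = 1e-7  # T·m/A
NAM = 1e-9  # one nA·m in A·m

__all__ = [
    "HeadModel",
    "SensorArray",
    "DipoleSource",
    "LeadFieldGrid",
    "dipole_field",
    "dipole_leadfield",
    "build_leadfield_grid",
]


@dataclass(frozen=True)
class HeadModel:
    """Spherical conductor: scalp sphere plus a concentric source region."""

    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scalp_radius: float = 0.09
    source_radius_max: float = 0.08

    def __post_init__(self):
        object.__setattr__(self, "centre", np.asarray(self.centre, float))
        if self.scalp_radius <= 0:
            raise ValueError("scalp_radius must be positive")
        if not self.source_radius_max < self.scalp_radius:
            raise ValueError("source_radius_max must be smaller than scalp_radius")


@dataclass(frozen=True)
class SensorArray:
    """Helmet geometry: sensor sites with 1 (radial) or 3 (triad) axes each.

    ``site_triads`` has shape (n_sites, n_axes, 3) with unit, mutually
    orthogonal axis vectors per site; axis 0 is radial by convention for
    arrays built by :func:`opmtheta.synth.build_array`.
    """

    site_positions: np.ndarray
    site_triads: np.ndarray
    system_tag: str = "opm_triaxial"
    scalp_offset: float = 0.0065
    labels: tuple = ()

    def __post_init__(self):
        pos = np.asarray(self.site_positions, float)
        tri = np.asarray(self.site_triads, float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("site_positions must be (n_sites, 3)")
        if tri.ndim != 3 or tri.shape[0] != pos.shape[0] or tri.shape[2] != 3:
            raise ValueError("site_triads must be (n_sites, n_axes, 3)")
        norms = np.linalg.norm(tri, axis=2)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("axis vectors must have unit norm")
        if tri.shape[1] > 1:
            gram = np.einsum("sai,sbi->sab", tri, tri)
            eye = np.eye(tri.shape[1])
            if np.max(np.abs(gram - eye)) > 1e-10:
                raise ValueError("site triads must be orthonormal")
        object.__setattr__(self, "site_positions", pos)
        object.__setattr__(self, "site_triads", tri)
        if not self.labels:
            axes = "xyz"[: tri.shape[1]] if tri.shape[1] == 3 else "r"
            object.__setattr__(
                self,
                "labels",
                tuple(
                    f"{self.system_tag}-{s:03d}{axes[a]}"
                    for s in range(pos.shape[0])
                    for a in range(tri.shape[1])
                ),
            )

    @property
    def n_sites(self) -> int:
        return self.site_positions.shape[0]

    @property
    def n_axes(self) -> int:
        return self.site_triads.shape[1]

    @property
    def n_channels(self) -> int:
        return self.n_sites * self.n_axes

    @property
    def channel_positions(self) -> np.ndarray:
        """(n_channels, 3) — each channel sits at its site position."""
        return np.repeat(self.site_positions, self.n_axes, axis=0)

    @property
    def channel_axes(self) -> np.ndarray:
        """(n_channels, 3) unit sensitive-axis vectors."""
        return self.site_triads.reshape(-1, 3)

    @property
    def channel_sites(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_sites), self.n_axes)

    def channel_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.channel_sites,
                "axis_id": np.tile(np.arange(self.n_axes), self.n_sites),
                "label": list(self.labels),
            }
        )

    def validate_outside(self, head: HeadModel) -> None:
        r = np.linalg.norm(self.site_positions - head.centre, axis=1)
        if np.any(r <= head.scalp_radius):
            raise ValueError("all sensor sites must lie strictly outside the scalp sphere")

    def to_tsv(self, path) -> None:
        rows = []
        for s in range(self.n_sites):
            for a in range(self.n_axes):
                rows.append(
                    dict(
                        site_id=s,
                        x=self.site_positions[s, 0],
                        y=self.site_positions[s, 1],
                        z=self.site_positions[s, 2],
                        axis_id=a,
                        ax=self.site_triads[s, a, 0],
                        ay=self.site_triads[s, a, 1],
                        az=self.site_triads[s, a, 2],
                        label=self.labels[s * self.n_axes + a],
                    )
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, system_tag="opm_triaxial", scalp_offset=0.0065) -> "SensorArray":
        df = pd.read_csv(path, sep="\t")
        sites = sorted(df["site_id"].unique())
        pos = np.array(
            [df[df.site_id == s].iloc[0][["x", "y", "z"]].to_numpy(float) for s in sites]
        )
        n_axes = df.groupby("site_id").size().iloc[0]
        tri = np.array(
            [
                df[df.site_id == s].sort_values("axis_id")[["ax", "ay", "az"]].to_numpy(float)
                for s in sites
            ]
        ).reshape(len(sites), n_axes, 3)
        labels = tuple(df.sort_values(["site_id", "axis_id"])["label"])
        return cls(pos, tri, system_tag=system_tag, scalp_offset=scalp_offset, labels=labels)


@dataclass
class DipoleSource:
    """Current dipole with a moment time course in nA·m."""

    position: np.ndarray
    orientation: np.ndarray
    moment: np.ndarray  # (n_samples,), nA·m
    fs: float

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        ori = np.asarray(self.orientation, float)
        n = np.linalg.norm(ori)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError("orientation must be a unit vector")
        self.orientation = ori / n
        self.moment = np.asarray(self.moment, float)


def dipole_field(position, moment, points, centre=None):
    """Field (tesla) of a current dipole inside a spherical conductor.

    Parameters
    ----------
    position : (3,) dipole location, metres.
    moment : (3,) dipole moment, A·m.
    points : (n, 3) field points strictly outside the conductor.
    centre : (3,) sphere centre (default origin).
    """
    position = np.asarray(position, float)
    moment = np.asarray(moment, float)
    points = np.atleast_2d(np.asarray(points, float))
    if centre is not None:
        position = position - centre
        points = points - centre

    qxr0 = np.cross(moment, position)
    a_vec = points - position
    a = np.linalg.norm(a_vec, axis=1)
    r = np.linalg.norm(points, axis=1)
    if np.any(a == 0) or np.any(r == 0):
        raise ValueError("field point coincides with dipole or sphere centre")
    adotr = np.einsum("ij,ij->i", a_vec, points)
    r0dotr = points @ position
    F = a * (r * a + r**2 - r0dotr)
    gradF = (a**2 / r + adotr / a + 2 * a + 2 * r)[:, None] * points - (
        a + 2 * r + adotr / a
    )[:, None] * position
    return MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0 - (points @ qxr0)[:, None] * gradF)


def dipole_leadfield(head: HeadModel, array: SensorArray, position) -> np.ndarray:
    """Lead field at one source location: (n_channels, 3), tesla per nA·m.

    Column j is the response of every channel (field at the channel position
    projected on its sensitive axis) to a unit 1 nA·m dipole along Cartesian
    basis direction j.  The map is linear in the dipole moment.
    """
    position = np.asarray(position, float)
    if np.linalg.norm(position - head.centre) >= head.source_radius_max:
        raise ValueError("dipole position lies outside the source region")
    array.validate_outside(head)
    pts = array.channel_positions
    axes = array.channel_axes
    L = np.empty((array.n_channels, 3))
    for j in range(3):
        q = np.zeros(3)
        q[j] = NAM
        B = dipole_field(position, q, pts, centre=head.centre)
        L[:, j] = np.einsum("ij,ij->i", B, axes)
    return L


def _leadfields_at(head, array, positions):
    """Stacked lead fields (n_pos, n_channels, 3) — vectorised over positions."""
    positions = np.asarray(positions, float) - head.centre
    pts = array.channel_positions - head.centre
    axes = array.channel_axes
    n_pos = positions.shape[0]
    out = np.empty((n_pos, array.n_channels, 3))
    # broadcast over positions per channel; loop over channels keeps memory flat
    r = np.linalg.norm(pts, axis=1)
    for c in range(array.n_channels):
        p = pts[c]
        a_vec = p[None, :] - positions
        a = np.linalg.norm(a_vec, axis=1)
        adotr = a_vec @ p
        r0dotr = positions @ p
        F = a * (r[c] * a + r[c] ** 2 - r0dotr)
        coef1 = a**2 / r[c] + adotr / a + 2 * a + 2 * r[c]
        coef2 = a + 2 * r[c] + adotr / a
        gradF = coef1[:, None] * p[None, :] - coef2[:, None] * positions
        for j in range(3):
            q = np.zeros(3)
            q[j] = NAM
            qxr0 = np.cross(np.broadcast_to(q, positions.shape), positions)
            B = (F[:, None] * qxr0 - (qxr0 @ p)[:, None] * gradF) * (
                MU0_OVER_4PI / F[:, None] ** 2
            )
            out[:, c, j] = B @ axes[c]
    return out


@dataclass
class LeadFieldGrid:
    """Regular source grid with per-voxel lead fields.

    Voxels are ordered x fastest, then y, then z; only voxels strictly inside
    the source sphere (and more than 1 mm from the centre, where the radial
    basis degenerates) are retained.
    """

    voxel_centres: np.ndarray  # (n_vox, 3), metres
    leadfields: np.ndarray  # (n_vox, n_channels, 3), T / nA·m
    spacing: float
    head: HeadModel
    system_tag: str

    @property
    def n_voxels(self) -> int:
        return self.voxel_centres.shape[0]

    def save(self, prefix) -> None:
        np.savez(f"{prefix}.npz", voxel_centres=self.voxel_centres, leadfields=self.leadfields)
        meta = dict(
            spacing=self.spacing,
            ordering="x-fastest",
            system_tag=self.system_tag,
            centre=list(self.head.centre),
            scalp_radius=self.head.scalp_radius,
            source_radius_max=self.head.source_radius_max,
        )
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "LeadFieldGrid":
        arrs = np.load(f"{prefix}.npz")
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        head = HeadModel(
            np.array(meta["centre"]), meta["scalp_radius"], meta["source_radius_max"]
        )
        return cls(
            arrs["voxel_centres"], arrs["leadfields"], meta["spacing"], head, meta["system_tag"]
        )


def grid_voxel_centres(head: HeadModel, spacing: float = 0.004) -> np.ndarray:
    """Lattice points inside the source sphere, x fastest, then y, then z."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing >= 2 * head.source_radius_max:
        raise ValueError("spacing must be smaller than the source-region diameter")
    n = int(np.floor(head.source_radius_max / spacing))
    coords = np.arange(-n, n + 1) * spacing
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    r = np.linalg.norm(pts, axis=1)
    keep = (r < head.source_radius_max) & (r > 1e-3)
    return pts[keep] + head.centre


def build_leadfield_grid(
    head: HeadModel, array: SensorArray, spacing: float = 0.004
) -> LeadFieldGrid:
    """Lead fields for every voxel of a regular grid inside the source sphere."""
    centres = grid_voxel_centres(head, spacing)
    array.validate_outside(head)
    lf = _leadfields_at(head, array, centres)
    return LeadFieldGrid(centres, lf, spacing, head, array.system_tag)
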