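"""Beam-frame resampling shared by the GED engine and the toy dose engine.

For a coplanar field with unit travel direction ``d`` in the axial plane,
every point is described by (s, t, z): depth t along the beam, lateral
offset s along u = rot90(d), and the unchanged grid z. A regular lattice in
(s, t) at the finer of the two axial voxel spacings supports deterministic
nearest-neighbour ray casting: for axis-aligned beams on isotropic grids
the lattice coincides with the voxel centers, which is what makes the 1-D
closed-form oracles exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cases import VoxelGrid

__all__ = ["BeamFrame", "make_frame", "mask_on_lattice", "gather_to_voxels"]


@dataclass
class BeamFrame:
    grid: VoxelGrid
    direction: np.ndarray  # unit beam-travel direction, z component 0
    lateral: np.ndarray    # unit lateral direction in the axial plane
    h: float               # lattice step (mm) in s and t
    s0: float
    t0: float
    n_s: int
    n_t: int
    vox_is: np.ndarray     # (nx, ny) lattice s-index of each axial voxel column
    vox_it: np.ndarray     # (nx, ny) lattice t-index
    vox_s: np.ndarray      # (nx, ny) snapped lateral coordinate (mm)
    vox_t: np.ndarray      # (nx, ny) snapped depth coordinate (mm)
    lat_ix: np.ndarray     # (n_s, n_t) nearest voxel x-index, -1 outside grid
    lat_iy: np.ndarray     # (n_s, n_t) nearest voxel y-index, -1 outside grid

    @property
    def t_samples(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.n_t)

    @property
    def s_samples(self) -> np.ndarray:
        return self.s0 + self.h * np.arange(self.n_s)


def make_frame(grid: VoxelGrid, direction: np.ndarray) -> BeamFrame:
    d = np.asarray(direction, dtype=float)
    if abs(d[2]) > 1e-12:
        raise ValueError("beam direction must lie in the axial plane")
    d = d / np.linalg.norm(d)
    u = np.array([-d[1], d[0], 0.0])

    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    T = X * d[0] + Y * d[1]
    S = X * u[0] + Y * u[1]

    h = float(min(grid.spacing_mm[0], grid.spacing_mm[1]))
    s0, t0 = float(S.min()), float(T.min())
    n_s = int(np.rint((S.max() - s0) / h)) + 1
    n_t = int(np.rint((T.max() - t0) / h)) + 1

    vox_is = np.clip(np.rint((S - s0) / h).astype(int), 0, n_s - 1)
    vox_it = np.clip(np.rint((T - t0) / h).astype(int), 0, n_t - 1)
    vox_s = s0 + h * vox_is
    vox_t = t0 + h * vox_it

    # nearest voxel for every lattice node (for sampling masks along rays)
    si = s0 + h * np.arange(n_s)
    ti = t0 + h * np.arange(n_t)
    Sg, Tg = np.meshgrid(si, ti, indexing="ij")
    wx = Sg * u[0] + Tg * d[0]
    wy = Sg * u[1] + Tg * d[1]
    ix = np.rint((wx - grid.origin_mm[0]) / grid.spacing_mm[0]).astype(int)
    iy = np.rint((wy - grid.origin_mm[1]) / grid.spacing_mm[1]).astype(int)
    inside = (ix >= 0) & (ix < grid.dims[0]) & (iy >= 0) & (iy < grid.dims[1])
    ix[~inside] = -1
    iy[~inside] = -1

    return BeamFrame(grid, d, u, h, s0, t0, n_s, n_t,
                     vox_is, vox_it, vox_s, vox_t, ix, iy)


def mask_on_lattice(frame: BeamFrame, mask: np.ndarray) -> np.ndarray:
    """Nearest-neighbour sample of a binary volume on the beam-frame lattice.

    Returns a boolean array of shape (n_s, n_t, nz); lattice nodes outside
    the grid are False.
    """
    mask = np.asarray(mask, dtype=bool)
    nz = frame.grid.dims[2]
    out = np.zeros((frame.n_s, frame.n_t, nz), dtype=bool)
    valid = frame.lat_ix >= 0
    out[valid, :] = mask[frame.lat_ix[valid], frame.lat_iy[valid], :]
    return out


def gather_to_voxels(frame: BeamFrame, volume_bf: np.ndarray) -> np.ndarray:
    """Pull a beam-frame volume (n_s, n_t, nz) back onto the voxel grid."""
    return volume_bf[frame.vox_is, frame.vox_it, :]
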