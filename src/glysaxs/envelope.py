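"""Solvation envelopes: the spatial region within a fixed distance of solute atoms.

The envelope decides which solvent molecules contribute to the computed
scattering signal (buffer subtraction is restricted to it).  It is
represented on a regular voxel grid built from the union of atom
positions over a trajectory window, so a dynamic solute is fully
enclosed in every frame of the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .core import AtomicFrame, Trajectory

__all__ = ["Envelope", "build_envelope"]


@dataclass
class Envelope:
    """Voxelized region within ``distance`` Å of a set of solute atoms."""

    origin: np.ndarray  # corner of voxel (0,0,0), Å
    spacing: float  # voxel edge, Å
    mask: np.ndarray  # bool, shape (nx, ny, nz); True = inside
    distance: float  # construction distance, Å

    @property
    def volume(self) -> float:
        """Voxel-integrated volume in Å³."""
        return float(self.mask.sum()) * self.spacing**3

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test for an ``(n, 3)`` array (or a single point)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((pts - self.origin) / self.spacing).astype(int)
        inside_grid = np.all((idx >= 0) & (idx < self.mask.shape), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        ig = idx[inside_grid]
        out[inside_grid] = self.mask[ig[:, 0], ig[:, 1], ig[:, 2]]
        return out[0] if np.asarray(points).ndim == 1 else out

    def voxel_centers(self) -> np.ndarray:
        """Centers of all occupied voxels, shape ``(n_occupied, 3)``."""
        ijk = np.argwhere(self.mask)
        return self.origin + (ijk + 0.5) * self.spacing

    def accessible_volume(self, solute_coords: np.ndarray, contact: float) -> float:
        """Envelope volume minus the region within ``contact`` Å of the solute."""
        centers = self.voxel_centers()
        if len(centers) == 0:
            return 0.0
        d, _ = cKDTree(np.asarray(solute_coords, float)).query(centers, workers=-1)
        return float(np.count_nonzero(d > contact)) * self.spacing**3

    def save(self, path) -> None:
        np.savez(path, origin=self.origin, spacing=self.spacing,
                 mask=self.mask, distance=self.distance)

    @classmethod
    def load(cls, path) -> "Envelope":
        with np.load(path) as z:
            return cls(origin=z["origin"], spacing=float(z["spacing"]),
                       mask=z["mask"], distance=float(z["distance"]))


def build_envelope(
    frames: Trajectory | Iterable[AtomicFrame] | AtomicFrame,
    distance: float = 7.0,
    voxel: float = 0.5,
    per_frame: bool = False,
) -> Envelope | list[Envelope]:
    """Build the solvation envelope of a trajectory window.

    The region is the union, over all frames, of points within
    ``distance`` of any solute atom (default 7 Å).  With
    ``per_frame=True`` a separate envelope is returned for every frame
    instead of the window union.

    Volume accuracy is set by ``voxel`` (0.5 Å default keeps the volume
    error of ~7 Å features below ~3%).
    """
    if distance <= 0:
        raise ValueError("envelope distance must be positive")
    if voxel <= 0:
        raise ValueError("voxel spacing must be positive")
    if isinstance(frames, AtomicFrame):
        frames = [frames]
    frame_list = list(frames)
    if not frame_list:
        raise ValueError("cannot build an envelope from an empty frame set")
    if per_frame:
        return [build_envelope(f, distance, voxel) for f in frame_list]

    coords = np.concatenate([f.coords for f in frame_list])
    lo = coords.min(axis=0) - distance - voxel
    hi = coords.max(axis=0) + distance + voxel
    shape = np.ceil((hi - lo) / voxel).astype(int)
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * voxel for d in range(3)]
    tree = cKDTree(coords)

    # query voxel centers slab by slab to bound peak memory
    mask = np.zeros(shape, dtype=bool)
    yz = np.stack(np.meshgrid(axes[1], axes[2], indexing="ij"), axis=-1).reshape(-1, 2)
    pts = np.empty((len(yz), 3))
    for i, x in enumerate(axes[0]):
        pts[:, 0] = x
        pts[:, 1:] = yz
        d, _ = tree.query(pts, workers=-1, distance_upper_bound=distance + voxel)
        mask[i] = (d <= distance).reshape(shape[1], shape[2])
    return Envelope(origin=lo, spacing=float(voxel), mask=mask, distance=float(distance))
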