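"""Core containers: atomistic frames, trajectories and 1D scattering curves.

Units are fixed internally: coordinates and box edges in Å, momentum
transfer q in Å⁻¹, times in ps.  Unit conversion happens only at I/O
boundaries (see :mod:`glysaxs.curve_analysis`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np

__all__ = ["AtomicFrame", "Trajectory", "ScatteringCurve", "SelectionError"]


class SelectionError(ValueError):
    """Raised when a ``resid:atomname`` selection does not resolve uniquely."""


@dataclass
class AtomicFrame:
    """A single configuration of atoms.

    Parameters
    ----------
    elements:
        Element symbols, shape ``(n_atoms,)``.
    coords:
        Cartesian coordinates in Å, shape ``(n_atoms, 3)``.
    resids:
        Residue indices (1-based), shape ``(n_atoms,)``.
    names:
        Atom names, shape ``(n_atoms,)``.
    box:
        Orthorhombic box edge lengths in Å, shape ``(3,)``.
    time:
        Frame time in ps.
    """

    elements: np.ndarray
    coords: np.ndarray
    resids: np.ndarray
    names: np.ndarray
    box: np.ndarray = field(default_factory=lambda: np.array([100.0, 100.0, 100.0]))
    time: float = 0.0

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.names = np.asarray(self.names, dtype="U6")
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if len(self.resids) != n or len(self.names) != n:
            raise ValueError("elements, coords, resids and names must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def select(self, selection: str) -> int:
        """Resolve a ``resid:atomname`` selection to a single atom index.

        Raises
        ------
        SelectionError
            If the selection matches zero or more than one atom; the
            message lists the matches found.
        """
        try:
            resid_s, name = selection.split(":")
            resid = int(resid_s)
        except ValueError as exc:
            raise SelectionError(
                f"selection {selection!r} is not of the form 'resid:atomname'"
            ) from exc
        hits = np.flatnonzero((self.resids == resid) & (self.names == name))
        if len(hits) != 1:
            found = [f"{self.resids[i]}:{self.names[i]}" for i in hits]
            raise SelectionError(
                f"selection {selection!r} matched {len(hits)} atoms: {found}"
            )
        return int(hits[0])

    def subset(self, indices: np.ndarray) -> "AtomicFrame":
        idx = np.asarray(indices)
        return AtomicFrame(
            elements=self.elements[idx],
            coords=self.coords[idx],
            resids=self.resids[idx],
            names=self.names[idx],
            box=self.box.copy(),
            time=self.time,
        )

    def copy(self) -> "AtomicFrame":
        return self.subset(np.arange(self.n_atoms))


@dataclass
class Trajectory:
    """Ordered ensemble of frames with constant atom count and ordering."""

    frames: list[AtomicFrame]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0]
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames[1:]:
            if f.n_atoms != ref.n_atoms:
                raise ValueError("atom count must be constant across frames")
            if not (np.array_equal(f.elements, ref.elements) and np.array_equal(f.names, ref.names)):
                raise ValueError("atom ordering/identity must be constant across frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def __iter__(self) -> Iterator[AtomicFrame]:
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, key):
        if isinstance(key, slice):
            return Trajectory(frames=self.frames[key], metadata=dict(self.metadata))
        return self.frames[key]

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into shape ``(n_frames, n_atoms, 3)``."""
        return np.stack([f.coords for f in self.frames])

    def concat(self, other: "Trajectory") -> "Trajectory":
        """Concatenate two trajectories of identical atom layout."""
        shift = self.frames[-1].time
        shifted = []
        for f in other.frames:
            g = f.copy()
            g.time = f.time + shift + 1e-9
            shifted.append(g)
        return Trajectory(frames=list(self.frames) + shifted, metadata=dict(self.metadata))


@dataclass
class ScatteringCurve:
    """A 1D SAXS profile: I(q) on a strictly increasing q grid (Å⁻¹)."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be equal-length 1D arrays")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.q)

    def scaled(self, scale: float = 1.0, constant: float = 0.0) -> "ScatteringCurve":
        sigma = None if self.sigma is None else np.abs(scale) * self.sigma
        return ScatteringCurve(self.q.copy(), scale * self.I + constant, sigma, dict(self.metadata))
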