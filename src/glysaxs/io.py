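"""Structure/trajectory I/O: multi-model PDB files.

Ensembles are exchanged as PDB-style MODEL/ENDMDL records via biotite.
PDB carries no frame-time field, so times are reconstructed from a
frame interval on read; coordinates, elements, residue indices and atom
names round-trip.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import AtomicFrame, Trajectory

__all__ = ["write_trajectory_pdb", "read_trajectory_pdb"]

_WATER_NAMES = {"OW", "HW1", "HW2"}


def _frame_to_atom_array(frame: AtomicFrame) -> struc.AtomArray:
    n = frame.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frame.coords.astype(np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = frame.resids
    arr.res_name = np.where(np.isin(frame.names, list(_WATER_NAMES)), "HOH", "GLY")
    arr.atom_name = frame.names
    arr.element = np.char.upper(frame.elements)
    arr.hetero = np.full(n, True)
    arr.box = np.diag(frame.box).astype(np.float32)
    return arr


def write_trajectory_pdb(traj: Trajectory | list[AtomicFrame], path) -> None:
    """Write frames as MODEL/ENDMDL records (one model per frame)."""
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    arrays = [_frame_to_atom_array(f) for f in frames]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        try:
            pdb.set_structure(struc.stack(arrays))
        except Exception:
            # varying atom counts (e.g. per-frame solvation): write models manually
            for i, arr in enumerate(arrays):
                pdb.set_structure(arr, model=i + 1)
    pdb.write(path)


def read_trajectory_pdb(path, frame_interval: float = 1.0) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`.

    Frame times are ``i * frame_interval`` (ps).  A cubic 100 Å box is
    assumed when the file has no CRYST1 record.
    """
    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    box = np.array([100.0, 100.0, 100.0])
    if stack.box is not None:
        diag = np.diagonal(np.asarray(stack.box), axis1=-2, axis2=-1)
        b = diag[0] if diag.ndim == 2 else diag
        if np.all(b > 0):
            box = np.asarray(b, dtype=float)
    frames = []
    elements = np.array([e.capitalize() for e in stack.element])
    for i in range(stack.stack_depth()):
        frames.append(AtomicFrame(
            elements=elements,
            coords=np.asarray(stack.coord[i], dtype=float),
            resids=np.asarray(stack.res_id, dtype=int),
            names=np.asarray(stack.atom_name),
            box=box.copy(),
            time=i * frame_interval))
    return Trajectory(frames=frames, metadata={"source": str(path)})
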