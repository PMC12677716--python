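"""Trajectory-side conformational analytics.

Radius of gyration, strand end-to-end distance, folded/unfolded (fc/ufc)
window classification, glycosidic torsions with Ramachandran densities,
and hydrogen-bond occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import AtomicFrame, Trajectory
from .formfactors import atomic_form_factor
from .synthetic_data import FC_RANGE, UFC_RANGE

__all__ = [
    "radius_of_gyration",
    "rg_series",
    "end_to_end_distance",
    "end_to_end_series",
    "ConformationWindow",
    "classify_windows",
    "dihedral",
    "TorsionSeries",
    "torsion_series",
    "RamachandranDensity",
    "ramachandran_density",
    "HBondOccupancy",
    "hbond_occupancy",
]

# simple mass table for the elements the pipeline produces (u)
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


def _weights(frame: AtomicFrame, weighting: str) -> np.ndarray:
    if weighting == "uniform":
        return np.ones(frame.n_atoms)
    if weighting == "mass":
        return np.array([_MASSES[e] for e in frame.elements])
    if weighting == "electron":
        # f(0) = electron number
        return np.array([atomic_form_factor(e, 0.0) for e in frame.elements])
    raise ValueError("weighting must be 'mass', 'electron' or 'uniform'")


def radius_of_gyration(frame: AtomicFrame,
                       weighting: Literal["mass", "electron", "uniform"] = "electron"
                       ) -> float:
    """Weighted RMS distance from the weighted centroid, in Å.

    Electron weighting (default) matches what SAXS senses; mass
    weighting matches the usual MD convention.
    """
    if frame.n_atoms < 1:
        raise ValueError("frame has no atoms")
    w = _weights(frame, weighting)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    center = (w[:, None] * frame.coords).sum(axis=0) / total
    d2 = np.sum((frame.coords - center) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * d2) / total))


def rg_series(traj: Trajectory,
              weighting: Literal["mass", "electron", "uniform"] = "electron"
              ) -> np.ndarray:
    return np.array([radius_of_gyration(f, weighting) for f in traj])


def end_to_end_distance(frame: AtomicFrame, sel_a: str, sel_b: str) -> float:
    """Distance between two uniquely selected atoms (``resid:atomname``)."""
    ia = frame.select(sel_a)
    ib = frame.select(sel_b)
    return float(np.linalg.norm(frame.coords[ia] - frame.coords[ib]))


def end_to_end_series(traj: Trajectory, sel_a: str | None = None,
                      sel_b: str | None = None) -> np.ndarray:
    """Per-frame end-to-end distances; selections default to the trajectory metadata."""
    sel_a = sel_a or traj.metadata.get("end_selection_a")
    sel_b = sel_b or traj.metadata.get("end_selection_b")
    if sel_a is None or sel_b is None:
        raise ValueError("end selections not given and not present in metadata")
    ia = traj.frames[0].select(sel_a)
    ib = traj.frames[0].select(sel_b)
    X = traj.coords_array()
    return np.linalg.norm(X[:, ia] - X[:, ib], axis=1)


@dataclass
class ConformationWindow:
    """A labelled contiguous frame interval selected by end-to-end distance."""

    label: Literal["fc", "ufc"]
    start: int  # inclusive
    end: int  # exclusive
    duration: float  # ps
    criterion: tuple[float, float]  # admissible distance range, Å

    @property
    def n_frames(self) -> int:
        return self.end - self.start


def classify_windows(distances: Sequence[float],
                     fc_range: tuple[float, float] = FC_RANGE,
                     ufc_range: tuple[float, float] = UFC_RANGE,
                     min_frames: int = 1000,
                     frame_interval: float = 1.0) -> list[ConformationWindow]:
    """Maximal contiguous fc/ufc runs of at least ``min_frames`` frames.

    A frame is fc when its distance lies in ``fc_range`` (checked
    first), ufc when in ``ufc_range``, otherwise unlabelled; unlabelled
    frames break windows.  Ranges may share an endpoint but must not
    overlap on an interval.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("distance series is empty")
    (f_lo, f_hi), (u_lo, u_hi) = fc_range, ufc_range
    if f_lo >= f_hi or u_lo >= u_hi:
        raise ValueError("ranges must have positive width")
    if max(f_lo, u_lo) < min(f_hi, u_hi):
        raise ValueError("fc and ufc ranges overlap on an interval")

    labels = np.full(d.size, 0, dtype=int)  # 0 = neither
    labels[(d >= f_lo) & (d <= f_hi)] = 1
    labels[(labels == 0) & (d >= u_lo) & (d <= u_hi)] = 2

    windows: list[ConformationWindow] = []
    start = 0
    for i in range(1, d.size + 1):
        if i == d.size or labels[i] != labels[start]:
            lab = labels[start]
            length = i - start
            if lab != 0 and length >= min_frames:
                windows.append(ConformationWindow(
                    label="fc" if lab == 1 else "ufc",
                    start=start, end=i,
                    duration=length * frame_interval,
                    criterion=fc_range if lab == 1 else ufc_range))
            start = i
    return windows


def dihedral(coords: np.ndarray | AtomicFrame, atoms: Sequence | None = None,
             convention: str | None = None) -> float:
    """Signed dihedral angle in degrees, in (−180, 180].

    Standard convention: cis = 0°, sign from the atan2 construction on
    the two bond-plane normals.  ``coords`` may be a ``(4, 3)`` array,
    or a frame together with four atom indices / ``resid:atomname``
    selections.  ``convention`` is a pass-through tag (heavy-atom vs
    hydrogen-based torsion definitions differ only in which atoms are
    passed in).
    """
    if isinstance(coords, AtomicFrame):
        if atoms is None or len(atoms) != 4:
            raise ValueError("need four atom ids with a frame")
        idx = [coords.select(a) if isinstance(a, str) else int(a) for a in atoms]
        if len(set(idx)) != 4:
            raise ValueError("the four atoms must be distinct")
        pts = coords.coords[idx]
    else:
        pts = np.asarray(coords, dtype=float)
        if pts.shape != (4, 3):
            raise ValueError("expected four 3D points")
    b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear atom triple; dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


@dataclass
class TorsionSeries:
    """Per-frame (Φ, Ψ) of one glycosidic linkage, degrees in (−180, 180]."""

    linkage_id: str
    convention: Literal["heavy_atom", "hydrogen_based"]
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have one value pair per frame")
        for a in (self.phi, self.psi):
            if np.any((a <= -180.0) | (a > 180.0)):
                raise ValueError("angles must lie in (-180, 180]")


def torsion_series(traj: Trajectory, linkage_id: str,
                   phi_atoms: Sequence, psi_atoms: Sequence,
                   convention: Literal["heavy_atom", "hydrogen_based"] = "heavy_atom"
                   ) -> TorsionSeries:
    """Evaluate one linkage's (Φ, Ψ) over all frames.

    ``phi_atoms``/``psi_atoms`` are four selections each — e.g. the
    heavy-atom convention Φ: O5'-C1'-On-Cn, Ψ: C1'-On-Cn-Cn−1, or the
    hydrogen-based Φ: H1'-C1'-O4-C4, Ψ: C1'-O4-C4-H4.
    """
    phi = np.array([dihedral(f, phi_atoms) for f in traj])
    psi = np.array([dihedral(f, psi_atoms) for f in traj])
    return TorsionSeries(linkage_id=linkage_id, convention=convention, phi=phi, psi=psi)


@dataclass
class RamachandranDensity:
    """Normalized 2D (Φ, Ψ) histogram on (−180, 180]²."""

    density: np.ndarray  # sums to 1
    edges: np.ndarray  # shared bin edges for both axes
    mode: tuple[float, float]  # bin-center of the max-density bin


def ramachandran_density(series: TorsionSeries, bin_width: float = 10.0
                         ) -> RamachandranDensity:
    """Histogram the torsion population; mode ties break toward smallest (Φ, Ψ)."""
    nbins = 360.0 / bin_width
    if not np.isclose(nbins, round(nbins)) or bin_width <= 0:
        raise ValueError("bin_width must positively divide 360")
    nbins = int(round(nbins))
    if len(series.phi) < 1:
        raise ValueError("need at least one frame")
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    # (−180, 180]: nudge exact −180/180 into the right half-open binning
    phi = np.where(series.phi == 180.0, np.nextafter(180.0, -np.inf), series.phi)
    psi = np.where(series.psi == 180.0, np.nextafter(180.0, -np.inf), series.psi)
    H, _, _ = np.histogram2d(phi, psi, bins=[edges, edges])
    density = H / H.sum()
    i, j = np.unravel_index(np.argmax(density), density.shape)  # first = smallest (Φ,Ψ)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RamachandranDensity(density=density, edges=edges,
                               mode=(float(centers[i]), float(centers[j])))


@dataclass
class HBondOccupancy:
    """Geometric hydrogen-bond occupancy over a trajectory."""

    donor: str
    hydrogen: str
    acceptor: str
    d_cut: float  # donor–acceptor distance cutoff, Å
    angle_cut: float  # D–H…A angle cutoff, degrees
    occupancy: float  # satisfied-frames / total-frames
    warning: str | None = None


def hbond_occupancy(traj: Trajectory,
                    triples: Sequence[tuple[str, str, str]],
                    d_cut: float = 3.5,
                    angle_cut: float = 150.0) -> list[HBondOccupancy]:
    """Occupancy of donor–H…acceptor bonds under geometric criteria.

    A frame satisfies a bond when the donor–acceptor distance is ≤
    ``d_cut`` *and* the D–H…A angle is ≥ ``angle_cut`` (common
    MD-analysis defaults 3.5 Å / 150°).  If the hydrogen is not bonded
    to its donor (distance > 1.2 Å in any frame), the record carries a
    warning instead of failing.
    """
    results = []
    X = traj.coords_array()
    for don, hyd, acc in triples:
        f0 = traj.frames[0]
        di, hi, ai = f0.select(don), f0.select(hyd), f0.select(acc)
        D, H, A = X[:, di], X[:, hi], X[:, ai]
        d_da = np.linalg.norm(D - A, axis=1)
        v1 = D - H
        v2 = A - H
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = (d_da <= d_cut) & (ang >= angle_cut)
        d_dh = np.linalg.norm(D - H, axis=1)
        warning = None
        if np.any(d_dh > 1.2):
            warning = (f"hydrogen {hyd} is {d_dh.max():.2f} Å from donor {don} "
                       "in at least one frame (> 1.2 Å); not a covalent D-H pair?")
        results.append(HBondOccupancy(
            donor=don, hydrogen=hyd, acceptor=acc, d_cut=d_cut,
            angle_cut=angle_cut, occupancy=float(ok.mean()), warning=warning))
    return results
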