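"""Synthetic glycan-hairpin ensembles, hydration water and oracle fixtures.

The generator emulates the two conformational regimes of a two-strand
oligosaccharide hairpin: a *folded* (fc) state with the terminal-to-
terminal distance of the strands held within 3–10 Å, and an *unfolded*
(ufc) state with 10–25 Å.  Residues are idealized pyranose-like
templates (a 6-atom C₅O ring plus one exocyclic O4 per residue, 1.5 Å
bonds), not force-field chemistry: downstream scattering and
conformational analytics only need plausible element/coordinate
ensembles with controllable geometry.

All generators are seeded and bit-reproducible; one top-level seed is
expanded deterministically into per-frame sub-seeds, so reproducibility
does not depend on frame order.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .core import AtomicFrame, ScatteringCurve, Trajectory
from .envelope import Envelope

__all__ = [
    "SyntheticSpec",
    "FC_RANGE",
    "UFC_RANGE",
    "generate_hairpin_trajectory",
    "end_selections",
    "solvate_frame",
    "solvate_trajectory",
    "generate_solvent_trajectory",
    "generate_analytic_shape",
    "synthesize_experimental_curve",
    "BULK_WATER_DENSITY",
]

FC_RANGE = (3.0, 10.0)  # Å, folded terminal-to-terminal distance
UFC_RANGE = (10.0, 25.0)  # Å, unfolded
BULK_WATER_DENSITY = 0.0334  # molecules/Å³ at ambient conditions

_AGU_RISE = 5.15  # Å per residue along the strand axis
_RING_RADIUS = 1.5  # Å, idealized pyranose ring circumradius
_EXO_BOND = 1.4  # Å, C4—O4 exocyclic bond
_STRAND_SEP = 4.6  # Å, interstrand separation at the turn
_RANGE_MARGIN = 0.6  # Å, inset when sampling target end-to-end distances
_MAX_ATTEMPTS = 100  # rejection-sampling cap per frame

# water internal geometry (3-site rigid model)
_OH = 0.9572  # Å
_HOH = np.deg2rad(104.52)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic hairpin ensemble."""

    seed: int = 0
    n_frames: int = 1000
    state: Literal["folded", "unfolded"] = "folded"
    n_residues_per_strand: int = 3
    frame_interval: float = 1.0  # ps; the saving interval is a free parameter
    torsion_jitter: float = 8.0  # degrees std-dev of per-residue ring rotation
    box_edge: float = 40.0  # Å

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_residues_per_strand < 1:
            raise ValueError("n_residues_per_strand must be >= 1")
        if self.torsion_jitter < 0:
            raise ValueError("torsion_jitter must be >= 0")
        if self.state not in ("folded", "unfolded"):
            raise ValueError("state must be 'folded' or 'unfolded'")

    @property
    def distance_range(self) -> tuple[float, float]:
        return FC_RANGE if self.state == "folded" else UFC_RANGE


def end_selections(spec: SyntheticSpec) -> tuple[str, str]:
    """``resid:atomname`` selections of the two terminal O4 end atoms."""
    n = spec.n_residues_per_strand
    return f"{n}:O4", f"{2 * n + 3}:O4"


def _ring_template() -> tuple[np.ndarray, list[str], list[str]]:
    """Idealized residue: hexagonal C₅O ring + exocyclic O4, local frame.

    Local x is the chain axis; C4 sits on +x with O4 extending further
    along it, so torsional rotation about the axis leaves O4 fixed.
    """
    ang = np.deg2rad(60.0 * np.arange(6))
    ring = np.column_stack([_RING_RADIUS * np.cos(ang),
                            np.zeros(6),
                            _RING_RADIUS * np.sin(ang)])
    names = ["C4", "C3", "C2", "C1", "O5", "C5"]
    elements = ["C", "C", "C", "C", "O", "C"]
    o4 = np.array([[_RING_RADIUS + _EXO_BOND, 0.0, 0.0]])
    return np.vstack([ring, o4]), names + ["O4"], elements + ["O"]


_TEMPLATE_XYZ, _TEMPLATE_NAMES, _TEMPLATE_ELEMENTS = _ring_template()
ATOMS_PER_RESIDUE = len(_TEMPLATE_NAMES)


def _rot_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _place_residue(center: np.ndarray, axis: np.ndarray, roll: float) -> np.ndarray:
    """Place the ring template at ``center`` with chain axis ``axis`` and torsion ``roll``."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    y = np.cross(ref, axis)
    y /= np.linalg.norm(y)
    z = np.cross(axis, y)
    R = np.column_stack([axis, y, z]) @ _rot_about_axis(np.array([1.0, 0, 0]), roll).T
    return center + _TEMPLATE_XYZ @ R.T


def _build_hairpin_coords(spec: SyntheticSpec, rng: np.random.Generator,
                          target_d: float) -> np.ndarray:
    """One hairpin configuration aiming at end-to-end distance ``target_d``."""
    n = spec.n_residues_per_strand
    half = _STRAND_SEP / 2.0
    # opening half-angle from the terminal-O4 lever arm
    lever = (n - 0.5) * _AGU_RISE + _RING_RADIUS + _EXO_BOND
    s = np.clip((target_d - _STRAND_SEP) / (2.0 * lever), -0.999, 0.999)
    alpha = np.arcsin(s)
    dir_a = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    dir_b = np.array([np.cos(alpha), -np.sin(alpha), 0.0])
    start_a = np.array([0.0, half, 0.0])
    start_b = np.array([0.0, -half, 0.0])

    jitter_t = np.deg2rad(spec.torsion_jitter)
    pos_sigma = 0.05 + 0.02 * spec.torsion_jitter  # Å

    blocks: list[np.ndarray] = []
    # strand A: resid 1..n, resid n terminal
    for k in range(n):
        roll = (np.pi if k % 2 else 0.0) + rng.normal(0.0, jitter_t)
        c = start_a + (k + 0.5) * _AGU_RISE * dir_a
        blocks.append(_place_residue(c, dir_a, roll))
    # turn: resid n+1..n+3 on a semicircle bridging the strand starts
    for j, theta in enumerate(np.deg2rad([135.0, 180.0, 225.0])):
        c = np.array([half * np.cos(theta) - 1.0, half * np.sin(theta), 0.0])
        axis = np.array([-np.sin(theta), np.cos(theta), 0.0])
        blocks.append(_place_residue(c, axis, rng.normal(0.0, jitter_t)))
    # strand B: resid n+4..2n+3, resid 2n+3 terminal
    for k in range(n):
        roll = (np.pi if k % 2 else 0.0) + rng.normal(0.0, jitter_t)
        c = start_b + (k + 0.5) * _AGU_RISE * dir_b
        blocks.append(_place_residue(c, dir_b, roll))

    coords = np.vstack(blocks)
    coords += rng.normal(0.0, pos_sigma, size=coords.shape)
    return coords


def generate_hairpin_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Generate a seeded hairpin ensemble in the spec's conformational state.

    Every frame's terminal-to-terminal distance (between the designated
    O4 end atoms of the two strands) lies inside the state's admissible
    range — [3, 10] Å folded, [10, 25] Å unfolded — enforced by
    rejection sampling with a cap of 100 attempts per frame.

    Raises
    ------
    RuntimeError
        If the jitter makes the admissible range unattainable within the
        attempt cap (the message reports the attempts used).
    """
    n = spec.n_residues_per_strand
    n_res = 2 * n + 3
    names = np.array(_TEMPLATE_NAMES * n_res)
    elements = np.array(_TEMPLATE_ELEMENTS * n_res)
    resids = np.repeat(np.arange(1, n_res + 1), ATOMS_PER_RESIDUE)
    lo, hi = spec.distance_range
    end_a = n * ATOMS_PER_RESIDUE - 1  # O4 is the template's last atom
    end_b = (2 * n + 3) * ATOMS_PER_RESIDUE - 1

    sample_lo = lo + _RANGE_MARGIN
    sample_hi = hi - _RANGE_MARGIN
    if sample_hi <= sample_lo:
        sample_lo = sample_hi = 0.5 * (lo + hi)

    frames = []
    for i in range(spec.n_frames):
        rng = np.random.default_rng([spec.seed, i])  # per-frame sub-seed
        coords = None
        for attempt in range(1, _MAX_ATTEMPTS + 1):
            target = rng.uniform(sample_lo, sample_hi)
            trial = _build_hairpin_coords(spec, rng, target)
            d = np.linalg.norm(trial[end_a] - trial[end_b])
            if lo <= d <= hi:
                coords = trial
                break
        if coords is None:
            raise RuntimeError(
                f"frame {i}: could not reach end-to-end range [{lo}, {hi}] Å in "
                f"{_MAX_ATTEMPTS} attempts; torsion_jitter={spec.torsion_jitter}° "
                "is too large for this range")
        coords = coords - coords.mean(axis=0) + spec.box_edge / 2.0
        frames.append(AtomicFrame(
            elements=elements, coords=coords, resids=resids, names=names,
            box=np.full(3, spec.box_edge), time=i * spec.frame_interval))
    sel_a, sel_b = end_selections(spec)
    return Trajectory(frames=frames, metadata={
        "spec": asdict(spec), "end_selection_a": sel_a, "end_selection_b": sel_b})


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _water_sites_to_atoms(sites: np.ndarray, rng: np.random.Generator,
                          first_resid: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Expand O sites into rigid 3-site waters with random orientations."""
    local = np.array([
        [0.0, 0.0, 0.0],
        [_OH, 0.0, 0.0],
        [_OH * np.cos(_HOH), _OH * np.sin(_HOH), 0.0],
    ])
    coords = np.empty((3 * len(sites), 3))
    for m, site in enumerate(sites):
        R = _random_rotation(rng)
        coords[3 * m:3 * m + 3] = site + local @ R.T
    n = len(sites)
    names = np.tile(["OW", "HW1", "HW2"], n)
    elements = np.tile(["O", "H", "H"], n)
    resids = np.repeat(first_resid + np.arange(n), 3)
    return coords, elements, resids, names


def solvate_frame(frame: AtomicFrame, envelope: Envelope,
                  number_density: float = BULK_WATER_DENSITY,
                  contact: float = 1.8,
                  seed: int = 0,
                  max_clash_fraction: float = 0.9) -> AtomicFrame:
    """Add hydration water inside the envelope around a solute frame.

    Water oxygens are placed on a randomly offset cubic lattice of
    spacing ``density^(-1/3)``, jittered, restricted to the envelope,
    and rejected within ``contact`` Å of any solute atom; two hydrogens
    at rigid 3-site geometry (O–H 0.9572 Å, H–O–H 104.52°) with random
    orientation complete each molecule.  The realized count matches
    ``number_density × accessible volume`` to within lattice statistics.

    Raises
    ------
    ValueError
        If the clash-rejected fraction of in-envelope sites exceeds
        ``max_clash_fraction`` (steric infeasibility).
    """
    from scipy.spatial import cKDTree

    if number_density <= 0:
        raise ValueError("number density must be positive")
    if envelope.volume <= 0:
        return frame.copy()

    rng = np.random.default_rng([seed, 0x57A7E])
    a = number_density ** (-1.0 / 3.0)
    centers = envelope.voxel_centers()
    lo = centers.min(axis=0) - envelope.spacing
    hi = centers.max(axis=0) + envelope.spacing
    offset = rng.uniform(0.0, a, size=3)
    axes = [np.arange(lo[d] + offset[d] - a, hi[d] + a, a) for d in range(3)]
    sites = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    sites = sites + rng.uniform(-0.3 * a, 0.3 * a, size=sites.shape)
    sites = sites[envelope.contains(sites)]
    if len(sites) == 0:
        return frame.copy()

    if frame.n_atoms and contact > 0:
        d, _ = cKDTree(frame.coords).query(sites, workers=-1)
        keep = d > contact
        clash_fraction = 1.0 - keep.mean()
        if clash_fraction > max_clash_fraction:
            raise ValueError(
                f"water placement failed for {clash_fraction:.0%} of in-envelope sites "
                f"(cap {max_clash_fraction:.0%}); density/contact sterically infeasible")
        sites = sites[keep]
    if len(sites) == 0:
        return frame.copy()

    first_resid = int(frame.resids.max()) + 1 if frame.n_atoms else 1
    wc, we, wr, wn = _water_sites_to_atoms(sites, rng, first_resid)
    return AtomicFrame(
        elements=np.concatenate([frame.elements, we]),
        coords=np.vstack([frame.coords, wc]),
        resids=np.concatenate([frame.resids, wr]),
        names=np.concatenate([frame.names, wn]),
        box=frame.box.copy(), time=frame.time)


def solvate_trajectory(traj: Trajectory, envelope: Envelope,
                       number_density: float = BULK_WATER_DENSITY,
                       contact: float = 1.8, seed: int = 0) -> list[AtomicFrame]:
    """Solvate every frame with per-frame sub-seeded water.

    Returns a plain frame list (atom counts vary per frame, so the
    result is not a constant-layout :class:`Trajectory`).
    """
    return [solvate_frame(f, envelope, number_density, contact,
                          seed=int(np.random.default_rng([seed, i]).integers(2**31)))
            for i, f in enumerate(traj.frames)]


def generate_solvent_trajectory(envelope: Envelope, n_frames: int,
                                number_density: float = BULK_WATER_DENSITY,
                                seed: int = 0,
                                box_edge: float = 40.0,
                                frame_interval: float = 1.0) -> list[AtomicFrame]:
    """Pure-water frames filling the envelope at bulk density (no solute)."""
    rng_master = np.random.default_rng([seed, 0xB0F])
    frames = []
    empty = AtomicFrame(elements=np.empty(0, "U2"), coords=np.empty((0, 3)),
                        resids=np.empty(0, int), names=np.empty(0, "U6"),
                        box=np.full(3, box_edge), time=0.0)
    for i in range(n_frames):
        sub = int(rng_master.integers(2**31))
        f = solvate_frame(empty, envelope, number_density, contact=0.0, seed=sub)
        f.time = i * frame_interval
        frames.append(f)
    return frames


def generate_analytic_shape(shape: Literal["point_set_sphere", "point_set_cylinder"],
                            *, n: int, radius: float, length: float | None = None,
                            seed: int = 0, element: str = "C") -> AtomicFrame:
    """Uniform point set filling a solid sphere or cylinder (oracle fixture).

    Closed forms these fixtures validate: sphere Rg = √(3/5)·R; cylinder
    Rg = √(L²/12 + R²/2); sphere form-factor first minimum at
    q ≈ 4.493/R.
    """
    if n < 1:
        raise ValueError("point count must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    if shape == "point_set_sphere":
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius * rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
        coords = v * r[:, None]
        extent = 2 * radius
    elif shape == "point_set_cylinder":
        if length is None or length <= 0:
            raise ValueError("cylinder length must be positive")
        rr = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
        phi = rng.uniform(0.0, 2 * np.pi, n)
        z = rng.uniform(-length / 2.0, length / 2.0, n)
        coords = np.column_stack([rr * np.cos(phi), rr * np.sin(phi), z])
        extent = max(length, 2 * radius)
    else:
        raise ValueError("shape must be 'point_set_sphere' or 'point_set_cylinder'")
    return AtomicFrame(
        elements=np.full(n, element), coords=coords,
        resids=np.arange(1, n + 1), names=np.full(n, "PS"),
        box=np.full(3, extent + 20.0))


def synthesize_experimental_curve(model: ScatteringCurve, scale: float = 1.0,
                                  constant: float = 0.0, noise_seed: int = 0,
                                  relative_sigma: float = 0.05) -> ScatteringCurve:
    """Emulate a measured curve: affine transform plus Gaussian noise.

    ``I_exp = scale·I + constant + ε`` with ε ~ N(0, (relative_sigma ×
    (scale·I + constant))²); the sigma column records that magnitude.
    Mirrors dilute, low-concentration measurement statistics.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if relative_sigma < 0:
        raise ValueError("relative_sigma must be >= 0")
    base = scale * model.I + constant
    sigma = relative_sigma * np.abs(base)
    rng = np.random.default_rng(noise_seed)
    noisy = base + rng.normal(0.0, 1.0, len(base)) * sigma
    return ScatteringCurve(model.q.copy(), noisy, sigma, metadata={
        "synthetic_experiment": True, "scale": scale, "constant": constant,
        "relative_sigma": relative_sigma, "noise_seed": noise_seed})
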