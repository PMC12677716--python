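"""SAXS intensities from atomistic ensembles.

Two routes to the orientationally averaged intensity are provided:

* :func:`debye_intensity` — the Debye double sum
  ``I(q) = Σ_i Σ_j f_i f_j sin(q r_ij)/(q r_ij)``, the *exact*
  orientational average of a single configuration.  O(N²) per frame; it
  serves as the brute-force oracle.
* :func:`orientational_intensity` — numerical orientational averaging of
  ``|Σ_i f_i exp(i q u·r_i)|²`` over a deterministic Fibonacci point set
  of directions ``u``, averaged over frames.  This is the workhorse for
  ensembles and converges to the Debye result as the direction count
  grows.

:func:`excess_intensity` computes the buffer-subtracted ensemble
intensity ``⟨|A|²⟩_solute-system − ⟨|B|²⟩_solvent-system`` restricted to
a solvation envelope, which is the quantity comparable to a
background-subtracted experiment.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np

from .core import AtomicFrame, ScatteringCurve, Trajectory
from .envelope import Envelope, build_envelope  # re-exported
from .formfactors import atomic_form_factor, form_factor_table

__all__ = [
    "default_q_grid",
    "fibonacci_directions",
    "debye_intensity",
    "orientational_intensity",
    "excess_intensity",
    "Envelope",
    "build_envelope",
    "atomic_form_factor",
]

WATER_ATOM_NAMES = frozenset({"OW", "HW1", "HW2"})


def default_q_grid(qmin: float = 0.01, qmax: float = 0.5, n: int = 100,
                   spacing: str = "log") -> np.ndarray:
    """Default momentum-transfer grid, 0.01–0.5 Å⁻¹.

    ``spacing`` is ``"log"`` (default, resolves the Guinier region) or
    ``"linear"`` (enables the fast uniform-grid path of
    :func:`orientational_intensity`).
    """
    if qmin <= 0 or qmax <= qmin:
        raise ValueError("need 0 < qmin < qmax")
    if spacing == "log":
        return np.geomspace(qmin, qmax, n)
    if spacing == "linear":
        return np.linspace(qmin, qmax, n)
    raise ValueError("spacing must be 'log' or 'linear'")


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform point set of ``n`` unit vectors (golden-spiral)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _as_frames(obj) -> list[AtomicFrame]:
    if isinstance(obj, AtomicFrame):
        return [obj]
    if isinstance(obj, Trajectory):
        return list(obj.frames)
    frames = list(obj)
    if not frames:
        raise ValueError("empty frame set")
    return frames


def debye_intensity(frame: AtomicFrame | Trajectory, q_grid: np.ndarray | None = None
                    ) -> ScatteringCurve:
    """Exact orientationally averaged intensity of one or more frames (Debye sum).

    For a trajectory the per-frame intensities are averaged.  The i=j /
    r_ij→0 limit of sin(x)/x is 1, so ``I(0) = (Σ_i f_i(0))²``.
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
    frames = _as_frames(frame)
    F = form_factor_table(frames[0].elements, q)  # (Q, N)
    n = frames[0].n_atoms
    iu, ju = np.triu_indices(n, k=1)
    I = np.zeros(len(q))
    for fr in frames:
        d = np.linalg.norm(fr.coords[iu] - fr.coords[ju], axis=1)
        self_term = np.sum(F * F, axis=1)
        I_frame = self_term.copy()
        if len(d):
            for k, qk in enumerate(q):
                # np.sinc(x) = sin(pi x)/(pi x)  ->  sin(qd)/(qd)
                I_frame[k] += 2.0 * np.sum(F[k, iu] * F[k, ju] * np.sinc(qk * d / np.pi))
        I += I_frame
    I /= len(frames)
    return ScatteringCurve(q, I, metadata={"method": "debye", "n_frames": len(frames)})


def _orient_frame_intensity(coords: np.ndarray, F: np.ndarray, q: np.ndarray,
                            U: np.ndarray) -> np.ndarray:
    """Direction-averaged |A(q)|² for one configuration; F is (Q, N)."""
    T = coords @ U.T  # (N, M) projected coordinates u·r
    Q = len(q)
    I = np.empty(Q)
    dq = np.diff(q)
    uniform = Q > 2 and np.allclose(dq, dq[0], rtol=1e-9, atol=1e-12)
    if uniform:
        # phase recurrence: exp(i q_k t) = exp(i q_0 t) · exp(i Δq t)^k
        P = np.exp(1j * q[0] * T)
        B = np.exp(1j * dq[0] * T)
        for k in range(Q):
            A = F[k] @ P
            I[k] = np.mean(A.real**2 + A.imag**2)
            if k < Q - 1:
                P *= B
    else:
        for k in range(Q):
            A = F[k] @ np.exp(1j * q[k] * T)
            I[k] = np.mean(A.real**2 + A.imag**2)
    return I


def orientational_intensity(frames: Trajectory | AtomicFrame | Iterable[AtomicFrame],
                            q_grid: np.ndarray | None = None,
                            n_directions: int = 400) -> ScatteringCurve:
    """Ensemble intensity by numerical orientational averaging.

    For each q the squared amplitude is averaged over a deterministic
    Fibonacci direction set (seedless and reproducible), then over
    frames.  Converges to :func:`debye_intensity` as ``n_directions``
    grows; ~400 directions keep the error well under 1% for q ≤ 0.5 Å⁻¹
    on solute-sized systems.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
    frame_list = _as_frames(frames)
    U = fibonacci_directions(n_directions)
    F = form_factor_table(frame_list[0].elements, q)
    I = np.zeros(len(q))
    for fr in frame_list:
        I += _orient_frame_intensity(fr.coords, F, q, U)
    I /= len(frame_list)
    return ScatteringCurve(q, I, metadata={
        "method": "orientational", "n_directions": n_directions,
        "n_frames": len(frame_list)})


def _water_molecule_filter(frame: AtomicFrame, envelope: Envelope,
                           solvent_names: frozenset[str]) -> np.ndarray:
    """Indices keeping non-water atoms plus water molecules whose O is in the envelope."""
    is_water = np.isin(frame.names, list(solvent_names))
    keep = ~is_water
    ow = np.flatnonzero(frame.names == "OW")
    if len(ow):
        inside = envelope.contains(frame.coords[ow])
        for oi, ok in zip(ow, np.atleast_1d(inside)):
            if ok:
                sel = np.flatnonzero(frame.resids == frame.resids[oi])
                keep[sel] = True
    return np.flatnonzero(keep)


def _mean_system_intensity(frames: list[AtomicFrame], envelope: Envelope,
                           q: np.ndarray, U: np.ndarray,
                           solvent_names: frozenset[str],
                           require_solute_inside: bool) -> np.ndarray:
    I = np.zeros(len(q))
    for fr in frames:
        idx = _water_molecule_filter(fr, envelope, solvent_names)
        sub = fr.subset(idx)
        if require_solute_inside:
            solute = ~np.isin(sub.names, list(solvent_names))
            if np.any(solute) and not np.all(envelope.contains(sub.coords[solute])):
                raise ValueError(
                    "envelope excludes solute atoms; rebuild it from the same window")
        if sub.n_atoms == 0:
            continue
        F = form_factor_table(sub.elements, q)
        I += _orient_frame_intensity(sub.coords, F, q, U)
    return I / len(frames)


def excess_intensity(solute_system: Trajectory,
                     solvent_system: Trajectory | None,
                     envelope: Envelope,
                     q_grid: np.ndarray | None = None,
                     n_directions: int = 400,
                     solvent_names: frozenset[str] = WATER_ATOM_NAMES) -> ScatteringCurve:
    """Buffer-subtracted ensemble intensity restricted to the envelope.

    ``I(q) = ⟨|A(q)|²⟩ − ⟨|B(q)|²⟩`` where A sums the amplitudes of the
    solute plus in-envelope water of the solute system and B sums the
    in-envelope amplitudes of the pure-solvent system; each term is
    orientationally averaged per frame and then ensemble averaged.  The
    estimator is the plain difference of the two ensemble means (exact
    in the mean; swap in a variance-reduced estimator by replacing this
    function behind the same signature).

    Water atoms are recognized by name (``OW``/``HW1``/``HW2`` by
    default); a water molecule is kept when its oxygen lies inside the
    envelope.  Every solute atom must be inside the envelope in every
    frame.  Passing ``solvent_system=None`` gives the vacuum limit
    (no subtraction).
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
    U = fibonacci_directions(n_directions)
    solute_frames = _as_frames(solute_system)
    IA = _mean_system_intensity(solute_frames, envelope, q, U, solvent_names,
                                require_solute_inside=True)
    n_solvent = 0
    if solvent_system is None:
        I = IA
    else:
        solvent_frames = _as_frames(solvent_system)
        n_solvent = len(solvent_frames)
        if n_solvent != len(solute_frames):
            warnings.warn(
                f"frame counts differ: {len(solute_frames)} solute-system vs "
                f"{n_solvent} solvent-system frames; ensemble means are still unbiased",
                stacklevel=2)
        IB = _mean_system_intensity(solvent_frames, envelope, q, U, solvent_names,
                                    require_solute_inside=False)
        I = IA - IB
    return ScatteringCurve(q, I, metadata={
        "method": "excess", "n_directions": n_directions,
        "n_frames": len(solute_frames), "n_solvent_frames": n_solvent,
        "envelope_distance": envelope.distance})
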