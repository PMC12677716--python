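"""Trajectory analytics: Rg, end-to-end, window classification, torsions, H-bonds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glysaxs as g
from glysaxs.conformation import (ConformationWindow, classify_windows, dihedral,
                                  end_to_end_distance, end_to_end_series,
                                  hbond_occupancy, radius_of_gyration,
                                  ramachandran_density, torsion_series)
from glysaxs.conformation import TorsionSeries
from glysaxs.core import SelectionError


def _frame(coords, elements=None, names=None, resids=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    return g.AtomicFrame(
        elements=elements or ["C"] * n,
        coords=coords,
        resids=resids if resids is not None else np.arange(1, n + 1),
        names=names or [f"A{i}" for i in range(n)])


# ------------------------------------------------------- radius of gyration

def test_single_atom_rg_zero():
    assert radius_of_gyration(_frame([[1.0, 2.0, 3.0]])) == pytest.approx(0.0, abs=1e-12)


def test_symmetric_dumbbell():
    fr = _frame([[0, 0, 0], [2, 0, 0]])
    assert radius_of_gyration(fr, "uniform") == pytest.approx(1.0)


def test_weighting_modes_differ_for_mixed_elements():
    fr = _frame([[0, 0, 0], [2, 0, 0]], elements=["H", "O"])
    r_u = radius_of_gyration(fr, "uniform")
    r_m = radius_of_gyration(fr, "mass")
    r_e = radius_of_gyration(fr, "electron")
    assert r_u == pytest.approx(1.0)
    assert r_m < r_u and r_e < r_u  # both pulled toward the heavy atom
    assert r_m != pytest.approx(r_e, rel=1e-3)


@settings(max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_rg_rigid_motion_invariance(seed):
    rng = np.random.default_rng(seed)
    fr = _frame(rng.normal(0, 3, (15, 3)))
    r0 = radius_of_gyration(fr, "uniform")
    # random rotation + translation
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    fr2 = fr.copy()
    fr2.coords = fr.coords @ Q.T + rng.uniform(-50, 50, 3)
    assert radius_of_gyration(fr2, "uniform") == pytest.approx(r0, rel=1e-9)


# --------------------------------------------------------- end-to-end

def test_345_triangle():
    fr = _frame([[0, 0, 0], [3, 4, 0]], names=["O4", "O4"], resids=[1, 2])
    assert end_to_end_distance(fr, "1:O4", "2:O4") == pytest.approx(5.0)


def test_identical_selection_zero():
    fr = _frame([[1, 1, 1], [2, 2, 2]], names=["O4", "O4"], resids=[1, 2])
    assert end_to_end_distance(fr, "1:O4", "1:O4") == 0.0


def test_ambiguous_selection_names_matches():
    fr = _frame([[0, 0, 0], [1, 0, 0]], names=["O4", "O4"], resids=[1, 1])
    with pytest.raises(SelectionError, match="matched 2"):
        end_to_end_distance(fr, "1:O4", "1:O4")


def test_folded_series_in_range(folded_traj):
    d = end_to_end_series(folded_traj)
    assert np.all((d >= 3.0) & (d <= 10.0))


# ------------------------------------------------- window classification

def test_all_folded_series_single_window():
    w = classify_windows(np.full(1200, 5.0))
    assert len(w) == 1 and w[0].label == "fc" and (w[0].start, w[0].end) == (0, 1200)


def test_all_unfolded_series_single_window():
    w = classify_windows(np.full(1200, 15.0))
    assert len(w) == 1 and w[0].label == "ufc"


def test_short_runs_dropped():
    d = np.concatenate([np.full(1500, 5.0), np.full(500, 15.0), np.full(1100, 16.0)])
    w = classify_windows(d)
    # the 500-frame ufc run merges with the following 1100-frame run (same label)
    assert [(x.label, x.start, x.end) for x in w] == [("fc", 0, 1500), ("ufc", 1500, 3100)]


def test_gap_frames_break_windows():
    d = np.concatenate([np.full(1200, 5.0), np.full(3, 30.0), np.full(1200, 5.0)])
    w = classify_windows(d)
    assert [(x.start, x.end) for x in w] == [(0, 1200), (1203, 2403)]


def test_every_window_frame_satisfies_its_range():
    rng = np.random.default_rng(3)
    d = rng.uniform(0.0, 30.0, 5000)
    for w in classify_windows(d, min_frames=2):
        lo, hi = w.criterion
        assert np.all((d[w.start:w.end] >= lo) & (d[w.start:w.end] <= hi))


def test_windows_do_not_overlap():
    rng = np.random.default_rng(4)
    d = rng.uniform(2.0, 26.0, 20000)
    ws = classify_windows(d, min_frames=1)
    for a, b in zip(ws, ws[1:]):
        assert a.end <= b.start


def test_interior_overlapping_ranges_rejected():
    with pytest.raises(ValueError, match="overlap"):
        classify_windows([5.0], fc_range=(3, 12), ufc_range=(10, 25))


def test_brute_force_oracle_agreement():
    """Run-length scan oracle on a long random series."""
    rng = np.random.default_rng(99)
    d = rng.choice([5.0, 15.0, 28.0], size=100_000, p=[0.45, 0.45, 0.1])
    min_frames = 7

    def oracle(series):
        out = []
        i = 0
        while i < len(series):
            if 3 <= series[i] <= 10:
                lab = "fc"
            elif 10 < series[i] <= 25:
                lab = "ufc"
            else:
                lab = None
            j = i
            while j < len(series) and (
                (lab == "fc" and 3 <= series[j] <= 10)
                or (lab == "ufc" and 10 < series[j] <= 25)
                or (lab is None and not (3 <= series[j] <= 25))
            ):
                j += 1
            if lab and j - i >= min_frames:
                out.append((lab, i, j))
            i = j
        return out

    got = [(w.label, w.start, w.end)
           for w in classify_windows(d, min_frames=min_frames)]
    assert got == oracle(d)


# ---------------------------------------------------------------- dihedral

def test_planar_cis_is_zero():
    pts = np.array([[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]], float)
    assert dihedral(pts) == pytest.approx(0.0, abs=1e-10)


def test_planar_trans_is_180():
    pts = np.array([[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]], float)
    assert dihedral(pts) == pytest.approx(180.0)


def test_quarter_turn_example():
    pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], float)
    assert dihedral(pts) == pytest.approx(-90.0)


def test_collinear_rejected():
    pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], float)
    with pytest.raises(ValueError, match="collinear"):
        dihedral(pts)


@settings(max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_dihedral_rigid_invariance_and_mirror_flip(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(0, 2, (4, 3))
    try:
        a0 = dihedral(pts)
    except ValueError:
        return  # degenerate draw
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    moved = pts @ Q.T + rng.uniform(-10, 10, 3)
    assert dihedral(moved) == pytest.approx(a0, abs=1e-6)
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    if abs(abs(a0) - 180.0) > 1e-6:  # ±180 is the same angle
        assert dihedral(mirrored) == pytest.approx(-a0, abs=1e-6)


# ------------------------------------------------------------ Ramachandran

def test_point_mass_mode():
    series = TorsionSeries("L1", "heavy_atom",
                           np.full(50, 45.0), np.full(50, -15.0))
    dens = ramachandran_density(series, bin_width=10.0)
    assert dens.density.sum() == pytest.approx(1.0)
    phi_star, psi_star = dens.mode
    assert abs(phi_star - 45.0) <= 5.0 and abs(psi_star - (-15.0)) <= 5.0


def test_single_frame_single_bin():
    series = TorsionSeries("L1", "heavy_atom", np.array([10.0]), np.array([20.0]))
    dens = ramachandran_density(series, 10.0)
    assert dens.density.max() == 1.0


def test_uniform_angles_flatten():
    rng = np.random.default_rng(5)
    n = 100_000
    series = TorsionSeries("L1", "hydrogen_based",
                           rng.uniform(-179.99, 180.0, n),
                           rng.uniform(-179.99, 180.0, n))
    dens = ramachandran_density(series, 30.0)
    counts = dens.density * n
    # chi-square uniformity: all 144 bins within 5 sigma of the mean
    expect = n / counts.size
    assert np.all(np.abs(counts - expect) < 5 * np.sqrt(expect))


def test_bad_bin_width_rejected():
    series = TorsionSeries("L1", "heavy_atom", np.array([0.0]), np.array([0.0]))
    with pytest.raises(ValueError):
        ramachandran_density(series, 7.0)


def test_torsion_series_on_trajectory(folded_traj):
    ts = torsion_series(folded_traj, "1-2", ["1:O5", "1:C1", "2:O4", "2:C4"],
                        ["1:C1", "2:O4", "2:C4", "2:C3"])
    assert len(ts.phi) == folded_traj.n_frames
    assert np.all((ts.phi > -180) & (ts.phi <= 180))


# -------------------------------------------------------------- H-bonds

def _hbond_traj(n_satisfied, n_total, d_good=2.8, d_bad=10.0):
    frames = []
    for i in range(n_total):
        d_oa = d_good if i < n_satisfied else d_bad
        coords = [[0, 0, 0], [0.96, 0, 0], [d_oa, 0, 0]]  # linear D-H...A
        frames.append(g.AtomicFrame(
            elements=["O", "H", "O"], coords=coords,
            resids=[1, 1, 2], names=["O3", "HO3", "O5"], time=float(i)))
    return g.Trajectory(frames=frames)


def test_always_satisfied_occupancy_one():
    occ = hbond_occupancy(_hbond_traj(10, 10), [("1:O3", "1:HO3", "2:O5")])
    assert occ[0].occupancy == 1.0
    assert occ[0].warning is None


def test_never_satisfied_occupancy_zero():
    occ = hbond_occupancy(_hbond_traj(0, 10), [("1:O3", "1:HO3", "2:O5")])
    assert occ[0].occupancy == 0.0


def test_half_satisfied_counting():
    occ = hbond_occupancy(_hbond_traj(600, 1200), [("1:O3", "1:HO3", "2:O5")])
    assert occ[0].occupancy == pytest.approx(0.5)


def test_detached_hydrogen_warns_in_record():
    frames = [g.AtomicFrame(elements=["O", "H", "O"],
                            coords=[[0, 0, 0], [3.0, 0, 0], [5.8, 0, 0]],
                            resids=[1, 1, 2], names=["O3", "HO3", "O5"])]
    occ = hbond_occupancy(g.Trajectory(frames=frames), [("1:O3", "1:HO3", "2:O5")])
    assert occ[0].warning is not None and "1.2" in occ[0].warning
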