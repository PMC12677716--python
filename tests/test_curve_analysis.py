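"""Curve analytics: I/O round trip, Guinier, Kratky, rod model, model fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glysaxs as g
from glysaxs.curve_analysis import (AGU_LENGTH, agu_count, compare_models,
                                    cylinder_rg, fit_model_to_experiment,
                                    guinier_fit, kratky, kratky_peak, read_curve,
                                    rod_length_from_rg, write_curve)


def _gaussian_curve(rg, i0=100.0, q=None, sigma_rel=None):
    q = np.geomspace(0.01, 0.5, 120) if q is None else q
    I = i0 * np.exp(-q**2 * rg**2 / 3.0)
    sigma = None if sigma_rel is None else sigma_rel * I
    return g.ScatteringCurve(q, I, sigma)


# ------------------------------------------------------------------- I/O

def test_round_trip_preserves_values(tmp_path):
    curve = _gaussian_curve(8.8, sigma_rel=0.05)
    path = tmp_path / "c.dat"
    write_curve(curve, path)
    back = read_curve(path)
    assert np.allclose(back.q, curve.q, rtol=1e-6)
    assert np.allclose(back.I, curve.I, rtol=1e-6)
    assert np.allclose(back.sigma, curve.sigma, rtol=1e-6)


def test_nm_unit_conversion(tmp_path):
    path = tmp_path / "nm.dat"
    path.write_text("# q[1/nm] I\n1.0 10.0\n2.0 5.0\n")
    c = read_curve(path, q_unit="nm")
    assert np.allclose(c.q, [0.1, 0.2])
    auto = read_curve(path, q_unit="auto")  # max q > 2? no; stays angstrom
    assert np.allclose(auto.q, [1.0, 2.0])
    path.write_text("1.0 10.0\n25.0 5.0\n")
    auto2 = read_curve(path, q_unit="auto")  # max q > 2 -> assumed nm^-1
    assert np.allclose(auto2.q, [0.1, 2.5])


def test_two_column_file_has_no_sigma(tmp_path):
    path = tmp_path / "two.dat"
    path.write_text("0.1 10\n0.2 5\n0.3 2\n")
    c = read_curve(path)
    assert c.sigma is None


def test_bad_files_rejected(tmp_path):
    p = tmp_path / "bad.dat"
    p.write_text("0.2 10\n0.1 5\n")
    with pytest.raises(ValueError, match="increasing"):
        read_curve(p)
    p.write_text("0.1 10 -1\n0.2 5 1\n")
    with pytest.raises(ValueError, match="sigma"):
        read_curve(p)


# ---------------------------------------------------------------- Guinier

def test_guinier_exact_on_model_matched_input():
    for rg, i0 in [(8.8, 100.0), (7.9, 3.0)]:
        res = guinier_fit(_gaussian_curve(rg, i0))
        assert res.rg == pytest.approx(rg, rel=1e-12)
        assert res.i0 == pytest.approx(i0, rel=1e-12)


@settings(max_examples=50, derandomize=True)
@given(rg=st.floats(min_value=2.0, max_value=20.0),
       i0=st.floats(min_value=1e-3, max_value=1e6))
def test_guinier_exact_for_random_parameters(rg, i0):
    res = guinier_fit(_gaussian_curve(rg, i0))
    assert res.rg == pytest.approx(rg, rel=1e-9)
    assert res.i0 == pytest.approx(i0, rel=1e-9)


def test_guinier_validity_flag():
    assert not guinier_fit(_gaussian_curve(8.8)).valid  # qmax*Rg = 2.16
    assert guinier_fit(_gaussian_curve(3.0)).valid  # qmax*Rg = 0.73


def test_guinier_qmax_rg_limited_mode():
    res = guinier_fit(_gaussian_curve(8.8), qmax_rg_limit=1.3)
    assert res.qmax_rg <= 1.3 + 1e-6
    assert res.rg == pytest.approx(8.8, rel=1e-9)


def test_guinier_error_cases():
    q = np.geomspace(0.01, 0.5, 50)
    rising = g.ScatteringCurve(q, 1.0 + q**2)
    with pytest.raises(ValueError, match="Guinier decay"):
        guinier_fit(rising)
    narrow = g.ScatteringCurve(np.array([0.01, 0.02]), np.array([1.0, 0.9]))
    with pytest.raises(ValueError, match="3 points"):
        guinier_fit(narrow)


def test_guinier_sigma_weighting_downweights_outlier():
    curve = _gaussian_curve(8.0, sigma_rel=0.01)
    k = len(curve.q) // 2
    curve.I[k] *= 3.0  # corrupt one point
    curve.sigma[k] = 1e6  # and mark it unreliable
    res = guinier_fit(curve)
    assert res.rg == pytest.approx(8.0, rel=1e-3)


# ----------------------------------------------------------------- Kratky

def test_kratky_transform_and_gaussian_peak():
    rg = 8.66
    curve = _gaussian_curve(rg, q=np.geomspace(0.01, 0.5, 200))
    k = kratky(curve)
    assert np.allclose(k.I, curve.q**2 * curve.I)
    peak = kratky_peak(curve)
    expected = np.sqrt(3.0) / rg
    step = np.max(np.diff(curve.q[(curve.q > 0.15) & (curve.q < 0.25)]))
    assert abs(peak - expected) <= step


def test_flat_curve_peak_at_last_point():
    q = np.linspace(0.01, 0.5, 30)
    c = g.ScatteringCurve(q, np.ones_like(q))
    assert np.allclose(kratky(c).I, q**2)
    assert kratky_peak(c) == q[-1]


def test_kratky_peak_scale_invariant():
    c = _gaussian_curve(8.66)
    assert kratky_peak(c) == kratky_peak(c.scaled(10.0))


# ------------------------------------------------------------- rod model

def test_rod_lengths_from_reported_rg_values():
    rod_a = rod_length_from_rg(8.8, 3.0)
    assert rod_a.length == pytest.approx(np.sqrt(12 * 8.8**2 - 6 * 9.0))
    assert rod_a.length_rounded == 30
    rod_b = rod_length_from_rg(7.9, 3.0)
    assert rod_b.length_rounded == 26


def test_thin_rod_limit():
    rod = rod_length_from_rg(5.0, 0.0)
    assert rod.length == pytest.approx(np.sqrt(12.0) * 5.0)


def test_inconsistent_rg_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        rod_length_from_rg(2.0, 3.0)


def test_agu_counting():
    assert agu_count(26.0).count == 5
    assert agu_count(5.15) == (1, pytest.approx(1.0))
    c30 = agu_count(30.0)
    assert c30.count == 6 and c30.ratio == pytest.approx(30.0 / 5.15)
    with pytest.raises(ValueError):
        agu_count(0.0)


def test_cylinder_rg_closed_form_and_inverse():
    assert cylinder_rg(26.0, 3.0) == pytest.approx(np.sqrt(26**2 / 12 + 4.5))
    assert cylinder_rg(0.0, 3.0) == pytest.approx(3.0 / np.sqrt(2.0))
    with pytest.raises(ValueError):
        cylinder_rg(0.0, 0.0)


@settings(max_examples=40, derandomize=True)
@given(length=st.floats(min_value=1.0, max_value=100.0),
       radius=st.floats(min_value=0.1, max_value=10.0))
def test_rod_relation_round_trips(length, radius):
    assert rod_length_from_rg(cylinder_rg(length, radius), radius).length == \
        pytest.approx(length, rel=1e-9)


def test_rod_guinier_pipeline_recovers_length_within_10pct():
    """Rod fixture -> Debye -> validity-limited Guinier -> rod length."""
    true_L, R = 40.0, 3.0
    fr = g.generate_analytic_shape("point_set_cylinder", n=1500, radius=R,
                                   length=true_L, seed=6)
    q = np.geomspace(0.005, 0.3, 80)
    curve = g.debye_intensity(fr, q)
    res = guinier_fit(curve, q2_range=(2.5e-5, 0.06), qmax_rg_limit=1.3)
    L = rod_length_from_rg(res.rg, R).length
    assert L == pytest.approx(true_L, rel=0.10)


# ------------------------------------------------------ model fitting

def test_identity_fit():
    c = _gaussian_curve(8.0, sigma_rel=0.05)
    f = fit_model_to_experiment(c, c)
    assert f.scale == pytest.approx(1.0)
    assert f.constant == pytest.approx(0.0, abs=1e-9)
    assert f.chi2 == pytest.approx(0.0, abs=1e-12)


def test_affine_recovery():
    model = _gaussian_curve(8.0)
    exp = model.scaled(2.0, 5.0)
    f = fit_model_to_experiment(model, exp)
    assert f.scale == pytest.approx(2.0)
    assert f.constant == pytest.approx(5.0)


def test_chi2_calibrated_on_correct_noise():
    q = np.linspace(0.01, 0.5, 200)
    model = _gaussian_curve(8.0, q=q)
    exp = g.synthesize_experimental_curve(model, noise_seed=21, relative_sigma=0.05)
    f = fit_model_to_experiment(model, exp)
    assert 0.7 <= f.chi2_reduced <= 1.3
    assert f.dof == f.n_points - 2


def test_non_overlapping_ranges_rejected():
    a = g.ScatteringCurve(np.linspace(0.01, 0.1, 10), np.ones(10))
    b = g.ScatteringCurve(np.linspace(0.2, 0.4, 10), np.ones(10))
    with pytest.raises(ValueError, match="overlap"):
        fit_model_to_experiment(a, b)


def test_compare_models_picks_truth():
    q = np.linspace(0.01, 0.5, 150)
    folded = _gaussian_curve(7.0, q=q)
    unfolded = _gaussian_curve(9.5, q=q)
    exp = g.synthesize_experimental_curve(folded, noise_seed=4, relative_sigma=0.05)
    verdict, fits = compare_models({"folded": folded, "unfolded": unfolded}, exp)
    assert verdict == "folded"
    assert fits["folded"].chi2 < fits["unfolded"].chi2
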