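"""Forward-model and montage geometry tests.

The eccentric-dipole series is validated against an independent closed form:
the generating-function potential ``V = (1/(4 pi sigma)) m . grad_r0 F`` with
``F = (1/R) [2 (1/k - 1) + ln(2 / (1 - t x + k))]``, ``k = sqrt(1 - 2 t x +
t^2)``, evaluated by central finite differences — a derivation path that never
touches the Legendre recurrences used by the implementation.
"""

import math

import numpy as np
import pytest

from icpolarity.head_model import (
    Dipole,
    Electrode,
    HeadModel,
    MONTAGE_62,
    dipole_potential,
    electrode_array,
    leadfield,
    load_electrodes,
    make_montage,
    packaged_62_montage,
    save_electrodes,
    standard_62_montage,
)
from icpolarity.dipole_fit import fibonacci_directions


def closed_form_potential(r0_mm, p_nam, e_mm, R_mm=85.0, sigma=0.33):
    """Independent oracle: generating-function closed form + numeric gradient."""
    R = R_mm * 1e-3
    e = np.asarray(e_mm, float) * 1e-3
    ehat = e / np.linalg.norm(e)
    p = np.asarray(p_nam, float) * 1e-9

    def F(r0):
        b = np.linalg.norm(r0)
        t = b / R
        x = (r0 @ ehat) / b if b > 0 else 0.0
        k = math.sqrt(1.0 - 2.0 * t * x + t * t)
        return (1.0 / R) * (2.0 * (1.0 / k - 1.0) + math.log(2.0 / (1.0 - t * x + k)))

    r0 = np.asarray(r0_mm, float) * 1e-3
    h = 1e-7
    grad = np.zeros(3)
    for j in range(3):
        dp = np.zeros(3)
        dp[j] = h
        grad[j] = (F(r0 + dp) - F(r0 - dp)) / (2 * h)
    return (p @ grad) / (4.0 * math.pi * sigma)


class TestMontage:
    def test_vertex_electrode(self):
        (cz,) = make_montage(["Cz"], 85.0)
        assert np.allclose(cz.position, [0.0, 0.0, 85.0], atol=1e-12)

    def test_full_62_montage(self, montage62):
        assert len(montage62) == 62
        radii = np.linalg.norm(electrode_array(montage62), axis=1)
        assert np.allclose(radii, 85.0, rtol=1e-9)
        assert len({e.label for e in montage62}) == 62
        # anatomical sanity: odd indices left (x<0), Fz anterior, Oz posterior
        by = {e.label: e.position for e in montage62}
        assert by["F3"][0] < 0 < by["F4"][0]
        assert by["Fz"][1] > 0 > by["Oz"][1]
        assert by["PO9"][2] == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_label_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_montage(["Cz", "Cz"])

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="XX9"):
            make_montage(["Cz", "XX9"])

    def test_packaged_fixture_matches_analytic(self, montage62):
        shipped = packaged_62_montage()
        assert [e.label for e in shipped] == [e.label for e in montage62]
        np.testing.assert_allclose(electrode_array(shipped),
                                   electrode_array(montage62), atol=1e-9)

    def test_electrode_file_roundtrip(self, tmp_path, montage62):
        path = tmp_path / "elec.tsv"
        save_electrodes(path, montage62)
        back = load_electrodes(path)
        assert [e.label for e in back] == [e.label for e in montage62]
        np.testing.assert_allclose(electrode_array(back),
                                   electrode_array(montage62), atol=1e-9)


class TestForwardModel:
    def test_central_dipole_closed_form(self, rng, head_model):
        R, sigma = head_model.radius_mm, head_model.conductivity_sm
        for _ in range(10):
            p = rng.standard_normal(3) * 10
            e = 85.0 * fibonacci_directions(50)[rng.integers(50)]
            v = dipole_potential(Dipole([0, 0, 0], p), [Electrode("e", e)],
                                 head_model)[0]
            ehat = e / np.linalg.norm(e)
            expected = 3.0 * (p * 1e-9) @ ehat / (4 * np.pi * sigma * (R * 1e-3) ** 2)
            assert v == pytest.approx(expected, rel=1e-10)

    def test_central_vertical_dipole_value(self, head_model):
        # 10 nA*m along z, electrode at the north pole: ~1.0013 microvolts
        v = dipole_potential(Dipole([0, 0, 0], [0, 0, 10.0]),
                             [Electrode("N", [0, 0, 85.0])], head_model)[0]
        assert v * 1e6 == pytest.approx(1.00129, abs=1e-4)

    def test_equatorial_symmetry_zero(self, head_model):
        v = dipole_potential(Dipole([0, 0, 0], [0, 0, 10.0]),
                             [Electrode("E", [85.0, 0, 0])], head_model)[0]
        assert v == pytest.approx(0.0, abs=1e-20)

    def test_linearity_in_moment(self, rng, head_model, montage62):
        r0 = [10.0, -5.0, 40.0]
        p = rng.standard_normal(3)
        v1 = dipole_potential(Dipole(r0, p), montage62, head_model)
        v2 = dipole_potential(Dipole(r0, 2 * p), montage62, head_model)
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-12)

    def test_eccentric_series_matches_independent_closed_form(self, rng):
        hm = HeadModel(n_terms=200)
        for _ in range(8):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            r0 = rng.uniform(0.2, 0.8) * 85.0 * d
            p = rng.standard_normal(3) * 10
            e = 85.0 * fibonacci_directions(33)[rng.integers(33)]
            got = dipole_potential(Dipole(r0, p), [Electrode("e", e)], hm)[0]
            want = closed_form_potential(r0, p, e)
            assert got == pytest.approx(want, rel=1e-6)

    def test_series_truncation_converged(self, rng, montage62):
        hm60 = HeadModel(n_terms=60)
        hm120 = HeadModel(n_terms=120)
        for _ in range(5):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            r0 = rng.uniform(0.0, 0.7) * 85.0 * d
            p = rng.standard_normal(3) * 10
            v60 = dipole_potential(Dipole(r0, p), montage62, hm60)
            v120 = dipole_potential(Dipole(r0, p), montage62, hm120)
            scale = np.max(np.abs(v120))
            assert np.max(np.abs(v60 - v120)) < 1e-8 * scale

    def test_rotational_equivariance(self, rng, head_model):
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=3).as_matrix()
        r0 = np.array([20.0, 10.0, 45.0])
        p = np.array([3.0, -7.0, 2.0])
        elec = [Electrode("a", [50.0, 40.0, 51.1469]),
                Electrode("b", [-30.0, 60.0, -52.2016])]
        elec = [Electrode(e.label, e.position / np.linalg.norm(e.position) * 85.0)
                for e in elec]
        v = dipole_potential(Dipole(r0, p), elec, head_model)
        elec_rot = [Electrode(e.label, rot @ e.position) for e in elec]
        v_rot = dipole_potential(Dipole(rot @ r0, rot @ p), elec_rot, head_model)
        np.testing.assert_allclose(v_rot, v, rtol=1e-10)

    def test_leadfield_times_moment_equals_potential(self, rng, head_model, montage62):
        r0 = [15.0, 25.0, 30.0]
        p = rng.standard_normal(3) * 5
        lf = leadfield(r0, montage62, head_model)
        np.testing.assert_allclose(lf @ p,
                                   dipole_potential(Dipole(r0, p), montage62,
                                                    head_model), rtol=1e-12)

    def test_average_referenced_leadfield_columns_sum_zero(self, head_model, montage62):
        lf = leadfield([10.0, -20.0, 35.0], montage62, head_model,
                       average_reference=True)
        np.testing.assert_allclose(lf.sum(axis=0), 0.0, atol=1e-18)

    def test_central_leadfield_columns_orthogonal_dense_montage(self, head_model):
        dense = [Electrode(f"d{i}", 85.0 * d)
                 for i, d in enumerate(fibonacci_directions(1000))]
        lf = leadfield([0.0, 0.0, 0.0], dense, head_model)
        gram = lf.T @ lf
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 0.01 * np.min(np.diag(gram))

    def test_dipole_outside_sphere_rejected(self, head_model, montage62):
        with pytest.raises(ValueError, match="outside"):
            dipole_potential(Dipole([0, 0, 90.0], [0, 0, 1.0]), montage62,
                             head_model)
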