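"""Orientation <-> moments mapping, inversion chain, ratiometric observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polarsmolm.orientation import (EmptySignalError, cone_order_parameter,
                                    invert_intensities,
                                    moments_from_orientation,
                                    moments6_from_orientation,
                                    orientation_from_moments,
                                    ratiometric_observables,
                                    wobble_from_order_parameter,
                                    FLAG_XI_ILL_DEFINED)


def _cone_mc_moments(eta, xi, delta, n, rng):
    """Brute-force second moments: directions uniform in solid angle inside
    the cone, rotated onto the mean axis."""
    c = np.cos(np.deg2rad(delta) / 2.0)
    cos_a = rng.uniform(c, 1.0, n)
    sin_a = np.sqrt(1.0 - cos_a**2)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    v = np.stack([sin_a * np.cos(phi), sin_a * np.sin(phi), cos_a], axis=1)
    e, x = np.deg2rad(eta), np.deg2rad(xi)
    Ry = np.array([[np.cos(e), 0, np.sin(e)], [0, 1, 0],
                   [-np.sin(e), 0, np.cos(e)]])
    Rz = np.array([[np.cos(x), -np.sin(x), 0], [np.sin(x), np.cos(x), 0],
                   [0, 0, 1]])
    u = v @ (Rz @ Ry).T
    return np.array([np.mean(u[:, 0] ** 2), np.mean(u[:, 1] ** 2),
                     np.mean(u[:, 2] ** 2), np.mean(u[:, 0] * u[:, 1])])


class TestMomentsFromOrientation:
    def test_fixed_x_dipole(self):
        m = moments_from_orientation(90.0, 0.0, 0.0)
        assert np.allclose(m, [1, 0, 0, 0], atol=1e-12)

    def test_isotropic_limit(self):
        for eta, xi in [(10.0, 5.0), (80.0, 170.0)]:
            m = moments_from_orientation(eta, xi, 180.0)
            assert np.allclose(m, [1 / 3, 1 / 3, 1 / 3, 0], atol=1e-12)

    def test_against_cone_monte_carlo(self, rng):
        m = moments_from_orientation(45.0, 30.0, 100.0)
        mc = _cone_mc_moments(45.0, 30.0, 100.0, 1_000_000, rng)
        assert np.abs(m - mc).max() < 1e-3

    def test_trace_one_everywhere(self, rng):
        eta = rng.uniform(0, 90, 200)
        xi = rng.uniform(0, 180, 200)
        delta = rng.uniform(0, 180, 200)
        m = moments_from_orientation(eta, xi, delta)
        assert np.allclose(m[:, :3].sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m[:, 3] ** 2 <= m[:, 0] * m[:, 1] + 1e-12)

    def test_order_parameter_strictly_decreasing(self):
        d = np.linspace(0.0, 180.0, 361)
        g = cone_order_parameter(d)
        assert g[0] == pytest.approx(1.0)
        assert g[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(g) < 0)

    def test_wobble_inverse_of_order_parameter(self):
        d = np.linspace(0.0, 180.0, 50)
        assert np.allclose(wobble_from_order_parameter(cone_order_parameter(d)),
                           d, atol=1e-9)


class TestInversionChain:
    def test_round_trip_on_manifold(self):
        m = moments_from_orientation(50.0, 120.0, 100.0)
        o = orientation_from_moments(m)
        assert o["eta"] == pytest.approx(50.0, abs=1e-6)
        assert o["xi"] == pytest.approx(120.0, abs=1e-6)
        assert o["delta"] == pytest.approx(100.0, abs=1e-6)

    def test_round_trip_grid_noise_free(self):
        """Noiseless retrieval is unbiased over the open parameter range."""
        etas = np.linspace(2.0, 88.0, 18)
        xis = np.linspace(1.0, 175.0, 12)
        deltas = np.linspace(4.0, 176.0, 12)
        E, X, D = np.meshgrid(etas, xis, deltas, indexing="ij")
        m = moments_from_orientation(E.ravel(), X.ravel(), D.ravel())
        o = orientation_from_moments(m)
        assert np.abs(o["eta"] - E.ravel()).max() < 0.01
        assert np.abs(o["delta"] - D.ravel()).max() < 0.01
        dxi = (o["xi"] - X.ravel() + 90.0) % 180.0 - 90.0
        assert np.abs(dxi).max() < 0.01

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(eta=st.floats(1.0, 89.0), xi=st.floats(0.0, 179.0),
           delta=st.floats(1.0, 179.0))
    def test_round_trip_property(self, eta, xi, delta):
        m = moments_from_orientation(eta, xi, delta)
        o = orientation_from_moments(m)
        assert abs(o["eta"] - eta) < 1e-5
        assert abs(o["delta"] - delta) < 1e-5

    def test_isotropic_flags_xi_ill_defined(self):
        o = orientation_from_moments(np.array([1 / 3, 1 / 3, 1 / 3, 0.0]))
        assert o["delta"] == pytest.approx(180.0, abs=1e-6)
        assert o["flags"] & FLAG_XI_ILL_DEFINED

    def test_intensity_round_trip(self, bset):
        K = bset.K
        m = moments_from_orientation(40.0, 70.0, 120.0)
        I = K @ m
        out = invert_intensities(I, K)
        assert np.abs(out["m"] - m).max() < 1e-9
        assert not out["clipped"].any()

    def test_negative_intensity_rejected(self, bset):
        with pytest.raises(ValueError):
            invert_intensities(np.array([10.0, -1.0, 5.0, 5.0]), bset.K)

    def test_zero_intensity_rejected(self, bset):
        with pytest.raises(EmptySignalError):
            invert_intensities(np.zeros(4), bset.K)

    def test_poisson_inversion_nearly_unbiased(self, bset, rng):
        """Moments retrieved from Poisson-perturbed intensities at 5000
        photons are centred on the truth (bias < 0.01 per component)."""
        m = moments_from_orientation(45.0, 30.0, 100.0)
        I = bset.channel_intensities(moments6_from_orientation(45., 30., 100.),
                                     5000.0)
        draws = rng.poisson(I, size=(10_000, 4)).astype(float)
        out = invert_intensities(draws, bset.K)
        bias = out["m"].mean(axis=0) - m
        assert np.abs(bias).max() < 0.01

    def test_clipping_moves_toward_manifold(self, rng):
        """Projection into the physical set never increases the distance to
        the orientation-model manifold."""
        grid = moments_from_orientation(
            *np.meshgrid(np.linspace(1, 89, 30), np.linspace(0, 175, 24),
                         np.linspace(2, 178, 24), indexing="ij")
        ).reshape(-1, 4)

        def dist(m4):
            return np.sqrt(((grid - m4) ** 2).sum(axis=1)).min()

        raw = rng.normal(0, 0.25, (50, 4)) + np.array([0.4, 0.3, 0.3, 0.0])
        from polarsmolm.orientation import _clip_moments
        clipped, flag = _clip_moments(raw)
        # the physical-set projection is not the exact metric projection onto
        # the manifold, so allow a small numerical slack
        for r, c in zip(raw, clipped):
            tr = r[:3].sum()
            r_n = r / tr if tr > 0 else r
            assert dist(c) <= dist(r_n) + 5e-3

    def test_xi_equivariance_through_forward_model(self, bset):
        """Rotating the molecule's azimuth shifts retrieved xi by the same
        angle (mod 180)."""
        for phi in (20.0, 55.0, 110.0):
            I0 = bset.channel_intensities(
                moments6_from_orientation(60.0, 10.0, 90.0), 5000.0)
            I1 = bset.channel_intensities(
                moments6_from_orientation(60.0, 10.0 + phi, 90.0), 5000.0)
            o0 = orientation_from_moments(invert_intensities(I0, bset.K)["m"])
            o1 = orientation_from_moments(invert_intensities(I1, bset.K)["m"])
            shift = (o1["xi"] - o0["xi"]) % 180.0
            assert shift == pytest.approx(phi, abs=1e-6)


class TestRatiometricObservables:
    def test_in_plane_dipole_along_x(self, bset):
        I = bset.channel_intensities(moments6_from_orientation(90., 0., 0.), 1e4)
        r = ratiometric_observables(I)
        assert abs(r.P45) < 1e-9
        # P0 is maximal over xi at xi = 0
        for xi in (20.0, 45.0, 70.0):
            Ix = bset.channel_intensities(
                moments6_from_orientation(90., xi, 0.), 1e4)
            assert ratiometric_observables(Ix).P0 < r.P0 + 1e-12

    def test_isotropic_molecule(self, bset):
        I = bset.channel_intensities(moments6_from_orientation(0., 0., 180.), 1e4)
        r = ratiometric_observables(I)
        assert abs(r.P0) < 1e-9 and abs(r.P45) < 1e-9

    def test_arm_ratio_monotone_in_eta(self, bset):
        R = [ratiometric_observables(bset.channel_intensities(
            moments6_from_orientation(e, 0.0, 0.0), 1e4)).R_NA
            for e in np.linspace(0, 90, 31)]
        assert np.all(np.diff(R) > 0)

    def test_polarization_norm_decreasing_in_delta(self, bset):
        P = []
        for d in np.linspace(0, 179, 30):
            r = ratiometric_observables(bset.channel_intensities(
                moments6_from_orientation(60.0, 25.0, d), 1e4))
            P.append(r.P0**2 + r.P45**2)
        assert np.all(np.diff(P) < 0)

    def test_zero_denominator_flagged(self):
        r = ratiometric_observables(np.array([0.0, 0.0, 5.0, 3.0]))
        assert not r.valid
        assert np.isnan(r.P0)
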