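"""Confidence filtering, population binning, radial profiles, rendering."""

import numpy as np
import pandas as pd
import pytest

from polarsmolm.analysis import (ETA_LABELS, ROISpec, bin_eta,
                                 eta_fraction_profile, filter_confidence,
                                 focus_classes, misclassification_rates,
                                 polar_histogram, radiality,
                                 radiality_profile, render_stick_map)


def _table(eta, xi=None, delta=None, photons=None, x=None, y=None, **extra):
    n = len(eta)
    t = pd.DataFrame({
        "molecule_id": np.arange(n),
        "eta": np.asarray(eta, float),
        "xi": np.zeros(n) if xi is None else np.asarray(xi, float),
        "delta": np.full(n, 100.0) if delta is None else np.asarray(delta, float),
        "photons": np.full(n, 5000.0) if photons is None else np.asarray(photons, float),
        "x_nm": np.zeros(n) if x is None else np.asarray(x, float),
        "y_nm": np.zeros(n) if y is None else np.asarray(y, float),
    })
    for k, v in extra.items():
        t[k] = v
    return t


class TestFilterConfidence:
    def test_rejection_reasons(self):
        t = _table(eta=[89.0, 45.0, 45.0, 45.0],
                   delta=[100.0, 2.0, 100.0, 100.0],
                   photons=[5000.0, 5000.0, 500.0, 1001.0])
        kept, counts = filter_confidence(t)
        assert counts["eta_range"] == 1
        assert counts["delta_range"] == 1
        assert counts["low_photons"] == 1
        assert counts["kept"] == 1
        assert kept.photons.iloc[0] == 1001.0  # boundary-inclusive survivor

    def test_empty_table(self):
        kept, counts = filter_confidence(_table(eta=[]))
        assert len(kept) == 0 and counts["kept"] == 0


class TestBinEta:
    @pytest.mark.parametrize("eta,scheme,label", [
        (25.0, "standard", "off-plane"),
        (50.0, "standard", "intermediate"),
        (50.0, "cell", "intermediate"),
        (35.0, "cell", "off-plane"),
        (35.0, "standard", "intermediate"),
        (60.0, "standard", "intermediate"),   # boundary goes to the lower bin
        (61.0, "standard", "in-plane"),
    ])
    def test_assignments(self, eta, scheme, label):
        out = bin_eta(_table(eta=[eta]), scheme)
        assert out.eta_class.iloc[0] == label

    def test_partition_property(self, rng):
        t = _table(eta=rng.uniform(0, 90, 500))
        out = bin_eta(t)
        assert out.eta_class.notna().all()
        assert set(out.eta_class.cat.categories) == set(ETA_LABELS)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            bin_eta(_table(eta=[10.0]), "bogus")


class TestMisclassification:
    def test_perfect_retrieval_zero_rates(self, rng):
        t = _table(eta=rng.uniform(0, 90, 300))
        rates = misclassification_rates(t, t)
        assert all(rates[c] == 0.0 for c in ETA_LABELS)

    def test_global_shift_breaks_off_plane_class(self, rng):
        truth = _table(eta=rng.uniform(0, 90, 300))
        shifted = truth.copy()
        shifted["eta"] = np.clip(truth.eta + 90.0, 0, 90)
        rates = misclassification_rates(shifted, truth)
        assert rates["off-plane"] == 1.0

    def test_per_retrieved_conditioning(self, rng):
        truth = _table(eta=rng.uniform(0, 90, 400))
        noisy = truth.copy()
        noisy["eta"] = np.clip(truth.eta + rng.normal(0, 8, 400), 0, 90)
        r1 = misclassification_rates(noisy, truth, per="truth")
        r2 = misclassification_rates(noisy, truth, per="retrieved")
        assert r1["n_matched"] == r2["n_matched"] == 400


class TestRadiality:
    def test_perfectly_radial_scene(self, rng):
        n = 500
        ang = rng.uniform(0, 2 * np.pi, n)
        r = rng.uniform(50, 900, n)
        t = _table(eta=np.full(n, 90.0), xi=np.degrees(ang) % 180.0,
                   x=r * np.cos(ang), y=r * np.sin(ang))
        roi = ROISpec(0.0, 0.0, 1000.0)
        prof = radiality_profile(t, [roi], step_nm=100.0)
        assert (prof.fraction_radial > 0.999).all()

    def test_uniform_xi_matches_null_expectation(self, rng):
        """Random stick angles give fraction-radial 2*cutoff/180 within
        binomial error in every distance bin."""
        n = 40000
        ang = rng.uniform(0, 2 * np.pi, n)
        r = rng.uniform(50, 950, n)
        t = _table(eta=np.full(n, 90.0), xi=rng.uniform(0, 180, n),
                   x=r * np.cos(ang), y=r * np.sin(ang))
        prof = radiality_profile(t, [ROISpec(0.0, 0.0, 1000.0)], step_nm=100.0)
        p0 = 2 * 10.0 / 180.0
        for _, row in prof.iterrows():
            se = np.sqrt(p0 * (1 - p0) / row.n)
            assert abs(row.fraction_radial - p0) < 3.5 * se

    def test_synthetic_podosome_ring_peaks_at_ring_radius(self, rng):
        """Radial in-plane ring at ~400 nm + disordered core: the radial
        fraction peaks near the ring radius."""
        n_ring, n_core = 3000, 3000
        ang = rng.uniform(0, 2 * np.pi, n_ring)
        r = rng.normal(400.0, 40.0, n_ring)
        ring = _table(eta=np.full(n_ring, 80.0),
                      xi=(np.degrees(ang) + rng.normal(0, 5, n_ring)) % 180.0,
                      x=r * np.cos(ang), y=r * np.sin(ang))
        ang2 = rng.uniform(0, 2 * np.pi, n_core)
        r2 = rng.uniform(0, 700.0, n_core)
        core = _table(eta=np.full(n_core, 20.0), xi=rng.uniform(0, 180, n_core),
                      x=r2 * np.cos(ang2), y=r2 * np.sin(ang2))
        core["molecule_id"] += n_ring
        t = pd.concat([ring, core], ignore_index=True)
        prof = radiality_profile(t, [ROISpec(0.0, 0.0, 700.0)], step_nm=50.0)
        peak = prof.loc[prof.fraction_radial.idxmax(), "distance_nm"]
        assert 300.0 <= peak <= 500.0

    def test_molecule_at_centre_excluded(self):
        t = _table(eta=[90.0, 90.0], xi=[0.0, 0.0], x=[0.0, 100.0],
                   y=[0.0, 0.0])
        r = radiality(t, ROISpec(0.0, 0.0, 500.0))
        assert len(r) == 1


class TestEtaFractionProfile:
    def test_all_off_plane(self, rng):
        n = 200
        ang = rng.uniform(0, 2 * np.pi, n)
        r = rng.uniform(10, 490, n)
        t = _table(eta=np.full(n, 20.0), x=r * np.cos(ang), y=r * np.sin(ang))
        prof = eta_fraction_profile(t, [ROISpec(0.0, 0.0, 500.0)], step_nm=100.0)
        assert (prof.fraction_off_plane == 1.0).all()
        assert (prof.fraction_in_plane == 0.0).all()

    def test_off_plane_concentrated_at_centre(self, rng):
        """Vertical core + in-plane surround: the off-plane fraction is
        maximal at the ROI centre."""
        n = 4000
        ang = rng.uniform(0, 2 * np.pi, n)
        r = rng.uniform(5, 600.0, n)
        eta = np.where(r < 200.0, 20.0, 80.0)
        t = _table(eta=eta, x=r * np.cos(ang), y=r * np.sin(ang))
        prof = eta_fraction_profile(t, [ROISpec(0.0, 0.0, 600.0)], step_nm=50.0)
        assert prof.fraction_off_plane.idxmax() == 0

    def test_empty_roi_warns(self):
        t = _table(eta=[50.0], x=[5000.0], y=[5000.0])
        with pytest.warns(UserWarning):
            prof = eta_fraction_profile(t, [ROISpec(0.0, 0.0, 100.0)])
        assert len(prof) == 0


class TestFocusClasses:
    @pytest.mark.parametrize("eta,radius,label", [
        (70.0, 1.2, "in-plane/in-focus"),
        (30.0, 2.3, "off-plane/off-focus"),
        (50.0, 1.7, "other"),
        (70.0, 2.5, "other"),
    ])
    def test_classes(self, eta, radius, label):
        t = _table(eta=[eta], radius_px=[radius])
        out = focus_classes(t)
        assert out.focus_class.iloc[0] == label


class TestStickMap:
    def test_single_horizontal_stick(self):
        t = _table(eta=[90.0], xi=[0.0], x=[500.0], y=[500.0])
        img = render_stick_map(t, "xi", stick_length_nm=200.0, pixel_nm=20.0,
                               shape=(50, 50))
        lit = np.argwhere(img.sum(axis=2) > 0)
        assert len(lit) > 5
        assert np.all(lit[:, 0] == 25)            # one row: horizontal stick
        assert lit[:, 1].min() < 25 < lit[:, 1].max()

    def test_rendering_deterministic(self, rng):
        t = _table(eta=rng.uniform(0, 90, 50), xi=rng.uniform(0, 180, 50),
                   x=rng.uniform(0, 2000, 50), y=rng.uniform(0, 2000, 50))
        a = render_stick_map(t, "eta", eta_bins=(30.0, 60.0, 90.0))
        b = render_stick_map(t, "eta", eta_bins=(30.0, 60.0, 90.0))
        assert np.array_equal(a, b)

    def test_crossing_filaments_bimodal_xi_histogram(self, rng):
        xi = np.concatenate([rng.normal(20.0, 4.0, 400) % 180,
                             rng.normal(90.0, 4.0, 400) % 180])
        hist = polar_histogram(xi, n_bins=36)
        top = hist.sort_values("count").xi_center.values[-2:]
        gap = abs(top[0] - top[1])
        assert min(gap, 180 - gap) == pytest.approx(70.0, abs=7.5)
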