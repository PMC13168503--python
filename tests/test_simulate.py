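"""Synthetic-data generator: scenes, rendering, noise, aberrations."""

import numpy as np
import pytest
from scipy.stats import kstest

import polarsmolm as pm
from polarsmolm.optics import CHANNELS
from polarsmolm.simulate import (AberrationSpec, NoiseModel, PackingError,
                                 aberration_phase, make_scene_filaments,
                                 make_scene_random_orientations,
                                 make_scene_sphere_membrane, render_stack,
                                 _noll_to_nm)


class TestRandomOrientationScene:
    def test_seeded_determinism(self):
        a = make_scene_random_orientations(10, 5, seed=42)
        b = make_scene_random_orientations(10, 5, seed=42)
        assert a.table.equals(b.table)

    def test_cos_eta_uniform_on_hemisphere(self):
        sc = make_scene_random_orientations(10, 1000, seed=7)
        cos_eta = np.cos(np.deg2rad(sc.table.eta.values))
        assert kstest(cos_eta, "uniform").pvalue > 0.01
        assert kstest(sc.table.xi.values / 180.0, "uniform").pvalue > 0.01

    def test_minimum_separation_respected(self):
        sc = make_scene_random_orientations(10, 20, frame_size=64,
                                            min_separation=8.0, seed=3)
        for _, sub in sc.table.groupby("frame"):
            pos = sub[["x_px", "y_px"]].values
            d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 8.0

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError):
            make_scene_random_orientations(40, 1, frame_size=32,
                                           min_separation=8.0, seed=0)


class TestSphereScene:
    def test_bottom_plane_is_vertical(self):
        sc = make_scene_sphere_membrane(2000.0, n_planes=1, label_tilt_deg=0.0,
                                        plane_span_nm=0.0, seed=1,
                                        frame_size=128)
        assert np.allclose(sc.table.eta, 0.0, atol=1e-9)

    def test_equator_plane_is_in_plane_and_radial(self):
        R = 2000.0
        sc = make_scene_sphere_membrane(R, n_planes=2, label_tilt_deg=0.0,
                                        plane_span_nm=R, seed=1,
                                        frame_size=128)
        eq = sc.table[sc.table.plane == 1]
        assert np.allclose(eq.eta, 90.0, atol=1e-6)
        cx = cy = 64.0 * 130.0
        radial = np.degrees(np.arctan2(eq.y_nm - cy, eq.x_nm - cx)) % 180.0
        dxi = (eq.xi.values - radial + 90.0) % 180.0 - 90.0
        assert np.abs(dxi).max() < 1e-6

    def test_plane_above_equator_rejected(self):
        from polarsmolm.optics import GeometryError
        with pytest.raises(GeometryError):
            make_scene_sphere_membrane(500.0, plane_span_nm=800.0)

    def test_eta_increases_with_distance_full_pipeline(self, cfg):
        """Retrieved off-plane angle grows from the sphere bottom towards the
        equator (distance to the bead-image centre)."""
        sc = make_scene_sphere_membrane(1800.0, n_planes=4, wobble=100.0,
                                        density=25.0, photons=8000.0,
                                        seed=5, frame_size=48,
                                        molecules_per_frame=6)
        st = render_stack(sc, cfg, NoiseModel(background=10.0), seed=6)
        table, _ = pm.run_pipeline(st, cfg)
        cx = cy = 24.0 * 130.0
        d = np.hypot(table.x_nm - cx, table.y_nm - cy)
        bins = np.digitize(d, [600.0, 1200.0])
        means = [table.eta[bins == k].mean() for k in range(3)]
        assert means[0] < means[1] < means[2]


class TestFilamentScene:
    def test_zero_offset_horizontal_filament(self):
        seg = [(600.0, 2000.0, 5000.0, 2000.0)]
        sc = make_scene_filaments(seg, label_offset_deg=0.0, wobble=0.0,
                                  density=20.0, seed=2, frame_size=48)
        assert np.allclose(sc.table.eta, 90.0)
        assert np.allclose(sc.table.xi, 0.0, atol=1e-9)

    def test_vertical_filament_with_20_deg_label_offset(self):
        """A filament along the optical axis labelled at 20 degrees off-axis
        gives eta = 20 for every molecule."""
        seg = [(2000.0, 2000.0, 0.0, 2000.0, 2000.0, 800.0)]
        sc = make_scene_filaments(seg, label_offset_deg=20.0, wobble=100.0,
                                  density=100.0, seed=3, frame_size=48)
        assert np.allclose(sc.table.eta, 20.0, atol=1e-9)

    def test_crossing_families_bimodal_xi(self):
        segs = [(500.0, 1000.0, 5500.0, 1000.0),
                (500.0, 1200.0, 5500.0, 1200.0)]
        segs2 = []
        th = np.deg2rad(70.0)
        for x0, y0, x1, y1 in [(1000.0, 500.0, 1000.0 + 4000 * np.cos(th),
                                500.0 + 4000 * np.sin(th))]:
            segs2.append((x0, y0, x1, y1))
        sc = make_scene_filaments(segs + segs2, label_offset_deg=0.0,
                                  wobble=100.0, density=40.0, seed=4,
                                  frame_size=48)
        hist = pm.polar_histogram(sc.table.xi, n_bins=18)
        top2 = hist.sort_values("count").xi_center.values[-2:]
        gap = abs(top2[0] - top2[1])
        assert min(gap, 180 - gap) == pytest.approx(70.0, abs=10.0)

    def test_empty_segment_list_rejected(self):
        with pytest.raises(ValueError):
            make_scene_filaments([])


class TestRenderStack:
    def test_zeroed_noise_model_is_deterministic_render(self, cfg):
        sc = make_scene_random_orientations(5, 2, seed=9)
        a = render_stack(sc, cfg, NoiseModel.zeroed(), seed=1)
        b = render_stack(sc, cfg, NoiseModel.zeroed(), seed=999)
        for c in CHANNELS:
            assert np.array_equal(a.channels[c], b.channels[c])

    def test_empty_scene_background_poisson(self, cfg):
        import pandas as pd
        from polarsmolm.simulate import Scene, TRUTH_COLUMNS
        sc = Scene(pd.DataFrame(columns=["molecule_id", "frame", "x_px",
                                         "y_px", "eta", "xi", "delta",
                                         "photons", "x_nm", "y_nm"]),
                   frame_size=64, n_frames=8)
        st = render_stack(sc, cfg, NoiseModel(background=10.0), seed=13)
        pix = st.channels["I0"].ravel()
        assert pix.mean() == pytest.approx(10.0, abs=0.1)
        assert pix.var() == pytest.approx(10.0, rel=0.05)

    def test_photon_bookkeeping(self, cfg, bset):
        """Total counts above background match the photon budget times the
        collection/split factors to better than 0.5%."""
        sc = make_scene_random_orientations(6, 10, photons=5000.0, seed=15,
                                            margin=16.0, min_separation=6.0,
                                            frame_size=64)
        st = render_stack(sc, cfg, NoiseModel.zeroed(), seed=None)
        total = sum(st.channels[c].sum() for c in CHANNELS)
        expected = (st.truth.photons * st.truth.collection_factor).sum()
        assert total == pytest.approx(expected, rel=5e-3)

    def test_truth_positions_match_rendered_centroids(self, cfg):
        sc = make_scene_random_orientations(1, 4, delta_fixed=150.0, seed=16,
                                            margin=20.0)
        st = render_stack(sc, cfg, NoiseModel.zeroed(), seed=None)
        img = sum(st.channels[c] for c in CHANNELS)
        for f in range(4):
            t = st.truth[st.truth.frame == f].iloc[0]
            yy, xx = np.mgrid[:64, :64]
            w = img[f]
            cy = (w * yy).sum() / w.sum()
            cx = (w * xx).sum() / w.sum()
            assert cy == pytest.approx(t.y_px, abs=0.05)
            assert cx == pytest.approx(t.x_px, abs=0.05)


class TestAberrations:
    def test_noll_indexing_low_orders(self):
        assert _noll_to_nm(1) == (0, 0)
        assert _noll_to_nm(4) == (2, 0)       # defocus
        assert set(map(_noll_to_nm, (5, 6))) == {(2, -2), (2, 2)}  # astigmatism
        assert _noll_to_nm(11) == (4, 0)      # spherical

    def test_aberration_deforms_psf_but_not_integrals(self, cfg):
        """Pupil-phase aberrations deform the PSFs while the integrated
        ratios (pupil power integrals) are untouched."""
        from polarsmolm.simulate import Scene
        sc = make_scene_random_orientations(3, 2, seed=17, margin=16.0)
        clean = render_stack(sc, cfg, NoiseModel.zeroed(), seed=None)
        ab = AberrationSpec(zernike=(0.0,) * 4 + (0.8, 0.0, 0.5))
        abd = render_stack(sc, cfg, NoiseModel.zeroed(), seed=None,
                           aberration=ab)
        diff = max(np.abs(clean.channels[c] - abd.channels[c]).max()
                   for c in CHANNELS)
        assert diff > 1.0  # shapes visibly deformed
        for c in CHANNELS:
            a, b = clean.channels[c].sum(), abd.channels[c].sum()
            assert abs(a / b - 1) < 0.01
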