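import numpy as np
import pandas as pd
import pytest

from radialign import deformation as dfm, scene
from radialign.angles import rotation_matrix


def _field_from_tracks(cfg, fld, n=300, noise=0.0, region_radius=None):
    obs, _ = scene.simulate_bead_tracks(n, fld, noise, cfg,
                                        region_radius=region_radius)
    return dfm.displacement_field(obs, 0, fld.n_frames - 1)


class TestDetection:
    def test_two_spots_ten_sigma_apart(self, small_cfg):
        img = scene.render_beads(np.array([[40.0, 60.0], [80.0, 60.0]]),
                                 small_cfg, sigma_px=2.0, snr=np.inf)
        det = dfm.detect_spots(img, 2.0, small_cfg.pixel_size)
        assert len(det) == 2
        got = np.sort(det.x_um.to_numpy())
        assert np.allclose(got, [40.0, 80.0], atol=0.1)

    def test_invalid_sigma_raises(self):
        with pytest.raises(ValueError):
            dfm.detect_spots(np.zeros((8, 8)), 0.0, 1.0)


class TestLinking:
    def test_noiseless_simulated_beads_recover_truth(self, cfg):
        # gentle stretch: steps well below the bead spacing, so the ground
        # truth linking is unambiguous
        fld = scene.generate_field(scene.FieldSpec(
            kind="affine", affine_matrix=np.diag([1.02, 1.02]), n_frames=5), cfg)
        obs, truth = scene.simulate_bead_tracks(60, fld, 0.0, cfg)
        # feed detections unsorted and unlabelled
        det = obs[["x_um", "y_um", "frame"]].sample(frac=1.0, random_state=0)
        linked = dfm.link_tracks(det, max_disp=3.0)
        assert linked.track_id.nunique() == 60
        # every linked track matches one ground-truth bead at every frame
        merged = linked.merge(truth, on=["frame"], suffixes=("", "_t"))
        for tid, grp in linked.groupby("track_id"):
            p0 = grp[grp.frame == 0][["x_um", "y_um"]].to_numpy()
            t0 = truth[truth.frame == 0]
            bead = t0.iloc[np.argmin(np.hypot(t0.x_um - p0[0, 0],
                                              t0.y_um - p0[0, 1]))].track_id
            ref = truth[truth.track_id == bead].sort_values("frame")
            got = grp.sort_values("frame")
            assert np.allclose(got[["x_um", "y_um"]], ref[["x_um", "y_um"]],
                               atol=1e-9)

    def test_single_frame_gives_singleton_tracks(self):
        det = pd.DataFrame({"x_um": [1.0, 5.0, 9.0], "y_um": [1.0, 1.0, 1.0],
                            "frame": 0})
        linked = dfm.link_tracks(det, max_disp=10.0)
        assert linked.track_id.nunique() == 3
        assert linked.groupby("track_id").size().eq(1).all()

    def test_gap_closing_rejoins_dropped_frame(self):
        """A detection missing in one middle frame is re-joined across the
        gap when max_gap=1."""
        rows = []
        for f in range(5):
            if f != 2:
                rows.append((10.0 + f, 10.0, f))   # moving bead, frame 2 lost
            rows.append((50.0, 50.0 + f, f))       # second bead, always seen
        det = pd.DataFrame(rows, columns=["x_um", "y_um", "frame"])
        linked = dfm.link_tracks(det, max_disp=3.0, max_gap=1)
        assert linked.track_id.nunique() == 2
        sizes = sorted(linked.groupby("track_id").size())
        assert sizes == [4, 5]
        no_gap = dfm.link_tracks(det, max_disp=3.0, max_gap=0)
        assert no_gap.track_id.nunique() == 3


class TestDisplacementField:
    def test_affine_scene_exact(self, cfg, affine_field):
        disp = _field_from_tracks(cfg, affine_field)
        c = np.array(cfg.pillar_center)
        expected = (disp[["x0", "y0"]].to_numpy() - c) @ (np.diag([1.1, 1.1])
                                                          - np.eye(2)).T
        assert np.allclose(disp[["ux", "uy"]].to_numpy(), expected, atol=1e-9)

    def test_same_frame_is_zero_field(self, cfg, affine_field):
        obs, _ = scene.simulate_bead_tracks(20, affine_field, 0.0, cfg)
        disp = dfm.displacement_field(obs, 1, 1)
        assert np.allclose(disp[["ux", "uy"]], 0.0)

    def test_missing_tracks_excluded_and_counted(self, cfg, affine_field):
        obs, _ = scene.simulate_bead_tracks(50, affine_field, 0.0, cfg)
        drop = obs.track_id.unique()[:5]
        pruned = obs[~((obs.track_id.isin(drop)) & (obs.frame == 4))]
        disp = dfm.displacement_field(pruned, 0, 4)
        assert len(disp) == 45

    def test_underdetermined_field_raises(self, cfg, affine_field):
        obs, _ = scene.simulate_bead_tracks(2, affine_field, 0.0, cfg)
        with pytest.raises(ValueError, match="underdetermined"):
            dfm.displacement_field(obs, 0, 4)


class TestEstimateF:
    def test_affine_field_exact_to_1e9(self, cfg, affine_field):
        disp = _field_from_tracks(cfg, affine_field)
        fmap = dfm.estimate_F(disp, cfg.pillar_center, cfg.pillar_radius)
        F = dfm.F_matrices(fmap)
        assert len(fmap) > 500
        assert np.abs(F - np.diag([1.1, 1.1])).max() <= 1e-9
        assert (fmap.n_support >= 3).all()

    def test_radial_field_matches_analytic_formula(self, cfg, quadratic_field):
        """Noiseless dense beads: F agrees with the polar ground-truth
        formula within 1e-3 away from the centre.  A dense regular bead
        lattice extending beyond the pillar (the membrane is larger than the
        analysis disc) gives every node symmetric support, so the local
        affine fit has no leading-order curvature bias."""
        R = cfg.pillar_radius
        c = np.array(cfg.pillar_center)
        ax = np.arange(-R - 30, R + 30 + 1e-9, 6.0)
        gx, gy = np.meshgrid(c[0] + ax, c[1] + ax)
        p = np.column_stack([gx.ravel(), gy.ravel()])
        p = p[np.hypot(*(p - c).T) <= R + 30]
        u = quadratic_field.displacement(p)
        disp = pd.DataFrame({"x0": p[:, 0], "y0": p[:, 1],
                             "ux": u[:, 0], "uy": u[:, 1]})
        spacing = cfg.pillar_radius / 20
        fmap = dfm.estimate_F(disp, cfg.pillar_center, cfg.pillar_radius)
        nodes = fmap[["x", "y"]].to_numpy()
        r = np.hypot(*(nodes - cfg.pillar_center).T)
        sel = r > 2 * spacing
        F = dfm.F_matrices(fmap)[sel]
        truth = quadratic_field.true_F(nodes[sel])
        assert np.abs(F - truth).max() < 1e-3

    def test_translation_invariance(self, cfg, quadratic_field):
        disp = _field_from_tracks(cfg, quadratic_field, n=400)
        fmap = dfm.estimate_F(disp, cfg.pillar_center, cfg.pillar_radius)
        shifted = disp.copy()
        shifted[["x0", "y0"]] += [123.4, -56.7]
        center2 = (cfg.pillar_center[0] + 123.4, cfg.pillar_center[1] - 56.7)
        fmap2 = dfm.estimate_F(shifted, center2, cfg.pillar_radius)
        assert np.allclose(dfm.F_matrices(fmap), dfm.F_matrices(fmap2),
                           atol=1e-9)

    def test_rotation_conjugates_F(self, cfg, quadratic_field):
        """Rotating the whole scene by phi conjugates F by R(phi)."""
        disp = _field_from_tracks(cfg, quadratic_field, n=400)
        c = np.array(cfg.pillar_center)
        phi = 33.0
        R = rotation_matrix(phi)
        rot = disp.copy()
        rot[["x0", "y0"]] = (disp[["x0", "y0"]].to_numpy() - c) @ R.T + c
        rot[["ux", "uy"]] = disp[["ux", "uy"]].to_numpy() @ R.T
        fmap = dfm.estimate_F(disp, c, cfg.pillar_radius)
        fmap_r = dfm.estimate_F(rot, c, cfg.pillar_radius)
        # compare at rotated node positions
        nodes = fmap[["x", "y"]].to_numpy()
        rnodes = (nodes - c) @ R.T + c
        lookup = {(round(x, 6), round(y, 6)): i
                  for i, (x, y) in enumerate(fmap_r[["x", "y"]].to_numpy())}
        F = dfm.F_matrices(fmap)
        Fr = dfm.F_matrices(fmap_r)
        checked = 0
        for i, (x, y) in enumerate(rnodes):
            j = lookup.get((round(x, 6), round(y, 6)))
            if j is None:
                continue   # rotated node off the grid
            assert np.allclose(R @ F[i] @ R.T, Fr[j], atol=1e-9)
            checked += 1
        assert checked > 0

    def test_standard_error_scales_inverse_sqrt_n(self, cfg):
        """F component scatter over seeds shrinks ~ n^(-1/2)."""
        sds = {}
        for n in (50, 200, 800):
            vals = []
            for s in range(8):
                c = scene.SceneConfig(seed=900 + s)
                fld = scene.generate_field(scene.FieldSpec(
                    kind="affine", affine_matrix=np.diag([1.1, 1.1]),
                    n_frames=3), c)
                obs, _ = scene.simulate_bead_tracks(n, fld, 0.3, c)
                disp = dfm.displacement_field(obs, 0, 2)
                fmap = dfm.estimate_F(disp, c.pillar_center, c.pillar_radius,
                                      grid_spacing=c.pillar_radius,
                                      neighborhood_radius=c.pillar_radius)
                # single central node, fixed neighborhood across n
                node = fmap.iloc[(np.hypot(fmap.x - c.pillar_center[0],
                                           fmap.y - c.pillar_center[1])).idxmin()]
                vals.append(node.Fxx)
            sds[n] = np.std(vals, ddof=1)
        ratio = sds[50] / sds[800]
        assert 2.0 < ratio < 8.0     # ideal sqrt(16) = 4


class TestDecomposition:
    def test_isotropic_stretch(self):
        d = dfm.decompose_F(np.diag([1.1, 1.1]))
        assert d.rotation_deg == pytest.approx(0.0, abs=1e-12)
        assert d.lambda1 == pytest.approx(1.1)
        assert d.lambda2 == pytest.approx(1.1)
        assert d.max_shear == pytest.approx(0.0, abs=1e-12)
        assert d.equibiaxiality == pytest.approx(1.0)

    def test_constructed_rotation_recovered(self):
        F = rotation_matrix(5.0) @ np.diag([1.1, 1.1])
        d = dfm.decompose_F(F)
        assert d.rotation_deg == pytest.approx(5.0, abs=1e-9)
        assert d.lambda1 == pytest.approx(1.1)

    def test_max_shear_from_unequal_stretches(self):
        d = dfm.decompose_F(np.diag([1.2, 1.05]))
        assert d.max_shear == pytest.approx(0.075)

    def test_polar_reconstruction_error(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            F = np.eye(2) + 0.2 * rng.standard_normal((2, 2))
            if np.linalg.det(F) <= 0:
                continue
            d = dfm.decompose_F(F)
            R = rotation_matrix(d.rotation_deg)
            U = R.T @ F
            assert np.allclose(U, U.T, atol=1e-10)
            assert np.allclose(R @ U, F, atol=1e-10)

    def test_nonphysical_flagged(self):
        assert not dfm.decompose_F(np.diag([1.0, -1.0])).physical


class TestDisplacementMapAndBands:
    def test_uniform_magnitude_is_constant(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 100, (50, 2))
        ang = rng.uniform(0, 2 * np.pi, 50)
        disp = pd.DataFrame({"x0": p[:, 0], "y0": p[:, 1],
                             "ux": np.cos(ang), "uy": np.sin(ang)})
        gx, gy = np.meshgrid(np.linspace(20, 80, 10), np.linspace(20, 80, 10))
        m = dfm.displacement_map(disp, gx, gy)
        inside = ~np.isnan(m)
        assert inside.sum() > 50
        assert np.allclose(m[inside], 1.0, atol=1e-9)

    def test_masked_outside_hull(self):
        disp = pd.DataFrame({"x0": [0, 10, 0, 10], "y0": [0, 0, 10, 10],
                             "ux": [1.0] * 4, "uy": [0.0] * 4})
        m = dfm.displacement_map(disp, np.array([[5.0, 50.0]]),
                                 np.array([[5.0, 50.0]]))
        assert np.isfinite(m[0, 0]) and np.isnan(m[0, 1])

    def test_uniform_strain_bands(self, cfg):
        fld = scene.generate_field(scene.FieldSpec(
            profile=scene.RadialProfile.linear(0.1), n_frames=3), cfg)
        disp = _field_from_tracks(cfg, fld, n=500)
        fmap = dfm.estimate_F(disp, cfg.pillar_center, cfg.pillar_radius)
        prof = dfm.radial_strain_profile(fmap, cfg.pillar_center,
                                         cfg.pillar_radius, n_bands=3)
        assert np.allclose(prof.mean_strain, 0.10, atol=1e-9)

    def test_quadratic_strain_bands_increase(self, cfg, quadratic_field):
        disp = _field_from_tracks(cfg, quadratic_field, n=2000)
        fmap = dfm.estimate_F(disp, cfg.pillar_center, cfg.pillar_radius)
        prof = dfm.radial_strain_profile(fmap, cfg.pillar_center,
                                         cfg.pillar_radius, n_bands=3)
        assert prof.mean_strain.is_monotonic_increasing

    def test_single_band_mean_matches_area_weighted_analytic(self, cfg,
                                                             quadratic_field):
        """One overall band: node-mean strain matches the area-weighted
        analytic mean 1.5*eps*E[r]/R = 0.1 within 2%."""
        disp = _field_from_tracks(cfg, quadratic_field, n=6000)
        fmap = dfm.estimate_F(disp, cfg.pillar_center, cfg.pillar_radius)
        prof = dfm.radial_strain_profile(fmap, cfg.pillar_center,
                                         cfg.pillar_radius, n_bands=1)
        analytic = 1.5 * 0.1 * (2.0 / 3.0)   # E[r]/R = 2/3 over the disc
        assert prof.mean_strain[0] == pytest.approx(analytic, rel=0.02)

    def test_empty_band_reported_missing(self, cfg):
        disp = pd.DataFrame({"x0": [10, 20, 30], "y0": [10, 20, 25],
                             "ux": [0.1] * 3, "uy": [0.0] * 3})
        fmap = dfm.estimate_F(disp, (20.0, 20.0), 30.0,
                              grid_spacing=10.0, neighborhood_radius=30.0)
        prof = dfm.radial_strain_profile(fmap, (2000.0, 2000.0), 30.0,
                                         n_bands=2)
        assert prof.missing.all()
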