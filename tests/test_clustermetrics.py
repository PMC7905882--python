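"""Cluster statistics: KDE density maps, k-NN distances, FWHM sizing."""

import numpy as np
import pytest

from stedclust.core import ClusterLocalizations, StedImage
from stedclust.clustermetrics import (
    LineProfile,
    cluster_fwhm,
    density_map,
    density_peak_intensities,
    extract_line_profiles,
    fit_lorentzian,
    knn_distances,
)
from stedclust.simulate import (
    PointProcessSpec,
    make_cell_mask,
    sample_cluster_points,
)

PX = 20.0


def _locs(points, **kw):
    return ClusterLocalizations(points=np.asarray(points, dtype=float), **kw)


def _grid_value_at(dmap, x, y):
    x0, y0 = dmap.origin
    ci = int(round((x - x0) / dmap.grid_spacing - 0.5))
    ri = int(round((y - y0) / dmap.grid_spacing - 0.5))
    return dmap.grid[ri, ci]


class TestDensityMap:
    def test_unit_peak_for_single_cluster(self):
        # place the cluster on a grid sample so the peak is read exactly
        dmap = density_map(_locs([[1010.0, 1010.0]]), bandwidth=200.0,
                           grid_spacing=20.0, extent_nm=(2020.0, 2020.0))
        assert np.isclose(dmap.grid.max(), 1.0, atol=1e-9)
        assert np.isclose(_grid_value_at(dmap, 1010.0, 1010.0), 1.0, atol=1e-9)

    def test_coincident_clusters_add(self):
        dmap = density_map(_locs([[1010.0, 1010.0]] * 5), bandwidth=200.0,
                           grid_spacing=20.0, extent_nm=(2020.0, 2020.0))
        assert np.isclose(dmap.grid.max(), 5.0, atol=1e-8)

    def test_midpoint_of_two_clusters_closed_form(self):
        """Two clusters 200 nm apart, bw 200: midpoint = 2 exp(-1/8)."""
        dmap = density_map(_locs([[910.0, 1010.0], [1110.0, 1010.0]]),
                           bandwidth=200.0, grid_spacing=20.0,
                           extent_nm=(2020.0, 2020.0))
        val = _grid_value_at(dmap, 1010.0, 1010.0)
        assert np.isclose(val, 2 * np.exp(-0.125), rtol=1e-9)

    def test_additivity_of_point_sets(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(200, 1800, (12, 2))
        b = rng.uniform(200, 1800, (7, 2))
        kw = dict(bandwidth=200.0, grid_spacing=40.0, extent_nm=(2000.0, 2000.0))
        m_ab = density_map(_locs(np.vstack([a, b])), **kw)
        m_a = density_map(_locs(a), **kw)
        m_b = density_map(_locs(b), **kw)
        assert np.allclose(m_ab.grid, m_a.grid + m_b.grid, rtol=1e-9)

    def test_normalization_modes_differ_by_constant(self):
        pts = np.random.default_rng(1).uniform(300, 1700, (9, 2))
        kw = dict(bandwidth=200.0, grid_spacing=40.0, extent_nm=(2000.0, 2000.0))
        ks = density_map(_locs(pts), normalization="kernel_sum", **kw)
        de = density_map(_locs(pts), normalization="density", **kw)
        const = len(pts) * 2 * np.pi * 200.0**2
        assert np.allclose(ks.grid, de.grid * const, rtol=1e-9)

    def test_empty_localizations_rejected(self):
        with pytest.raises(ValueError):
            density_map(_locs(np.empty((0, 2))))


class TestDensityPeaks:
    def test_single_cluster_single_unit_peak(self):
        dmap = density_map(_locs([[1010.0, 1010.0]]), bandwidth=200.0,
                           grid_spacing=20.0, extent_nm=(2020.0, 2020.0))
        peaks = density_peak_intensities(dmap)
        assert len(peaks) == 1
        assert np.isclose(peaks.values[0], 1.0, atol=1e-9)

    def test_two_coincident_groups_give_group_sizes(self):
        pts = [[610.0, 610.0]] * 3 + [[2610.0, 2610.0]] * 5
        dmap = density_map(_locs(pts), bandwidth=200.0, grid_spacing=20.0,
                           extent_nm=(3220.0, 3220.0))
        peaks = np.sort(density_peak_intensities(dmap).values)
        assert np.allclose(peaks, [3.0, 5.0], atol=1e-3)

    def test_flat_map_yields_empty(self):
        from stedclust.clustermetrics import DensityMap

        flat = DensityMap(grid=np.full((32, 32), 2.0), grid_spacing=20.0, bandwidth=200.0)
        assert len(density_peak_intensities(flat)) == 0

    def test_aggregated_pattern_has_larger_peaks_than_csr(self):
        """Thomas clustering concentrates density: peak intensities are
        stochastically larger than CSR at equal expected count."""
        mask = make_cell_mask((128, 128), 25.0, seed=3)
        csr = PointProcessSpec(kind="csr", intensity=4.0)
        tho = PointProcessSpec(kind="thomas", parent_intensity=1.0,
                               offspring_per_parent=4.0, offspring_sd=100.0)
        tops_csr, tops_tho = [], []
        for s in range(100):
            for spec, out in ((csr, tops_csr), (tho, tops_tho)):
                gt = sample_cluster_points(spec, mask, 25.0, seed=1000 + s)
                if len(gt) == 0:
                    continue
                dmap = density_map(_locs(gt.true_points), bandwidth=200.0,
                                   grid_spacing=50.0, extent_nm=(3200.0, 3200.0))
                out.append(density_peak_intensities(dmap).values.max())
        assert np.mean(tops_tho) > np.mean(tops_csr)


class TestKnn:
    def test_collinear_points_hand_geometry(self):
        pts = [[i * 100.0, 0.0] for i in range(6)]
        d = knn_distances(_locs(pts), k=4)
        assert len(d) == 24
        # distances from an end point: 100, 200, 300, 400
        assert np.allclose(np.sort(d.values[:4]), [100, 200, 300, 400])

    @pytest.mark.parametrize("n", [6, 25, 120])
    def test_matches_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        pts = rng.uniform(0, 5000, (n, 2))
        d = knn_distances(_locs(pts), k=4)
        brute = np.sort(
            np.linalg.norm(pts[:, None] - pts[None], axis=-1), axis=1
        )[:, 1:5].ravel()
        assert np.allclose(np.sort(d.values), np.sort(brute), rtol=1e-12)

    def test_isolated_pairs_min_distance_is_spacing(self):
        centers = np.array([[1000.0, 1000.0], [4000.0, 1000.0], [1000.0, 4000.0],
                            [4000.0, 4000.0], [2500.0, 2500.0]])
        rng = np.random.default_rng(5)
        pts = []
        for c in centers:
            ang = rng.uniform(0, 2 * np.pi)
            off = 202.3 / 2 * np.array([np.cos(ang), np.sin(ang)])
            pts += [c + off, c - off]
        d = knn_distances(_locs(np.array(pts)), k=4)
        per_point = d.values.reshape(-1, 4)
        assert np.allclose(per_point[:, 0], 202.3, rtol=1e-12)

    def test_too_few_points_names_cell(self):
        with pytest.raises(ValueError, match="cellX"):
            knn_distances(_locs([[0, 0], [1, 1]], cell_id="cellX"), k=4)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 4000, (40, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = pts @ R.T
        a = np.sort(knn_distances(_locs(pts)).values)
        b = np.sort(knn_distances(_locs(rot)).values)
        assert np.allclose(a, b, rtol=1e-9)


def _lorentzian_image(shape, px, center, gamma_x, gamma_y, amp=10.0, offset=1.0):
    """Elliptical Lorentzian spot sampled at pixel centres."""
    rows, cols = shape
    x = (np.arange(cols) + 0.5) * px - center[0]
    y = (np.arange(rows) + 0.5) * px - center[1]
    xx, yy = np.meshgrid(x, y)
    pix = offset + amp / (1.0 + (xx / gamma_x) ** 2 + (yy / gamma_y) ** 2)
    return StedImage(pixels=pix, pixel_size=px)


class TestLineProfiles:
    def test_radially_symmetric_spot_profiles_agree(self):
        img = _lorentzian_image((96, 96), PX, (960.0, 960.0), 40.0, 40.0)
        profs = extract_line_profiles(img, (960.0, 960.0))
        assert len(profs) == 4
        for p in profs[1:]:
            assert np.allclose(p.values, profs[0].values, rtol=0.02, atol=0.02)

    def test_constant_image_gives_constant_profile(self):
        img = StedImage(pixels=np.full((96, 96), 3.3), pixel_size=PX)
        for p in extract_line_profiles(img, (960.0, 960.0)):
            assert np.allclose(p.values, 3.3)

    def test_horizontal_profile_matches_pixel_row(self):
        rng = np.random.default_rng(7)
        img = StedImage(pixels=rng.uniform(0, 5, (96, 96)), pixel_size=PX)
        center = ((48 + 0.5) * PX, (30 + 0.5) * PX)  # pixel-aligned
        prof = extract_line_profiles(img, center, angles_deg=(0.0,))[0]
        on_pixel = np.isclose((prof.positions / PX) % 1.0, 0.0, atol=1e-9)
        cols = np.round(center[0] / PX - 0.5 + prof.positions[on_pixel] / PX).astype(int)
        assert np.allclose(prof.values[on_pixel], img.pixels[30, cols], atol=1e-9)

    def test_edge_center_skips_profiles(self):
        img = StedImage(pixels=np.zeros((96, 96)), pixel_size=PX)
        profs = extract_line_profiles(img, (30.0, 960.0))  # 30 nm from left edge
        assert len(profs) < 4


class TestLorentzianFit:
    @staticmethod
    def _profile(gamma=34.0, amp=5.0, x0=0.0, offset=1.0, noise_sd=0.0, seed=0):
        x = np.arange(-200.0, 201.0, 10.0)
        y = offset + amp / (1 + ((x - x0) / gamma) ** 2)
        if noise_sd:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, x.shape)
        return LineProfile(positions=x, values=y, angle_deg=0.0)

    def test_exact_lorentzian_recovers_fwhm_68(self):
        fit = fit_lorentzian(self._profile(gamma=34.0))
        assert fit.ok
        assert np.isclose(fit.fwhm, 68.0, atol=0.01)
        assert fit.r_squared > 0.9999

    def test_pure_noise_rejected_by_r2(self):
        rejected = 0
        for s in range(20):
            x = np.arange(-200.0, 201.0, 10.0)
            y = np.random.default_rng(s).normal(5, 1, x.shape)
            fit = fit_lorentzian(LineProfile(positions=x, values=y, angle_deg=0.0))
            if not (fit.ok and fit.r_squared > 0.9):
                rejected += 1
        assert rejected == 20

    def test_amplitude_scaling_equivariance(self):
        base = self._profile(gamma=40.0, amp=3.0, noise_sd=0.05)
        scaled = LineProfile(positions=base.positions, values=base.values * 10,
                             angle_deg=0.0)
        fa, fb = fit_lorentzian(base), fit_lorentzian(scaled)
        assert np.isclose(fa.gamma, fb.gamma, rtol=1e-6)
        assert np.isclose(fa.r_squared, fb.r_squared, atol=1e-9)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_lorentzian(LineProfile(positions=np.arange(5.0), values=np.ones(5),
                                       angle_deg=0.0))

    def test_constant_profile_not_passing(self):
        fit = fit_lorentzian(LineProfile(positions=np.arange(-200.0, 201.0, 10.0),
                                         values=np.full(41, 2.0), angle_deg=0.0))
        assert not (fit.ok and fit.r_squared > 0.9)


class TestClusterFwhm:
    def test_isotropic_spot_recovered(self):
        img = _lorentzian_image((96, 96), PX, (953.0, 967.0), 40.0, 40.0)
        d = cluster_fwhm(img, _locs([[953.0, 967.0]]))
        assert len(d) == 1
        assert abs(d.values[0] - 80.0) <= 15.0

    def test_elongated_spot_minimum_rule(self):
        """An 80 x 160 nm spot reports its narrow axis."""
        img = _lorentzian_image((96, 96), PX, (960.0, 960.0), 40.0, 80.0)
        d = cluster_fwhm(img, _locs([[960.0, 960.0]]))
        assert len(d) == 1
        assert abs(d.values[0] - 80.0) <= 15.0

    def test_impossible_r2_threshold_empty(self):
        img = _lorentzian_image((96, 96), PX, (960.0, 960.0), 40.0, 40.0)
        d = cluster_fwhm(img, _locs([[960.0, 960.0]]), r2_threshold=1.01)
        assert len(d) == 0
        assert d.meta["n_dropped"] == 1

    def test_edge_cluster_profiles_counted_as_skipped(self):
        img = _lorentzian_image((96, 96), PX, (100.0, 960.0), 40.0, 40.0)
        d = cluster_fwhm(img, _locs([[100.0, 960.0]]))
        assert d.meta["n_skipped_profiles"] > 0
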