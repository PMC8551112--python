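"""FCC Wigner-Seitz scoring: assignment, volumes, clusters, DSB conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.spatial import cKDTree

from trackevent import (
    ClusterSizeDistribution,
    ROISpec,
    assign_points,
    cluster_size_cdf,
    dsb_given_ic,
    lattice_from_diameter,
    roi_single_event,
    score_cvs,
    score_ics,
    site_positions,
    sites_in_box,
)
from trackevent.lattice import LATTICE_FACTOR


class TestLatticeGeometry:
    def test_lattice_constant_from_diameter(self):
        assert LATTICE_FACTOR == pytest.approx((2 * np.pi / 3) ** (1 / 3), rel=1e-15)
        assert lattice_from_diameter(2.0).a == pytest.approx(2.5588777, abs=1e-6)
        assert lattice_from_diameter(1.0).a == pytest.approx(1.2794389, abs=1e-6)

    def test_cell_volume_equals_sphere_volume(self):
        for d in (1.0, 2.0, 2.5, 3.0, 12.0, 18.0):
            lat = lattice_from_diameter(d)
            assert lat.cell_volume == pytest.approx(np.pi * d**3 / 6.0, rel=1e-12)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            lattice_from_diameter(0.0)

    def test_wigner_seitz_volume_by_rejection_sampling(self, rng):
        """MC volume of the cell of the origin site within 0.5%."""
        lat = lattice_from_diameter(2.0)
        n = 2 * 10**6
        pts = rng.uniform(-lat.a / 2, lat.a / 2, (n, 3))
        cells = assign_points(pts, lat)
        frac = (cells == 0).all(axis=1).mean()
        volume = frac * lat.a**3
        assert volume == pytest.approx(lat.cell_volume, rel=5e-3)


class TestAssignment:
    def test_point_at_site_maps_to_it(self):
        lat = lattice_from_diameter(2.0)
        sites = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0], [1, 0, 1]])
        pts = site_positions(sites, lat)
        assert (assign_points(pts, lat) == sites).all()

    def test_assignment_is_nearest_site(self, rng):
        """Decoder agrees with a KD-tree nearest-neighbour search."""
        lat = lattice_from_diameter(3.0)
        pts = rng.uniform(-20, 20, (2000, 3))
        cells = assign_points(pts, lat)
        all_sites = sites_in_box(lat, [-30] * 3, [30] * 3)
        tree = cKDTree(site_positions(all_sites, lat))
        d_tree, idx = tree.query(pts)
        d_ours = np.linalg.norm(pts - site_positions(cells, lat), axis=1)
        assert np.abs(d_ours - d_tree).max() < 1e-9

    def test_every_point_assigned_exactly_once(self, rng):
        lat = lattice_from_diameter(2.5)
        pts = rng.normal(0, 10, (5000, 3))
        cells = assign_points(pts, lat)
        assert cells.shape == (5000, 3)
        assert ((cells.sum(axis=1) % 2) == 0).all()  # valid FCC indices

    def test_uniform_points_fill_cells_uniformly(self, rng):
        """Cell occupancies of a uniform gas match equal cell volumes."""
        lat = lattice_from_diameter(4.0)
        half = 5 * lat.a / 2
        pts = rng.uniform(-half, half, (10**5, 3))
        cells = assign_points(pts, lat)
        # restrict to interior sites to avoid boundary truncation
        pos = site_positions(cells, lat)
        interior = (np.abs(pos) < half - lat.a).all(axis=1)
        uniq, counts = np.unique(cells[interior], axis=0, return_counts=True)
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-3

    def test_nonfinite_points_rejected(self):
        lat = lattice_from_diameter(2.0)
        with pytest.raises(ValueError):
            assign_points(np.array([[0.0, np.nan, 1.0]]), lat)


class TestScoreICs:
    def test_centroid_and_size(self):
        lat = lattice_from_diameter(4.0)
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        ics = score_ics(pts, lat)
        assert len(ics) == 1
        assert ics.iloc[0]["z"] == pytest.approx(0.5)
        assert ics.iloc[0]["size"] == 2

    def test_isolated_point_is_no_cluster(self):
        lat = lattice_from_diameter(4.0)
        ics = score_ics(np.array([[0.0, 0.0, 0.0]]), lat)
        assert len(ics) == 0

    def test_conservation_of_ionizations(self, rng):
        """Every ionization lands in exactly one cell; totals are conserved."""
        lat = lattice_from_diameter(2.0)
        pts = rng.normal(0, 5, (4000, 3))
        cells = assign_points(pts, lat)
        _, counts = np.unique(cells, axis=0, return_counts=True)
        assert counts.sum() == 4000
        ics = score_ics(pts, lat)
        assert int(ics["size"].sum()) == counts[counts >= 2].sum()

    def test_poisson_gas_ic_fraction(self, rng):
        """Occupied-cell IC fraction matches 1 - e^-mu (1 + mu)."""
        lat = lattice_from_diameter(3.0)
        mu = 0.3
        density = mu / lat.cell_volume
        box = 120.0
        n = rng.poisson(density * box**3)
        pts = rng.uniform(0, box, (n, 3))
        cells = assign_points(pts, lat)
        pos = site_positions(cells, lat)
        counts_all = pd.DataFrame(cells, columns=list("ijk")).groupby(
            list("ijk")).size()
        interior_sites = sites_in_box(lat, [lat.a] * 3, [box - lat.a] * 3)
        idx = pd.MultiIndex.from_arrays(interior_sites.T, names=list("ijk"))
        counts = counts_all.reindex(idx, fill_value=0).to_numpy()
        frac = (counts >= 2).mean()
        expected = 1.0 - np.exp(-mu) * (1.0 + mu)
        se = np.sqrt(expected * (1 - expected) / counts.size)
        assert counts.size > 5 * 10**4
        assert abs(frac - expected) < 3 * se
        del pos


class TestScoreCVs:
    def test_two_ics_in_one_cv(self):
        lat_cv = lattice_from_diameter(12.0)
        ics = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        cvs = score_cvs(ics, lat_cv)
        assert len(cvs) == 1
        assert cvs.iloc[0]["n_ic"] == 2

    def test_empty_input(self):
        assert len(score_cvs(np.zeros((0, 3)), lattice_from_diameter(12.0))) == 0

    def test_thinned_gas_poisson_counts(self, rng):
        """Uniform IC positions give Poisson counts per CV cell."""
        lat_cv = lattice_from_diameter(10.0)
        box, lam = 200.0, 0.5  # mean ICs per CV cell
        density = lam / lat_cv.cell_volume
        n = rng.poisson(density * box**3)
        ics = rng.uniform(0, box, (n, 3))
        cvs = score_cvs(ics, lat_cv)
        interior = sites_in_box(lat_cv, [lat_cv.a] * 3, [box - lat_cv.a] * 3)
        idx = pd.MultiIndex.from_arrays(interior.T, names=list("ijk"))
        counts = cvs.set_index(list("ijk"))["n_ic"].reindex(
            idx, fill_value=0).to_numpy()
        # shape test at the realized mean (conditioning out the global
        # count fluctuation, which shifts every bin together)
        lam_hat = counts.mean()
        assert lam_hat == pytest.approx(lam, rel=0.1)
        for k in range(4):
            p = stats.poisson.pmf(k, lam_hat)
            se = np.sqrt(p * (1 - p) / counts.size)
            assert abs((counts == k).mean() - p) < 3 * se


class TestROISingleEvent:
    def make_cv_table(self, positions, n_ics):
        pos = np.asarray(positions, dtype=float).reshape(-1, 3)
        return pd.DataFrame(
            {"i": 0, "j": 0, "k": 0, "x": pos[:, 0], "y": pos[:, 1],
             "z": pos[:, 2], "n_ic": n_ics}
        )

    def test_empty_track_gives_point_mass_at_origin(self):
        roi = ROISpec(r_roi=50.0, head_trim=0.0, tail_trim=0.0)
        pooled, _ = roi_single_event(
            [self.make_cv_table(np.zeros((0, 3)), [])], [(0.0, 500.0)], roi
        )
        assert pooled.masses[0, 0] == pytest.approx(1.0)

    def test_single_ic_counted_in_axis_placement(self):
        roi = ROISpec(r_roi=50.0, head_trim=0.0, tail_trim=0.0)
        table = self.make_cv_table([[0.0, 0.0, 250.0]], [1])
        pooled, placements = roi_single_event([table], [(0.0, 500.0)], roi)
        on_axis = placements[placements["placement"] == 0]
        assert tuple(on_axis[["n_single", "n_multi"]].iloc[0]) == (1, 0)

    def test_multi_ic_cv_counted_in_second_channel(self):
        roi = ROISpec(r_roi=50.0, head_trim=0.0, tail_trim=0.0)
        table = self.make_cv_table([[0.0, 0.0, 250.0]], [3])
        _, placements = roi_single_event([table], [(0.0, 500.0)], roi)
        on_axis = placements[placements["placement"] == 0]
        assert tuple(on_axis[["n_single", "n_multi"]].iloc[0]) == (0, 1)

    def test_short_track_rejected(self):
        roi = ROISpec(r_roi=300.0, head_trim=100.0, tail_trim=50.0)
        with pytest.raises(ValueError):
            roi_single_event(
                [self.make_cv_table(np.zeros((0, 3)), [])], [(0.0, 650.0)], roi
            )

    def test_placement_weights_are_sector_areas(self):
        roi = ROISpec(r_roi=10.0, n_sectors=8)
        offs, weights = roi.placements()
        assert offs.shape[0] == 1 + 8 * 4  # disc + 4 off-axis bins
        assert weights.sum() == pytest.approx(np.pi * 50.0**2)
        assert weights[0] == pytest.approx(np.pi * 100.0)

    def test_pooled_matches_random_placement_oracle(self, rng):
        """Deterministic sector tiling reproduces uniformly random ROI
        offsets over the same disc, for an azimuthally symmetric field."""
        rng_local = rng
        # radially symmetric CV field around the axis
        n_cv = 60
        r = rng_local.uniform(0, 80, n_cv)
        phi = rng_local.uniform(0, 2 * np.pi, n_cv)
        z = rng_local.uniform(100, 400, n_cv)
        pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        n_ic = rng_local.integers(1, 4, n_cv)
        table = self.make_cv_table(pos, n_ic)
        roi = ROISpec(r_roi=40.0, radial_bin_width=10.0, max_radius=200.0,
                      n_sectors=32, head_trim=0.0, tail_trim=0.0)
        pooled, _ = roi_single_event([table], [(0.0, 500.0)], roi)

        # oracle: uniform random offsets over the full placement disc
        m = 200_000
        rr = roi.placement_radius * np.sqrt(rng_local.random(m))
        pp = rng_local.uniform(0, 2 * np.pi, m)
        centers = np.column_stack(
            [rr * np.cos(pp), pp * 0 + rr * np.sin(pp), np.full(m, 250.0)]
        )
        n1 = np.zeros(m, dtype=int)
        n2 = np.zeros(m, dtype=int)
        for cv_pos, k in zip(pos, n_ic):
            inside = ((centers - cv_pos) ** 2).sum(axis=1) <= roi.r_roi**2
            if k == 1:
                n1 += inside
            else:
                n2 += inside
        emp = np.zeros_like(pooled.masses)
        np.add.at(emp, (np.minimum(n1, emp.shape[0] - 1),
                        np.minimum(n2, emp.shape[1] - 1)), 1.0)
        emp /= m
        # sector centres vs uniform offsets: agree to quadrature error
        assert np.abs(emp - pooled.masses).max() < 0.02


class TestDSBGivenIC:
    def test_pure_size_two_clusters(self):
        f = ClusterSizeDistribution([1.0, 0.4, 0.0])
        assert dsb_given_ic(f) == pytest.approx(0.5)

    def test_worked_value(self):
        f = ClusterSizeDistribution([1.0, 0.1, 0.02, 0.0])
        assert dsb_given_ic(f) == pytest.approx(0.55)

    def test_large_clusters_approach_unity(self):
        f2 = 0.3
        f = ClusterSizeDistribution([1.0] + [f2] * 60)
        assert dsb_given_ic(f) == pytest.approx(1.0, abs=1e-9)

    def test_zero_f2_rejected(self):
        with pytest.raises(ValueError):
            dsb_given_ic(ClusterSizeDistribution([1.0, 0.0]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=12),
           st.floats(0.01, 1.0))
    def test_equals_strand_assignment_enumeration(self, weights, scale):
        """Cumulative form equals sum_j P_j (1 - 2^(1-j)) / P(size >= 2)."""
        w = np.asarray(weights) + 1e-6
        pmf = scale * w / w.sum()  # cluster-size pmf over sizes 1..m
        sizes = np.arange(1, pmf.size + 1)
        f = np.array([pmf[sizes >= k].sum() for k in sizes])
        f = np.minimum(1.0, f)
        if f[1] <= 1e-12:
            return
        enum = float(
            (pmf[1:] * (1.0 - 2.0 ** (1.0 - sizes[1:]))).sum() / pmf[1:].sum()
        )
        assert abs(dsb_given_ic(ClusterSizeDistribution(f)) - enum) < 1e-12

    def test_cluster_size_cdf_from_counts(self):
        f = cluster_size_cdf(np.array([1, 2, 2, 3, 5]))
        assert f.f[0] == 1.0
        assert f.f[1] == pytest.approx(0.8)
        assert f.f[4] == pytest.approx(0.2)
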