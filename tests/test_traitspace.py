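"""Gower distances, PCoA embedding, hull areas and the RFS statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from coralfish.traitspace import (
    FOUR_TRAITS,
    build_trait_space,
    gower_distance,
    hull_area,
    hull_vertices,
    pcoa,
    rfs,
)


class TestGower:
    def test_identical_rows_zero(self, tiny_traits):
        t = pd.concat([tiny_traits.iloc[[0]], tiny_traits.iloc[[0]]])
        t.index = ["a", "b"]
        assert gower_distance(t).loc["a", "b"] == 0.0

    def test_opposite_extremes_distance_one(self):
        t = pd.DataFrame(
            {"total_length": [1.0, 100.0], "trophic_level": [2.0, 4.5],
             "group_size": ["solitary", "school"]},
            index=["lo", "hi"],
        )
        assert gower_distance(t).loc["lo", "hi"] == pytest.approx(1.0)

    def test_hand_computed_quantitative_oracle(self):
        # 3 species, 2 quantitative traits; ranges 10 and 2
        t = pd.DataFrame(
            {"total_length": [10.0, 15.0, 20.0], "trophic_level": [2.0, 4.0, 3.0]},
            index=["a", "b", "c"],
        )
        d = gower_distance(t, columns=["total_length", "trophic_level"])
        assert d.loc["a", "b"] == pytest.approx((5 / 10 + 2 / 2) / 2)
        assert d.loc["a", "c"] == pytest.approx((10 / 10 + 1 / 2) / 2)
        assert d.loc["b", "c"] == pytest.approx((5 / 10 + 1 / 2) / 2)

    def test_ordered_trait_uses_ranks(self):
        # ranks 1, 2, 3 -> distances 1/2 and 1 after range normalization
        t = pd.DataFrame(
            {"group_size": ["solitary", "pair", "school"]}, index=["a", "b", "c"]
        )
        d = gower_distance(t, columns=["group_size"])
        assert d.loc["a", "b"] == pytest.approx(0.5)
        assert d.loc["a", "c"] == pytest.approx(1.0)

    def test_bounds_symmetry_zero_diagonal(self, tiny_traits):
        d = gower_distance(tiny_traits).to_numpy()
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_missing_values_named(self, tiny_traits):
        t = tiny_traits.copy()
        t.loc["sp2", "aspect_ratio"] = np.nan
        with pytest.raises(ValueError, match="sp2"):
            gower_distance(t)

    def test_unknown_ordered_level_rejected(self):
        t = pd.DataFrame({"group_size": ["solitary", "swarm"]}, index=["a", "b"])
        with pytest.raises(ValueError, match="swarm"):
            gower_distance(t, columns=["group_size"])


class TestPcoa:
    def test_line_recovered_on_first_axis(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        d = np.abs(x[:, None] - x[None, :])
        coords, _ = pcoa(d, n_axes=2, correction="none")
        axis1 = coords.iloc[:, 0].to_numpy()
        gaps = np.diff(np.sort(axis1))
        np.testing.assert_allclose(sorted(gaps), [1.0, 1.0, 3.0], atol=1e-8)

    def test_planar_distances_roundtrip(self, rng):
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        coords, eig = pcoa(d, n_axes=2)
        d_back = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(d_back, d, atol=1e-8)

    def test_label_permutation_equivariance(self, tiny_traits):
        d = gower_distance(tiny_traits)
        perm = ["sp3", "sp0", "sp4", "sp1", "sp2"]
        c1, _ = pcoa(d)
        c2, _ = pcoa(d.loc[perm, perm])
        # same embedding rows, up to per-axis sign
        a = c1.loc[perm].to_numpy()
        b = c2.to_numpy()
        for ax in range(a.shape[1]):
            assert np.allclose(a[:, ax], b[:, ax], atol=1e-8) or np.allclose(
                a[:, ax], -b[:, ax], atol=1e-8
            )

    def test_cailliez_makes_gower_embeddable(self, tiny_traits):
        d = gower_distance(tiny_traits)
        coords, eig = pcoa(d, n_axes=2, correction="cailliez")
        assert coords.shape == (5, 2)
        assert eig[:2].min() > 0

    def test_axes_beyond_negative_eigenvalues_rejected(self):
        # 4-cycle graph metric: Gram eigenvalues (2, 2, 0, -1), so a fourth
        # axis would require a negative eigenvalue
        d = np.array(
            [[0, 1, 2, 1], [1, 0, 1, 2], [2, 1, 0, 1], [1, 2, 1, 0]], dtype=float
        )
        with pytest.raises(ValueError, match="positive eigenvalues"):
            pcoa(d, n_axes=4, correction="none")
        coords, _ = pcoa(d, n_axes=2, correction="none")
        assert coords.shape == (4, 2)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0, 1], [2, 0]]))


class TestHullArea:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert hull_area(sq) == pytest.approx(1.0)

    def test_interior_points_are_no_ops(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5], [0.1, 0.9]])
        assert hull_area(pts) == pytest.approx(1.0)

    def test_degenerate_sets_are_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert hull_area(np.array([[0, 0], [1, 1]])) == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert hull_area(np.array([[0, 0], [1, 1], [2, 2]])) == 0.0

    def test_subset_validation(self):
        pts = np.zeros((4, 2))
        with pytest.raises(IndexError):
            hull_area(pts, subset=[0, 9])

    def test_matches_rejection_sampling(self, rng):
        # Monte-Carlo membership integration as an independent area oracle
        from scipy.spatial import Delaunay

        pts = rng.normal(size=(50, 2))
        area = hull_area(pts)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        box = np.prod(hi - lo)
        samples = rng.uniform(lo, hi, size=(200_000, 2))
        inside = Delaunay(pts).find_simplex(samples) >= 0
        estimate = box * inside.mean()
        assert area == pytest.approx(estimate, rel=0.02)

    def test_monotone_in_subsets(self, rng):
        pts = rng.normal(size=(30, 2))
        sub = rng.choice(30, size=15, replace=False)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert hull_area(pts, sub) <= hull_area(pts) + 1e-12

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(25, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + np.array([3.0, -2.0])
        assert hull_area(moved) == pytest.approx(hull_area(pts), rel=1e-9)


class TestRfs:
    def test_boundary_identities(self):
        assert rfs(5.0, 5.0) == 0.0
        assert rfs(0.0, 5.0) == 100.0

    def test_ratio_arithmetic(self):
        assert rfs(0.947, 1.0) == pytest.approx(5.3)

    def test_degenerate_complete_space_rejected(self):
        with pytest.raises(ValueError):
            rfs(0.0, 0.0)

    def test_reduced_above_complete_rejected(self):
        with pytest.raises(ValueError):
            rfs(2.0, 1.0)


class TestBuildTraitSpace:
    def test_complete_space_properties(self, tiny_traits):
        ts = build_trait_space(tiny_traits)
        assert ts.area_complete > 0
        assert set(ts.hull_vertex_ids) <= set(ts.species_id)
        # coordinates centered
        np.testing.assert_allclose(ts.coordinates.mean(axis=0), 0, atol=1e-8)

    def test_removing_interior_species_is_free(self, tiny_traits):
        ts = build_trait_space(tiny_traits)
        interior = set(ts.species_id) - set(ts.hull_vertex_ids)
        if interior:
            assert ts.rfs_of_removal(interior) == pytest.approx(0.0, abs=1e-9)

    def test_four_trait_variant(self, tiny_traits):
        ts = build_trait_space(tiny_traits, trait_set="four")
        assert ts.area_complete > 0
        ts2 = build_trait_space(tiny_traits, trait_set=list(FOUR_TRAITS))
        assert ts2.area_complete == pytest.approx(ts.area_complete)

    def test_subset_area_never_exceeds_complete(self, tiny_traits, rng):
        ts = build_trait_space(tiny_traits)
        import warnings

        for _ in range(10):
            keep = rng.choice(ts.species_id, size=4, replace=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert ts.area_of(keep) <= ts.area_complete + 1e-12

    def test_hull_vertices_helper(self):
        pts = np.array([[0, 0], [2, 0], [1, 2], [1, 0.5]], dtype=float)
        assert hull_vertices(pts).tolist() == [0, 1, 2]
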