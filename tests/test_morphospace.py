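"""Trait-probability-density morphospace: grids, bandwidths, species and
community densities, richness, loss maps, uniqueness and prioritization."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import threatspace as ts
from threatspace.morphospace import TraitGrid, species_tpd


@pytest.fixture(scope="module")
def grid2():
    """A generous 2-D grid around the origin."""
    return TraitGrid(lower=np.array([-6.0, -6.0]), upper=np.array([6.0, 6.0]),
                     divisions=60)


def tpd_at(grid, x, y, bw=0.5, alpha=0.95):
    return species_tpd(np.array([x, y]), np.array([bw, bw]), grid, alpha)


class TestGrid:
    def test_cell_count_is_divisions_to_the_k(self):
        scores = np.random.default_rng(0).random((30, 3))
        grid = ts.build_grid(scores, divisions=50)
        assert grid.n_cells == 125_000

    def test_zero_buffer_bounds_equal_data_range(self):
        scores = np.array([[0.0, -1.0], [2.0, 3.0], [1.0, 1.0]])
        grid = ts.build_grid(scores, divisions=10, buffer_fraction=0.0)
        np.testing.assert_allclose(grid.lower, [0.0, -1.0])
        np.testing.assert_allclose(grid.upper, [2.0, 3.0])

    def test_all_means_inside_buffered_grid(self, world_small):
        from threatspace.ppca import ppca, preprocess_traits
        scores = ts.select_components(
            ppca(preprocess_traits(world_small.traits), world_small.tree), 3)
        grid = ts.build_grid(scores)
        for _, row in scores.iterrows():
            assert grid.contains(row.to_numpy())

    def test_constant_axis_rejected(self):
        with pytest.raises(ValueError):
            ts.build_grid(np.ones((5, 2)))


class TestBandwidth:
    def test_scale_equivariance(self):
        x = np.random.default_rng(1).standard_normal((300, 2))
        h = ts.bandwidth_select(x)
        np.testing.assert_allclose(ts.bandwidth_select(2.5 * x), 2.5 * h,
                                   rtol=1e-12)

    def test_permutation_invariance(self):
        x = np.random.default_rng(2).standard_normal((200, 2))
        perm = np.random.default_rng(3).permutation(200)
        np.testing.assert_allclose(ts.bandwidth_select(x),
                                   ts.bandwidth_select(x[perm]))

    def test_close_to_plugin_oracle_on_gaussian_cloud(self):
        # for Gaussian data the plug-in optimum is the normal-scale value
        # (4 / 3n)^(1/5) * sigma; the selector should land within 25%
        x = np.random.default_rng(4).standard_normal((1000, 3))
        h = ts.bandwidth_select(x)
        oracle = (4.0 / (3.0 * 1000)) ** 0.2
        assert np.all(np.abs(h - oracle) / oracle < 0.25)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ts.bandwidth_select(np.zeros((1, 2)))


class TestSpeciesTPD:
    def test_untrimmed_mass_matches_quadrature(self):
        """Cell masses on a fine 1-D grid match brute-force integration."""
        grid = TraitGrid(np.array([-8.0]), np.array([8.0]), divisions=2000)
        t = species_tpd(np.array([0.3]), np.array([1.0]), grid, alpha=1.0)
        assert t.total_mass == pytest.approx(1.0, abs=1e-9)
        # independently integrate the density over the grid's range
        total, _ = quad(lambda v: norm.pdf(v, 0.3, 1.0), -8, 8)
        dense = t.dense()
        # compare a band of individual cells against exact cell integrals
        for ci in range(990, 1010):
            lo = grid.lower[0] + ci * grid.steps[0]
            exact = (norm.cdf(lo + grid.steps[0], 0.3, 1.0)
                     - norm.cdf(lo, 0.3, 1.0)) / total
            assert dense[ci] == pytest.approx(exact, abs=1e-6)

    def test_alpha_trim_matches_sort_and_cumulate_oracle(self, grid2):
        full = tpd_at(grid2, 0.5, -0.25, alpha=1.0)
        trimmed = tpd_at(grid2, 0.5, -0.25, alpha=0.95)
        dense = full.dense()
        order = np.argsort(dense)[::-1]
        csum = np.cumsum(dense[order])
        n_keep = int(np.searchsorted(csum, 0.95) + 1)
        assert trimmed.cells.size == n_keep
        assert set(trimmed.cells) == set(order[:n_keep])
        assert dense[order[:n_keep]].sum() >= 0.95 - 1e-12
        assert trimmed.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_reflection_symmetry_at_grid_center(self, grid2):
        t = tpd_at(grid2, 0.0, 0.0, alpha=1.0)
        dense = t.dense().reshape(60, 60)
        np.testing.assert_allclose(dense, dense[::-1, :], atol=1e-15)
        np.testing.assert_allclose(dense, dense[:, ::-1], atol=1e-15)

    def test_invalid_inputs(self, grid2):
        with pytest.raises(ValueError):
            species_tpd(np.array([99.0, 0.0]), np.array([1.0, 1.0]), grid2)
        with pytest.raises(ValueError):
            species_tpd(np.array([0.0, 0.0]), np.array([0.0, 1.0]), grid2)


class TestCommunity:
    def test_single_species_identity(self, grid2):
        t = tpd_at(grid2, 1.0, 1.0)
        comm = ts.community_tpd([t])
        np.testing.assert_allclose(comm.dense(), t.dense())

    def test_disjoint_species_mass_and_support(self, grid2):
        a = tpd_at(grid2, -4.0, -4.0, bw=0.2)
        b = tpd_at(grid2, 4.0, 4.0, bw=0.2)
        assert set(a.cells).isdisjoint(b.cells)
        comm = ts.community_tpd([a, b])
        assert comm.total_mass == pytest.approx(2.0)
        assert set(comm.cells) == set(a.cells) | set(b.cells)

    def test_zero_weight_removes_species(self, grid2):
        a, b = tpd_at(grid2, -2.0, 0.0), tpd_at(grid2, 2.0, 0.0)
        comm = ts.community_tpd([a, b], np.array([1.0, 0.0]))
        np.testing.assert_allclose(comm.dense(), a.dense())

    def test_grid_mismatch_rejected(self, grid2):
        other = TraitGrid(np.array([-5.0, -5.0]), np.array([5.0, 5.0]), 60)
        with pytest.raises(ValueError):
            ts.community_tpd([tpd_at(grid2, 0, 0),
                              species_tpd(np.zeros(2), np.array([0.5, 0.5]),
                                          other)])


class TestRichness:
    def test_cell_count_oracle(self, grid2):
        t = tpd_at(grid2, 0.0, 0.0, bw=2.0, alpha=1.0)
        comm = ts.community_tpd([t])
        expected = np.count_nonzero(t.dense() > 0) * grid2.cell_volume
        assert ts.functional_richness(comm) == pytest.approx(expected)

    def test_monotone_under_adding_species(self, grid2):
        a = tpd_at(grid2, -3.0, 0.0)
        b = tpd_at(grid2, 3.0, 0.0)
        r1 = ts.functional_richness(ts.community_tpd([a]))
        r2 = ts.functional_richness(ts.community_tpd([a, b]))
        assert r2 >= r1

    def test_duplicate_species_leave_richness_unchanged(self, grid2):
        a = tpd_at(grid2, 1.0, -1.0)
        r1 = ts.functional_richness(ts.community_tpd([a]))
        r2 = ts.functional_richness(ts.community_tpd([a, a]))
        assert r1 == pytest.approx(r2)

    def test_weights_do_not_change_richness(self, grid2):
        tpds = [tpd_at(grid2, x, 0.0) for x in (-2.0, 0.0, 2.0)]
        r1 = ts.functional_richness(ts.community_tpd(tpds))
        r2 = ts.functional_richness(
            ts.community_tpd(tpds, np.array([0.1, 5.0, 900.0])))
        assert r1 == pytest.approx(r2)


class TestFdLoss:
    def test_no_extinctions_no_loss(self, grid2):
        tpds = [tpd_at(grid2, x, 0.0) for x in (-2.0, 2.0)]
        losses = ts.fd_loss(tpds, np.ones((2, 10), dtype=int))
        np.testing.assert_allclose(losses, 0.0)

    def test_identical_species_removal_costs_nothing(self, grid2):
        t = tpd_at(grid2, 0.0, 0.0)
        survival = np.array([[1], [0]])
        losses = ts.fd_loss([t, t], survival)
        np.testing.assert_allclose(losses, 0.0)

    def test_disjoint_two_species_world_loses_half(self, grid2):
        a = tpd_at(grid2, -4.0, -4.0, bw=0.2)
        b = tpd_at(grid2, 4.0, 4.0, bw=0.2)
        # equal support sizes -> removing one of two disjoint species = 50%
        assert a.cells.size == b.cells.size
        losses = ts.fd_loss([a, b], np.array([[1], [0]]))
        assert losses[0] == pytest.approx(50.0)

    def test_all_extinct_scores_100(self, grid2):
        tpds = [tpd_at(grid2, 0.0, 0.0)]
        losses = ts.fd_loss(tpds, np.zeros((1, 3), dtype=int))
        np.testing.assert_allclose(losses, 100.0)

    def test_losses_bounded(self, grid2):
        rng = np.random.default_rng(5)
        tpds = [tpd_at(grid2, *rng.uniform(-3, 3, 2)) for _ in range(8)]
        survival = (rng.random((8, 50)) > 0.4).astype(int)
        losses = ts.fd_loss(tpds, survival)
        assert ((losses >= 0) & (losses <= 100)).all()


class TestDensityLossMap:
    def test_no_extinction_no_density_loss(self, grid2):
        tpds = [tpd_at(grid2, -1.0, 0.0), tpd_at(grid2, 1.0, 0.0)]
        loss = ts.density_loss_map(tpds, np.array([1000, 1000]))
        occupied = ~np.isnan(loss)
        np.testing.assert_allclose(loss[occupied], 0.0)

    def test_total_extinction_everywhere_on_support(self, grid2):
        tpds = [tpd_at(grid2, -1.0, 0.0)]
        loss = ts.density_loss_map(tpds, np.array([0]))
        np.testing.assert_allclose(loss[~np.isnan(loss)], 100.0)

    def test_losing_one_of_two_equal_species_halves_shared_cells(self, grid2):
        t = tpd_at(grid2, 0.0, 0.0)
        loss = ts.density_loss_map([t, t], np.array([1000, 0]))
        np.testing.assert_allclose(loss[~np.isnan(loss)], 50.0)

    def test_counts_out_of_range_rejected(self, grid2):
        with pytest.raises(ValueError):
            ts.density_loss_map([tpd_at(grid2, 0, 0)], np.array([2000]))


class TestUniqueness:
    def test_singleton_community_scores_one(self, grid2):
        u = ts.uniqueness([tpd_at(grid2, 0.0, 0.0)], ["solo"])
        assert u["solo"] == pytest.approx(1.0)

    def test_identical_pair_scores_half(self, grid2):
        t = tpd_at(grid2, 0.0, 0.0)
        u = ts.uniqueness([t, t], ["a", "b"])
        np.testing.assert_allclose(u, 0.5)

    @pytest.mark.parametrize("n", [3, 7])
    def test_n_identical_species_score_one_over_n(self, grid2, n):
        t = tpd_at(grid2, 0.0, 0.0)
        u = ts.uniqueness([t] * n, [f"s{i}" for i in range(n)])
        np.testing.assert_allclose(u, 1.0 / n)

    def test_community_mass_equals_species_count(self, grid2):
        rng = np.random.default_rng(6)
        tpds = [tpd_at(grid2, *rng.uniform(-3, 3, 2)) for _ in range(9)]
        comm = ts.community_tpd(tpds)
        assert comm.total_mass == pytest.approx(9.0)


class TestPrioritize:
    def test_hand_built_top3(self):
        scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.6, "e": 0.5})
        cats = pd.Series({"a": "LC", "b": "CR", "c": "VU", "d": "EN", "e": "VU"})
        assert ts.prioritize_unique(scores, cats, 3) == ["b", "c", "d"]

    def test_low_risk_never_selected(self):
        scores = pd.Series({"a": 1.0, "b": 0.1})
        cats = pd.Series({"a": "NT", "b": "EN"})
        assert ts.prioritize_unique(scores, cats, 1) == ["b"]

    def test_whole_pool(self):
        scores = pd.Series({"a": 0.2, "b": 0.4})
        cats = pd.Series({"a": "VU", "b": "CR"})
        assert set(ts.prioritize_unique(scores, cats, 2)) == {"a", "b"}

    def test_ties_broken_by_species_id(self):
        scores = pd.Series({"z": 0.5, "a": 0.5, "m": 0.5})
        cats = pd.Series({"z": "VU", "a": "VU", "m": "VU"})
        assert ts.prioritize_unique(scores, cats, 2) == ["a", "m"]

    def test_k_beyond_pool_rejected(self):
        scores = pd.Series({"a": 0.2})
        cats = pd.Series({"a": "VU"})
        with pytest.raises(ValueError):
            ts.prioritize_unique(scores, cats, 2)
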