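"""Synthetic pool generators: schema, determinism, skewness, spatial structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import ecorare as ec
from ecorare.synthetic import CELL_AREA_KM2, lag1_autocorrelation
from ecorare.traits_space import TraitSpec


class TestTraits:
    def test_fuzzy_components_sum_to_one(self):
        cfg = ec.PoolConfig(
            n_species=30,
            trait_spec=[TraitSpec("diet", "fuzzy", n_components=10)],
            seed=1,
        )
        table = ec.generate_traits(cfg)
        sums = table.data[table.columns_of("diet")].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_same_seed_same_table(self, pool_cfg):
        a = ec.generate_traits(pool_cfg)
        b = ec.generate_traits(pool_cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_columns_match_declared_kinds(self):
        cfg = ec.PoolConfig(n_species=100, seed=2)
        table = ec.generate_traits(cfg)
        for spec in cfg.trait_spec:
            cols = table.columns_of(spec.name)
            if spec.kind == "fuzzy":
                assert len(cols) == spec.n_components
            else:
                assert cols == [spec.name]
            if spec.kind == "categorical":
                assert table.data[cols[0]].nunique() <= spec.n_levels

    def test_invalid_trait_spec_rejected(self):
        with pytest.raises(ValueError, match="fuzzy"):
            TraitSpec("diet", "fuzzy", n_components=1)
        with pytest.raises(ValueError, match="levels"):
            TraitSpec("activity", "categorical", n_levels=1)


class TestOccurrence:
    def test_degenerate_distribution_single_cell_ranges(self):
        cfg = ec.PoolConfig(
            n_species=20, grid_shape=(6, 6), range_size_log_mean=0.0, range_size_log_sd=0.0, seed=4
        )
        occ = ec.generate_occurrence(cfg)
        assert (occ.occupancy == 1).all()

    def test_every_species_occupies_at_least_one_cell(self, pool_cfg):
        occ = ec.generate_occurrence(pool_cfg)
        assert (occ.occupancy >= 1).all()
        assert set(np.unique(occ.data.to_numpy())) <= {0, 1}

    def test_right_skewed_occupied_fractions(self):
        cfg = ec.PoolConfig(n_species=200, seed=5)
        occ = ec.generate_occurrence(cfg)
        frac = occ.occupancy / occ.k_tot
        assert frac.median() < frac.mean()

    def test_ranges_are_contiguous_patches(self, pool_cfg):
        occ = ec.generate_occurrence(pool_cfg)
        rows, cols = occ.grid_shape
        for sp in occ.species[:15]:
            grid = occ.data[sp].to_numpy().reshape(rows, cols)
            _, n_patches = ndimage.label(grid)
            assert n_patches == 1

    def test_island_flag_is_contiguous_block(self, pool_cfg):
        occ = ec.generate_occurrence(pool_cfg)
        grid = occ.island.to_numpy().reshape(occ.grid_shape)
        _, n_patches = ndimage.label(grid)
        assert n_patches == 1
        assert grid.sum() == round(pool_cfg.island_fraction * pool_cfg.n_cells)

    def test_same_seed_same_matrix(self, pool_cfg):
        a = ec.generate_occurrence(pool_cfg)
        b = ec.generate_occurrence(pool_cfg)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestPhylogeny:
    def test_two_tips_form_an_ultrametric_cherry(self):
        t = ec.generate_phylogeny(2, seed=0)
        depths = [lf.distance_from_root() for lf in t.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1])
        assert depths[0] > 0

    def test_binary_tree_node_arithmetic(self):
        t = ec.generate_phylogeny(64, seed=1)
        internal = sum(1 for nd in t.preorder_node_iter() if not nd.is_leaf())
        assert internal == 63

    def test_branch_lengths_strictly_positive(self):
        t = ec.generate_phylogeny(16, seed=2)
        lengths = [nd.edge.length for nd in t.preorder_node_iter() if nd.parent_node]
        assert min(lengths) > 0

    def test_same_seed_same_newick(self):
        a = ec.generate_phylogeny(10, seed=7).as_string(schema="newick")
        b = ec.generate_phylogeny(10, seed=7).as_string(schema="newick")
        assert a == b

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            ec.generate_phylogeny(1)


class TestBinaryTrait:
    @pytest.mark.parametrize("mode", ["random", "brownian_threshold", "clade_clumped"])
    def test_exact_prevalence_count(self, tree64, mode):
        trait = ec.generate_binary_trait(tree64, mode, 0.25, seed=3)
        assert trait.sum() == 16

    def test_clumped_ones_contiguous_in_traversal_order(self, tree64):
        trait = ec.generate_binary_trait(tree64, "clade_clumped", 0.25, seed=3)
        ones = np.flatnonzero(trait.to_numpy())  # trait index = preorder tip order
        assert (np.diff(ones) == 1).all()

    def test_brownian_labels_vary_across_seeds(self, tree64):
        sets = {
            tuple(ec.generate_binary_trait(tree64, "brownian_threshold", 0.25, seed=s))
            for s in range(5)
        }
        assert len(sets) > 1

    def test_monomorphic_prevalence_rejected(self, tree64):
        with pytest.raises(ValueError):
            ec.generate_binary_trait(tree64, "random", 0.001, seed=0)


@pytest.fixture(scope="module")
def layers(pool_cfg):
    occ = ec.generate_occurrence(pool_cfg)
    return occ, ec.generate_conservation_layers(pool_cfg, occ, seed=6)


class TestConservationLayers:
    def test_range_size_is_occupancy_times_cell_area(self, layers):
        occ, (species, _) = layers
        four_cells = occ.occupancy[occ.occupancy == 4]
        if len(four_cells):
            assert species.loc[four_cells.index[0], "range_km2"] == 4 * CELL_AREA_KM2
        np.testing.assert_allclose(
            species["range_km2"], occ.occupancy.to_numpy() * CELL_AREA_KM2
        )

    def test_protected_fractions_bounded(self, layers):
        _, (species, _) = layers
        assert species["protected_fraction"].between(0, 1).all()

    def test_status_codes_in_iucn_vocabulary(self, layers):
        _, (species, _) = layers
        assert species["status"].isin(["CR", "EN", "VU", "LC", "NT", "DD", "NE"]).all()

    def test_covariate_grids_spatially_autocorrelated(self, pool_cfg):
        occ = ec.generate_occurrence(pool_cfg)
        acs = []
        for seed in (1, 2, 3):
            _, cells = ec.generate_conservation_layers(pool_cfg, occ, seed=seed)
            for col in cells.columns:
                grid = cells[col].to_numpy().reshape(pool_cfg.grid_shape)
                acs.append(lag1_autocorrelation(grid))
        assert min(acs) > 0
        assert np.mean(acs) > 0.3

    def test_deterministic_under_seed(self, pool_cfg):
        occ = ec.generate_occurrence(pool_cfg)
        a = ec.generate_conservation_layers(pool_cfg, occ, seed=9)
        b = ec.generate_conservation_layers(pool_cfg, occ, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestPoolConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ec.PoolConfig(n_species=2)
        with pytest.raises(ValueError):
            ec.PoolConfig(island_fraction=1.5)
        with pytest.raises(ValueError):
            ec.PoolConfig(grid_shape=(1, 1))
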