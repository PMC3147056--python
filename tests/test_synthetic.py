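"""Synthetic cohort generator: trees, sizes, gene states, plates."""

import numpy as np
import pandas as pd
import pytest

from phenodecouple.distances import parse_newick, patristic_matrix, tree_to_newick
from phenodecouple.exceptions import InvalidConfigError, InvalidParameterError
from phenodecouple.synthetic import (
    SyntheticConfig,
    gen_gene_states,
    gen_pathway_sizes,
    gen_plate,
    gen_tree,
    generate_dataset,
)


class TestTree:
    def test_single_leaf_degenerate(self):
        tree = gen_tree(1, 1, seed=0)
        assert len(tree.leaf_nodes()) == 1
        assert patristic_matrix(tree).values.shape == (1, 1)

    def test_four_leaf_matrix_symmetric_zero_diagonal(self):
        dm = patristic_matrix(gen_tree(4, 2, seed=1))
        assert dm.values.shape == (4, 4)
        np.testing.assert_allclose(dm.values, dm.values.T)
        np.testing.assert_allclose(np.diag(dm.values), 0.0)

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_distances_bounded_and_nonnegative(self, seed):
        dm = patristic_matrix(gen_tree(25, 5, seed=seed))
        assert dm.values.min() >= 0.0
        assert dm.values.max() <= 0.25 + 1e-9
        assert dm.values.max() == pytest.approx(0.25, abs=1e-9)

    def test_clade_structure_gives_bimodal_distances(self):
        """Intra- vs inter-clade distances leave a dip in the histogram."""
        dm = patristic_matrix(gen_tree(20, 4, seed=7))
        d = dm.condensed()
        counts, _ = np.histogram(d, bins=12, range=(0, 0.25))
        occupied = np.nonzero(counts)[0]
        interior = counts[occupied[0] : occupied[-1] + 1]
        assert (interior == 0).any()  # an empty bin between the two modes

    def test_too_many_clades_rejected(self):
        with pytest.raises(InvalidConfigError):
            gen_tree(3, 5, seed=0)

    def test_newick_round_trip(self):
        tree = gen_tree(8, 2, seed=3)
        reparsed = parse_newick(tree_to_newick(tree))
        d1 = patristic_matrix(tree)
        d2 = patristic_matrix(reparsed).reorder(d1.labels)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-9)


class TestPathwaySizes:
    def test_constant_law(self):
        np.testing.assert_array_equal(gen_pathway_sizes(3, ("constant", 1)), [1, 1, 1])

    def test_default_law_bounds(self):
        sizes = gen_pathway_sizes(395, "default", seed=3)
        assert sizes.min() >= 1 and sizes.max() <= 20

    def test_default_law_mean(self):
        # 1 + Poisson(4) truncated at 20: mean 5, variance ~4
        sizes = gen_pathway_sizes(10_000, "default", seed=3)
        se = np.sqrt(4.0 / 10_000)
        assert abs(sizes.mean() - 5.0) < 3 * se


def _pair_tree(d):
    return parse_newick(f"(A:{d / 2},B:{d / 2});")


class TestGeneStates:
    def test_neutral_mutations_leave_all_pairs_identical(self):
        states, _ = gen_gene_states(_pair_tree(0.2), np.ones(500, int), mu=1.0,
                                    lam=0.5, seed=0)
        assert (states.iloc[0] == states.iloc[1]).all()

    @pytest.mark.parametrize(
        "d,expected", [(0.25, 0.0590750), (0.0, 0.0221)]
    )
    def test_pairwise_difference_fraction(self, d, expected):
        # hand arithmetic: p_M = (1-0.83) * (1 - (1-d) * (1-0.13))
        sizes = np.ones(100_000, int)
        states, _ = gen_gene_states(_pair_tree(d), sizes, mu=0.83, lam=0.13, seed=5)
        frac = (states.iloc[0] != states.iloc[1]).mean()
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(frac - expected) < 3 * se

    def test_difference_fraction_monotone_in_distance(self):
        sizes = np.ones(100_000, int)
        fracs = []
        for d in [0.0, 0.05, 0.10, 0.15, 0.20, 0.25]:
            states, _ = gen_gene_states(_pair_tree(d), sizes, seed=11)
            fracs.append((states.iloc[0] != states.iloc[1]).mean())
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_gene_states(_pair_tree(0.1), np.ones(10, int), mu=1.2)
        with pytest.raises(InvalidParameterError):
            gen_gene_states(_pair_tree(0.1), np.ones(10, int), lam=-0.1)

    def test_genes_partition_into_pathways(self):
        sizes = np.array([2, 3, 1])
        states, pathways = gen_gene_states(_pair_tree(0.1), sizes, seed=0)
        all_genes = [g for pw in pathways for g in pw.genes]
        assert len(all_genes) == len(set(all_genes)) == 6
        assert states.shape[1] == 6

    def test_stationary_marginal_functionality(self):
        """The functional gene fraction does not drift down the strain chain."""
        tree = gen_tree(30, 3, seed=2)
        states, _ = gen_gene_states(tree, np.ones(20_000, int), seed=2)
        per_strain = states.mean(axis=1)
        assert per_strain.min() > 0.90
        assert per_strain.max() < 1.00


class TestPlate:
    def test_all_functional_yields_from_high_component(self, small_cohort):
        from phenodecouple.growth import subtract_blank

        config, truth, _ = small_cohort
        cfg = SyntheticConfig(n_strains=config.n_strains, n_substrates=20,
                              n_pathways=config.n_pathways, date_effect_sd=0.0, seed=9)
        forced = truth.growth_states.iloc[:, :20].copy()
        forced.loc[:, :] = True
        import dataclasses

        t2 = dataclasses.replace(truth, growth_states=forced,
                                 date_of_strain=None, date_offsets=None)
        plate = gen_plate(t2, cfg, seed=9)
        ym = subtract_blank(plate)
        vals = ym.long["yield_od"].to_numpy()
        # high component: N(1.0, 0.2) minus blank N(0.02, 0.02)
        assert vals.mean() == pytest.approx(0.98, abs=0.03)
        assert (vals > 0.2).mean() > 0.999

    def test_two_date_offsets_separate_raw_means(self, small_cohort):
        import dataclasses

        config, truth, _ = small_cohort
        cfg = SyntheticConfig(n_strains=config.n_strains, n_substrates=20,
                              n_pathways=config.n_pathways, n_dates=2, seed=4)
        forced = truth.growth_states.iloc[:, :20].copy()
        forced.loc[:, :] = True
        strains = list(forced.index)
        dates = pd.Series(["d1", "d2"] * (len(strains) // 2), index=strains)
        t2 = dataclasses.replace(truth, growth_states=forced, date_of_strain=dates,
                                 date_offsets={"d1": 0.1, "d2": -0.1})
        plate = gen_plate(t2, cfg, seed=4)
        wells = plate[~plate["is_blank"]]
        means = wells.groupby("date")["od"].mean()
        assert means["d1"] - means["d2"] == pytest.approx(0.2, abs=0.03)

    def test_one_blank_per_plate(self, small_cohort):
        _, _, plate = small_cohort
        per_plate = plate.groupby(["strain", "date", "replicate"])["is_blank"].sum()
        assert (per_plate == 1).all()


class TestConfigAndRoundTrip:
    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(n_strains=0)
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(n_strains=5, n_clades=9)
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(mixture_spec=((0.5, 0.0, 0.1), (0.6, 1.0, 0.1)))
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(n_substrates=100, n_pathways=50)

    def test_artifacts_round_trip(self, tmp_path, small_cohort):
        from phenodecouple.io import (
            read_labeled_matrix,
            read_pathways,
            read_substrate_map,
        )

        _, truth, _ = small_cohort
        paths = truth.write(tmp_path)
        genes = read_labeled_matrix(paths["genes"])
        pd.testing.assert_frame_equal(
            genes, truth.gene_states.rename_axis("strain"), check_dtype=False
        )
        pathways = read_pathways(paths["pathways"])
        assert [p.id for p in pathways] == [p.id for p in truth.pathways]
        assert pathways[0].genes == truth.pathways[0].genes
        assert read_substrate_map(paths["map"]) == truth.substrate_map
        reparsed = parse_newick(paths["tree"].read_text())
        d1 = truth.genetic_distance
        d2 = patristic_matrix(reparsed).reorder(d1.labels)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-9)

    def test_generation_is_seed_deterministic(self):
        cfg = SyntheticConfig(n_strains=8, n_substrates=10, n_pathways=15, seed=5)
        t1, p1 = generate_dataset(cfg)
        t2, p2 = generate_dataset(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1.gene_states, t2.gene_states)
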