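"""Synthetic-data generator: communities, genealogies, sequences, errors."""

import numpy as np
import pytest

import barcodiv as bd
from conftest import make_bundle


class TestCommunity:
    def test_explicit_all_singleton_abundances(self):
        p = bd.SimParams(
            n_species=6, n_specimens=6,
            abundance_model=("explicit", [1] * 6), seed=0,
        )
        truth = bd.simulate_community(p)
        assert truth.singleton_fraction() == 1.0
        assert truth.n_specimens == 6

    def test_deterministic_under_seed(self):
        p = bd.SimParams(n_species=15, n_specimens=40, seed=9)
        a, b = bd.simulate_community(p), bd.simulate_community(p)
        assert a.abundances == b.abundances
        assert a.true_partition == b.true_partition
        assert a.sampling_unit_of_specimen == b.sampling_unit_of_specimen
        assert a.levels_of_species == b.levels_of_species

    def test_study_scale_singleton_fraction_in_band(self):
        truth = bd.simulate_community(bd.SimParams(seed=1))
        # ~52.6% of 266 morphospecies were singletons in the survey
        assert 0.476 <= truth.singleton_fraction() <= 0.576
        assert truth.species_count == 266
        assert truth.n_specimens == 674

    def test_unreachable_singleton_target_fails_loudly(self):
        p = bd.SimParams(
            n_species=5, n_specimens=5, target_singleton_fraction=0.0, seed=0
        )
        with pytest.raises(ValueError, match="achieved"):
            bd.simulate_community(p)

    def test_partition_blocks_match_abundances(self, small_sim):
        truth = small_sim.truth
        assert sorted(len(b) for b in truth.true_partition.blocks) == sorted(
            truth.abundances
        )

    def test_turnover_confines_most_species_to_one_level(self):
        truth = bd.simulate_community(bd.SimParams(seed=3))
        single = sum(1 for lv in truth.levels_of_species if len(lv) == 1)
        assert single / truth.species_count > 0.8

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            bd.SimParams(n_species=0)
        with pytest.raises(ValueError):
            bd.SimParams(mutation_rate=-0.1)
        with pytest.raises(ValueError):
            bd.SimParams(turnover_prob=1.5)


class TestGenealogy:
    def test_single_species_pure_coalescent(self):
        p = bd.SimParams(
            n_species=1, n_specimens=5,
            abundance_model=("explicit", [5]), seed=2,
        )
        truth = bd.simulate_community(p)
        tree = bd.simulate_genealogy(truth, p)
        assert tree.n_tips == 5
        assert tree.is_ultrametric()
        assert tree.root_age() == pytest.approx(1.0)

    def test_all_singletons_pure_yule(self):
        p = bd.SimParams(
            n_species=8, n_specimens=8,
            abundance_model=("explicit", [1] * 8), seed=4,
        )
        truth = bd.simulate_community(p)
        tree = bd.simulate_genealogy(truth, p)
        assert tree.n_tips == 8
        assert tree.is_ultrametric()

    def test_ultrametric_root_one_within_tolerance(self, small_sim):
        depths = small_sim.tree.depths().values()
        assert all(abs(d - 1.0) <= 1e-9 for d in depths)

    def test_within_species_subtrees_younger_than_attachment(self):
        """Every within-species MRCA sits below the start of its species'
        terminal branch (checked over many seeded simulations)."""
        for seed in range(30):
            bundle = make_bundle(
                bd.SimParams(n_species=6, n_specimens=24, seed=seed)
            )
            ages = bundle.tree.node_ages()
            tree = bundle.tree.tree
            for label in bundle.truth.species_labels:
                tips = bundle.truth.specimens_of_species(label)
                if len(tips) < 2:
                    continue
                mrca = tree.mrca(taxon_labels=tips)
                assert ages[mrca] < ages[mrca.parent_node]

    def test_species_monophyletic_with_shallow_coalescent(self):
        """With coalescent depth << species depth, true species are
        monophyletic in >= 99% of simulations."""
        mono = total = 0
        for seed in range(100):
            bundle = make_bundle(
                bd.SimParams(n_species=5, n_specimens=15, seed=seed,
                             abundance_model=("explicit", [3] * 5))
            )
            tree = bundle.tree.tree
            for label in bundle.truth.species_labels:
                tips = set(bundle.truth.specimens_of_species(label))
                total += 1
                mrca = tree.mrca(taxon_labels=tips)
                clade = {l.taxon.label for l in mrca.leaf_iter()}
                mono += clade == tips
        assert mono / total >= 0.99

    def test_two_specimens_minimum(self):
        p = bd.SimParams(n_species=1, n_specimens=1,
                         abundance_model=("explicit", [1]), seed=0)
        truth = bd.simulate_community(p)
        with pytest.raises(ValueError):
            bd.simulate_genealogy(truth, p)


class TestSequences:
    def test_zero_mutation_rate_identical_sequences(self, small_sim):
        import dataclasses

        p = dataclasses.replace(small_sim.params, mutation_rate=0.0)
        aln = bd.simulate_sequences(small_sim.tree, p)
        assert len(set(aln.sequences)) == 1

    def test_one_row_per_tip_with_default_length(self, small_sim):
        aln = small_sim.aln
        assert aln.n == small_sim.tree.n_tips
        assert aln.length == 658

    def test_jc69_closed_form_on_two_tip_tree(self):
        """Mean p-distance across replicates matches the JC69 expectation
        (3/4)(1 - exp(-4 mu t / 3)) within 3 Monte-Carlo SE."""
        import dataclasses

        from barcodiv.trees import from_newick_string

        tree = from_newick_string("(x:0.5,y:0.5);")
        mu, t_total, L = 0.2, 1.0, 658
        expected = 0.75 * (1 - np.exp(-4 * mu * t_total / 3))
        base = bd.SimParams(alignment_length=L, mutation_rate=mu, seed=0)
        obs = []
        for rep in range(200):
            p = dataclasses.replace(base, seed=rep)
            aln = bd.simulate_sequences(tree, p)
            obs.append(bd.p_distance_matrix(aln).values[0, 1])
        se = np.std(obs, ddof=1) / np.sqrt(len(obs))
        assert abs(np.mean(obs) - expected) <= 3 * se

    def test_deterministic_under_seed(self, small_sim):
        again = bd.simulate_sequences(small_sim.tree, small_sim.params)
        assert again == small_sim.aln


class TestMorphospeciesError:
    def test_zero_rates_reproduce_truth(self, small_sim):
        out = bd.corrupt_morphospecies(small_sim.truth, 0.0, 0.0, seed=1)
        assert out == small_sim.truth.true_partition

    def test_certain_split_yields_two_labels(self):
        p = bd.SimParams(n_species=1, n_specimens=4,
                         abundance_model=("explicit", [4]), seed=0)
        truth = bd.simulate_community(p)
        out = bd.corrupt_morphospecies(truth, 1.0, 0.0, seed=3)
        assert out.n_groups == 2

    def test_certain_lump_merges_adjacent_pair(self):
        p = bd.SimParams(n_species=2, n_specimens=4,
                         abundance_model=("explicit", [2, 2]), seed=0)
        truth = bd.simulate_community(p)
        out = bd.corrupt_morphospecies(truth, 0.0, 1.0, seed=3)
        assert out.n_groups == 1

    def test_deterministic_under_seed(self, small_sim):
        a = bd.corrupt_morphospecies(small_sim.truth, 0.3, 0.3, seed=7)
        b = bd.corrupt_morphospecies(small_sim.truth, 0.3, 0.3, seed=7)
        assert a == b

    def test_result_covers_all_specimens(self, small_sim):
        out = bd.corrupt_morphospecies(small_sim.truth, 0.5, 0.5, seed=11)
        assert out.specimens == small_sim.truth.true_partition.specimens


class TestExports:
    def test_metadata_frame_columns_and_rows(self, small_sim):
        meta = small_sim.meta
        assert list(meta.columns) == [
            "specimen_id", "true_species", "morphospecies",
            "sampling_unit", "level", "method",
        ]
        assert len(meta) == small_sim.truth.n_specimens

    def test_write_simulation_outputs(self, small_sim, tmp_path):
        from barcodiv.simulate import write_simulation

        paths = write_simulation(
            tmp_path, small_sim.truth, small_sim.tree, small_sim.aln,
            small_sim.morpho, small_sim.params,
        )
        aln = bd.read_alignment(paths["fasta"])
        assert aln.n == small_sim.aln.n
        tree = bd.read_newick(paths["tree"])
        assert sorted(tree.tip_labels) == sorted(small_sim.tree.tip_labels)
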