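"""Gene-tree/trait simulator, bias injection and permutation nulls."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paracontrast.contrasts import compute_pic
from paracontrast.gene_trees import Event, TraitTable, node_metrics
from paracontrast.synthetic_data import (
    DEFAULT_SPECIATION_AGES, SimulationConfig, generate_gene_tree,
    generate_study, inject_calibration_bias, permute_node_events,
    permute_tip_traits, random_event_tree, simulate_trait, species_tree,
)


class TestSpeciesTree:
    def test_default_ladder_shape(self):
        sp = species_tree()
        assert sp.n_tips == len(DEFAULT_SPECIATION_AGES) + 1
        assert sp.is_ultrametric()
        ages = sorted((node_metrics(sp)[n.id].age for n in sp.internal_nodes),
                      reverse=True)
        assert ages == pytest.approx(sorted(DEFAULT_SPECIATION_AGES,
                                            reverse=True))


class TestGenerateGeneTree:
    def test_no_duplication_gives_species_tree(self):
        cfg = SimulationConfig(dup_rate=0.0, ancient_rate=0.0, loss_prob=0.0)
        tree = generate_gene_tree(cfg, seed=0)
        assert tree.n_tips == 8
        assert all(n.event is Event.SPECIATION for n in tree.internal_nodes)
        assert tree.is_ultrametric()
        m = node_metrics(tree)
        root_age = m[tree.root.id].age
        assert root_age == pytest.approx(296.0)

    def test_output_ultrametric_and_fully_tagged(self):
        for s in range(10):
            tree = generate_gene_tree(SimulationConfig(), seed=s)
            assert tree.is_ultrametric()
            assert all(n.event is not None for n in tree.internal_nodes)
            assert all(n.length > 0 for n in tree.nodes if n is not tree.root)

    def test_duplication_count_matches_poisson_expectation(self):
        # with no loss and no ancient events, E[#dup] ~ rate x total length,
        # but each accepted duplication extends the tree; use the species
        # tree length as a lower bound and a generous band
        cfg = SimulationConfig(dup_rate=0.002, ancient_rate=0.0,
                               loss_prob=0.0)
        sp = species_tree()
        base_len = sum(n.length for n in sp.nodes if n is not sp.root)
        counts = []
        for s in range(300):
            tree = generate_gene_tree(cfg, seed=s)
            counts.append(sum(1 for n in tree.internal_nodes
                              if n.event is Event.DUPLICATION))
        # lower bound: Poisson on the base species tree alone
        assert np.mean(counts) > 0.002 * base_len
        assert np.mean(counts) < 5 * 0.002 * base_len

    def test_ancient_rate_places_old_duplications(self):
        cfg = SimulationConfig(dup_rate=0.0, ancient_rate=0.01,
                               loss_prob=0.0)
        n_with_old = 0
        for s in range(50):
            tree = generate_gene_tree(cfg, seed=s)
            m = node_metrics(tree)
            if any(n.event is Event.DUPLICATION and m[n.id].age > 296.0
                   for n in tree.internal_nodes):
                n_with_old += 1
        # P(no ancient dup) = exp(-0.01 * 879) ~ 0.00015
        assert n_with_old >= 45

    def test_study_determinism(self):
        a = generate_study(SimulationConfig(n_trees=4), seed=7)
        b = generate_study(SimulationConfig(n_trees=4), seed=7)
        for ta, tb in zip(a.trees, b.trees):
            assert ta.to_newick() == tb.to_newick()
            assert a.traits[ta.tree_id].values == b.traits[tb.tree_id].values


class TestBiasInjection:
    def test_no_old_duplication_identity(self):
        cfg = SimulationConfig(ancient_rate=0.0)
        tree = generate_gene_tree(cfg, seed=1)
        out = inject_calibration_bias(tree, seed=0, age_threshold=296.0)
        assert out.to_newick() == tree.to_newick()

    def test_degenerate_factor_identity(self):
        cfg = SimulationConfig(ancient_rate=0.01)
        tree = generate_gene_tree(cfg, seed=3)
        out = inject_calibration_bias(tree, seed=0, age_threshold=296.0,
                                      factor_low=1.0, factor_high=1.0)
        assert out.to_newick() == tree.to_newick()

    def test_stretch_inflates_expected_sd_of_old_dup_contrast(self):
        # single ancient duplication: the contrast taken at it has a larger
        # expected SD after injection, everything below is untouched
        cfg = SimulationConfig(dup_rate=0.0, ancient_rate=0.0, loss_prob=0.0)
        rng = np.random.default_rng(0)
        tree = generate_gene_tree(cfg, seed=rng)
        # graft one ancient duplication by hand at 600 My
        from paracontrast.gene_trees import GeneTree, Node
        copy2 = generate_gene_tree(cfg, seed=rng)
        dup = Node(event=Event.DUPLICATION)
        r1 = tree.root
        r2 = copy2.root
        r1.length = 600.0 - 296.0
        r2.length = 600.0 - 296.0
        dup.add_child(r1)
        dup.add_child(r2)
        big = GeneTree(dup, tree_id="grafted")
        # relabel: the two copies carry clashing tip names
        for i, t in enumerate(big.tips):
            t.label = f"g{i}"
        traits = simulate_trait(big, SimulationConfig(trait_model="BM1"),
                                seed=4)
        before = {r.node_id: r.expected_sd for r in compute_pic(big, traits)}
        biased = inject_calibration_bias(big, seed=5, age_threshold=296.0,
                                         factor_low=10.0, factor_high=10.0)
        after = {r.node_id: r.expected_sd for r in compute_pic(biased, traits)}
        dup_id = big.root.id
        assert after[dup_id] > before[dup_id] * 2.0
        assert not biased.ultrametric_expected
        for nid in before:
            if nid != dup_id:
                assert after[nid] == pytest.approx(before[nid], rel=1e-9)


class TestSimulateTrait:
    def test_zero_rate_constant(self):
        tree = random_event_tree(8, seed=0)
        traits = simulate_trait(tree, SimulationConfig(trait_model="BM1",
                                                       sigma2=0.0), seed=1)
        assert set(traits.values.values()) == {0.5}

    def test_bm_marginal_variance(self):
        tree = random_event_tree(6, height=50.0, seed=2)
        cfg = SimulationConfig(trait_model="BM1", sigma2=0.01)
        rng = np.random.default_rng(3)
        lab = tree.tip_labels()[0]
        vals = [simulate_trait(tree, cfg, seed=rng)[lab]
                for _ in range(2000)]
        var = np.var(vals)
        # chi-square 99% band around sigma^2 * height = 0.5
        lo = 0.5 * 1862 / 2000  # rough chi2 0.005/0.995 quantiles per df
        hi = 0.5 * 2143 / 2000
        assert lo < var < hi

    def test_oc_rate_ratio_recovered_by_contrasts(self):
        # mean squared standardized contrast at duplication nodes ~ rho x
        # that at speciation nodes when traits evolve under OC on true trees
        cfg = SimulationConfig(trait_model="OC", oc_rho=4.0, sigma2=0.01)
        rng = np.random.default_rng(9)
        spe, dup = [], []
        for s in range(300):
            tree = generate_gene_tree(cfg, seed=rng)
            traits = simulate_trait(tree, cfg, seed=rng)
            for r in compute_pic(tree, traits):
                if r.event is Event.SPECIATION:
                    spe.append(r.contrast ** 2)
                elif r.event is Event.DUPLICATION:
                    dup.append(r.contrast ** 2)
        ratio = np.mean(dup) / np.mean(spe)
        assert 3.0 < ratio < 5.0

    def test_unknown_model_rejected(self):
        tree = random_event_tree(6, seed=0)
        with pytest.raises(ValueError):
            simulate_trait(tree, SimulationConfig(trait_model="JUMP"), seed=0)


class TestPermutations:
    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_tip_permutation_preserves_multiset(self, seed):
        tree = random_event_tree(12, seed=seed % 7)
        rng = np.random.default_rng(seed)
        traits = TraitTable({lab: float(rng.normal())
                             for lab in tree.tip_labels()})
        permuted = permute_tip_traits(tree, traits, seed=seed)
        assert sorted(permuted.values.values()) == \
            sorted(traits.values.values())

    def test_tip_permutation_two_tips_half_swap(self):
        from paracontrast.gene_trees import read_trees
        tree = read_trees("(A:1,B:1)[&&NHX:Ev=spec];")[0]
        traits = TraitTable({"A": 0.0, "B": 1.0})
        swapped = sum(
            permute_tip_traits(tree, traits, seed=s)["A"] == 1.0
            for s in range(400))
        assert 150 < swapped < 250

    def test_tip_permutation_deterministic(self):
        tree = random_event_tree(10, seed=1)
        traits = TraitTable({lab: float(i)
                             for i, lab in enumerate(tree.tip_labels())})
        a = permute_tip_traits(tree, traits, seed=99)
        b = permute_tip_traits(tree, traits, seed=99)
        assert a.values == b.values

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_event_permutation_preserves_counts(self, seed):
        tree = generate_gene_tree(SimulationConfig(), seed=seed % 11)
        permuted = permute_node_events(tree, seed=seed)
        before = collections.Counter(n.event for n in tree.internal_nodes)
        after = collections.Counter(n.event for n in permuted.internal_nodes)
        assert before == after

    def test_event_permutation_single_category_identity(self):
        cfg = SimulationConfig(dup_rate=0.0, ancient_rate=0.0)
        tree = generate_gene_tree(cfg, seed=0)
        permuted = permute_node_events(tree, seed=1)
        assert [n.event for n in permuted.internal_nodes] == \
            [n.event for n in tree.internal_nodes]
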