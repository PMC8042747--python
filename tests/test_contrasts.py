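"""Independent contrasts, Blomberg's K, diagnostics and transformation."""

import subprocess
import textwrap

import numpy as np
import pytest

from paracontrast.contrasts import (
    TRANSFORM_EXPONENTS, blomberg_k, compute_pic, diagnostics,
    phylogenetic_covariance, transform_branch_lengths,
)
from paracontrast.gene_trees import Event, TraitTable, read_trees
from paracontrast.synthetic_data import (SimulationConfig,
                                         random_event_tree, simulate_trait)
from conftest import random_tree_and_bm_trait
from oracles import blomberg_k_matrix_oracle, gls_contrasts


class TestComputePic:
    def test_cherry_worked_example(self, cherry):
        rec, = compute_pic(cherry, TraitTable({"A": 1.0, "B": 0.0}))
        assert rec.contrast == pytest.approx(1.0 / 3.0)
        assert rec.expected_sd == pytest.approx(3.0)
        assert rec.ancestral_value == pytest.approx(5.0 / 9.0)

    def test_three_tip_worked_example(self, three_tip):
        recs = compute_pic(three_tip,
                           TraitTable({"A": 2.0, "B": 4.0, "C": 1.0}))
        by_depth = sorted(recs, key=lambda r: r.node_depth)
        assert by_depth[1].contrast == pytest.approx(-np.sqrt(2.0))
        # cherry branch adjusted to 1 + 0.5; contrast (3-1)/sqrt(1.5+2)
        assert by_depth[0].contrast == pytest.approx(2.0 / np.sqrt(3.5))

    def test_identical_traits_give_zero_contrasts(self, mixed_tree):
        recs = compute_pic(mixed_tree, TraitTable({k: 0.7 for k in "ABCD"}))
        assert all(r.contrast == 0.0 for r in recs)

    def test_missing_trait_lists_tips(self, mixed_tree):
        with pytest.raises(KeyError, match="D"):
            compute_pic(mixed_tree, TraitTable({k: 0.5 for k in "ABC"}))

    def test_record_count_and_events(self, mixed_tree):
        recs = compute_pic(mixed_tree, TraitTable(
            {k: v for k, v in zip("ABCD", [0.1, 0.4, 0.2, 0.9])}))
        assert len(recs) == mixed_tree.n_tips - 1
        assert sorted(r.event.value for r in recs) == \
            ["duplication", "speciation", "speciation"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_gls_orthogonalization_oracle(self, seed):
        tree, traits = random_tree_and_bm_trait(
            int(np.random.default_rng(seed).integers(4, 11)), seed)
        recs = compute_pic(tree, traits)
        oracle = gls_contrasts(tree, traits)
        for r in recs:
            u, sd = oracle[r.node_id]
            assert r.contrast == pytest.approx(u, abs=1e-9)
            assert r.expected_sd == pytest.approx(sd, abs=1e-9)

    def test_matches_ape_pic_on_fixture(self, tmp_path):
        """Cross-check against the reference implementation in R (ape)."""
        tree, traits = random_tree_and_bm_trait(6, seed=123)
        plain = tree.copy()
        for node in plain.internal_nodes:
            node.event = None
        script = tmp_path / "pic.R"
        vals = ", ".join(f"{traits[l]!r}" for l in tree.tip_labels())
        labs = ", ".join(f'"{l}"' for l in tree.tip_labels())
        script.write_text(textwrap.dedent(f"""
            library(ape)
            tr <- read.tree(text='{plain.to_newick()}')
            x <- c({vals}); names(x) <- c({labs})
            cat(sprintf("%.12f\\n", pic(x, tr)))
        """))
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, check=True)
        ape_abs = sorted(abs(float(v)) for v in out.stdout.split())
        ours = sorted(r.abs_contrast
                      for r in compute_pic(tree, traits))
        assert np.allclose(ours, ape_abs, atol=1e-9)


class TestBlombergK:
    def test_invariant_trait_undefined(self, mixed_tree):
        res = blomberg_k(mixed_tree, TraitTable({k: 0.5 for k in "ABCD"}),
                         n_perm=10, seed=0)
        assert not res.defined
        assert not res.strong_signal

    def test_cutoff_flag(self):
        tree, traits = random_tree_and_bm_trait(16, seed=3)
        res = blomberg_k(tree, traits, n_perm=50, seed=0)
        assert res.strong_signal == (res.k > 0.551)

    def test_matches_matrix_oracle_and_clade_sorting(self):
        # balanced 4-tip tree; clade-sorted traits show more signal than
        # anti-sorted ones, and both match the explicit matrix formula
        tree = read_trees("((A:1,B:1)[&&NHX:Ev=spec]:1,"
                          "(C:1,D:1)[&&NHX:Ev=spec]:1)[&&NHX:Ev=spec];")[0]
        C, labels = phylogenetic_covariance(tree)
        sorted_traits = TraitTable({"A": 0.0, "B": 0.1, "C": 1.0, "D": 1.1})
        anti = TraitTable({"A": 0.0, "B": 1.0, "C": 0.1, "D": 1.1})
        k_sorted = blomberg_k(tree, sorted_traits, n_perm=0).k
        k_anti = blomberg_k(tree, anti, n_perm=0).k
        assert k_sorted > k_anti
        for tt, k in ((sorted_traits, k_sorted), (anti, k_anti)):
            x = np.array([tt[lab] for lab in labels])
            assert k == pytest.approx(blomberg_k_matrix_oracle(C, x),
                                      abs=1e-12)

    def test_permutation_p_small_for_clade_sorted_trait(self):
        tree = random_event_tree(24, height=100.0, seed=6)
        traits = simulate_trait(
            tree, SimulationConfig(trait_model="BM1", sigma2=0.01), seed=7)
        res = blomberg_k(tree, traits, n_perm=199, seed=1)
        assert 0 < res.p_value <= 1


class TestDiagnostics:
    def _records(self, tree, traits):
        return compute_pic(tree, traits)

    def test_constructed_sd_correlation_fails(self):
        # |contrast| exactly proportional to SD -> r = 1, p ~ 0 -> fail
        from paracontrast.contrasts import ContrastRecord
        rng = np.random.default_rng(0)
        recs = []
        for i in range(20):
            sd = float(rng.uniform(1, 10))
            recs.append(ContrastRecord(
                tree_id="t", node_id=i, event=Event.SPECIATION,
                age_class=None, contrast=2.0 * sd, expected_sd=sd,
                ancestral_value=0.0, node_age=rng.uniform(1, 50),
                node_height=rng.uniform(0, 50), node_depth=i % 5))
        res = diagnostics(recs)
        assert res.test("expected_sd").p < 0.05
        assert not res.passed

    def test_constant_abs_contrast_degenerate_pass(self):
        from paracontrast.contrasts import ContrastRecord
        recs = [ContrastRecord(tree_id="t", node_id=i,
                               event=Event.SPECIATION, age_class=None,
                               contrast=1.0, expected_sd=float(i + 1),
                               ancestral_value=0.0, node_age=float(i + 1),
                               node_height=float(i), node_depth=i)
                for i in range(6)]
        res = diagnostics(recs)
        assert res.passed
        assert all(t.degenerate for t in res.tests)

    def test_alpha_boundary_p_equal_alpha_passes(self):
        from paracontrast.contrasts import DiagnosticTest
        t = DiagnosticTest("expected_sd", r=0.5, p=0.05, n=10)
        t._alpha = 0.05
        assert t.passed

    def test_too_few_records_not_evaluable(self):
        res = diagnostics([])
        assert not res.evaluable
        assert not res.passed

    def test_bm_pass_rate_near_nominal(self):
        # under BM on the true tree the four tests are each ~alpha-level
        passed = 0
        n = 150
        for s in range(n):
            tree, traits = random_tree_and_bm_trait(16, seed=1000 + s)
            passed += diagnostics(compute_pic(tree, traits)).passed
        rate = passed / n
        expected = 0.95 ** 4  # if the four tests were independent
        assert abs(rate - expected) < 0.12


class TestTransform:
    def test_exponent_one_is_identity(self, mixed_tree):
        traits = TraitTable(dict(zip("ABCD", [0.1, 0.8, 0.4, 0.6])))
        before = compute_pic(mixed_tree, traits)
        from paracontrast.contrasts import _transformed_copy
        after = compute_pic(_transformed_copy(mixed_tree, 1.0), traits)
        for a, b in zip(after, before):
            assert a.contrast == b.contrast  # bit-identical
            assert a.expected_sd == b.expected_sd

    def test_exponent_zero_unit_branches(self, mixed_tree):
        from paracontrast.contrasts import _transformed_copy
        t0 = _transformed_copy(mixed_tree, 0.0)
        assert all(n.length == 1.0 for n in t0.nodes if n is not t0.root)

    def test_candidate_grid(self):
        assert len(TRANSFORM_EXPONENTS) == 21
        assert TRANSFORM_EXPONENTS[0] == 0.0
        assert TRANSFORM_EXPONENTS[-1] == 2.0

    def test_nonpositive_branch_rejected(self):
        tree = read_trees("((A:0.0,B:1)[&&NHX:Ev=dup]:1,C:2)"
                          "[&&NHX:Ev=spec];")[0]
        with pytest.raises(ValueError):
            transform_branch_lengths(tree, TraitTable(
                {"A": 0.1, "B": 0.5, "C": 0.9}))

    def test_speciational_change_prefers_flat_exponent(self):
        # trait change with equal variance per node (punctuated clock):
        # contrasts standardize under b^0, not under b^1
        rng = np.random.default_rng(42)
        chosen = []
        for s in range(10):
            tree = random_event_tree(32, height=100.0, seed=rng)
            # one unit-variance step per branch regardless of its length
            vals = {}
            order = list(tree.preorder())
            vals[tree.root.id] = 0.0
            for node in order:
                if node is not tree.root:
                    vals[node.id] = vals[node.parent.id] + rng.normal(0, 1.0)
            traits = TraitTable({t.label: vals[t.id] for t in tree.tips})
            res = transform_branch_lengths(tree, traits)
            if not res.excluded:
                chosen.append(res.exponent)
        assert chosen, "every tree excluded"
        numeric = [e for e in chosen if e != "log10"]
        assert np.median(numeric) < 1.0

    def test_bm_data_keeps_diagnostics_after_transform(self):
        ok = 0
        for s in range(20):
            tree, traits = random_tree_and_bm_trait(16, seed=500 + s)
            res = transform_branch_lengths(tree, traits)
            if not res.excluded and res.diagnostics.passed:
                ok += 1
        assert ok >= 15
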