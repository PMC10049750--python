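"""Mk likelihoods and marginal reconstructions against enumeration oracles.

The brute-force oracle sums the joint probability over every assignment
of states to internal nodes (tips enter through their conditional
likelihood indicators), using plain recursion over the dendropy tree —
fully independent of the pruning implementation's flat-array machinery.
"""

import itertools
import math

import dendropy
import numpy as np
import pytest

from polymatrix import mkasr
from polymatrix.mkasr import (
    TraitTable,
    TreeIndex,
    aicc,
    fit_mk,
    log_likelihood,
    marginal_asr,
    model_select,
    significance_call,
    transition_matrix,
)
from polymatrix.simulate import RateModel, simulate_binary_trait, simulate_species_tree, apply_missingness


# ---------------------------------------------------------------------------
# Oracles


def brute_force_likelihood(tree, traits, model, prior=(0.5, 0.5), fixed=None):
    """Total likelihood by enumeration over internal-state assignments.

    ``fixed`` optionally pins {node_label: state} during the enumeration
    (used for the fix-and-recompute marginal oracle).
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    labels = {}
    for k, node in enumerate(tree.preorder_node_iter()):
        if not node.is_leaf():
            labels[id(node)] = node.label if node.label else f"N{k}"
    P = {
        id(n): transition_matrix(model, n.edge.length or 0.0)
        for n in tree.preorder_node_iter()
    }
    total = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, assignment)}
        if fixed and any(states[k] != v for k, v in (
            (next(id(n) for n in internals if labels[id(n)] == lab), st)
            for lab, st in fixed.items()
        )):
            continue
        prob = prior[states[id(tree.seed_node)]]
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            ps = states[id(node.parent_node)]
            if node.is_leaf():
                a0, a1 = traits.partial(node.taxon.label)
                prob *= P[id(node)][ps, 0] * a0 + P[id(node)][ps, 1] * a1
            else:
                prob *= P[id(node)][ps, states[id(node)]]
        total += prob
    return total


def random_instance(seed, max_tips=6):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_tips + 1))
    tree = simulate_species_tree(n, seed=seed)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.0, 2.0))
    if rng.random() < 0.5:
        model = RateModel.er(float(rng.uniform(0.05, 2.0)))
    else:
        model = RateModel.ard(float(rng.uniform(0.05, 2.0)), float(rng.uniform(0.05, 2.0)))
    tokens = ["0", "1", "unknown"]
    traits = TraitTable({
        leaf.taxon.label: tokens[int(rng.choice(3, p=[0.4, 0.4, 0.2]))]
        for leaf in tree.leaf_node_iter()
    })
    return tree, traits, model


# ---------------------------------------------------------------------------
# Transition probabilities


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        assert np.allclose(transition_matrix(RateModel.ard(0.7, 0.2), 0.0), np.eye(2))

    def test_er_closed_form(self):
        P = transition_matrix(RateModel.er(1.0), 1.0)
        assert P[0, 0] == pytest.approx(0.5 * (1 + math.exp(-2.0)))
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_long_time_stationary(self):
        q01, q10 = 0.7, 0.3
        P = transition_matrix(RateModel.ard(q01, q10), 1e3)
        pi = np.array([q10, q01]) / (q01 + q10)
        assert np.allclose(P, np.vstack([pi, pi]), atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(RateModel.er(1.0), -0.1)


# ---------------------------------------------------------------------------
# Likelihood


class TestLogLikelihood:
    def test_two_tips_zero_branches(self):
        ns = dendropy.TaxonNamespace(["a", "b"])
        tree = dendropy.Tree(taxon_namespace=ns)
        for t in ns:
            node = dendropy.Node(taxon=t)
            node.edge.length = 0.0
            tree.seed_node.add_child(node)
        traits = TraitTable({"a": "0", "b": "0"})
        lnl = log_likelihood(tree, traits, RateModel.er(1.0))
        assert lnl == pytest.approx(math.log(0.5))

    def test_matches_enumeration_oracle(self):
        """Pruning equals brute-force enumeration, 50 seeded instances."""
        for seed in range(50):
            tree, traits, model = random_instance(seed)
            expected = brute_force_likelihood(tree, traits, model)
            got = log_likelihood(tree, traits, model)
            assert got == pytest.approx(math.log(expected), rel=1e-10)

    def test_unknown_tip_is_likelihood_neutral(self):
        tree, traits, model = random_instance(3)
        tip = sorted(traits.observations)[0]
        obs = dict(traits.observations)
        obs[tip] = "unknown"
        lnl_with = log_likelihood(tree, traits.__class__(obs), model)
        pruned = tree.clone(depth=1)
        pruned.prune_taxa_with_labels([tip])
        pruned.suppress_unifurcations()
        obs.pop(tip)
        lnl_without = log_likelihood(pruned, traits.__class__(obs), model)
        assert lnl_with == pytest.approx(lnl_without, abs=1e-12)

    def test_impossible_data_is_minus_infinity(self):
        ns = dendropy.TaxonNamespace(["a", "b"])
        tree = dendropy.Tree(taxon_namespace=ns)
        for t in ns:
            node = dendropy.Node(taxon=t)
            node.edge.length = 1.0
            tree.seed_node.add_child(node)
        traits = TraitTable({"a": "0", "b": "1"})
        assert log_likelihood(tree, traits, RateModel.er(0.0)) == -math.inf

    def test_multifurcation_handled(self):
        ns = dendropy.TaxonNamespace(["a", "b", "c"])
        tree = dendropy.Tree(taxon_namespace=ns)
        for t in ns:
            node = dendropy.Node(taxon=t)
            node.edge.length = 0.5
            tree.seed_node.add_child(node)
        traits = TraitTable({"a": "0", "b": "1", "c": "0"})
        model = RateModel.er(0.8)
        expected = brute_force_likelihood(tree, traits, model)
        assert log_likelihood(tree, traits, model) == pytest.approx(math.log(expected))


# ---------------------------------------------------------------------------
# AICc and model selection


class TestAicc:
    def test_arithmetic(self):
        assert aicc(-10.0, 1, 36) == pytest.approx(22 + 4 / 34)

    def test_zero_parameters(self):
        assert aicc(-10.0, 0, 10) == 20.0

    def test_penalty_monotone_in_k(self):
        for n in (4, 10, 100):
            assert aicc(-5.0, 1, n) < aicc(-5.0, 2, n)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 2, 3)


class TestModelSelect:
    def test_lowest_aicc_wins(self):
        er = mkasr.MkFit(RateModel.er(0.1), -11.3, 1, 36, 24.77317)
        ard = mkasr.MkFit(RateModel.ard(0.1, 0.2), -10.7, 2, 36, 25.86218)
        assert model_select([er, ard]) is er

    def test_single_fit(self):
        fit = mkasr.MkFit(RateModel.er(0.1), -1.0, 1, 10, 4.5)
        assert model_select([fit]) is fit

    def test_exact_tie_takes_first(self):
        a = mkasr.MkFit(RateModel.er(0.1), -1.0, 1, 10, 4.5)
        b = mkasr.MkFit(RateModel.ard(0.1, 0.1), -1.0, 2, 10, 4.5)
        assert model_select([a, b]) is a


# ---------------------------------------------------------------------------
# Fitting


class TestFitMk:
    def test_er_equals_sym_two_states_and_ard_nests_er(self):
        tree = simulate_species_tree(40, seed=2)
        truth = simulate_binary_trait(tree, RateModel.er(0.4), 0, seed=3)
        traits = TraitTable({t: str(s) for t, s in truth.tip_states.items()})
        er = fit_mk(tree, traits, "ER")
        ard = fit_mk(tree, traits, "ARD")
        assert ard.lnL >= er.lnL - 1e-6
        assert er.K == 1 and ard.K == 2

    def test_degenerate_data_flagged_rate_at_bound(self):
        tree = simulate_species_tree(10, seed=4)
        traits = TraitTable({t.label: "0" for t in tree.taxon_namespace})
        fit = fit_mk(tree, traits, "ER")
        assert fit.diagnostics["degenerate"]
        assert fit.model.q01 == pytest.approx(1e-9, rel=1e-3)
        assert fit.lnL == pytest.approx(math.log(0.5))

    def test_rate_recovery_order_of_magnitude(self):
        tree = simulate_species_tree(300, seed=6, mean_branch_length=0.5)
        truth = simulate_binary_trait(tree, RateModel.er(0.3), 0, seed=7)
        traits = TraitTable({t: str(s) for t, s in truth.tip_states.items()})
        fit = fit_mk(tree, traits, "ER")
        assert 0.1 < fit.model.q01 < 0.9


# ---------------------------------------------------------------------------
# Marginal ASR


class TestMarginalASR:
    def test_vectors_sum_to_one_and_match_fix_and_recompute(self):
        for seed in range(25):
            tree, traits, model = random_instance(seed + 100)
            fit = mkasr.MkFit(model, 0.0, 1, 6, 0.0)
            recon = marginal_asr(tree, traits, fit)
            for label, vec in recon.nodes.items():
                assert vec[0] + vec[1] == pytest.approx(1.0, abs=1e-12)
                l0 = brute_force_likelihood(tree, traits, model, fixed={label: 0})
                l1 = brute_force_likelihood(tree, traits, model, fixed={label: 1})
                assert vec[0] == pytest.approx(l0 / (l0 + l1), rel=1e-10)

    def test_symmetric_star_gives_half_half_root(self):
        ns = dendropy.TaxonNamespace([f"t{i}" for i in range(6)])
        tree = dendropy.Tree(taxon_namespace=ns)
        for t in ns:
            node = dendropy.Node(taxon=t)
            node.edge.length = 1.0
            tree.seed_node.add_child(node)
        traits = TraitTable({f"t{i}": str(i % 2) for i in range(6)})
        fit = mkasr.MkFit(RateModel.er(0.5), 0.0, 1, 6, 0.0)
        recon = marginal_asr(tree, traits, fit)
        root_vec = next(iter(recon.nodes.values()))
        assert root_vec[0] == pytest.approx(0.5, abs=1e-12)

    def test_uniform_tips_bias_all_nodes(self):
        tree = simulate_species_tree(12, seed=8)
        traits = TraitTable({t.label: "1" for t in tree.taxon_namespace})
        fit = mkasr.MkFit(RateModel.er(0.3), 0.0, 1, 12, 0.0)
        recon = marginal_asr(tree, traits, fit)
        assert all(v[1] > 0.5 for v in recon.nodes.values())


# ---------------------------------------------------------------------------
# Significance and trait coding


class TestSignificance:
    @pytest.mark.parametrize(
        "vec,expected_sig,expected_dir",
        [
            ((0.093, 0.908), True, 1),
            ((0.865, 0.135), False, None),
            ((0.874, 0.126), False, None),
            ((0.659, 0.341), False, None),
            ((0.547, 0.453), False, None),
            ((0.488, 0.512), False, None),
            ((0.5, 0.5), False, None),
        ],
    )
    def test_proportional_likelihood_rule(self, vec, expected_sig, expected_dir):
        sig, direction = significance_call(vec)
        assert sig is expected_sig
        assert direction == expected_dir

    def test_zero_entry_clamped(self):
        sig, direction = significance_call((0.0, 1.0))
        assert sig and direction == 1


class TestCodeTraits:
    RECORDS = [
        ("Gen1 spA", "Gen1", "indirect"),
        ("Gen1 spB", "Gen1", "indirect"),
        ("Gen2 spA", "Gen2", "indirect"),
        ("Gen2 spB", "Gen2", "direct"),
        ("Gen3 spA", "Gen3", "unknown"),
        ("Gen3 spB", "Gen3", "direct"),
        ("Gen4 spA", "Gen4", "unknown"),
    ]

    def test_genus_level_coding(self):
        table = mkasr.code_traits(self.RECORDS, level="genus")
        assert table.observations["Gen1 spA"] == "indirect"
        assert table.observations["Gen2 spA"] == "both"
        assert table.observations["Gen3 spA"] == "direct"  # via congener
        assert table.observations["Gen4 spA"] == "unknown"

    def test_species_level_coding(self):
        table = mkasr.code_traits(self.RECORDS, level="species")
        assert table.observations["Gen3 spA"] == "unknown"

    def test_override_applied_last(self):
        table = mkasr.code_traits(
            self.RECORDS, level="genus", overrides={"Gen4 spA": "indirect"}
        )
        assert table.observations["Gen4 spA"] == "indirect"

    def test_unknown_override_tip_rejected(self):
        with pytest.raises(ValueError):
            mkasr.code_traits(self.RECORDS, overrides={"nope": "direct"})
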