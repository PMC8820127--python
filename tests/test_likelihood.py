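"""Pruning likelihood against an enumeration oracle, plus fit behavior.

The oracle sums the joint probability over every assignment of ancestral
codon states at the internal nodes — an independent computation that the
pruning recursion must reproduce exactly on small trees.
"""

import numpy as np
import pytest

from opsinsel.codon_model import (
    CodonSubstitutionModel,
    build_codon_rate_matrix,
    decompose_rate_matrix,
)
from opsinsel.errors import ValidationError
from opsinsel.genetic_code import STANDARD_CODE
from opsinsel.io_formats import parse_newick, validate_codon_alignment
from opsinsel.likelihood import (
    PruningEngine,
    conditional_site_likelihoods,
    fit_model_series,
    fit_site_model,
    mixture_log_likelihood,
    site_class_logliks,
)
from opsinsel.site_models import get_model
from opsinsel.synthetic_data import simulate_codon_alignment, simulate_tree

CODONS = STANDARD_CODE.sense_codons


def brute_force_site_likelihoods(tree, aln, kappa, omega, pi):
    """Sum the joint probability over every assignment of ancestral codon
    states at the internal nodes (vectorized over the assignment grid)."""
    model = CodonSubstitutionModel(kappa=kappa, omega=omega, pi=pi)
    q = build_codon_rate_matrix(model)
    dec = decompose_rate_matrix(q, pi)
    nodes = list(tree.root.postorder())
    parent_of = {}
    for node in nodes:
        for child in node.children:
            parent_of[id(child)] = node
    p_of = {id(n): dec.transition_matrix(n.length) for n in nodes if n is not tree.root}
    internals = [n for n in nodes if not n.is_leaf]
    taxon_idx = {name: i for i, name in enumerate(aln.taxon_names)}
    states = aln.state_sets()

    grids = np.meshgrid(*([np.arange(61)] * len(internals)), indexing="ij")
    state_of = {id(n): g.ravel() for n, g in zip(internals, grids)}

    out = np.zeros(aln.n_sites)
    for site in range(aln.n_sites):
        prob = pi[state_of[id(tree.root)]].copy()
        for node in nodes:
            if node is tree.root:
                continue
            parent_states = state_of[id(parent_of[id(node)])]
            p = p_of[id(node)]
            if node.is_leaf:
                allowed = list(states[taxon_idx[node.label]][site])
                prob *= p[:, allowed].sum(axis=1)[parent_states]
            else:
                prob *= p[parent_states, state_of[id(node)]]
        out[site] = prob.sum()
    return out


def _random_alignment(rng, labels, n_sites, ambig_prob=0.1):
    records = []
    for name in labels:
        codons = []
        for _ in range(n_sites):
            if rng.random() < ambig_prob:
                codons.append(rng.choice(["NNN", "AAN", "---"]))
            else:
                codons.append(CODONS[rng.integers(61)])
        records.append((name, "".join(codons)))
    return validate_codon_alignment(records)


class TestPruningOracle:
    TOPOLOGIES = [
        "(A:{a},B:{b},C:{c});",
        "((A:{a},B:{b}):{e},C:{c},D:{d});",
        "((A:{a},B:{b}):{e},(C:{c},D:{d}):{f});",
    ]

    def test_pruning_equals_enumeration_on_small_trees(self):
        """50 random parameter draws on trees with <= 4 tips, <= 3 sites."""
        rng = np.random.default_rng(7)
        for draw in range(50):
            newick = self.TOPOLOGIES[draw % len(self.TOPOLOGIES)]
            lengths = {k: rng.uniform(0.02, 0.5) for k in "abcdef"}
            tree = parse_newick(newick.format(**lengths))
            labels = sorted(tree.tip_labels)
            kappa = rng.uniform(0.5, 5.0)
            omega = rng.uniform(0.05, 3.0)
            pi = rng.dirichlet(np.full(61, 5.0))
            n_sites = int(rng.integers(1, 4))
            aln = _random_alignment(rng, labels, n_sites)
            expected = brute_force_site_likelihoods(tree, aln, kappa, omega, pi)
            got = conditional_site_likelihoods(aln, tree, kappa, pi, [omega])[:, 0]
            assert np.allclose(got, expected, atol=1e-10), f"draw {draw}"

    def test_zero_branch_lengths_give_pi_for_identical_codons(self):
        aln = validate_codon_alignment({"A": "AAA", "B": "AAA"})
        tree = parse_newick("(A:0,B:0);")
        pi = np.random.default_rng(0).dirichlet(np.ones(61))
        lik = conditional_site_likelihoods(aln, tree, 2.0, pi, [0.5])
        assert lik[0, 0] == pytest.approx(pi[STANDARD_CODE.index("AAA")], abs=1e-12)

    def test_two_taxon_closed_form(self):
        """2-taxon, 1-site mixture equals the hand formula pi_i * P_ij(ta+tb)."""
        aln = validate_codon_alignment({"A": "ATG", "B": "ACG"})
        tree = parse_newick("(A:0.1,B:0.25);")
        pi = np.full(61, 1 / 61)
        weights = np.array([0.7, 0.3])
        omegas = np.array([0.2, 1.5])
        lik = conditional_site_likelihoods(aln, tree, 2.0, pi, omegas, weights=weights)
        from opsinsel.codon_model import get_structure
        from opsinsel.likelihood import mixture_rate_normalizer
        from opsinsel.site_models import ClassDistribution

        dist = ClassDistribution(weights, omegas)
        mu_bar = mixture_rate_normalizer(2.0, pi, dist, STANDARD_CODE)
        i, j = STANDARD_CODE.index("ATG"), STANDARD_CODE.index("ACG")
        expected = 0.0
        struct = get_structure()
        for w_c, omega in zip(weights, omegas):
            qu = struct.unscaled_rates(2.0, omega, pi) / mu_bar
            np.fill_diagonal(qu, 0.0)
            np.fill_diagonal(qu, -qu.sum(axis=1))
            p = decompose_rate_matrix(qu, pi).transition_matrix(0.35)
            expected += w_c * pi[i] * p[i, j]
        mixture = float(weights @ lik[0])
        assert mixture == pytest.approx(expected, rel=1e-10)

    def test_all_ambiguous_leaf_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(11)
        aln4 = _random_alignment(rng, ["A", "B", "C", "D"], 3, ambig_prob=0)
        tree4 = parse_newick("((A:0.1,B:0.2):0.1,C:0.3,D:0.15);")
        tree5 = parse_newick("((A:0.1,B:0.2):0.1,(C:0.25,E:0.4):0.05,D:0.15);")
        # same unrooted tree with C's edge subdivided by an all-N tip E
        aln5 = validate_codon_alignment(
            aln4.records() + [("E", "N" * (3 * aln4.n_sites))]
        )
        pi = np.full(61, 1 / 61)
        lik4 = conditional_site_likelihoods(aln4, tree4, 2.0, pi, [0.3])
        lik5 = conditional_site_likelihoods(aln5, tree5, 2.0, pi, [0.3])
        assert np.allclose(lik4, lik5, rtol=1e-10)


class TestMixtureLikelihood:
    def test_invariant_to_tip_order_and_rerooting(self, m0_dataset, uniform_pi):
        aln, tree, _ = m0_dataset
        spec = get_model("M0")
        theta = {"omega": 0.2, "kappa": 2.0}
        base = mixture_log_likelihood(aln, tree, spec, theta, pi=uniform_pi)
        # reversed record order
        aln_rev = validate_codon_alignment(list(reversed(aln.records())))
        assert mixture_log_likelihood(aln_rev, tree, spec, theta, pi=uniform_pi) == (
            pytest.approx(base, abs=1e-9)
        )

    def test_rerooting_along_an_edge_preserves_likelihood(self, uniform_pi):
        aln = validate_codon_alignment(
            {"A": "ATGAAA", "B": "ATGAAG", "C": "ATGGAA", "D": "TTGAAA"}
        )
        rep1 = parse_newick("(A:0.1,B:0.2,(C:0.3,D:0.25):0.15);")
        rep2 = parse_newick("(C:0.3,D:0.25,(A:0.1,B:0.2):0.15);")
        spec = get_model("M1a")
        theta = {"p0": 0.8, "omega0": 0.1, "kappa": 2.0}
        l1 = mixture_log_likelihood(aln, rep1, spec, theta, pi=uniform_pi)
        l2 = mixture_log_likelihood(aln, rep2, spec, theta, pi=uniform_pi)
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_per_site_logs_sum_to_total(self, m8_dataset, uniform_pi):
        aln, tree, _ = m8_dataset
        spec = get_model("M8")
        theta = {"p0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 3.0, "kappa": 2.0}
        total = mixture_log_likelihood(aln, tree, spec, theta, pi=uniform_pi)
        logl, dist = site_class_logliks(aln, tree, spec, theta, pi=uniform_pi)
        per_site = np.log(np.exp(logl) @ dist.proportions)
        assert per_site.sum() == pytest.approx(total, abs=1e-8)

    def test_pattern_compression_invariance(self, uniform_pi):
        rng = np.random.default_rng(5)
        base = _random_alignment(rng, ["A", "B", "C"], 4, ambig_prob=0)
        # duplicate the columns: lnL must double exactly
        doubled = validate_codon_alignment(
            [(n, s + s) for n, s in base.records()]
        )
        tree = parse_newick("(A:0.2,B:0.1,C:0.3);")
        spec = get_model("M0")
        theta = {"omega": 0.4, "kappa": 1.5}
        l1 = mixture_log_likelihood(base, tree, spec, theta, pi=uniform_pi)
        l2 = mixture_log_likelihood(doubled, tree, spec, theta, pi=uniform_pi)
        assert l2 == pytest.approx(2 * l1, abs=1e-9)

    def test_tree_taxon_mismatch_raises(self, uniform_pi):
        aln = validate_codon_alignment({"A": "ATG", "B": "ACG"})
        tree = parse_newick("(A:0.1,X:0.2);")
        with pytest.raises(ValidationError):
            mixture_log_likelihood(
                aln, tree, get_model("M0"), {"omega": 1.0, "kappa": 2.0}, pi=uniform_pi
            )


class TestNestingIdentities:
    def test_m8_at_zero_positive_weight_equals_m7(self, m8_dataset, uniform_pi):
        aln, tree, _ = m8_dataset
        theta7 = {"p": 0.4, "q": 1.2, "kappa": 2.1}
        l7 = mixture_log_likelihood(aln, tree, get_model("M7"), theta7, pi=uniform_pi)
        theta8 = {"p0": 1.0, "p": 0.4, "q": 1.2, "omega_s": 2.0, "kappa": 2.1}
        l8 = mixture_log_likelihood(aln, tree, get_model("M8"), theta8, pi=uniform_pi)
        assert l8 == pytest.approx(l7, abs=1e-9)

    def test_m2a_at_zero_third_class_equals_m1a(self, m8_dataset, uniform_pi):
        aln, tree, _ = m8_dataset
        theta1 = {"p0": 0.8, "omega0": 0.15, "kappa": 2.0}
        l1 = mixture_log_likelihood(aln, tree, get_model("M1a"), theta1, pi=uniform_pi)
        theta2 = {"p0": 0.8, "p1": 0.2, "omega0": 0.15, "omega2": 3.0, "kappa": 2.0}
        l2 = mixture_log_likelihood(aln, tree, get_model("M2a"), theta2, pi=uniform_pi)
        assert l2 == pytest.approx(l1, abs=1e-9)

    def test_m8a_equals_m8_with_omega_s_pinned(self, m8_dataset, uniform_pi):
        aln, tree, _ = m8_dataset
        theta_a = {"p0": 0.85, "p": 0.5, "q": 1.5, "kappa": 2.0}
        la = mixture_log_likelihood(aln, tree, get_model("M8a"), theta_a, pi=uniform_pi)
        theta_8 = dict(theta_a, omega_s=1.0)
        l8 = mixture_log_likelihood(aln, tree, get_model("M8"), theta_8, pi=uniform_pi)
        assert l8 == pytest.approx(la, abs=1e-9)


class TestFitting:
    def test_m0_recovery_on_simulated_data(self, uniform_pi):
        tree = simulate_tree(16, seed=31)
        aln, _ = simulate_codon_alignment(
            tree, get_model("M0"), {"omega": 0.2}, 300, kappa=2.0, pi=uniform_pi, seed=32
        )
        fit = fit_site_model(aln, tree, get_model("M0"), pi=uniform_pi)
        assert 0.15 <= fit.theta_hat["omega"] <= 0.25
        assert fit.converged

    def test_reported_lnl_matches_reevaluation(self, m0_dataset, uniform_pi):
        aln, tree, _ = m0_dataset
        fit = fit_site_model(aln, tree, get_model("M0"), pi=uniform_pi)
        again = mixture_log_likelihood(
            aln, tree, get_model("M0"), fit.theta_hat, pi=uniform_pi
        )
        assert fit.lnL == pytest.approx(again, abs=1e-8)

    def test_np_counts_follow_codeml_convention(self, m0_dataset, uniform_pi):
        aln, tree, _ = m0_dataset
        fit = fit_site_model(aln, tree, get_model("M0"), pi=uniform_pi)
        assert fit.np == (2 * aln.n_taxa - 3) + 1 + 1

    def test_alternatives_never_fit_worse_than_their_nulls(self, m8_dataset, uniform_pi):
        aln, tree, _ = m8_dataset
        fits = fit_model_series(
            aln, tree, [get_model(m) for m in ("M7", "M8a", "M8")], pi=uniform_pi
        )
        assert fits["M8"].lnL >= fits["M7"].lnL - 1e-4
        assert fits["M8"].lnL >= fits["M8a"].lnL - 1e-4
        assert fits["M8a"].lnL >= fits["M7"].lnL - 1e-4

    def test_branch_modes_are_increasingly_flexible(self, uniform_pi):
        tree = simulate_tree(5, seed=91)
        aln, _ = simulate_codon_alignment(
            tree, get_model("M0"), {"omega": 0.3}, 100, kappa=2.0, pi=uniform_pi,
            seed=92,
        )
        starts = [{"omega": 0.3}]
        lnl = {
            mode: fit_site_model(
                aln, tree, get_model("M0"), starts=starts, pi=uniform_pi,
                branch_mode=mode,
            ).lnL
            for mode in ("fixed", "scale", "full")
        }
        assert lnl["scale"] >= lnl["fixed"] - 1e-6
        assert lnl["full"] >= lnl["scale"] - 1e-6

    def test_fit_is_deterministic_given_starts(self, m0_dataset, uniform_pi):
        aln, tree, _ = m0_dataset
        starts = [{"omega": 0.3}]
        fit1 = fit_site_model(aln, tree, get_model("M0"), starts=starts, pi=uniform_pi)
        fit2 = fit_site_model(aln, tree, get_model("M0"), starts=starts, pi=uniform_pi)
        assert fit1.lnL == fit2.lnL
        assert fit1.theta_hat == fit2.theta_hat
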