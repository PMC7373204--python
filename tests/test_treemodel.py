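"""Likelihood engine: rate matrices, gamma discretization, trees,
pruning likelihood against closed forms and brute-force enumeration."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from comphet.seqio import Alignment, DNA
from comphet.treemodel import (
    PhyloModel,
    Tree,
    build_q,
    discrete_gamma_rates,
    jukes_cantor_exch,
    log_likelihood,
    random_rooted_tree,
    read_paml_rates,
    transition_matrix,
)

from conftest import make_dna_alignment


def random_gtr(rng, n=4):
    exch = rng.gamma(2.0, 1.0, (n, n)) + 0.05
    exch = 0.5 * (exch + exch.T)
    np.fill_diagonal(exch, 0.0)
    return exch


class TestRateMatrix:
    def test_jc_closed_form(self):
        q = build_q(jukes_cantor_exch(4), np.full(4, 0.25))
        assert np.allclose(np.diag(q), -1.0)
        off = q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)

    def test_stationarity(self, rng):
        pi = rng.dirichlet(np.ones(4) * 3)
        q = build_q(random_gtr(rng), pi)
        assert np.allclose(pi @ q, 0.0, atol=1e-12)

    def test_unit_expected_rate(self, rng):
        pi = rng.dirichlet(np.ones(4) * 3)
        q = build_q(random_gtr(rng), pi)
        assert -float(pi @ np.diag(q)) == pytest.approx(1.0)

    def test_zero_composition_rejected(self):
        with pytest.raises(ValueError):
            build_q(jukes_cantor_exch(4), np.array([0.5, 0.5, 0.0, 0.0]))


class TestTransitionMatrix:
    def test_identity_at_zero(self, rng):
        q = build_q(random_gtr(rng), rng.dirichlet(np.ones(4)))
        assert np.allclose(transition_matrix(q, 0.0), np.eye(4))

    def test_limiting_distribution_jc(self):
        q = build_q(jukes_cantor_exch(4), np.full(4, 0.25))
        p = transition_matrix(q, 500.0)
        assert np.allclose(p, 0.25, atol=1e-9)

    def test_jc_closed_form_entry(self):
        q = build_q(jukes_cantor_exch(4), np.full(4, 0.25))
        p = transition_matrix(q, 0.1)
        expect = 0.25 + 0.75 * np.exp(-0.4 / 3.0)
        assert p[0, 0] == pytest.approx(expect, rel=1e-10)

    def test_decomposition_matches_expm(self, rng):
        pi = rng.dirichlet(np.ones(4) * 2)
        exch = random_gtr(rng)
        q = build_q(exch, pi)
        from comphet.treemodel import _symmetric_decomposition

        dec = _symmetric_decomposition(exch, pi)
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(
                transition_matrix(dec, t), expm(q * t), atol=1e-10
            )


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 5.0])
    def test_mean_one(self, alpha):
        r = discrete_gamma_rates(alpha)
        assert r.mean() == pytest.approx(1.0)
        assert np.all(np.diff(r) > 0)

    def test_large_alpha_approaches_equal_rates(self):
        r = discrete_gamma_rates(1e7)
        assert np.allclose(r, 1.0, atol=1e-3)

    def test_single_category_is_rate_one(self):
        assert discrete_gamma_rates(0.5, 1) == pytest.approx([1.0])


class TestTreeStructure:
    def test_newick_round_trip(self):
        nwk = "((a:0.1,b:0.2):0.05,(c:0.3,d:0.4):0.15);"
        t = Tree.from_newick(nwk)
        t2 = Tree.from_newick(t.to_newick())
        assert t2.nontrivial_clades() == t.nontrivial_clades()
        assert t2.tree_length() == pytest.approx(t.tree_length())

    def test_random_tree_has_right_leaves(self, rng):
        t = random_rooted_tree([f"t{i}" for i in range(12)], rng)
        assert sorted(t.leaf_names()) == sorted(f"t{i}" for i in range(12))
        assert t.n_nodes == 2 * 12 - 1

    def test_copy_is_deep(self):
        t = Tree.from_newick("((a:0.1,b:0.2):0.05,c:0.3);")
        c = t.copy()
        c.nodes[0].length = 99.0
        assert t.nodes[0].length != 99.0


class TestPamlReader:
    def test_round_trip_synthetic_matrix(self, tmp_path, rng):
        # synthetic PAML-format file: 19 lower-triangular rows + frequencies
        r = rng.gamma(1.0, 1.0, (20, 20))
        r = 0.5 * (r + r.T)
        np.fill_diagonal(r, 0.0)
        freqs = rng.dirichlet(np.ones(20))
        lines = []
        for i in range(1, 20):
            lines.append(" ".join(f"{r[i, j]:.6f}" for j in range(i)))
        lines.append("")
        lines.append(" ".join(f"{f:.6f}" for f in freqs))
        p = tmp_path / "synthetic_rates.dat"
        p.write_text("\n".join(lines) + "\n")
        r2, f2 = read_paml_rates(p)
        assert np.allclose(r2, r, atol=1e-6)
        assert np.allclose(f2, freqs, atol=1e-5)

    def test_wrong_count_rejected(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("0.1 0.2 0.3\n")
        with pytest.raises(ValueError):
            read_paml_rates(p)


def brute_force_loglik(a, model):
    """Likelihood by explicit enumeration over internal-node states."""
    tree = model.tree
    rates = model.rates.rates
    post = tree.postorder()
    internals = [n for n in post if not n.is_leaf]
    leaf_row = {n.id: a.taxa.index(n.name) for n in post if n.is_leaf}
    states = a.alphabet.states
    total = 0.0
    for site in range(a.n_sites):
        site_l = 0.0
        for r in rates:
            ps = {
                n.id: expm(
                    build_q(model.exch, model.comps[model.node_assignment[n.id]])
                    * n.length
                    * r
                )
                for n in post
                if n.parent is not None
            }
            acc = 0.0
            for assign in itertools.product(
                range(len(states)), repeat=len(internals)
            ):
                st = {n.id: s for n, s in zip(internals, assign)}
                for nid, row in leaf_row.items():
                    code = a.matrix[row, site]
                    st[nid] = code  # handled below via indicator
                prob = model.comps[model.node_assignment[tree.root.id]][
                    st[tree.root.id]
                ]
                for n in post:
                    if n.parent is None:
                        continue
                    parent_state = st[n.parent.id]
                    if n.is_leaf:
                        ind = a.alphabet.indicator(a.matrix[leaf_row[n.id], site])
                        prob *= float(ps[n.id][parent_state] @ ind)
                    else:
                        prob *= ps[n.id][parent_state, st[n.id]]
                acc += prob
            site_l += acc / len(rates)
        total += np.log(site_l)
    return total


class TestPruningLikelihood:
    def test_two_taxon_jc_closed_form(self):
        tree = Tree.from_newick("(a:0.05,b:0.05);")
        m = PhyloModel.cv1(
            tree, np.full(4, 0.25), jukes_cantor_exch(4), alpha=1.0, n_categories=1
        )
        a = make_dna_alignment({"a": "A", "b": "A"})
        expect = np.log(0.25 * (0.25 + 0.75 * np.exp(-0.4 / 3.0)))
        assert log_likelihood(a, m) == pytest.approx(expect, abs=1e-10)

    def test_matches_brute_force_ndch2(self, rng):
        tree = Tree.from_newick("((a:0.1,b:0.23):0.11,(c:0.4,d:0.05):0.2);")
        comps = rng.dirichlet(np.ones(4) * 5, size=tree.n_nodes)
        m = PhyloModel.ndch2(tree, comps, random_gtr(rng), alpha=0.7)
        mat = rng.choice(list("ACGT"), size=(4, 20))
        a = Alignment(["a", "b", "c", "d"], mat, DNA)
        assert log_likelihood(a, m) == pytest.approx(
            brute_force_loglik(a, m), abs=1e-8
        )

    def test_matches_brute_force_with_ambiguity(self, rng):
        tree = Tree.from_newick("((a:0.2,b:0.1):0.15,(c:0.3,d:0.25):0.1);")
        comps = rng.dirichlet(np.ones(4) * 5, size=tree.n_nodes)
        m = PhyloModel.ndch2(tree, comps, random_gtr(rng), alpha=1.2)
        mat = rng.choice(list("ACGT-NRY"), size=(4, 12))
        a = Alignment(["a", "b", "c", "d"], mat, DNA)
        assert log_likelihood(a, m) == pytest.approx(
            brute_force_loglik(a, m), abs=1e-8
        )

    def test_site_order_invariance(self, rng):
        tree = Tree.from_newick("((a:0.1,b:0.2):0.1,(c:0.1,d:0.2):0.1);")
        m = PhyloModel.cv1(tree, rng.dirichlet(np.ones(4)), random_gtr(rng))
        mat = rng.choice(list("ACGT"), size=(4, 40))
        a = Alignment(["a", "b", "c", "d"], mat, DNA)
        perm = rng.permutation(40)
        b = Alignment(["a", "b", "c", "d"], mat[:, perm], DNA)
        assert log_likelihood(a, m) == pytest.approx(
            log_likelihood(b, m), rel=1e-12
        )

    def test_cv1_reroot_invariance(self, rng):
        # reversible homogeneous model: likelihood obeys the pulley principle
        tree = Tree.from_newick("((a:0.1,b:0.23):0.11,(c:0.4,d:0.05):0.2);")
        pi = rng.dirichlet(np.ones(4) * 5)
        exch = random_gtr(rng)
        mat = rng.choice(list("ACGT"), size=(4, 30))
        a = Alignment(["a", "b", "c", "d"], mat, DNA)
        m = PhyloModel.cv1(tree, pi, exch, alpha=0.8)
        ll0 = log_likelihood(a, m)
        for leaf in ("a", "c"):
            target = next(n for n in tree.nodes if n.name == leaf)
            t2 = tree.reroot_on_branch(target, 0.3)
            m2 = PhyloModel.cv1(t2, pi, exch, alpha=0.8)
            assert log_likelihood(a, m2) == pytest.approx(ll0, abs=1e-9)

    def test_ndch2_reroot_changes_likelihood(self, rng):
        # with unequal node compositions the process is not reversible
        tree = Tree.from_newick("((a:0.1,b:0.23):0.11,(c:0.4,d:0.05):0.2);")
        comps = rng.dirichlet(np.ones(4) * 3, size=tree.n_nodes)
        exch = random_gtr(rng)
        mat = rng.choice(list("ACGT"), size=(4, 30))
        a = Alignment(["a", "b", "c", "d"], mat, DNA)
        ll0 = log_likelihood(a, PhyloModel.ndch2(tree, comps, exch, alpha=0.8))
        target = next(n for n in tree.nodes if n.name == "c")
        t2 = tree.reroot_on_branch(target, 0.3)
        ll1 = log_likelihood(
            a, PhyloModel.ndch2(t2, comps[: t2.n_nodes], exch, alpha=0.8)
        )
        assert abs(ll0 - ll1) > 1e-6

    def test_likelihood_decreases_away_from_long_branch_optimum(self, rng):
        # smoke property: ll is smooth and unimodal in one branch length
        tree = Tree.from_newick("((a:0.1,b:0.2):0.1,(c:0.1,d:0.2):0.1);")
        m = PhyloModel.cv1(tree, np.full(4, 0.25), jukes_cantor_exch(4))
        mat = rng.choice(list("ACGT"), size=(4, 200))
        a = Alignment(["a", "b", "c", "d"], mat, DNA)
        target = next(n for n in m.tree.nodes if n.name == "a")
        grid = np.linspace(0.01, 3.0, 40)
        lls = []
        for t in grid:
            target.length = float(t)
            lls.append(log_likelihood(a, m))
        lls = np.array(lls)
        k = int(np.argmax(lls))
        assert np.all(np.diff(lls[: k + 1]) >= 0)
        assert np.all(np.diff(lls[k:]) <= 0)

    def test_leaf_mismatch_rejected(self, rng):
        tree = Tree.from_newick("(a:0.1,b:0.1);")
        m = PhyloModel.cv1(tree, np.full(4, 0.25), jukes_cantor_exch(4))
        a = make_dna_alignment({"a": "A", "z": "A"})
        with pytest.raises(ValueError, match="leaves"):
            log_likelihood(a, m)
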