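"""MCMC machinery: determinism, summaries, composition chi-square,
posterior predictive plumbing and the marginal-likelihood estimate."""

import numpy as np
import pytest

from comphet.mcmc import (
    McmcConfig,
    McmcSample,
    McmcTrace,
    asdoss,
    composition_chi2,
    consensus_tree,
    harmonic_mean_logml,
    posterior_predictive_chi2,
    run_mcmc,
    tree_splits,
    write_trace,
)
from comphet.seqio import Alignment, DNA
from comphet.simulate import SimulationSpec, simulate_alignment
from comphet.treemodel import PhyloModel, RateModel, Tree, jukes_cantor_exch

from conftest import make_dna_alignment


def small_alignment(seed=0, n_sites=300):
    tree = Tree.from_newick("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
    comps = np.tile(np.full(4, 0.25), (tree.n_nodes, 1))
    spec = SimulationSpec(
        tree=tree,
        comps=comps,
        exch=jukes_cantor_exch(4),
        alpha=1.0,
        n_sites=n_sites,
        seed=seed,
    )
    return simulate_alignment(spec)


def model_on(nwk, pi=None):
    tree = Tree.from_newick(nwk)
    pi = np.full(4, 0.25) if pi is None else pi
    return PhyloModel.cv1(tree, pi, jukes_cantor_exch(4), alpha=1.0)


def trace_of_trees(newicks, burnin=0.0):
    samples = []
    for nwk in newicks:
        tree = Tree.from_newick(nwk)
        model = PhyloModel.cv1(
            tree, np.full(4, 0.25), jukes_cantor_exch(4), alpha=1.0
        )
        samples.append(McmcSample(0, model, -1.0, 0.0))
    cfg = McmcConfig(n_generations=0, burnin_fraction=burnin)
    return McmcTrace(samples, {}, (0, 0), cfg)


class TestRunMcmc:
    def test_zero_generations_empty(self):
        a = small_alignment()
        cfg = McmcConfig(n_generations=0, n_chains=1, seed=1)
        trace = run_mcmc(a, "CV1", cfg)
        assert trace.samples == []

    def test_deterministic_under_seed(self):
        a = small_alignment()
        cfg = McmcConfig(
            n_generations=200, sample_interval=10, n_chains=1, seed=42
        )
        t1 = run_mcmc(a, "CV1", cfg)
        t2 = run_mcmc(a, "CV1", cfg)
        assert [s.log_likelihood for s in t1.samples] == [
            s.log_likelihood for s in t2.samples
        ]
        assert [s.newick for s in t1.samples] == [s.newick for s in t2.samples]

    def test_sample_count(self):
        a = small_alignment()
        cfg = McmcConfig(n_generations=205, sample_interval=10, n_chains=1, seed=1)
        trace = run_mcmc(a, "CV1", cfg)
        assert len(trace.samples) == 20

    def test_compositions_stay_on_simplex(self):
        a = small_alignment()
        cfg = McmcConfig(n_generations=300, sample_interval=10, n_chains=1, seed=7)
        trace = run_mcmc(a, "NDCH2", cfg)
        for s in trace.samples:
            assert np.all(s.model.comps > 0)
            assert np.allclose(s.model.comps.sum(axis=1), 1.0)

    def test_coupled_chains_swap(self):
        a = small_alignment()
        cfg = McmcConfig(
            n_generations=300, sample_interval=50, n_chains=2, seed=3,
            swap_interval=5,
        )
        trace = run_mcmc(a, "CV1", cfg)
        assert trace.swap[1] > 0  # swaps attempted

    def test_trace_serialization(self, tmp_path):
        a = small_alignment()
        cfg = McmcConfig(n_generations=100, sample_interval=10, n_chains=1, seed=2)
        trace = run_mcmc(a, "CV1", cfg)
        write_trace(trace, tmp_path / "run1")
        lines = (tmp_path / "run1.p.tsv").read_text().splitlines()
        assert len(lines) == 1 + len(trace.samples)
        trees = (tmp_path / "run1.t").read_text().splitlines()
        assert len(trees) == len(trace.samples)


class TestConsensus:
    def test_identical_trees_full_support(self):
        nwk = "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);"
        trace = trace_of_trees([nwk] * 10)
        tree, table = consensus_tree([trace])
        assert table.supports[frozenset(["c", "d"])] == 1.0
        assert tree.nontrivial_clades()  # resolved consensus

    def test_conflicting_splits_at_half_excluded(self):
        t1 = "(((a:1,b:1):1,c:1):1,d:1);"
        t2 = "(((a:1,c:1):1,b:1):1,d:1);"
        trace = trace_of_trees([t1, t2])
        tree, table = consensus_tree([trace])
        # canonical split sides exclude taxon 'a': ab|cd -> {c,d}, ac|bd -> {b,d}
        assert table.supports[frozenset(["c", "d"])] == 0.5
        assert table.supports[frozenset(["b", "d"])] == 0.5
        assert tree.nontrivial_clades() == set()  # star consensus

    def test_supports_equal_hand_tallied_frequencies(self):
        t1 = "((a:1,b:1):1,(c:1,d:1):1);"
        t2 = "((a:1,c:1):1,(b:1,d:1):1);"
        trace = trace_of_trees([t1] * 7 + [t2] * 3)
        _, table = consensus_tree([trace])
        assert table.supports[frozenset(["c", "d"])] == pytest.approx(0.7)
        assert table.supports[frozenset(["b", "d"])] == pytest.approx(0.3)

    def test_mean_tree_length(self):
        t1 = "((a:1,b:1):1,(c:1,d:1):1);"  # TL 6 (root child branches incl.)
        trace = trace_of_trees([t1] * 4)
        _, table = consensus_tree([trace])
        assert table.mean_tree_length == pytest.approx(6.0)

    def test_leaf_set_mismatch_rejected(self):
        tr1 = trace_of_trees(["((a:1,b:1):1,c:1);"])
        tr2 = trace_of_trees(["((a:1,b:1):1,d:1);"])
        with pytest.raises(ValueError, match="leaf sets"):
            consensus_tree([tr1, tr2])


class TestAsdoss:
    def test_identical_runs_zero(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1);"
        tr1 = trace_of_trees([nwk] * 5)
        tr2 = trace_of_trees([nwk] * 5)
        assert asdoss([tr1, tr2]) == 0.0

    def test_hand_computed_sd(self):
        # one contested split with supports 0.9 and 1.0 across two runs
        t_ab = "((a:1,b:1):1,(c:1,d:1):1);"
        t_ac = "((a:1,c:1):1,(b:1,d:1):1);"
        run1 = trace_of_trees([t_ab] * 9 + [t_ac] * 1)
        run2 = trace_of_trees([t_ab] * 10)
        # splits {a,b}... appear 0.9 vs 1.0 (sd 0.0707); {a,c},{b,d} 0.1 vs 0
        val = asdoss([run1, run2], min_support=0.5)
        assert val == pytest.approx(np.std([0.9, 1.0], ddof=1), abs=1e-12)

    def test_requires_two_runs(self):
        tr = trace_of_trees(["((a:1,b:1):1,(c:1,d:1):1);"])
        with pytest.raises(ValueError):
            asdoss([tr])


class TestCompositionChi2:
    def test_identical_compositions_zero(self):
        a = make_dna_alignment({"x": "ACGTACGT", "y": "GTACGTAC"})
        assert composition_chi2(a) == 0.0

    def test_hand_evaluated_two_taxa(self):
        a = make_dna_alignment({"x": "AAAA", "y": "CCCC"})
        assert composition_chi2(a) == pytest.approx(8.0)

    def test_gaps_and_ambiguity_excluded(self):
        a = make_dna_alignment({"x": "AAAA--NN", "y": "CCCC????"})
        assert composition_chi2(a) == pytest.approx(8.0)


class TestPosteriorPredictive:
    def test_single_replicate_tail_p_binary(self):
        a = small_alignment(seed=3)
        cfg = McmcConfig(n_generations=100, sample_interval=10, n_chains=1, seed=5)
        trace = run_mcmc(a, "CV1", cfg)
        r = posterior_predictive_chi2(trace, a, n_reps=1, seed=2)
        assert len(r.simulated_statistics) == 1
        assert r.tail_p in (0.0, 1.0)

    def test_rep_count_validated(self):
        a = small_alignment(seed=3)
        cfg = McmcConfig(n_generations=100, sample_interval=10, n_chains=1, seed=5)
        trace = run_mcmc(a, "CV1", cfg)
        with pytest.raises(ValueError, match="exceeds"):
            posterior_predictive_chi2(trace, a, n_reps=1000, seed=2)

    def test_statistic_bounds(self):
        a = small_alignment(seed=3)
        cfg = McmcConfig(n_generations=200, sample_interval=10, n_chains=1, seed=5)
        trace = run_mcmc(a, "CV1", cfg)
        r = posterior_predictive_chi2(trace, a, n_reps=5, seed=2)
        assert r.sample_min <= r.sample_max
        assert 0.0 <= r.tail_p <= 1.0


class TestHarmonicMean:
    def trace_with_lls(self, lls):
        tree = Tree.from_newick("(a:0.1,b:0.1);")
        model = PhyloModel.cv1(tree, np.full(4, 0.25), jukes_cantor_exch(4))
        samples = [McmcSample(i, model, ll, 0.0) for i, ll in enumerate(lls)]
        cfg = McmcConfig(n_generations=0, burnin_fraction=0.0)
        return McmcTrace(samples, {}, (0, 0), cfg)

    def test_constant_samples(self):
        est = harmonic_mean_logml(self.trace_with_lls([-7.5] * 20))
        assert est.value == pytest.approx(-7.5)

    def test_two_sample_closed_form(self):
        est = harmonic_mean_logml(self.trace_with_lls([-10.0, -12.0]))
        expect = -np.log(0.5 * (np.exp(10.0) + np.exp(12.0)))
        assert est.value == pytest.approx(expect, rel=1e-12)

    def test_bounded_by_max_loglik(self):
        lls = list(-np.random.default_rng(0).uniform(5, 50, size=30))
        est = harmonic_mean_logml(self.trace_with_lls(lls))
        assert est.value <= max(lls) + 1e-12
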