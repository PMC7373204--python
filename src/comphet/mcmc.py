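"""Bayesian MCMC over trees and tree-heterogeneous composition models.

A Metropolis–Hastings sampler over topology, branch lengths, node
compositions, exchangeabilities and the gamma shape, with optional
Metropolis coupling (one cold plus heated chains).  Companion summaries:
majority-rule consensus with split supports, the asdoss convergence
diagnostic (average standard deviation of split support between
independent runs), the chi-square statistic of composition homogeneity
and its posterior predictive test, and a (crude) harmonic-mean marginal
likelihood estimate.

Priors (flat Dirichlet on simplex parameters, exponential branch
lengths, uniform log gamma-shape) are deliberately weak; every run logs
them in its header.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

from .seqio import Alignment
from .simulate import SimulationSpec, simulate_alignment
from .treemodel import (
    Node,
    PhyloModel,
    RateModel,
    Tree,
    jukes_cantor_exch,
    log_likelihood,
    random_rooted_tree,
)

logger = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "McmcSample",
    "McmcTrace",
    "SplitSupportTable",
    "PosteriorPredictiveResult",
    "MarginalLikelihoodEstimate",
    "run_mcmc",
    "consensus_tree",
    "asdoss",
    "composition_chi2",
    "posterior_predictive_chi2",
    "harmonic_mean_logml",
    "write_trace",
]


DEFAULT_PROPOSAL_WEIGHTS = {
    "brlen": 3.0,
    "alpha": 1.0,
    "comp": 3.0,
    "exch": 1.0,
    "nni": 2.0,
    "espr": 1.0,
}


@dataclass
class McmcConfig:
    """Sampler settings and priors.

    ``n_chains`` > 1 enables Metropolis coupling with heating factors
    1/(1 + heating_lambda * rank); swaps between adjacent chains are
    attempted every ``swap_interval`` generations.  The burnin default
    discards the first quarter of samples, matching the convention of
    discarding 10,000 of 40,000 samples.
    """

    n_generations: int = 10_000
    sample_interval: int = 10
    burnin_fraction: float = 0.25
    n_chains: int = 4
    heating_lambda: float = 0.2
    swap_interval: int = 10
    proposal_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPOSAL_WEIGHTS)
    )
    # priors
    comp_dirichlet: float = 1.0
    exch_dirichlet: float = 1.0
    brlen_prior_mean: float = 0.1
    log_alpha_bounds: tuple[float, float] = (-3.0, 3.0)
    # proposal tuning
    brlen_tune: float = 1.0
    alpha_tune: float = 0.5
    comp_proposal_conc: float = 300.0
    exch_proposal_conc: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.burnin_fraction < 1.0):
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.comp_dirichlet <= 0 or self.exch_dirichlet <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


@dataclass
class McmcSample:
    generation: int
    model: PhyloModel
    log_likelihood: float
    log_prior: float

    @property
    def newick(self) -> str:
        return self.model.tree.to_newick()


@dataclass
class McmcTrace:
    """Sampled states plus acceptance/swap bookkeeping."""

    samples: list[McmcSample]
    acceptance: dict[str, tuple[int, int]]  # proposal -> (accepted, tried)
    swap: tuple[int, int]
    config: McmcConfig

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: (a / t if t else float("nan"))
            for k, (a, t) in self.acceptance.items()
        }

    def post_burnin(self) -> list[McmcSample]:
        k = int(len(self.samples) * self.config.burnin_fraction)
        return self.samples[k:]


@dataclass
class SplitSupportTable:
    """Clade (frozenset of leaf names) -> posterior support."""

    supports: dict[frozenset, float]
    mean_tree_length: float
    n_trees: int


@dataclass
class PosteriorPredictiveResult:
    original_statistic: float
    simulated_statistics: np.ndarray
    tail_p: float

    @property
    def sample_min(self) -> float:
        return float(np.min(self.simulated_statistics))

    @property
    def sample_max(self) -> float:
        return float(np.max(self.simulated_statistics))


@dataclass
class MarginalLikelihoodEstimate:
    estimator_id: str
    value: float
    n_samples: int


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


def log_prior(model: PhyloModel, cfg: McmcConfig) -> float:
    """Joint log prior density (flat-Dirichlet terms enter as constants)."""
    la = math.log(model.rates.alpha)
    lo, hi = cfg.log_alpha_bounds
    if not (lo <= la <= hi):
        return -math.inf
    lp = 0.0
    mean = cfg.brlen_prior_mean
    for n in model.tree.nodes:
        if n.parent is not None:
            if n.length < 0:
                return -math.inf
            lp += -n.length / mean - math.log(mean)
    if cfg.comp_dirichlet != 1.0:
        a = cfg.comp_dirichlet
        for row in model.comps:
            lp += float(
                gammaln(a * row.size)
                - row.size * gammaln(a)
                + (a - 1.0) * np.sum(np.log(row))
            )
    return lp


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + np.sum((alpha - 1.0) * np.log(x))
    )


# ---------------------------------------------------------------------------
# Proposals (each mutates a fresh copy and returns log Hastings ratio)
# ---------------------------------------------------------------------------

_COMP_FLOOR = 1e-6


def _propose_brlen(model: PhyloModel, cfg, rng) -> float:
    nodes = [n for n in model.tree.nodes if n.parent is not None]
    node = nodes[rng.integers(len(nodes))]
    m = math.exp(cfg.brlen_tune * (rng.random() - 0.5))
    node.length *= m
    return math.log(m)


def _propose_alpha(model: PhyloModel, cfg, rng) -> float:
    m = math.exp(cfg.alpha_tune * (rng.random() - 0.5))
    model.rates.alpha *= m
    return math.log(m)


def _propose_simplex(x: np.ndarray, conc: float, rng) -> tuple[np.ndarray, float]:
    a_fwd = conc * x
    y = rng.dirichlet(a_fwd)
    y = np.clip(y, _COMP_FLOOR, None)
    y /= y.sum()
    a_rev = conc * y
    logh = _dirichlet_logpdf(x, a_rev) - _dirichlet_logpdf(y, a_fwd)
    return y, logh


def _propose_comp(model: PhyloModel, cfg, rng) -> float:
    vi = int(rng.integers(model.comps.shape[0]))
    new, logh = _propose_simplex(model.comps[vi], cfg.comp_proposal_conc, rng)
    model.comps[vi] = new
    return logh


def _propose_exch(model: PhyloModel, cfg, rng) -> float:
    ns = model.exch.shape[0]
    iu = np.triu_indices(ns, k=1)
    x = model.exch[iu]
    x = x / x.sum()
    new, logh = _propose_simplex(x, cfg.exch_proposal_conc, rng)
    r = np.zeros_like(model.exch)
    r[iu] = new
    model.exch = r + r.T
    return logh


def _propose_nni(model: PhyloModel, cfg, rng) -> float:
    """Rooted NNI: swap a child of an internal node with one of its
    siblings.  Selection is uniform and the move is self-inverse, so the
    proposal is symmetric."""
    tree = model.tree
    candidates = [
        n for n in tree.nodes if n.children and n.parent is not None
    ]
    if not candidates:
        return -math.inf
    c = candidates[rng.integers(len(candidates))]
    p = c.parent
    x = c.children[rng.integers(len(c.children))]
    sibs = [s for s in p.children if s is not c]
    y = sibs[rng.integers(len(sibs))]
    # swap x and y
    c.children[c.children.index(x)] = y
    p.children[p.children.index(y)] = x
    x.parent = p
    y.parent = c
    return 0.0


def _subtree_ids(node: Node) -> set[int]:
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        out.add(n.id)
        stack.extend(n.children)
    return out


def _spr_prune_candidates(tree: Tree) -> list[Node]:
    return [
        n
        for n in tree.nodes
        if n.parent is not None and n.parent.parent is not None
    ]


def _propose_espr(model: PhyloModel, cfg, rng) -> float:
    """Rooted SPR: prune a subtree, splice out its parent, reattach on a
    uniformly chosen branch at a uniform position.  The Hastings ratio
    accounts for the candidate counts and the branch-length densities of
    the attachment points."""
    tree = model.tree
    prunable = _spr_prune_candidates(tree)
    if not prunable:
        return -math.inf
    s = prunable[rng.integers(len(prunable))]
    p = s.parent
    g = p.parent
    o = [c for c in p.children if c is not s][0]
    n_prune_fwd = len(prunable)

    # detach: splice p out, merging its branch into o's
    merged_rev = o.length + p.length  # length of the reverse attachment branch
    o.length = merged_rev
    o.parent = g
    g.children[g.children.index(p)] = o
    p.parent = None
    p.children = [s]

    sub = _subtree_ids(s)
    targets = [
        n
        for n in tree.nodes
        if n.parent is not None and n.id not in sub and n is not p
    ]
    if not targets:  # cannot happen on trees with >= 3 leaves
        # undo and reject
        o.length -= p.length
        o.parent = p
        p.children = [s, o]
        g.children[g.children.index(o)] = p
        p.parent = g
        return -math.inf
    u = targets[rng.integers(len(targets))]
    n_targets_fwd = len(targets)
    lu = u.length
    w = rng.random()
    # insert p between u and its parent
    gp = u.parent
    p.parent = gp
    gp.children[gp.children.index(u)] = p
    p.children = [s, u]
    u.parent = p
    p.length = (1.0 - w) * lu
    u.length = w * lu

    # reverse-move counts on the new tree
    n_prune_rev = len(_spr_prune_candidates(tree))
    targets_rev = [
        n
        for n in tree.nodes
        if n.parent is not None and n.id not in sub and n is not p
    ]
    n_targets_rev = len(targets_rev)
    # forward density: 1/(n_prune_fwd * n_targets_fwd * lu)
    # reverse density: 1/(n_prune_rev * n_targets_rev * merged_rev)
    return (
        math.log(n_prune_fwd * n_targets_fwd * lu)
        - math.log(n_prune_rev * n_targets_rev * merged_rev)
    )


_PROPOSALS = {
    "brlen": _propose_brlen,
    "alpha": _propose_alpha,
    "comp": _propose_comp,
    "exch": _propose_exch,
    "nni": _propose_nni,
    "espr": _propose_espr,
}


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def _initial_model(a: Alignment, model_spec, cfg: McmcConfig, rng) -> PhyloModel:
    tree = random_rooted_tree(list(a.taxa), rng, branch_mean=cfg.brlen_prior_mean)
    ns = a.alphabet.n_states
    counts = np.zeros(ns)
    for k, s in enumerate(a.alphabet.states):
        counts[k] = np.sum(a.matrix == s)
    emp = (counts + 1.0) / (counts.sum() + ns)
    exch = jukes_cantor_exch(ns)
    if model_spec == "CV1":
        comps = emp[None, :]
        assign = np.zeros(tree.n_nodes, dtype=int)
        mode = "CV1"
    elif model_spec == "NDCH2":
        comps = np.tile(emp, (tree.n_nodes, 1))
        assign = np.arange(tree.n_nodes)
        mode = "NDCH2"
    elif isinstance(model_spec, tuple) and model_spec[0] == "NDCH":
        k = int(model_spec[1])
        comps = np.tile(emp, (k, 1))
        assign = rng.integers(0, k, size=tree.n_nodes)
        mode = "NDCH"
    else:
        raise ValueError(f"unknown model spec {model_spec!r}")
    return PhyloModel(
        tree=tree,
        comp_mode=mode,
        comps=comps,
        node_assignment=assign,
        exch=exch,
        rates=RateModel(1.0),
    )


class _ChainState:
    __slots__ = ("model", "loglik", "logprior", "beta")

    def __init__(self, model, loglik, logprior, beta):
        self.model = model
        self.loglik = loglik
        self.logprior = logprior
        self.beta = beta

    @property
    def logpost(self) -> float:
        return self.loglik + self.logprior


def run_mcmc(
    a: Alignment,
    model_spec="CV1",
    cfg: McmcConfig | None = None,
    init_model: PhyloModel | None = None,
) -> McmcTrace:
    """Metropolis(-coupled) MCMC; cold-chain samples every
    ``sample_interval`` generations.

    ``model_spec`` is "CV1", "NDCH2" or ("NDCH", K).  ``init_model``
    overrides the random initial state (the topology still moves unless
    the topology proposal weights are zero).  Reproducible under
    ``cfg.seed``.
    """
    cfg = cfg or McmcConfig()
    rng = np.random.default_rng(cfg.seed)
    if init_model is not None:
        model0 = init_model.copy()
    else:
        model0 = _initial_model(a, model_spec, cfg, rng)

    names = list(cfg.proposal_weights)
    weights = np.array([cfg.proposal_weights[n] for n in names], dtype=float)
    active = weights > 0
    names = [n for n, keep in zip(names, active) if keep]
    weights = weights[active]
    weights = weights / weights.sum()

    ll0 = log_likelihood(a, model0)
    lp0 = log_prior(model0, cfg)
    if not np.isfinite(ll0 + lp0):
        raise ValueError("non-finite posterior at the initial state")
    logger.info(
        "mcmc start: model=%s chains=%d gens=%d seed=%d priors="
        "{comp Dir(%g), exch Dir(%g), brlen Exp(mean %g), log-alpha U%s}",
        model_spec,
        cfg.n_chains,
        cfg.n_generations,
        cfg.seed,
        cfg.comp_dirichlet,
        cfg.exch_dirichlet,
        cfg.brlen_prior_mean,
        cfg.log_alpha_bounds,
    )

    chains = [
        _ChainState(model0.copy(), ll0, lp0, 1.0 / (1.0 + cfg.heating_lambda * k))
        for k in range(cfg.n_chains)
    ]

    accepted = {n: 0 for n in names}
    tried = {n: 0 for n in names}
    swap_acc, swap_try = 0, 0
    samples: list[McmcSample] = []

    for gen in range(1, cfg.n_generations + 1):
        for chain in chains:
            kind = names[rng.choice(len(names), p=weights)]
            cand = chain.model.copy()
            logh = _PROPOSALS[kind](cand, cfg, rng)
            if not np.isfinite(logh):
                if chain is chains[0]:
                    tried[kind] += 1
                continue
            lp = log_prior(cand, cfg)
            if np.isfinite(lp):
                ll = log_likelihood(a, cand)
            else:
                ll = -math.inf
            delta = chain.beta * ((ll + lp) - chain.logpost) + logh
            if chain is chains[0]:
                tried[kind] += 1
            if math.log(rng.random() + 1e-300) < delta:
                chain.model = cand
                chain.loglik = ll
                chain.logprior = lp
                if chain is chains[0]:
                    accepted[kind] += 1

        if cfg.n_chains > 1 and gen % cfg.swap_interval == 0:
            i = int(rng.integers(cfg.n_chains - 1))
            ci, cj = chains[i], chains[i + 1]
            swap_try += 1
            d = (ci.beta - cj.beta) * (cj.logpost - ci.logpost)
            if math.log(rng.random() + 1e-300) < d:
                ci.model, cj.model = cj.model, ci.model
                ci.loglik, cj.loglik = cj.loglik, ci.loglik
                ci.logprior, cj.logprior = cj.logprior, ci.logprior
                swap_acc += 1

        if gen % cfg.sample_interval == 0:
            cold = chains[0]
            samples.append(
                McmcSample(
                    generation=gen,
                    model=cold.model.copy(),
                    log_likelihood=cold.loglik,
                    log_prior=cold.logprior,
                )
            )

    total_tried = sum(tried.values())
    total_acc = sum(accepted.values())
    if total_tried and total_acc == 0:
        logger.warning("zero proposals accepted: chain appears stalled")

    return McmcTrace(
        samples=samples,
        acceptance={n: (accepted[n], tried[n]) for n in names},
        swap=(swap_acc, swap_try),
        config=cfg,
    )


def write_trace(trace: McmcTrace, prefix: str | Path) -> None:
    """Serialize a trace: <prefix>.p.tsv (parameters) + <prefix>.t (trees)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.p.tsv", "w") as fh:
        fh.write("generation\tlog_likelihood\tlog_prior\talpha\ttree_length\n")
        for s in trace.samples:
            fh.write(
                f"{s.generation}\t{s.log_likelihood:.6f}\t{s.log_prior:.6f}"
                f"\t{s.model.rates.alpha:.6f}\t{s.model.tree.tree_length():.6f}\n"
            )
    with open(f"{prefix}.t", "w") as fh:
        for s in trace.samples:
            fh.write(s.newick + "\n")


# ---------------------------------------------------------------------------
# Summaries over traces
# ---------------------------------------------------------------------------


def tree_splits(t: Tree) -> dict[frozenset, float]:
    """Canonical unrooted splits of a (rooted) tree, with branch lengths.

    Each split is represented by the bipartition side NOT containing the
    reference leaf (the alphabetically first taxon), so supports are
    invariant to root placement — under a reversible model the root is
    unidentifiable and rooted clade frequencies scatter across root
    positions while the splits stay stable.  The two root-adjacent
    edges describe the same split; their lengths are summed (the
    unrooted path through the root).  Trivial singleton splits (pendant
    edges) are included.
    """
    leaves = t.leaf_names()
    ref = min(leaves)
    all_leaves = frozenset(leaves)
    out: dict[frozenset, float] = {}
    for nid, clade in t.clades().items():
        node = t.nodes[nid]
        if node.parent is None:
            continue
        side = clade if ref not in clade else all_leaves - clade
        if not side:
            continue
        out[side] = out.get(side, 0.0) + node.length
    return out


def _split_supports(trees: list[Tree]) -> dict[frozenset, float]:
    counts: dict[frozenset, int] = {}
    for t in trees:
        for side in tree_splits(t):
            counts[side] = counts.get(side, 0) + 1
    return {c: k / len(trees) for c, k in counts.items()}


def consensus_tree(
    traces: list[McmcTrace], min_freq: float = 0.5
) -> tuple[Tree, SplitSupportTable]:
    """Majority-rule consensus of post-burnin trees from one or more runs.

    Splits with pooled posterior frequency strictly above ``min_freq``
    are retained (ties at exactly 0.5 are conflicting and excluded);
    they are mutually compatible and assemble into the consensus tree,
    drawn rooted at the reference leaf.  Branch lengths are means over
    the trees containing each split; internal node labels carry the
    supports.
    """
    if not traces:
        raise ValueError("no traces")
    trees = [s.model.tree for tr in traces for s in tr.post_burnin()]
    if not trees:
        raise ValueError("no post-burnin samples")
    leafsets = {frozenset(t.leaf_names()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("leaf sets differ across traces")
    all_leaves = leafsets.pop()
    n = len(all_leaves)
    ref = min(all_leaves)
    supports = _split_supports(trees)
    mean_tl = float(np.mean([t.tree_length() for t in trees]))

    per_tree_lengths = [tree_splits(t) for t in trees]

    def mean_brlen(side: frozenset) -> float:
        vals = [d[side] for d in per_tree_lengths if side in d]
        return float(np.mean(vals)) if vals else 0.0

    kept = sorted(
        (
            c
            for c, f in supports.items()
            if f > min_freq and 1 < len(c) < n - 1
        ),
        key=lambda c: (-len(c), tuple(sorted(c))),
    )

    root = Node(0, name=None)
    nodes = [root]
    clade_node: dict[frozenset, Node] = {all_leaves: root}
    singles = [frozenset([x]) for x in sorted(all_leaves)]
    for clade in kept + singles:
        node = Node(len(nodes))
        if len(clade) == 1:
            (node.name,) = clade
            side = clade if ref not in clade else all_leaves - clade
            node.length = mean_brlen(side)
        else:
            node.name = f"{supports[clade]:.3f}"
            node.length = mean_brlen(clade)
        parent_clade = min((c for c in clade_node if clade < c), key=len)
        parent = clade_node[parent_clade]
        parent.children.append(node)
        node.parent = parent
        nodes.append(node)
        if len(clade) > 1:
            clade_node[clade] = node
    tree = Tree(root, nodes)
    tree.reindex()

    table = SplitSupportTable(
        supports=dict(supports), mean_tree_length=mean_tl, n_trees=len(trees)
    )
    return tree, table


def asdoss(
    traces: list[McmcTrace], min_support: float = 0.1
) -> float:
    """Average standard deviation of split support between runs.

    Every non-trivial split reaching ``min_support`` in at least one
    run contributes the sample standard deviation (n-1 denominator) of
    its supports across runs (0 where absent); the average over splits
    is returned.  Small values indicate that independent runs agree on
    the posterior topology distribution.
    """
    if len(traces) < 2:
        raise ValueError("asdoss requires at least two independent runs")
    per_run = []
    n_leaves = None
    for tr in traces:
        trees = [s.model.tree for s in tr.post_burnin()]
        if not trees:
            raise ValueError("a trace has no post-burnin samples")
        n_leaves = len(trees[0].leaf_names())
        per_run.append(_split_supports(trees))
    leafsets = set()
    for tr in traces:
        leafsets.add(frozenset(tr.samples[0].model.tree.leaf_names()))
    if len(leafsets) != 1:
        raise ValueError("leaf sets differ across traces")
    splits = {
        c
        for sup in per_run
        for c, f in sup.items()
        if f >= min_support and 1 < len(c) < n_leaves - 1
    }
    if not splits:
        return 0.0
    sds = []
    for c in splits:
        vals = np.array([sup.get(c, 0.0) for sup in per_run])
        sds.append(float(np.std(vals, ddof=1)))
    return float(np.mean(sds))


# ---------------------------------------------------------------------------
# Composition homogeneity
# ---------------------------------------------------------------------------


def composition_chi2(a: Alignment) -> float:
    """Chi-square statistic of across-taxa composition homogeneity.

    Canonical-state counts per taxon against expectations from the
    pooled state proportions; gap/missing/ambiguity codes are excluded
    and globally absent states are skipped.
    """
    if a.n_taxa < 2:
        raise ValueError("need at least two taxa")
    states = a.alphabet.states
    counts = np.zeros((a.n_taxa, len(states)))
    for k, s in enumerate(states):
        counts[:, k] = (a.matrix == s).sum(axis=1)
    totals = counts.sum(axis=1)
    grand = counts.sum(axis=0)
    if grand.sum() == 0:
        raise ValueError("no canonical states in alignment")
    props = grand / grand.sum()
    keep = grand > 0
    expected = totals[:, None] * props[None, :]
    with np.errstate(invalid="ignore"):
        terms = (counts[:, keep] - expected[:, keep]) ** 2 / expected[:, keep]
    return float(np.nansum(terms))


def posterior_predictive_chi2(
    trace: McmcTrace,
    a: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    mask_original_gaps: bool = False,
) -> PosteriorPredictiveResult:
    """Posterior predictive test of composition homogeneity.

    ``n_reps`` post-burnin samples (evenly thinned) each simulate one
    gap-free alignment of the original dimensions under the sampled
    tree and parameters; the tail probability is the fraction of
    simulated chi-square statistics at or above the observed one
    (observed above the whole distribution => small p => the model's
    compositions cannot reproduce the data's heterogeneity).

    ``mask_original_gaps=True`` copies the original non-canonical
    (gap/missing/ambiguity) site patterns onto each simulated replicate
    before computing the statistic.
    """
    post = trace.post_burnin()
    if not post:
        raise ValueError("empty post-burnin trace")
    if n_reps > len(post):
        raise ValueError(f"n_reps={n_reps} exceeds {len(post)} available samples")
    idx = np.linspace(0, len(post) - 1, n_reps).round().astype(int)
    original = composition_chi2(a)
    rng = np.random.default_rng(seed)

    noncanon = None
    if mask_original_gaps:
        canon = np.isin(a.matrix, list(a.alphabet.states))
        noncanon = ~canon

    stats = np.empty(n_reps)
    for k, i in enumerate(idx):
        m = post[i].model
        spec = SimulationSpec(
            tree=m.tree.copy(),
            comps=m.comps[m.node_assignment],
            exch=m.exch,
            alpha=m.rates.alpha,
            n_sites=a.n_sites,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_categories=m.rates.n_categories,
        )
        sim = simulate_alignment(spec)
        if noncanon is not None:
            order = [sim.taxa.index(t) for t in a.taxa]
            sim.matrix = sim.matrix[order]
            sim.taxa = list(a.taxa)
            sim.matrix[noncanon] = a.matrix[noncanon]
        stats[k] = composition_chi2(sim)
    tail_p = float(np.mean(stats >= original))
    return PosteriorPredictiveResult(
        original_statistic=original, simulated_statistics=stats, tail_p=tail_p
    )


def harmonic_mean_logml(trace: McmcTrace) -> MarginalLikelihoodEstimate:
    """Harmonic-mean marginal-likelihood estimate (log scale, stable).

    A crude estimator with notoriously high variance; reported for
    comparability with run-legend conventions, not as a recommended
    model-choice tool.
    """
    post = trace.post_burnin()
    if not post:
        raise ValueError("empty post-burnin trace")
    lls = np.array([s.log_likelihood for s in post])
    n = lls.size
    value = math.log(n) - float(logsumexp(-lls))
    return MarginalLikelihoodEstimate(
        estimator_id="harmonic-mean", value=value, n_samples=n
    )
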