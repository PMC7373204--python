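"""Likelihood engine for tree-heterogeneous composition models.

The model family is GTR-type exchangeabilities combined with per-node
composition vectors: CV1 fixes a single composition for the whole tree
(the stationary, homogeneous case), NDCH shares K composition vectors
among nodes, and NDCH2 gives every node its own vector.  Rates among
sites follow a discrete gamma with four equal-probability categories
(category rate = conditional mean, overall mean 1).

Trees are rooted; the branch above a node is evolved under the rate
matrix built from that node's (the child's) composition, and the root's
own composition acts as the prior over states at the root.  Each
branch's rate matrix is normalised under its own composition so branch
lengths keep their expected-substitutions-per-site meaning across
composition regimes.  With unequal compositions the process is
non-reversible in the tree sense: re-rooting changes the likelihood,
which is why root placement is an explicit analysis choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy.linalg import eigh
from scipy.stats import gamma as gamma_dist

from .seqio import Alignment, AlignmentError

__all__ = [
    "Node",
    "Tree",
    "RateModel",
    "PhyloModel",
    "build_q",
    "transition_matrix",
    "discrete_gamma_rates",
    "read_paml_rates",
    "jukes_cantor_exch",
    "log_likelihood",
]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Node:
    """A node of a rooted tree; ``length`` is the branch above it."""

    __slots__ = ("id", "parent", "children", "length", "name")

    def __init__(self, id: int, name: str | None = None, length: float = 0.0):
        self.id = id
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length
        self.name = name

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.id}, {self.name!r})"


class Tree:
    """Rooted tree with stable node ids (0..n_nodes-1, root included)."""

    def __init__(self, root: Node, nodes: list[Node]):
        self.root = root
        self.nodes = nodes  # indexed by id

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "Tree":
        nodes: list[Node] = []

        def build(dnode) -> Node:
            node = Node(
                id=len(nodes),
                name=(dnode.taxon.label if dnode.taxon is not None else dnode.label),
                length=float(dnode.edge.length or 0.0),
            )
            nodes.append(node)
            for child in dnode.child_nodes():
                c = build(child)
                c.parent = node
                node.children.append(c)
            return node

        root = build(dt.seed_node)
        return cls(root, nodes)

    def to_newick(self, include_lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or f"n{node.id}"
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if include_lengths and node.parent is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        nodes = [Node(n.id, n.name, n.length) for n in self.nodes]
        for n in self.nodes:
            if n.parent is not None:
                nodes[n.id].parent = nodes[n.parent.id]
            nodes[n.id].children = [nodes[c.id] for c in n.children]
        return Tree(nodes[self.root.id], nodes)

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def tree_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent is not None)

    def clades(self) -> dict[int, frozenset]:
        """Node id -> frozenset of descendant leaf names (incl. itself)."""
        out: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node.id] = frozenset([node.name])
            else:
                s: frozenset = frozenset()
                for c in node.children:
                    s |= out[c.id]
                out[node.id] = s
        return out

    def nontrivial_clades(self) -> set[frozenset]:
        all_leaves = frozenset(self.leaf_names())
        return {
            c
            for c in self.clades().values()
            if 1 < len(c) < len(all_leaves)
        }

    # -- editing (used by MCMC proposals) ------------------------------------

    def reindex(self) -> None:
        """Reassign ids in postorder after structural edits."""
        self.nodes = self.postorder()
        for i, n in enumerate(self.nodes):
            n.id = i

    def reroot_on_branch(self, node: Node, fraction: float = 0.5) -> "Tree":
        """Return a copy rerooted on the branch above ``node``.

        The old root (if left with a single child) is spliced out.  Used
        by the reversibility ("pulley") checks; node ids are reassigned.
        """
        t = self.copy()
        target = t.nodes[node.id]
        if target.parent is None:
            return t
        # split the branch above target with a new root
        newroot = Node(id=-1, name=None, length=0.0)
        upper = target.length * (1.0 - fraction)
        lower = target.length * fraction
        old_parent = target.parent

        # reverse the path from old_parent up to the old root
        path = []
        p = old_parent
        while p is not None:
            path.append(p)
            p = p.parent
        old_parent.children.remove(target)
        for k in range(len(path) - 1):
            child, par = path[k], path[k + 1]
            par.children.remove(child)
            child.children.append(par)
            par.parent = child
            par.length = child.length
        newroot.children = [target, old_parent]
        target.parent = newroot
        target.length = lower
        old_parent.parent = newroot
        old_parent.length = upper
        # splice out degree-2 internal nodes left behind (the old root)
        def splice(n: Node) -> None:
            for c in list(n.children):
                splice(c)
            if n.parent is not None and len(n.children) == 1:
                only = n.children[0]
                only.length += n.length
                only.parent = n.parent
                idx = n.parent.children.index(n)
                n.parent.children[idx] = only

        splice(newroot)
        t.root = newroot
        t.reindex()
        return t


def random_rooted_tree(
    names: list[str], rng: np.random.Generator, branch_mean: float = 0.1
) -> Tree:
    """Random rooted binary topology by successive joins, Exp branch lengths."""
    nodes = [Node(i, name=n) for i, n in enumerate(names)]
    pool = list(nodes)
    all_nodes = list(nodes)
    while len(pool) > 1:
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parent = Node(len(all_nodes))
        parent.children = [a, b]
        a.parent = parent
        b.parent = parent
        all_nodes.append(parent)
        pool = [n for n in pool if n is not a and n is not b] + [parent]
    root = pool[0]
    tree = Tree(root, all_nodes)
    for n in all_nodes:
        if n.parent is not None:
            n.length = float(rng.exponential(branch_mean))
    tree.reindex()
    return tree


# ---------------------------------------------------------------------------
# Rate matrices and gamma rates
# ---------------------------------------------------------------------------


def jukes_cantor_exch(n_states: int = 4) -> np.ndarray:
    """Equal exchangeabilities (with equal frequencies this is JC-type)."""
    r = np.ones((n_states, n_states))
    np.fill_diagonal(r, 0.0)
    return r


def build_q(exch: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """GTR-type rate matrix Q_ab = R_ab * pi_b, normalised to mean rate 1.

    Rows sum to zero and -sum_a pi_a Q_aa = 1 so that time is measured
    in expected substitutions per site under ``pi``.
    """
    exch = np.asarray(exch, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if exch.shape[0] != pi.size:
        raise ValueError("dimension mismatch between exchangeabilities and pi")
    if np.any(pi <= 0):
        raise ValueError("composition entries must be positive")
    q = exch * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    if mu <= 0:
        raise ValueError("degenerate rate matrix")
    return q / mu


def _symmetric_decomposition(exch: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of Q via its similar symmetric form.

    Q = D^{-1/2} B D^{1/2} with D = diag(pi) and B symmetric, so
    P(t) = D^{-1/2} U exp(L t) U' D^{1/2}; numerically stable and
    guarantees real eigenvalues for reversible Q.
    """
    q = build_q(exch, pi)
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]
    b = 0.5 * (b + b.T)
    evals, evecs = eigh(b)
    left = evecs.T * d[None, :]       # U' D^{1/2}
    right = evecs / d[:, None]        # D^{-1/2} U
    return evals, right, left


def transition_matrix(
    q_or_decomp, t: float, rate_multiplier: float = 1.0
) -> np.ndarray:
    """P = exp(Q t r); accepts a Q matrix or a cached decomposition."""
    if t < 0:
        raise ValueError("negative branch length")
    if isinstance(q_or_decomp, tuple):
        evals, right, left = q_or_decomp
        p = (right * np.exp(evals * t * rate_multiplier)[None, :]) @ left
    else:
        from scipy.linalg import expm

        p = expm(np.asarray(q_or_decomp) * t * rate_multiplier)
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("non-finite transition matrix")
    return p


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of equal-probability gamma bins (mean exactly 1).

    Gamma has shape alpha and mean 1; the category rate is the
    conditional mean within each of the ``n_categories`` probability
    bins.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X; X in bin] = F_{alpha+1}(hi) - F_{alpha+1}(lo) for mean-1 gamma
    cdf1 = gamma_dist.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    rates = k * np.diff(cdf1)
    return rates / rates.mean() * 1.0


@dataclass
class RateModel:
    """Discrete-gamma among-site rate heterogeneity (mean rate 1)."""

    alpha: float
    n_categories: int = 4

    @property
    def rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.n_categories, 1.0 / self.n_categories)


def read_paml_rates(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a PAML-format empirical amino-acid rate file.

    Format: 19 lower-triangular rows of exchangeabilities followed
    (optionally) by a line of 20 equilibrium frequencies.  This is the
    format in which empirical matrices such as gcpREV are distributed.
    Returns (R, freqs) with R symmetric 20x20 and freqs possibly None.
    """
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            values.extend(float(x) for x in line.split())
    n_tri = 190
    if len(values) not in (n_tri, n_tri + 20):
        raise ValueError(
            f"expected 190 exchangeabilities (+20 frequencies), got {len(values)}"
        )
    r = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            r[i, j] = r[j, i] = values[k]
            k += 1
    freqs = None
    if len(values) == n_tri + 20:
        freqs = np.array(values[n_tri:])
        freqs = freqs / freqs.sum()
    return r, freqs


# ---------------------------------------------------------------------------
# The phylogenetic model
# ---------------------------------------------------------------------------


@dataclass
class PhyloModel:
    """Tree + composition regime + exchangeabilities + gamma rates.

    ``comps`` holds the distinct composition vectors (rows on the
    simplex); ``node_assignment[node_id]`` selects the vector for each
    node.  CV1 means one shared vector, NDCH K shared vectors, NDCH2
    one per node.
    """

    tree: Tree
    comp_mode: str  # "CV1" | "NDCH" | "NDCH2"
    comps: np.ndarray  # (n_vectors, n_states)
    node_assignment: np.ndarray  # (n_nodes,) -> vector index
    exch: np.ndarray
    rates: RateModel

    def __post_init__(self) -> None:
        self.comps = np.atleast_2d(np.asarray(self.comps, dtype=float))
        self.node_assignment = np.asarray(self.node_assignment, dtype=int)
        if self.comp_mode == "CV1" and self.comps.shape[0] != 1:
            raise ValueError("CV1 requires exactly one composition vector")
        if self.comp_mode == "NDCH2" and self.comps.shape[0] != self.tree.n_nodes:
            raise ValueError("NDCH2 requires one composition vector per node")
        if self.node_assignment.size != self.tree.n_nodes:
            raise ValueError("node assignment must cover every node")
        sums = self.comps.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("composition vectors must sum to 1")
        if np.any(self.comps <= 0):
            raise ValueError("composition entries must be positive")

    @property
    def n_states(self) -> int:
        return self.comps.shape[1]

    def node_comp(self, node_id: int) -> np.ndarray:
        return self.comps[self.node_assignment[node_id]]

    def copy(self) -> "PhyloModel":
        return PhyloModel(
            tree=self.tree.copy(),
            comp_mode=self.comp_mode,
            comps=self.comps.copy(),
            node_assignment=self.node_assignment.copy(),
            exch=self.exch.copy(),
            rates=RateModel(self.rates.alpha, self.rates.n_categories),
        )

    @classmethod
    def cv1(
        cls,
        tree: Tree,
        comp: np.ndarray,
        exch: np.ndarray,
        alpha: float = 1e6,
        n_categories: int = 4,
    ) -> "PhyloModel":
        return cls(
            tree=tree,
            comp_mode="CV1",
            comps=np.atleast_2d(comp),
            node_assignment=np.zeros(tree.n_nodes, dtype=int),
            exch=np.asarray(exch, dtype=float),
            rates=RateModel(alpha, n_categories),
        )

    @classmethod
    def ndch2(
        cls,
        tree: Tree,
        node_comps: np.ndarray,
        exch: np.ndarray,
        alpha: float = 1e6,
        n_categories: int = 4,
    ) -> "PhyloModel":
        return cls(
            tree=tree,
            comp_mode="NDCH2",
            comps=np.asarray(node_comps, dtype=float),
            node_assignment=np.arange(tree.n_nodes, dtype=int),
            exch=np.asarray(exch, dtype=float),
            rates=RateModel(alpha, n_categories),
        )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def compress_patterns(a: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique site columns and their multiplicities (cached per alignment)."""
    cached = getattr(a, "_pattern_cache", None)
    if cached is not None and cached[0] is a.matrix:
        return cached[1], cached[2]
    cols = a.matrix.T
    view = np.array(["".join(c) for c in cols])
    patterns, counts = np.unique(view, return_counts=True)
    a._pattern_cache = (a.matrix, patterns, counts)
    return patterns, counts


def _leaf_indicators(
    patterns: np.ndarray, a: Alignment
) -> dict[str, np.ndarray]:
    """taxon -> (n_patterns, n_states) partial-likelihood indicators."""
    cached = getattr(a, "_indicator_cache", None)
    if cached is not None and cached[0] is a.matrix:
        return cached[1]
    taxon_pos = {t: i for i, t in enumerate(a.taxa)}
    code_vec = {
        c: a.alphabet.indicator(c)
        for c in np.unique(a.matrix)
    }
    out = {}
    for t, i in taxon_pos.items():
        arr = np.empty((len(patterns), a.alphabet.n_states))
        for pi, pat in enumerate(patterns):
            arr[pi] = code_vec[pat[i]]
        out[t] = arr
    a._indicator_cache = (a.matrix, out)
    return out


def log_likelihood(a: Alignment, m: PhyloModel) -> float:
    """Felsenstein pruning likelihood under the per-node composition model.

    The branch above each node uses the rate matrix built from that
    node's composition; the root's composition is the prior over root
    states.  The gamma mixture is averaged with equal category weights,
    ambiguity codes enter as partial indicators, and per-pattern scaling
    guards against underflow.  The value is independent of site order.
    """
    leaf_names = set(m.tree.leaf_names())
    if leaf_names != set(a.taxa):
        raise ValueError("tree leaves do not match alignment taxa")
    if m.n_states != a.alphabet.n_states:
        raise ValueError("model dimension does not match alphabet")
    for n in m.tree.nodes:
        if n.parent is not None and not (np.isfinite(n.length) and n.length >= 0):
            raise ValueError(f"invalid branch length on node {n.id}")

    patterns, counts = compress_patterns(a)
    indicators = _leaf_indicators(patterns, a)
    rates = m.rates.rates
    ncat = len(rates)
    npat = len(patterns)
    ns = m.n_states

    # one eigendecomposition per distinct composition vector
    decomps = {}
    for vi in np.unique(m.node_assignment):
        decomps[vi] = _symmetric_decomposition(m.exch, m.comps[vi])

    post = m.tree.postorder()
    partial = {}  # node id -> (ncat, npat, ns)
    logscale = np.zeros(npat)
    for node in post:
        if node.is_leaf:
            partial[node.id] = np.broadcast_to(
                indicators[node.name], (ncat, npat, ns)
            )
            continue
        acc = np.ones((ncat, npat, ns))
        for child in node.children:
            dec = decomps[m.node_assignment[child.id]]
            ps = np.stack(
                [transition_matrix(dec, child.length, r) for r in rates]
            )  # (ncat, ns, ns)
            lifted = np.einsum("cab,cpb->cpa", ps, partial[child.id])
            acc = acc * lifted
        # per-pattern rescale
        mx = acc.max(axis=(0, 2))
        mx = np.where(mx > 0, mx, 1.0)
        acc = acc / mx[None, :, None]
        logscale += np.log(mx)
        partial[node.id] = acc

    root_pi = m.node_comp(m.tree.root.id)
    site_l = np.einsum("cps,s->p", partial[m.tree.root.id], root_pi) / ncat
    if np.any(site_l <= 0):
        return -np.inf
    return float(np.sum(counts * (np.log(site_l) + logscale)))
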