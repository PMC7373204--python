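"""Matched-pairs tests of model-process homogeneity between sequences.

For two aligned sequences, the m x m divergence matrix N counts sites by
their joint state pair.  Three chi-square tests interrogate it:

* Bowker's test of symmetry — the omnibus test of model-process
  homogeneity between the two lineages;
* Stuart's test of marginal homogeneity — sensitive to compositional
  non-stationarity (different state frequencies in the two lineages);
* Ababneh's test of internal symmetry — the Bowker minus Stuart
  component, signalling rate-homogeneity violation.

When Stuart's covariance matrix is nonsingular and every off-diagonal
Bowker cell is populated, Bowker = Stuart + Ababneh with additive
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .seqio import Alignment

__all__ = [
    "DivergenceMatrix",
    "TestResult",
    "MatchedPairsResult",
    "divergence_matrix",
    "bowker",
    "stuart",
    "ababneh",
    "matched_pairs_tests",
    "all_pairs_tests",
]

# singular values below RANK_TOL * s_max are treated as zero in Stuart's test
RANK_TOL = 1e-10


@dataclass
class DivergenceMatrix:
    """Joint state-pair counts for one ordered taxon pair.

    Only sites where both sequences carry a canonical (unambiguous,
    non-gap) state contribute; ``n_effective`` is the number of such
    sites.
    """

    pair: tuple[str, str]
    counts: np.ndarray  # (m, m) integer
    n_effective: int
    n_excluded: int

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def empty(self) -> bool:
        return self.n_effective == 0

    def transpose(self) -> "DivergenceMatrix":
        return DivergenceMatrix(
            pair=(self.pair[1], self.pair[0]),
            counts=self.counts.T.copy(),
            n_effective=self.n_effective,
            n_excluded=self.n_excluded,
        )


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    degenerate: bool = False

    def astuple(self) -> tuple[float, int, float]:
        return (self.statistic, self.df, self.p)


@dataclass
class MatchedPairsResult:
    pair: tuple[str, str]
    bowker: TestResult
    stuart: TestResult
    ababneh: TestResult


def divergence_matrix(a: Alignment, i: int | str, j: int | str) -> DivergenceMatrix:
    """Tally joint canonical states of taxa ``i`` and ``j``.

    Sites with any gap, missing or ambiguity code in either sequence are
    excluded (integer count semantics are kept intact).
    """
    ti = a.taxon_index(i) if isinstance(i, str) else i
    tj = a.taxon_index(j) if isinstance(j, str) else j
    if ti == tj:
        raise ValueError("need two distinct taxa")
    states = a.alphabet.states
    m = len(states)
    lut = np.full(128, -1, dtype=np.int8)
    for k, s in enumerate(states):
        lut[ord(s)] = k
    ri = lut[a.matrix[ti].view(np.uint32).astype(np.int64) & 0x7F]
    rj = lut[a.matrix[tj].view(np.uint32).astype(np.int64) & 0x7F]
    mask = (ri >= 0) & (rj >= 0)
    counts = np.zeros((m, m), dtype=np.int64)
    np.add.at(counts, (ri[mask], rj[mask]), 1)
    return DivergenceMatrix(
        pair=(a.taxa[ti], a.taxa[tj]),
        counts=counts,
        n_effective=int(mask.sum()),
        n_excluded=int((~mask).sum()),
    )


def bowker(d: DivergenceMatrix, fixed_df: bool = False) -> TestResult:
    """Bowker's chi-square test of divergence-matrix symmetry.

    The statistic sums (n_ab - n_ba)^2 / (n_ab + n_ba) over unordered
    state pairs a < b.  By default the degrees of freedom count only
    pairs with n_ab + n_ba > 0 (terms with an undefined contribution are
    dropped); ``fixed_df=True`` uses m(m-1)/2 regardless.
    """
    if d.empty:
        raise ValueError("empty divergence matrix")
    n = d.counts.astype(float)
    iu = np.triu_indices(d.m, k=1)
    s = n[iu] + n.T[iu]
    nonzero = s > 0
    stat = float(np.sum((n[iu][nonzero] - n.T[iu][nonzero]) ** 2 / s[nonzero]))
    df = int(d.m * (d.m - 1) // 2) if fixed_df else int(nonzero.sum())
    if df == 0:
        return TestResult(0.0, 0, 1.0, degenerate=True)
    return TestResult(stat, df, float(chi2.sf(stat, df)))


def stuart(d: DivergenceMatrix) -> TestResult:
    """Stuart's chi-square test of marginal homogeneity.

    With u the first m-1 entries of (row sums - column sums) and V the
    covariance matrix V_aa = row_a + col_a - 2 n_aa,
    V_ab = -(n_ab + n_ba), the statistic is u' V^- u with a
    Moore-Penrose generalized inverse; degrees of freedom equal
    rank(V).
    """
    if d.empty:
        raise ValueError("empty divergence matrix")
    n = d.counts.astype(float)
    m = d.m
    rows = n.sum(axis=1)
    cols = n.sum(axis=0)
    u = (rows - cols)[: m - 1]
    sym = n + n.T
    V = -sym[: m - 1, : m - 1].copy()
    np.fill_diagonal(V, (rows + cols - 2 * np.diag(n))[: m - 1])
    svals = np.linalg.svd(V, compute_uv=False)
    smax = svals[0] if svals.size else 0.0
    rank = int(np.sum(svals > RANK_TOL * max(smax, 1.0)))
    if rank == 0:
        return TestResult(0.0, 0, 1.0, degenerate=True)
    Vinv = np.linalg.pinv(V, rcond=RANK_TOL)
    stat = float(u @ Vinv @ u)
    stat = max(stat, 0.0)
    return TestResult(stat, rank, float(chi2.sf(stat, rank)))


def ababneh(d: DivergenceMatrix, fixed_df: bool = False) -> TestResult:
    """Ababneh's test of internal symmetry: Bowker minus Stuart.

    Degenerate (df <= 0, e.g. two-state data) results carry statistic 0
    and p = 1.
    """
    b = bowker(d, fixed_df=fixed_df)
    s = stuart(d)
    df = b.df - s.df
    stat = max(0.0, b.statistic - s.statistic)
    if df <= 0:
        return TestResult(0.0, max(df, 0), 1.0, degenerate=True)
    return TestResult(stat, df, float(chi2.sf(stat, df)))


def matched_pairs_tests(
    d: DivergenceMatrix, fixed_df: bool = False
) -> MatchedPairsResult:
    return MatchedPairsResult(
        pair=d.pair,
        bowker=bowker(d, fixed_df=fixed_df),
        stuart=stuart(d),
        ababneh=ababneh(d, fixed_df=fixed_df),
    )


def all_pairs_tests(
    a: Alignment, alpha: float = 0.05, fixed_df: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Run all three tests over every unordered taxon pair.

    Returns a table with one row per pair (n·(n−1)/2 rows) and a summary
    with counts and percentages of p < alpha per test.  The table's
    p-value columns are the input for rejection plots.
    """
    if a.n_taxa < 2:
        raise ValueError("need at least two taxa")
    rows = []
    for i, j in combinations(range(a.n_taxa), 2):
        d = divergence_matrix(a, i, j)
        if d.empty:
            rows.append(
                {
                    "taxon_i": a.taxa[i],
                    "taxon_j": a.taxa[j],
                    "n_effective": 0,
                    **{
                        f"{t}_{f}": np.nan
                        for t in ("bowker", "stuart", "ababneh")
                        for f in ("stat", "df", "p")
                    },
                }
            )
            continue
        r = matched_pairs_tests(d, fixed_df=fixed_df)
        rows.append(
            {
                "taxon_i": a.taxa[i],
                "taxon_j": a.taxa[j],
                "n_effective": d.n_effective,
                "bowker_stat": r.bowker.statistic,
                "bowker_df": r.bowker.df,
                "bowker_p": r.bowker.p,
                "stuart_stat": r.stuart.statistic,
                "stuart_df": r.stuart.df,
                "stuart_p": r.stuart.p,
                "ababneh_stat": r.ababneh.statistic,
                "ababneh_df": r.ababneh.df,
                "ababneh_p": r.ababneh.p,
            }
        )
    table = pd.DataFrame(rows)
    n_pairs = len(table)
    summary = {"n_pairs": n_pairs, "alpha": alpha}
    for t in ("bowker", "stuart", "ababneh"):
        k = int((table[f"{t}_p"] < alpha).sum())
        summary[t] = {"n_rejected": k, "pct_rejected": 100.0 * k / n_pairs}
    return table, summary


def plot_pvalues(table: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Scatter of per-pair p-values for the three tests (one panel each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    for ax, t in zip(axes, ("bowker", "stuart", "ababneh")):
        p = table[f"{t}_p"].to_numpy()
        ax.scatter(np.arange(len(p)), p, s=6, alpha=0.6)
        ax.axhline(alpha, color="red", lw=0.8, ls="--")
        ax.set_title(t.capitalize())
        ax.set_xlabel("taxon pair")
        ax.set_yscale("symlog", linthresh=1e-12)
    axes[0].set_ylabel("p-value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
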