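"""Order-statistic test for non-random mutational clustering on a line.

Given a protein with ``N`` available positions and ``n`` mutations, the
null model puts each mutation independently and uniformly on
``{1..N}``.  Collapsing mutations across samples yields order statistics
``X(1) <= ... <= X(n)``; a pair ``(X(i), X(k))`` is called clustered when
its span ``C_ki = X(k) - X(i)`` is improbably small under the null.

The span probability is approximated through the continuous limit

    Pr(C_ki / N <= c) = Pr(Beta(k - i, i + n - k + 1) <= c),

evaluated by default at ``c = (span + 1) / N`` — the right endpoint of
the discrete mass at ``span`` — which keeps same-residue clusters
(span 0) at a finite p-value and upper-bounds the exact discrete
probability.  An exact combinatorial evaluation is provided for
cross-checking at small scale.  All pairs are tested and adjusted with
Bonferroni (default) or Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Mapping

import numpy as np
from scipy.stats import beta as beta_dist
from statsmodels.stats.multitest import multipletests

from .mutations import MutationTable


@dataclass
class OrderStatistics:
    """Sorted mutation positions X(1..n) on a line with N available positions."""

    values: np.ndarray  # (n,) int, nondecreasing
    N: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if len(self.values) == 0:
            raise ValueError("no mutations to test")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("order statistics must be nondecreasing")
        if self.values[0] < 1 or self.values[-1] > self.N:
            raise ValueError(
                f"order statistics must lie in 1..{self.N}, got range "
                f"[{self.values[0]}, {self.values[-1]}]"
            )

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class PairTest:
    """One tested pair of order statistics (1-based indices i < k)."""

    i: int
    k: int
    span: int
    p_value: float
    p_adjusted: float


@dataclass
class Cluster:
    """A significant cluster mapped back to canonical residue numbering."""

    start: int
    end: int
    num_mutations: int
    p_value: float
    p_adjusted: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    alpha: float

    def __len__(self) -> int:
        return len(self.clusters)


def compute_order_statistics(
    table: MutationTable | Mapping[int, int], N: int
) -> OrderStatistics:
    """Expand per-position counts into sorted order statistics.

    ``table`` may be a :class:`MutationTable` or a plain position→count
    mapping, with positions already on the linear scale being tested
    (1..N).
    """
    counts = table.counts if isinstance(table, MutationTable) else dict(table)
    if sum(counts.values()) == 0:
        raise ValueError("no mutations to test")
    values = np.repeat(
        np.fromiter(sorted(counts), dtype=int),
        [counts[p] for p in sorted(counts)],
    )
    return OrderStatistics(values=values, N=N)


def _check_pair(i: int, k: int, n: int, N: int, span: int) -> None:
    if not (1 <= i < k <= n):
        raise ValueError(f"need 1 <= i < k <= n, got i={i}, k={k}, n={n}")
    if not (0 <= span <= N - 1):
        raise ValueError(f"span must be in 0..N-1, got {span} (N={N})")


def pair_pvalue_beta(
    i: int,
    k: int,
    n: int,
    N: int,
    span: int,
    c_convention: str = "span_plus_one",
) -> float:
    """Beta-approximate probability that the (i, k) span is <= ``span``.

    Returns ``Pr(Beta(k - i, i + n - k + 1) <= c)`` with
    ``c = (span + 1) / N`` by default, or ``c = span / N`` under the
    ``"span"`` convention (for sensitivity analysis; that variant is 0 at
    span 0).
    """
    _check_pair(i, k, n, N, span)
    if c_convention == "span_plus_one":
        c = (span + 1) / N
    elif c_convention == "span":
        c = span / N
    else:
        raise ValueError(f"unknown c convention {c_convention!r}")
    return float(beta_dist.cdf(min(c, 1.0), k - i, i + n - k + 1))


@lru_cache(maxsize=100_000)
def _pmf_pair(i: int, k: int, n: int, N: int, a: int, b: int) -> float:
    """Exact Pr(X(i) = a, X(k) = b) for n iid uniform draws on {1..N}."""
    inv_n = 1.0 / N
    p_lo = (a - 1) * inv_n  # values below a
    p_hi = (N - b) * inv_n  # values above b
    total = 0.0
    if a == b:
        # all order statistics i..k sit on value a
        for n1 in range(0, i):  # draws below a, at most i-1
            for n2 in range(k - n1, n - n1 + 1):  # draws equal to a
                n5 = n - n1 - n2
                total += (
                    comb(n, n1)
                    * comb(n - n1, n2)
                    * p_lo**n1
                    * inv_n**n2
                    * p_hi**n5
                )
        return total
    p_mid = (b - a - 1) * inv_n  # values strictly between a and b
    for n1 in range(0, i):
        for n2 in range(1, n - n1):
            if n1 + n2 < i:
                continue
            for n3 in range(0, n - n1 - n2):
                if n1 + n2 + n3 > k - 1:
                    break
                for n4 in range(1, n - n1 - n2 - n3 + 1):
                    if n1 + n2 + n3 + n4 < k:
                        continue
                    n5 = n - n1 - n2 - n3 - n4
                    total += (
                        comb(n, n1)
                        * comb(n - n1, n2)
                        * comb(n - n1 - n2, n3)
                        * comb(n - n1 - n2 - n3, n4)
                        * p_lo**n1
                        * inv_n ** (n2 + n4)
                        * p_mid**n3
                        * p_hi**n5
                    )
    return total


def pair_pvalue_exact(i: int, k: int, n: int, N: int, span: int) -> float:
    """Exact discrete Pr(X(k) - X(i) <= span) under the uniform null.

    Evaluated by summing the exact joint probability mass of
    ``(X(i), X(k))`` over all value pairs with the required span, using
    multinomial counts over the five value regions (below / at / between
    / at / above).  Intended as a small-scale oracle for the Beta
    approximation; cost grows as ~N·span·n³.
    """
    _check_pair(i, k, n, N, span)
    if n > 25 or N > 2000:
        raise ValueError(
            f"exact evaluation infeasible for n={n}, N={N}; "
            "use pair_pvalue_beta"
        )
    total = 0.0
    for a in range(1, N + 1):
        for b in range(a, min(a + span, N) + 1):
            total += _pmf_pair(i, k, n, N, a, b)
    return min(total, 1.0)


def test_all_pairs(
    order_stats: OrderStatistics,
    alpha: float = 0.05,
    method: str = "bonferroni",
    c_convention: str = "span_plus_one",
) -> list[PairTest]:
    """Test every pair of order statistics and adjust for multiplicity.

    All ``n(n-1)/2`` pairs ``i < k`` are tested.  Under Bonferroni the
    raw p-value is multiplied by the number of tested pairs (uncapped,
    so the adjustment can be inverted exactly for the cross-structure
    screen); under BH the Benjamini-Hochberg step-up adjustment is used.
    Pairs sharing ``(span, k - i)`` have identical p-values, computed
    once.
    """
    n, N = order_stats.n, order_stats.N
    if n < 2:
        raise ValueError("at least two mutations required")
    x = order_stats.values
    pairs = [(i, k) for i in range(1, n) for k in range(i + 1, n + 1)]
    cache: dict[tuple[int, int], float] = {}
    raw = np.empty(len(pairs))
    spans = np.empty(len(pairs), dtype=int)
    for idx, (i, k) in enumerate(pairs):
        span = int(x[k - 1] - x[i - 1])
        spans[idx] = span
        key = (span, k - i)
        if key not in cache:
            cache[key] = pair_pvalue_beta(i, k, n, N, span, c_convention)
        raw[idx] = cache[key]
    if method == "bonferroni":
        adjusted = raw * len(pairs)
    elif method == "bh":
        adjusted = multipletests(raw, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return [
        PairTest(i=i, k=k, span=int(s), p_value=float(p), p_adjusted=float(q))
        for (i, k), s, p, q in zip(pairs, spans, raw, adjusted)
    ]


def find_clusters(
    tests: list[PairTest],
    order_stats: OrderStatistics,
    linear_to_canonical: Mapping[int, int],
    counts: Mapping[int, int],
    alpha: float = 0.05,
) -> ClusterSet:
    """Report significant pairs as clusters in canonical numbering.

    ``linear_to_canonical`` maps each occupied linear position back to
    its canonical residue number; ``counts`` are the per-canonical-residue
    mutation counts.  A pair is significant when its adjusted p-value is
    at most ``alpha``; its cluster covers every mutated residue whose
    linear position lies within the pair's span, with start/end reported
    as (min, max) canonical positions.  Overlapping significant pairs are
    reported individually, not merged.
    """
    clusters: list[Cluster] = []
    x = order_stats.values
    for t in sorted(tests, key=lambda t: (t.p_adjusted, t.k - t.i, t.i)):
        if t.p_adjusted > alpha:
            continue
        lo, hi = int(x[t.i - 1]), int(x[t.k - 1])
        residues = [
            linear_to_canonical[p]
            for p in linear_to_canonical
            if lo <= p <= hi and counts.get(linear_to_canonical[p], 0) > 0
        ]
        if not residues:
            continue
        start, end = min(residues), max(residues)
        num = sum(counts[r] for r in residues)
        clusters.append(
            Cluster(
                start=start,
                end=end,
                num_mutations=num,
                p_value=t.p_value,
                p_adjusted=t.p_adjusted,
            )
        )
    return ClusterSet(clusters=clusters, alpha=alpha)


def min_adjusted_pvalues(
    positions: np.ndarray, N: int, c_convention: str = "span_plus_one"
) -> np.ndarray:
    """Bonferroni-adjusted minimum pair p-value per row of positions.

    Vectorized over replicates: ``positions`` is an (R, n) integer array
    of mutation positions (one simulation replicate per row).  Used by
    the Monte-Carlo calibration machinery; agrees with running
    :func:`test_all_pairs` row by row.
    """
    pos = np.sort(np.asarray(positions, dtype=int), axis=1)
    r, n = pos.shape
    if n < 2:
        raise ValueError("at least two mutations required")
    m = n * (n - 1) // 2
    best = np.full(r, np.inf)
    shift = 1 if c_convention == "span_plus_one" else 0
    for i in range(1, n):
        for k in range(i + 1, n + 1):
            c = np.minimum((pos[:, k - 1] - pos[:, i - 1] + shift) / N, 1.0)
            p = beta_dist.cdf(c, k - i, i + n - k + 1)
            np.minimum(best, p, out=best)
    return best * m
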