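"""Overlap enrichment between a hit list and an annotation gene set.

Builds the 2x2 contingency table hits/non-hits x annotated/not over a
common gene universe and reports overlap percentages, the odds ratio, and
an exact hypergeometric (Fisher) p value.  The annotated count K is taken
over the whole universe, hits included, so the annotated-non-hit cell is
K - k.

The two-sided p is computed by exact rational arithmetic: the sum of the
hypergeometric probabilities of every table (with the observed margins)
whose probability does not exceed the observed table's.  This keeps the
result free of floating-point tie artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable


def fisher_exact_p(k: int, n: int, K: int, N: int, alternative: str = "two-sided") -> float:
    """Exact hypergeometric p for observing k annotated among n draws,
    given K annotated in a universe of N.

    ``two-sided`` sums all tables at most as probable as the observed one;
    ``greater``/``less`` are the upper/lower tails (enrichment/depletion).
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent table: k={k}, n={n}, K={K}, N={N}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    weights = {j: math.comb(K, j) * math.comb(N - K, n - j) for j in range(lo, hi + 1)}
    denom = math.comb(N, n)
    if alternative == "two-sided":
        num = sum(w for w in weights.values() if w <= weights[k])
    elif alternative == "greater":
        num = sum(w for j, w in weights.items() if j >= k)
    elif alternative == "less":
        num = sum(w for j, w in weights.items() if j <= k)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(Fraction(num, denom))


@dataclass
class OverlapResult:
    """2x2 overlap of a hit list with an annotation set over a universe.

    k hits are annotated, out of n hits; K genes of the N-gene universe are
    annotated (K counts hits too, so the annotated-non-hit cell is K - k).
    """

    k: int
    n: int
    K: int
    N: int
    fisher_p: float
    odds_ratio: float
    alternative: str = "two-sided"

    @property
    def pct_hits(self) -> float:
        return 100.0 * self.k / self.n

    @property
    def pct_universe(self) -> float:
        return 100.0 * self.K / self.N

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.k, self.n - self.k],
            [self.K - self.k, self.N - self.n - self.K + self.k],
        ]

    def summary(self) -> str:
        orr = "NA" if math.isnan(self.odds_ratio) else f"{self.odds_ratio:.3g}"
        return (
            f"{self.k}/{self.n} hits annotated ({self.pct_hits:.1f}%) vs "
            f"{self.K}/{self.N} in the universe ({self.pct_universe:.1f}%); "
            f"odds ratio {orr}, exact {self.alternative} p = {self.fisher_p:.3g} "
            f"(test statistic is an extension beyond the reported percentages)"
        )


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    num = k * (N - n - K + k)
    den = (n - k) * (K - k)
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def overlap_result_from_counts(
    k: int, n: int, K: int, N: int, alternative: str = "two-sided"
) -> OverlapResult:
    """Build an :class:`OverlapResult` directly from the four counts."""
    if N <= 0 or n <= 0:
        raise ValueError("empty universe or hit list")
    return OverlapResult(
        k=k,
        n=n,
        K=K,
        N=N,
        fisher_p=fisher_exact_p(k, n, K, N, alternative),
        odds_ratio=_odds_ratio(k, n, K, N),
        alternative=alternative,
    )


def overlap_enrichment(
    hits: Iterable[str],
    annotation: Iterable[str],
    universe: Iterable[str],
    alternative: str = "two-sided",
) -> OverlapResult:
    """Overlap enrichment of ``hits`` in ``annotation`` over ``universe``.

    Hits must lie within the universe; the annotation is intersected with
    the universe before counting.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe or not hits:
        raise ValueError("empty universe or hit list")
    if not hits <= universe:
        extra = sorted(hits - universe)[:3]
        raise ValueError(f"hits outside the universe, e.g. {extra}")
    annotation = set(annotation) & universe
    k = len(hits & annotation)
    return overlap_result_from_counts(
        k, len(hits), len(annotation), len(universe), alternative
    )


def read_gene_list(path: str | Path) -> set[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes
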