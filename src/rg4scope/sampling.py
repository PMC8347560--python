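"""Expression-level group comparisons and the repeated-sampling test.

The headline comparison asks whether transcripts carrying a folded G4 in
their 3'-UTR are expressed higher than the rest.  Beyond a single
one-sided Wilcoxon rank-sum test, a simple-random-sampling procedure
repeats the comparison 10,000 times against random transcript sets of
equal size drawn from the pool, reporting the per-round p-values and the
number of rounds significant at 0.05.

Note on the round design: each round compares the fixed focal group
against a fresh random subset of the pool, drawn without replacement,
of size equal to the smaller of the two groups.  A literal mode that
samples ``len(group)`` items from the pool *with* replacement is
available for users who want the textbook-pseudocode reading even when
the pool is smaller than the group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SamplingResult",
    "filter_expressed",
    "group_compare",
    "random_sampling_test",
]


@dataclass
class SamplingResult:
    """Per-round p-values of the repeated sampling procedure."""

    P: np.ndarray
    n_significant: int
    n_group: int
    n_pool: int
    seed: int | None
    alpha: float = 0.05

    @property
    def n_rounds(self) -> int:
        return len(self.P)

    @property
    def frac_significant(self) -> float:
        return self.n_significant / self.n_rounds


def filter_expressed(
    expression: Mapping[str, float], threshold: float = 1.0
) -> set[str]:
    """Transcripts with expression strictly greater than the threshold."""
    return {tid for tid, v in expression.items() if v > threshold}


def group_compare(
    group_values: Sequence[float], other_values: Sequence[float]
) -> float:
    """One-sided Wilcoxon rank-sum p (alternative: group > other).

    Normal approximation with tie and continuity correction.
    """
    if len(group_values) == 0 or len(other_values) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        group_values, other_values, alternative="greater", method="asymptotic"
    )
    return float(res.pvalue)


def random_sampling_test(
    group_values: Sequence[float],
    pool_values: Sequence[float],
    n_rounds: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    pseudocode_literal: bool = False,
) -> SamplingResult:
    """Repeat group_compare against random equal-size pool subsets.

    Each round draws, without replacement, ``min(len(group), len(pool))``
    values from the larger of the two sets and tests group > drawn-set.
    With ``pseudocode_literal=True`` the round instead draws
    ``len(group)`` values from the pool with replacement.
    """
    group = np.asarray(group_values, dtype=float)
    pool = np.asarray(pool_values, dtype=float)
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 values")
    if len(group) == 0:
        raise ValueError("group must be non-empty")

    rng = np.random.default_rng(seed)
    k = min(len(group), len(pool))
    P = np.empty(n_rounds)
    for i in range(n_rounds):
        if pseudocode_literal:
            a = group
            b = rng.choice(pool, size=len(group), replace=True)
        else:
            a = group if len(group) == k else rng.choice(group, size=k, replace=False)
            b = pool if len(pool) == k else rng.choice(pool, size=k, replace=False)
        P[i] = group_compare(a, b)

    n_sig = int((P < alpha).sum())
    return SamplingResult(
        P=P,
        n_significant=n_sig,
        n_group=len(group),
        n_pool=len(pool),
        seed=seed,
        alpha=alpha,
    )
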