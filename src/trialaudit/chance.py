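"""Exact chance-level assessment of classification accuracy.

A decoder that gets k of n trials right has not demonstrated communication
unless k is improbably large under Binomial(n, chance).  At the small trial
counts typical of patient studies the exact tail matters: 8/10 correct
(80%!) gives p = 0.0547 against chance 0.5 and is *not* significant at
alpha = 0.05.  These are exact tail sums — no normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class ChanceTestResult:
    """Exact binomial assessment of k correct out of n trials."""

    k: int
    n: int
    chance: float
    alpha: float
    p_value: float  # one-sided P[X >= k] by default; see `alternative`
    ci: tuple[float, float]  # two-sided Clopper-Pearson interval at 1 - alpha
    alternative: str = "greater"

    @property
    def accuracy(self) -> float:
        return self.k / self.n

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> str:
        verdict = "significant" if self.significant else "NOT significant"
        return (
            f"accuracy {self.k}/{self.n} = {self.accuracy:.1%} vs chance {self.chance:.1%}: "
            f"p = {self.p_value:.4g} ({self.alternative}), {verdict} at alpha = {self.alpha:g}; "
            f"{1 - self.alpha:.0%} CI [{self.ci[0]:.3f}, {self.ci[1]:.3f}]"
        )


def accuracy_binomial_test(
    k: int,
    n: int,
    chance: float = 0.5,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> ChanceTestResult:
    """Exact binomial test of a classifier accuracy against chance.

    ``alternative="greater"`` (default) tests the scientific claim "above
    chance": p = P[X >= k] under X ~ Binomial(n, chance).  The reported CI
    is the two-sided Clopper-Pearson interval at level 1 - alpha.
    """
    if not isinstance(k, (int,)) or not isinstance(n, (int,)):
        raise ValueError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < chance < 1.0:
        raise ValueError(f"chance must lie in (0, 1), got {chance}")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    test = stats.binomtest(k, n, chance, alternative=alternative)
    ci = stats.binomtest(k, n, chance, alternative="two-sided").proportion_ci(
        confidence_level=1.0 - alpha, method="exact"
    )
    return ChanceTestResult(
        k=k,
        n=n,
        chance=chance,
        alpha=alpha,
        p_value=float(test.pvalue),
        ci=(float(ci.low), float(ci.high)),
        alternative=alternative,
    )


def min_trials_for_significance(
    target_accuracy: float,
    chance: float = 0.5,
    alpha: float = 0.05,
    max_n: int = 100_000,
) -> int:
    """Smallest n at which accuracy = target is significantly above chance.

    For each n the correct count is k = ceil(target_accuracy * n); returns
    the first n with P[X >= k] < alpha under Binomial(n, chance).  E.g. a
    perfect decoder against chance 0.5 needs n = 5 (p = 1/32); an 80%
    decoder needs more.
    """
    if not 0.0 < chance < 1.0:
        raise ValueError(f"chance must lie in (0, 1), got {chance}")
    if not chance < target_accuracy <= 1.0:
        raise ValueError(
            f"target accuracy must exceed chance ({chance}) and be <= 1, got {target_accuracy}"
        )
    for n in range(1, max_n + 1):
        k = math.ceil(target_accuracy * n - 1e-9)  # guard against float fuzz in the product
        if k > n:
            continue
        if stats.binomtest(k, n, chance, alternative="greater").pvalue < alpha:
            return n
    raise RuntimeError(f"no n <= {max_n} reaches significance; increase max_n")
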