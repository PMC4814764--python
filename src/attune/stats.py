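"""Monte Carlo permutation tests, effect sizes, and permutation correlations.

All tests use plain mean differences as the statistic and report add-one
corrected p-values, ``p = (1 + #{null >= observed}) / (1 + n_perm)``, so
p is always in (0, 1] and bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

Sided = Literal["greater", "less", "two"]


@dataclass(frozen=True)
class PermTestResult:
    observed: float
    p_value: float
    n_perm: int
    sided: Sided
    seed: int | None = None


@dataclass(frozen=True)
class EffectSize:
    d: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    stars: str


def _clean(x: Sequence[float]) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return a[~np.isnan(a)]


def _tail_count(null: np.ndarray, observed: float, sided: Sided) -> int:
    if sided == "greater":
        return int(np.count_nonzero(null >= observed))
    if sided == "less":
        return int(np.count_nonzero(null <= observed))
    if sided == "two":
        return int(np.count_nonzero(np.abs(null) >= abs(observed)))
    raise ValueError(f"unknown sidedness {sided!r}")


def _p_value(null: np.ndarray, observed: float, sided: Sided, n_perm: int) -> float:
    return (1 + _tail_count(null, observed, sided)) / (1 + n_perm)


def perm_test_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    sided: Sided = "greater",
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermTestResult:
    """Group-label permutation test of ``mean(a) - mean(b)``.

    The null distribution reshuffles group labels over the pooled values
    ``n_perm`` times. NaNs are dropped beforehand.
    """
    a, b = _clean(a), _clean(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[: a.size].mean() - perm[a.size :].mean()
    return PermTestResult(observed, _p_value(null, observed, sided, n_perm), n_perm, sided, seed)


def perm_test_paired(
    x: Sequence[float],
    y: Sequence[float],
    sided: Sided = "greater",
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermTestResult:
    """Sign-flip permutation test of the mean within-pair difference x - y.

    Pairs with a missing member are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"paired samples must have equal length ({x.size} vs {y.size})")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = (x - y)[keep]
    if d.size == 0:
        raise ValueError("no complete pairs")
    observed = float(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = (signs * d).mean(axis=1)
    return PermTestResult(observed, _p_value(null, observed, sided, n_perm), n_perm, sided, seed)


def perm_test_vs_value(
    x: Sequence[float],
    ref: float,
    sided: Sided = "greater",
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermTestResult:
    """Sign-flip permutation test of ``mean(x) - ref``.

    Deviations ``x - ref`` are randomly sign-flipped to build the null.
    """
    d = _clean(x) - ref
    if d.size == 0:
        raise ValueError("x must be nonempty")
    observed = float(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = (signs * np.abs(d)).mean(axis=1)
    return PermTestResult(observed, _p_value(null, observed, sided, n_perm), n_perm, sided, seed)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> EffectSize:
    """Cohen's d: the observed mean difference divided by the pooled SD.

    Pooled SD uses n-1 group variances; NaN when the pooled SD is 0.
    """
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    s_pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if s_pooled == 0:
        return EffectSize(float("nan"))
    return EffectSize(float((a.mean() - b.mean()) / s_pooled))


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 1000,
    seed: int | None = None,
) -> CorrelationResult:
    """Pearson correlation with a two-sided permutation p-value.

    Missing values are pairwise-deleted; the null shuffles y. Stars mark
    p < 0.05 (*) and p < 0.01 (**).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, have {x.size}")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
    p = _p_value(null, r, "two", n_perm)
    return CorrelationResult(r=r, n=int(x.size), p_value=p, stars=_stars(p))


def agreement_perm_test(
    codes_a: Sequence,
    codes_b: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermTestResult:
    """Inter-rater agreement (percent identical positions) versus shuffles.

    One sequence is shuffled ``n_perm`` times; p is the add-one corrected
    fraction of shuffles agreeing at least as well as observed.
    """
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    if a.size != b.size:
        raise ValueError(f"sequences must have equal length ({a.size} vs {b.size})")
    if a.size == 0:
        raise ValueError("sequences must be nonempty")
    observed = 100.0 * float(np.mean(a == b))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = 100.0 * np.mean(a == rng.permutation(b))
    return PermTestResult(
        observed, _p_value(null, observed, "greater", n_perm), n_perm, "greater", seed
    )
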