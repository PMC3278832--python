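"""Significance machinery: exact binomial tail and the permutation null.

Two questions are answered here.  First, is the *number* of monochromatic
complexes larger than chance?  Under the null each complex is
monochromatic with probability 1/2, so the count is Bin(n, 0.5) and the
upper tail P(X >= x) is computed with exact integer arithmetic.  Second,
is the *observed MCI (or sMCI)* larger than expected given the background?
The null replaces each cluster's contents with interactions drawn at
random from the screened pool while keeping every cluster size fixed;
the observed statistic is compared with the replicate distribution via an
empirical upper-tail p-value and a z-score (observed - mean) / std.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .clusters import ClusterSet
from .interactions import InteractionSet


@dataclass(frozen=True)
class BinomialTestResult:
    n: int
    x: int
    p_value: float


def binom_upper_tail(n: int, x: int) -> float:
    """Exact P(X >= x) for X ~ Bin(n, 1/2), via integer combinatorics."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must lie in [0, n]; got x={x}, n={n}")
    hits = sum(math.comb(n, k) for k in range(x, n + 1))
    return hits / (1 << n)


def binomial_test(n: int, x: int) -> BinomialTestResult:
    return BinomialTestResult(n, x, binom_upper_tail(n, x))


def z_score(observed: float, mean: float, std: float) -> float:
    """Standardized distance of the observed statistic from the null mean."""
    if std <= 0:
        raise ValueError("z-score undefined for std <= 0")
    return (observed - mean) / std


@dataclass(frozen=True)
class NullDistribution:
    """Permutation replicates of a statistic plus their summary."""

    values: np.ndarray
    b: int
    seed: int
    statistic: str
    observed: float
    mean: float
    std: float
    z: float  # NaN when the null is degenerate (zero variance)
    empirical_p: float
    display_p: str

    @property
    def z_defined(self) -> bool:
        return not math.isnan(self.z)


def empirical_p(observed: float, values: np.ndarray,
                add_one: bool = False) -> tuple[float, str]:
    """Upper-tail proportion of null values >= observed.

    Ties count against significance.  When no replicate reaches the
    observed value the display string reports the resolution bound
    ``< 1/b``; with ``add_one`` the (r + 1)/(b + 1) estimator is used and
    the display is always numeric.
    """
    values = np.asarray(values, dtype=float)
    b = len(values)
    if b < 1:
        raise ValueError("empirical p needs at least one replicate")
    r = int((values >= observed).sum())
    if add_one:
        p = (r + 1) / (b + 1)
        return p, f"{p:g}"
    p = r / b
    return p, (f"< {1 / b:g}" if r == 0 else f"{p:g}")


def _null_statistics(signs: np.ndarray, eps: np.ndarray, sizes: np.ndarray,
                     statistic: str) -> float:
    offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    if statistic == "mci":
        sums = np.add.reduceat(signs, offsets)
        return float(np.abs(sums).sum() / sizes.sum())
    # smci: weighted mean of per-cluster |sum eps| / sum |eps|
    num = np.abs(np.add.reduceat(eps, offsets))
    den = np.add.reduceat(np.abs(eps), offsets)
    return float((sizes * (num / den)).sum() / sizes.sum())


def permutation_null(clusters: ClusterSet, pool: InteractionSet,
                     b: int = 1000, seed: int = 0, statistic: str = "mci",
                     with_replacement: bool = False,
                     per_cluster: bool = False,
                     add_one: bool = False) -> NullDistribution:
    """Permutation null for MCI or sMCI with cluster sizes held fixed.

    Each replicate draws ``sum_i n_i`` interactions from ``pool`` —
    jointly without replacement by default (a true relabeling), or
    independently per cluster / with replacement behind flags — partitions
    them into pseudo-clusters matching the observed size multiset, and
    recomputes the statistic.

    The returned distribution is bit-reproducible for a fixed seed.  A
    degenerate pool (zero null variance) yields ``z = NaN``.
    """
    if statistic not in ("mci", "smci"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    if b < 1:
        raise ValueError("b must be >= 1")
    sizes = clusters.sizes
    total = int(sizes.sum())
    n_pool = len(pool)
    if not with_replacement and n_pool < total:
        raise ValueError(
            f"pool of {n_pool} interactions cannot fill clusters totalling "
            f"{total}; pass with_replacement=True to sample with replacement"
        )

    from .scores import score_population  # local import avoids a cycle

    pop = score_population(clusters)
    observed = pop.mci if statistic == "mci" else pop.smci

    pool_eps = pool.epsilons
    pool_signs = np.where(pool_eps > 0, 1, -1)
    rng = np.random.default_rng(seed)
    values = np.empty(b, dtype=float)
    for rep in range(b):
        if per_cluster:
            idx = np.concatenate([
                rng.choice(n_pool, size=int(n), replace=with_replacement)
                for n in sizes
            ])
        else:
            idx = rng.choice(n_pool, size=total, replace=with_replacement)
        values[rep] = _null_statistics(pool_signs[idx], pool_eps[idx],
                                       sizes, statistic)

    mean = float(values.mean())
    std = float(values.std(ddof=1)) if b > 1 else 0.0
    z = (observed - mean) / std if std > 0 else math.nan
    p, display = empirical_p(observed, values, add_one=add_one)
    return NullDistribution(values=values, b=b, seed=seed, statistic=statistic,
                            observed=observed, mean=mean, std=std, z=z,
                            empirical_p=p, display_p=display)
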