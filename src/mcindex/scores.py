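"""Monochromaticity statistics: beta, MCI, sMCI and the MP-score.

For a cluster with ``n_pos`` positive and ``n_neg`` negative interactions,

    beta = (n_pos - n_neg) / (n_pos + n_neg)        in [-1, 1].

|beta| = 1 means a pure (monochromatic) cluster; |beta| = 0 an exactly
balanced one.  The monochromatic index of a cluster population is the
interaction-count-weighted mean of |beta|,

    MCI = sum_i n_i |beta_i| / sum_i n_i            in [0, 1],

so large clusters count for more, reflecting their higher reliability.
The strength-based variant (sMCI) replaces the count purity with the
epsilon-magnitude purity |sum_j eps_j| / sum_j |eps_j| per cluster.

The MP-score is an earlier per-complex purity measure that adjusts for the
background sign ratio.  Its published algebraic form is not recoverable
from available text, so this module implements a reconstruction satisfying
its stated contract: +1 for an all-positive complex, -1 for all-negative,
0 when the complex matches the background positive fraction, monotone in
the cluster's positive fraction, classified monochromatic when |MP| > 0.5
(strict).  It is kept behind the single function :func:`mp_score` so an
alternative form can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .clusters import Cluster, ClusterSet
from .interactions import BackgroundComposition

_EPS_TOL = 1e-12


def beta(cluster: Cluster) -> float:
    """Signed count purity (n_pos - n_neg) / n_total of one cluster."""
    if cluster.n_total == 0:
        raise ValueError(f"beta of empty cluster {cluster.id}")
    return (cluster.n_positive - cluster.n_negative) / cluster.n_total


def beta_strength(cluster: Cluster) -> float:
    """Signed strength purity sum(eps) / sum(|eps|) of one cluster."""
    eps = cluster.epsilons
    denom = np.abs(eps).sum()
    if denom < _EPS_TOL:
        raise ValueError(
            f"cluster {cluster.id}: all interaction strengths below tolerance"
        )
    return float(eps.sum() / denom)


@dataclass(frozen=True)
class ClusterScore:
    cluster_id: str
    beta: float
    beta_strength: float
    weight: int  # n_total of the cluster

    @property
    def sign(self) -> str:
        if self.beta > 0:
            return "positive"
        if self.beta < 0:
            return "negative"
        return "none"


@dataclass(frozen=True)
class PopulationScore:
    """MCI and sMCI of a cluster population, with per-cluster detail."""

    mci: float
    smci: float
    n_clusters: int
    total_interactions: int
    per_cluster: tuple[ClusterScore, ...]


def score_population(clusters: ClusterSet) -> PopulationScore:
    """Compute MCI and sMCI over a retained cluster population."""
    if len(clusters) == 0:
        raise ValueError("population score of an empty cluster set")
    per = tuple(
        ClusterScore(c.id, beta(c), beta_strength(c), c.n_total)
        for c in clusters
    )
    weights = np.array([s.weight for s in per], dtype=float)
    total = weights.sum()
    mci_val = float(np.abs([s.beta for s in per]) @ weights / total)
    smci_val = float(np.abs([s.beta_strength for s in per]) @ weights / total)
    return PopulationScore(mci_val, smci_val, len(per), int(total), per)


def mci(clusters: ClusterSet) -> PopulationScore:
    """Count-based monochromatic index; see :func:`score_population`."""
    return score_population(clusters)


def smci(clusters: ClusterSet) -> float:
    """Strength-based monochromatic index as a plain value."""
    return score_population(clusters).smci


@dataclass(frozen=True)
class MPResult:
    cluster_id: str
    mp: float
    monochromatic: bool
    direction: str  # "positive" | "negative" | "none"


def mp_score(cluster: Cluster, background: BackgroundComposition) -> MPResult:
    """Background-adjusted purity of one cluster (MP-score reconstruction).

    With f the cluster's positive fraction and f0 the background's:

        mp = (f - f0) / (1 - f0)   if f >= f0
        mp = (f - f0) / f0         otherwise

    Pure clusters score exactly +/-1 regardless of background; a cluster at
    the background ratio scores 0.  A degenerate background (f0 in {0, 1})
    leaves the score undefined except for pure clusters.
    """
    if cluster.n_total == 0:
        raise ValueError(f"MP-score of empty cluster {cluster.id}")
    f = cluster.n_positive / cluster.n_total
    if f == 1.0:
        mp = 1.0
    elif f == 0.0:
        mp = -1.0
    else:
        f0 = background.f_positive
        if f0 in (0.0, 1.0):
            raise ValueError(
                "MP-score undefined: degenerate background with a mixed cluster"
            )
        mp = (f - f0) / (1 - f0) if f >= f0 else (f - f0) / f0
    monochromatic = abs(mp) > 0.5
    direction = "positive" if mp > 0.5 else "negative" if mp < -0.5 else "none"
    return MPResult(cluster.id, mp, monochromatic, direction)


@dataclass(frozen=True)
class MPCounts:
    positive: int
    negative: int
    non_monochromatic: int

    @property
    def monochromatic(self) -> int:
        return self.positive + self.negative

    @property
    def total(self) -> int:
        return self.monochromatic + self.non_monochromatic


def classify_mp(results: Iterable[MPResult]) -> MPCounts:
    """Tally positively / negatively / non-monochromatic complexes."""
    results = list(results)
    pos = sum(r.direction == "positive" for r in results)
    neg = sum(r.direction == "negative" for r in results)
    return MPCounts(pos, neg, len(results) - pos - neg)


@dataclass(frozen=True)
class HighlyMonochromatic:
    """Clusters whose |beta| strictly exceeds the population MCI."""

    members: tuple[ClusterScore, ...]
    n_positive: int
    n_negative: int


def highly_monochromatic(pop: PopulationScore) -> HighlyMonochromatic:
    """Select clusters with |beta| > MCI (strict), labeled by sign."""
    members = tuple(s for s in pop.per_cluster if abs(s.beta) > pop.mci)
    return HighlyMonochromatic(
        members,
        n_positive=sum(s.beta > 0 for s in members),
        n_negative=sum(s.beta < 0 for s in members),
    )
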