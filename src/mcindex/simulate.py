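"""Synthetic genetic-interaction datasets with planted monochromaticity.

The generator emulates an SGA-style screen over a catalog of disjoint
protein complexes: every intra-complex gene pair interacts with
probability ``within_density`` and every inter-complex pair with
``between_density``.  Each cluster (a complex, or a complex pair) is
planted with a majority sign; each of its interactions takes that sign
with probability ``purity``.  Epsilon magnitudes are lognormal with a
configurable median and spread, and p-values are a mixture of a
"significant" component (uniform below 0.05) and a uniform noise
component, so the confidence cutoffs are exercised.

Majority signs are drawn positive with probability

    q = (f_positive - (1 - purity)) / (2 purity - 1)      (clamped to [0,1])

so that the marginal positive fraction of generated interactions matches
``f_positive``; at purity 0.5 the marginal is 0.5 regardless of q.

:func:`expected_mci` is a deliberately simple, independent re-simulation
of the within-complex statistic used as a parameter-recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .clusters import GeneSetCatalog
from .interactions import COLUMNS, InteractionSet


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults give a desk-scale screen."""

    n_complexes: int = 30
    size_min: int = 3
    size_max: int = 8
    within_density: float = 0.6
    between_density: float = 0.1
    purity: float = 0.9          # P(interaction takes its cluster's majority sign)
    f_positive: float = 0.35     # marginal positive fraction of the background
    epsilon_location: float = 0.1  # median |epsilon| (lognormal)
    epsilon_scale: float = 0.6     # lognormal sigma of |epsilon|
    p_sig_weight: float = 0.9    # mixture weight of the p < 0.05 component
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_density", "between_density", "purity",
                     "f_positive", "p_sig_weight"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.size_min > self.size_max:
            raise ValueError("size_min must not exceed size_max")
        if self.size_min < 2:
            raise ValueError("size_min must be >= 2")
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        if self.epsilon_scale <= 0:
            raise ValueError("epsilon_scale must be > 0")
        if self.epsilon_location <= 0:
            raise ValueError("epsilon_location must be > 0")

    @property
    def q_positive_majority(self) -> float:
        """Majority-sign probability matching the target background."""
        if self.purity == 0.5:
            return self.f_positive
        q = (self.f_positive - (1 - self.purity)) / (2 * self.purity - 1)
        return min(1.0, max(0.0, q))


def _draw_interaction_fields(rng: np.random.Generator, n: int, majority: int,
                             params: SimulationParams):
    take_majority = rng.random(n) < params.purity
    signs = np.where(take_majority, majority, -majority)
    mags = params.epsilon_location * np.exp(
        params.epsilon_scale * rng.standard_normal(n)
    )
    significant = rng.random(n) < params.p_sig_weight
    p = np.where(significant, rng.uniform(0, 0.05, n), rng.uniform(0, 1, n))
    return signs * mags, p


def generate(params: SimulationParams
             ) -> tuple[GeneSetCatalog, InteractionSet, pd.DataFrame]:
    """Simulate a complex catalog, an interaction table and its ground truth.

    Returns the catalog, a raw :class:`InteractionSet` (one record per
    unordered pair), and a truth table with one row per realized cluster:
    cluster id, kind, planted majority sign, number of interactions and
    realized sign purity.
    """
    rng = np.random.default_rng(params.seed)
    sizes = rng.integers(params.size_min, params.size_max + 1,
                         size=params.n_complexes)
    names = [f"CPX{i:03d}" for i in range(params.n_complexes)]
    genes: dict[str, list[str]] = {}
    counter = 0
    for name, size in zip(names, sizes):
        genes[name] = [f"G{counter + j:05d}" for j in range(int(size))]
        counter += int(size)
    catalog = GeneSetCatalog({n: frozenset(g) for n, g in genes.items()},
                             kind="complexes")

    q = params.q_positive_majority
    records: list[tuple] = []
    truth: list[dict] = []

    def emit(cluster_id: str, kind: str, pairs: list[tuple[str, str]],
             density: float) -> None:
        hit = rng.random(len(pairs)) < density
        chosen = [p for p, h in zip(pairs, hit) if h]
        majority = 1 if rng.random() < q else -1
        if not chosen:
            return
        eps, p = _draw_interaction_fields(rng, len(chosen), majority, params)
        for (ga, gb), e, pv in zip(chosen, eps, p):
            records.append((ga, gb, float(e), float(pv)))
        realized = float((np.sign(eps) == majority).mean())
        truth.append({"cluster_id": cluster_id, "kind": kind,
                      "majority_sign": majority, "n_interactions": len(chosen),
                      "realized_purity": realized})

    for name in names:
        members = genes[name]
        pairs = [(members[i], members[j])
                 for i in range(len(members)) for j in range(i + 1, len(members))]
        emit(f"within:{name}", "within", pairs, params.within_density)

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = sorted((names[i], names[j]))
            pairs = [(ga, gb) for ga in genes[names[i]] for gb in genes[names[j]]]
            emit(f"between:{x}|{y}", "between", pairs, params.between_density)

    frame = pd.DataFrame(records, columns=list(COLUMNS))
    iset = InteractionSet(frame, cutoff_level="raw",
                          pair_policy="unordered-collapsed")
    return catalog, iset, pd.DataFrame(truth)


@dataclass(frozen=True)
class OracleEstimate:
    """Monte-Carlo estimate of the MCI the pipeline should recover."""

    mean: float
    se: float    # standard error of the mean
    sd: float    # across-replicate (dataset-level) standard deviation
    replicates: int


def expected_mci(params: SimulationParams, replicates: int = 200,
                 seed: int | None = None, min_interactions: int = 2,
                 apply_lenient_cutoff: bool = True) -> OracleEstimate:
    """Independent oracle for the within-complex MCI of generated data.

    Re-simulates the generative process directly — cluster sizes, sign
    draws, and (optionally) the lenient-cutoff thinning with keep
    probability ``w + (1 - w) * 0.05`` — without touching the pipeline
    code, and averages the resulting MCI over ``replicates`` datasets.
    """
    if replicates < 100:
        raise ValueError("use at least 100 oracle replicates")
    rng = np.random.default_rng(params.seed + 1_000_003 if seed is None else seed)
    keep_p = (params.p_sig_weight + (1 - params.p_sig_weight) * 0.05
              if apply_lenient_cutoff else 1.0)
    q = params.q_positive_majority
    values = []
    for _ in range(replicates):
        num = 0.0
        den = 0.0
        sizes = rng.integers(params.size_min, params.size_max + 1,
                             size=params.n_complexes)
        for size in sizes:
            n_pairs = comb(int(size), 2)
            m = rng.binomial(n_pairs, params.within_density)
            if m == 0:
                continue
            majority = 1 if rng.random() < q else -1
            is_majority = rng.random(m) < params.purity
            kept = rng.random(m) < keep_p
            k = int(kept.sum())
            if k < min_interactions:
                continue
            n_maj = int((is_majority & kept).sum())
            num += abs(2 * n_maj - k)
            den += k
        values.append(num / den if den else np.nan)
    values = np.array(values, dtype=float)
    values = values[~np.isnan(values)]
    sd = float(values.std(ddof=1))
    return OracleEstimate(mean=float(values.mean()),
                          se=sd / np.sqrt(len(values)),
                          sd=sd, replicates=len(values))


def write_dataset(catalog: GeneSetCatalog, iset: InteractionSet,
                  truth: pd.DataFrame, outdir) -> None:
    """Write interactions.tsv, complexes.gmt and truth.tsv under outdir."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iset.frame.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    with open(outdir / "complexes.gmt", "w") as fh:
        for name in sorted(catalog.sets):
            members = "\t".join(sorted(catalog.sets[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
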