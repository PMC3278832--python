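"""End-to-end analysis: cutoff -> clusters -> scores -> significance.

Runs the whole monochromaticity workflow on an interaction table plus a
complex catalog (and, optionally, subsystem gene lists): filter at a
confidence cutoff, build within- and between-complex clusters, compute
MCI/sMCI with permutation nulls, evaluate the MP-score census with an
exact binomial test, and repeat the cluster statistics inside each
cellular subsystem that retains enough clusters.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .clusters import (ClusterSet, GeneSetCatalog, assign_subsystems,
                       build_between_clusters, build_within_clusters)
from .interactions import (BackgroundComposition, InteractionSet, apply_cutoff,
                           background_composition, collapse_duplicates)
from .scores import (HighlyMonochromatic, MPCounts, PopulationScore,
                     classify_mp, highly_monochromatic, mp_score,
                     score_population)
from .significance import (BinomialTestResult, NullDistribution,
                           binomial_test, permutation_null)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    cutoff_level: str = "lenient"
    min_interactions: int = 2
    permutations: int = 1000
    seed: int = 0
    exclude_within: bool = False
    with_replacement: bool = False
    compute_smci_null: bool = True
    min_subsystem_clusters: int = 2  # subsystems with fewer are skipped

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PureCounts:
    positive: int  # beta == +1
    negative: int  # beta == -1
    mixed: int

    @property
    def total(self) -> int:
        return self.positive + self.negative + self.mixed


def pure_cluster_counts(pop: PopulationScore) -> PureCounts:
    """Count purely positive (beta = 1) and purely negative (beta = -1) clusters."""
    pos = sum(s.beta == 1.0 for s in pop.per_cluster)
    neg = sum(s.beta == -1.0 for s in pop.per_cluster)
    return PureCounts(pos, neg, len(pop.per_cluster) - pos - neg)


@dataclass
class Section:
    """Statistics of one cluster population (within or between)."""

    scores: PopulationScore
    null_mci: NullDistribution
    null_smci: NullDistribution | None
    highly: HighlyMonochromatic
    pure: PureCounts
    clusters: ClusterSet


@dataclass
class MPSummary:
    counts: MPCounts
    binomial: BinomialTestResult


@dataclass
class AnalysisReport:
    cutoff_level: str
    background: BackgroundComposition
    within: Section | None
    between: Section | None
    mp_summary: MPSummary | None
    per_subsystem: dict[str, dict[str, Section | None]]
    config: AnalysisConfig


def _derive_seed(base: int, k: int) -> int:
    return (base * 1_000_003 + k) % (2**31)


def _section(clusters: ClusterSet, pool: InteractionSet,
             config: AnalysisConfig, seed: int) -> Section | None:
    if len(clusters) == 0:
        return None
    pop = score_population(clusters)
    null_mci = permutation_null(clusters, pool, b=config.permutations,
                                seed=seed, statistic="mci",
                                with_replacement=config.with_replacement)
    null_smci = None
    if config.compute_smci_null:
        null_smci = permutation_null(clusters, pool, b=config.permutations,
                                     seed=seed + 1, statistic="smci",
                                     with_replacement=config.with_replacement)
    return Section(scores=pop, null_mci=null_mci, null_smci=null_smci,
                   highly=highly_monochromatic(pop),
                   pure=pure_cluster_counts(pop), clusters=clusters)


def _subset(clusters: ClusterSet, keep, min_interactions: int) -> ClusterSet:
    return ClusterSet([c for c in clusters if keep(c)],
                      min_interactions=min_interactions)


def run_analysis(interactions: InteractionSet, complexes: GeneSetCatalog,
                 subsystems: GeneSetCatalog | None = None,
                 config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full monochromaticity analysis; see module docstring."""
    config = config or AnalysisConfig()
    iset = interactions
    if iset.cutoff_level == "raw":
        iset = apply_cutoff(iset, config.cutoff_level)
    if iset.pair_policy == "ordered":
        iset = collapse_duplicates(iset)
    if len(iset) == 0:
        raise ValueError("no interactions survive the cutoff")
    background = background_composition(iset)

    within = build_within_clusters(iset, complexes, config.min_interactions)
    between = build_between_clusters(iset, complexes, config.min_interactions,
                                     exclude_within=config.exclude_within)
    within_sec = _section(within, iset, config, _derive_seed(config.seed, 1))
    between_sec = _section(between, iset, config, _derive_seed(config.seed, 3))
    if between_sec is None:
        logger.info("no between-complex clusters retained; section empty")

    mp_summary = None
    if within_sec is not None:
        results = [mp_score(c, background) for c in within]
        counts = classify_mp(results)
        mp_summary = MPSummary(counts, binomial_test(counts.total,
                                                     counts.monochromatic))

    per_subsystem: dict[str, dict[str, Section | None]] = {}
    if subsystems is not None:
        assignment = assign_subsystems(complexes, subsystems)
        for k, name in enumerate(sorted(subsystems.sets)):
            assigned = {c for c, subs in assignment.items() if name in subs}
            sub_within = _subset(within, lambda c: c.complexes[0] in assigned,
                                 config.min_interactions)
            sub_between = _subset(between,
                                  lambda c: set(c.complexes) <= assigned,
                                  config.min_interactions)
            n_eligible = len(sub_within) + len(sub_between)
            if n_eligible < config.min_subsystem_clusters:
                logger.info(
                    "subsystem %r skipped: %d eligible clusters (< %d)",
                    name, n_eligible, config.min_subsystem_clusters)
                continue
            per_subsystem[name] = {
                "within": _section(sub_within, iset, config,
                                   _derive_seed(config.seed, 10 + 4 * k)),
                "between": _section(sub_between, iset, config,
                                    _derive_seed(config.seed, 12 + 4 * k)),
            }

    return AnalysisReport(cutoff_level=iset.cutoff_level, background=background,
                          within=within_sec, between=between_sec,
                          mp_summary=mp_summary, per_subsystem=per_subsystem,
                          config=config)


# ---------------------------------------------------------------------------
# serialization

def _section_summary(sec: Section | None) -> dict[str, Any] | None:
    if sec is None:
        return None
    out: dict[str, Any] = {
        "n_clusters": sec.scores.n_clusters,
        "total_interactions": sec.scores.total_interactions,
        "mci": sec.scores.mci,
        "smci": sec.scores.smci,
        "pure_positive": sec.pure.positive,
        "pure_negative": sec.pure.negative,
        "mixed": sec.pure.mixed,
        "highly_monochromatic_positive": sec.highly.n_positive,
        "highly_monochromatic_negative": sec.highly.n_negative,
    }
    for label, null in (("mci", sec.null_mci), ("smci", sec.null_smci)):
        if null is None:
            continue
        out[f"null_{label}"] = {
            "b": null.b, "seed": null.seed, "mean": null.mean,
            "std": null.std,
            "z": None if not null.z_defined else null.z,
            "empirical_p": null.empirical_p, "display_p": null.display_p,
        }
    return out


def report_summary(report: AnalysisReport) -> dict[str, Any]:
    """Machine-readable summary of an analysis (JSON-serializable)."""
    summary: dict[str, Any] = {
        "cutoff_level": report.cutoff_level,
        "background": {
            "n_positive": report.background.n_positive,
            "n_negative": report.background.n_negative,
            "f_positive": report.background.f_positive,
            "alpha": report.background.alpha,
        },
        "within": _section_summary(report.within),
        "between": _section_summary(report.between),
        "per_subsystem": {
            name: {k: _section_summary(s) for k, s in secs.items()}
            for name, secs in report.per_subsystem.items()
        },
        "config": asdict(report.config),
    }
    if report.mp_summary is not None:
        c, b = report.mp_summary.counts, report.mp_summary.binomial
        summary["mp_summary"] = {
            "positive_monochromatic": c.positive,
            "negative_monochromatic": c.negative,
            "non_monochromatic": c.non_monochromatic,
            "binomial_n": b.n, "binomial_x": b.x, "binomial_p": b.p_value,
        }
    return summary


def score_table(pop: PopulationScore, clusters: ClusterSet) -> pd.DataFrame:
    """Per-cluster score table (TSV-ready)."""
    mci_val = pop.mci
    by_id = {c.id: c for c in clusters}
    rows = []
    for s in pop.per_cluster:
        c = by_id[s.cluster_id]
        rows.append({
            "cluster_id": s.cluster_id, "kind": c.kind,
            "complexes": "|".join(c.complexes), "n_total": c.n_total,
            "n_positive": c.n_positive, "n_negative": c.n_negative,
            "beta": s.beta, "beta_strength": s.beta_strength,
            "highly_monochromatic": abs(s.beta) > mci_val, "sign": s.sign,
        })
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    """Write summary.json, per-cluster score TSVs and null replicate TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report_summary(report), fh, indent=2, sort_keys=True)
    for label, sec in (("within", report.within), ("between", report.between)):
        if sec is None:
            continue
        score_table(sec.scores, sec.clusters).to_csv(
            outdir / f"{label}_scores.tsv", sep="\t", index=False)
        pd.DataFrame({"null_mci": sec.null_mci.values}).to_csv(
            outdir / f"{label}_null_mci.tsv", sep="\t", index=False)
        if sec.null_smci is not None:
            pd.DataFrame({"null_smci": sec.null_smci.values}).to_csv(
                outdir / f"{label}_null_smci.tsv", sep="\t", index=False)
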