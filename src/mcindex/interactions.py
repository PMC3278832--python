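"""Quantitative genetic-interaction data: representation, ingestion, filtering.

A genetic interaction between two genes is the deviation of the observed
double-mutant fitness from the expectation under a multiplicative model,

    epsilon = phi_AB - phi_A * phi_B,

where phi values are fitnesses relative to wild type.  epsilon > 0 is a
positive (alleviating) interaction, epsilon < 0 a negative (aggravating)
one; synthetic lethality is the extreme negative case.  Screens such as SGA
report, per gene pair, an epsilon score and a p-value; this module ingests
such tables, applies the standard confidence cutoffs, collapses the two
query/array orientations of a pair, and summarizes the sign composition of
the filtered population (the "background").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CUTOFF_LEVELS = ("raw", "lenient", "intermediate", "stringent")
PAIR_POLICIES = ("ordered", "unordered-collapsed")

#: canonical column names of the internal interaction frame
COLUMNS = ("gene_a", "gene_b", "epsilon", "p_value")


class FormatError(ValueError):
    """Raised when an input table cannot be mapped to the expected columns."""


def compute_epsilon(phi_ab, phi_a, phi_b):
    """Multiplicative-model deviation ``phi_ab - phi_a * phi_b``.

    Accepts scalars or arrays of relative fitness values (all >= 0).
    """
    phi_ab, phi_a, phi_b = (np.asarray(p, dtype=float) for p in (phi_ab, phi_a, phi_b))
    if np.any(phi_ab < 0) or np.any(phi_a < 0) or np.any(phi_b < 0):
        raise ValueError("relative fitness values must be non-negative")
    out = phi_ab - phi_a * phi_b
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GeneticInteraction:
    """One scored gene pair."""

    gene_a: str
    gene_b: str
    epsilon: float
    p_value: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction not allowed: {self.gene_a}")
        if self.epsilon == 0:
            raise ValueError("epsilon = 0 carries no sign; not representable")
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    @property
    def sign(self) -> int:
        """+1 for a positive (alleviating), -1 for a negative interaction."""
        return 1 if self.epsilon > 0 else -1


@dataclass
class InteractionSet:
    """A collection of interactions with provenance of filtering applied.

    ``frame`` holds one row per interaction with columns
    ``gene_a, gene_b, epsilon, p_value``.
    """

    frame: pd.DataFrame
    cutoff_level: str = "raw"
    pair_policy: str = "ordered"

    def __post_init__(self) -> None:
        if self.cutoff_level not in CUTOFF_LEVELS:
            raise ValueError(f"unknown cutoff level: {self.cutoff_level!r}")
        if self.pair_policy not in PAIR_POLICIES:
            raise ValueError(f"unknown pair policy: {self.pair_policy!r}")
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[GeneticInteraction]:
        for row in self.frame.itertuples(index=False):
            yield GeneticInteraction(row.gene_a, row.gene_b, row.epsilon, row.p_value)

    @property
    def epsilons(self) -> np.ndarray:
        return self.frame["epsilon"].to_numpy(dtype=float)

    @property
    def signs(self) -> np.ndarray:
        """Array of +1/-1 per interaction."""
        return np.where(self.epsilons > 0, 1, -1)


def _normalize_genes(series: pd.Series) -> pd.Series:
    # systematic names come in mixed case across yeast resources
    return series.astype(str).str.strip().str.upper()


def read_interactions(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> InteractionSet:
    """Read a delimited gene-pair table into an :class:`InteractionSet`.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Mapping from canonical names (``gene_a``, ``gene_b``, ``epsilon``,
        ``p_value``) to the column names used in the file.  Omitted keys
        default to the canonical name itself.
    delimiter:
        Field separator, tab by default.

    Rows with a missing epsilon or p-value, rows with epsilon exactly zero
    (sign undefined) and self-pairs are dropped; counts are logged.
    """
    column_map = dict(column_map or {})
    mapping = {column_map.get(c, c): c for c in COLUMNS}
    raw = pd.read_csv(path, sep=delimiter)
    missing = [src for src in mapping if src not in raw.columns]
    if missing:
        raise FormatError(
            f"column(s) {missing} not found in {path}; available: {list(raw.columns)}"
        )
    frame = raw[list(mapping)].rename(columns=mapping)
    frame["epsilon"] = pd.to_numeric(frame["epsilon"], errors="coerce")
    frame["p_value"] = pd.to_numeric(frame["p_value"], errors="coerce")

    n0 = len(frame)
    frame = frame.dropna(subset=["epsilon", "p_value"])
    n_missing = n0 - len(frame)

    frame["gene_a"] = _normalize_genes(frame["gene_a"])
    frame["gene_b"] = _normalize_genes(frame["gene_b"])
    self_pairs = frame["gene_a"] == frame["gene_b"]
    zero_eps = frame["epsilon"] == 0
    n_self = int(self_pairs.sum())
    n_zero = int(zero_eps.sum())
    frame = frame[~self_pairs & ~zero_eps].reset_index(drop=True)

    if n_missing or n_self or n_zero:
        logger.info(
            "read_interactions(%s): dropped %d rows with missing values, "
            "%d self-pairs, %d zero-epsilon rows; kept %d",
            path, n_missing, n_self, n_zero, len(frame),
        )
    return InteractionSet(frame, cutoff_level="raw", pair_policy="ordered")


def apply_cutoff(iset: InteractionSet, level: str) -> InteractionSet:
    """Filter a raw interaction set at a confidence cutoff.

    lenient:      p < 0.05
    intermediate: p < 0.05 and |epsilon| > 0.08
    stringent:    (epsilon > 0.16 or epsilon < -0.12) and p < 0.05
    """
    if iset.cutoff_level != "raw":
        raise ValueError(f"cutoff already applied: {iset.cutoff_level}")
    eps = iset.frame["epsilon"]
    p = iset.frame["p_value"]
    if level == "lenient":
        keep = p < 0.05
    elif level == "intermediate":
        keep = (p < 0.05) & (eps.abs() > 0.08)
    elif level == "stringent":
        keep = (p < 0.05) & ((eps > 0.16) | (eps < -0.12))
    else:
        raise ValueError(f"unknown cutoff level: {level!r}")
    out = iset.frame[keep].reset_index(drop=True)
    logger.info("apply_cutoff(%s): kept %d of %d", level, len(out), len(iset))
    return InteractionSet(out, cutoff_level=level, pair_policy=iset.pair_policy)


def collapse_duplicates(iset: InteractionSet) -> InteractionSet:
    """Collapse query/array orientations into one record per unordered pair.

    Records of a pair that agree in sign are merged (mean epsilon, min
    p-value); pairs whose records disagree in sign are removed entirely and
    counted in the log.  Idempotent.
    """
    frame = iset.frame
    if len(frame) == 0:
        return replace(iset, frame=frame.copy(), pair_policy="unordered-collapsed")
    a = frame["gene_a"].to_numpy()
    b = frame["gene_b"].to_numpy()
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    work = frame.assign(_lo=lo, _hi=hi)
    grouped = work.groupby(["_lo", "_hi"], sort=False)

    rows = []
    n_discordant = 0
    for (g_lo, g_hi), grp in grouped:
        signs = np.sign(grp["epsilon"].to_numpy())
        if len(set(signs)) > 1:
            n_discordant += 1
            continue
        rows.append(
            (g_lo, g_hi, grp["epsilon"].mean(), grp["p_value"].min())
        )
    out = pd.DataFrame(rows, columns=list(COLUMNS))
    if n_discordant:
        logger.info("collapse_duplicates: removed %d discordant pairs", n_discordant)
    return InteractionSet(out, cutoff_level=iset.cutoff_level,
                          pair_policy="unordered-collapsed")


@dataclass(frozen=True)
class BackgroundComposition:
    """Sign composition of a filtered interaction population.

    ``alpha`` is the signed imbalance (pos - neg) / total in [-1, 1]; the
    permutation null and the MP-score both depend on it through
    ``f_positive = (alpha + 1) / 2``.
    """

    n_positive: int
    n_negative: int

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative

    @property
    def f_positive(self) -> float:
        return self.n_positive / self.n_total

    @property
    def alpha(self) -> float:
        return (self.n_positive - self.n_negative) / self.n_total


def background_composition(iset: InteractionSet) -> BackgroundComposition:
    """Count positive/negative interactions of the whole (filtered) set."""
    if len(iset) == 0:
        raise ValueError("background composition of an empty interaction set")
    signs = iset.signs
    return BackgroundComposition(int((signs > 0).sum()), int((signs < 0).sum()))
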