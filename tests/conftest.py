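import numpy as np
import pandas as pd
import pytest

from mcindex import (ClusterSet, GeneSetCatalog, InteractionSet,
                     SimulationParams, generate)
from mcindex.clusters import Cluster


def make_iset(rows, cutoff_level="raw", pair_policy="ordered"):
    """Build an InteractionSet from (gene_a, gene_b, epsilon, p_value) tuples."""
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "epsilon", "p_value"])
    return InteractionSet(frame, cutoff_level=cutoff_level,
                          pair_policy=pair_policy)


def make_cluster(epsilons, cluster_id="c1", kind="within", complexes=("X",)):
    """Build a Cluster holding interactions with the given epsilon values."""
    rows = [(f"A{i}", f"B{i}", e, 0.01) for i, e in enumerate(epsilons)]
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "epsilon", "p_value"])
    return Cluster(id=cluster_id, kind=kind, complexes=tuple(complexes),
                   interactions=frame)


def make_cluster_counts(n_pos, n_neg, magnitude=0.2, **kw):
    """Cluster with n_pos positive and n_neg negative equal-magnitude epsilons."""
    eps = [magnitude] * n_pos + [-magnitude] * n_neg
    return make_cluster(eps, **kw)


@pytest.fixture
def toy_catalog():
    return GeneSetCatalog(
        {"CPX_A": {"A1", "A2", "A3"},
         "CPX_B": {"B1", "B2"},
         "CPX_AB": {"A1", "A2", "B1"}},  # overlaps both
        kind="complexes",
    )


@pytest.fixture(scope="session")
def default_sim():
    """One generated dataset at default parameters, shared across tests."""
    params = SimulationParams(seed=7)
    catalog, iset, truth = generate(params)
    return params, catalog, iset, truth
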