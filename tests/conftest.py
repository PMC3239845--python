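import numpy as np
import pandas as pd
import pytest

import netdiff as nd


@pytest.fixture(scope="session")
def binary_pair():
    """One fixed draw of the 20-node planted binary design (seed 0).

    Planted structure: nodes 1-5 clustered in both networks, 6-15 exclusive to
    A, 15-20 exclusive to B (1-based).
    """
    return nd.generate_binary_pair(seed=0)


@pytest.fixture(scope="session")
def binary_fact(binary_pair):
    return nd.compute_gsvd(binary_pair)


@pytest.fixture(scope="session")
def corr_pair():
    """One fixed draw of the 20-node signal-mixing correlation design."""
    return nd.generate_correlation_pair(seed=0)


@pytest.fixture(scope="session")
def spd_pair():
    """A well-conditioned random symmetric pair (both positive definite)."""
    rng = np.random.default_rng(7)
    n = 12
    Ma = rng.standard_normal((n, n))
    Mb = rng.standard_normal((n, n))
    return nd.NetworkPair(A=Ma @ Ma.T + 0.5 * np.eye(n),
                          B=Mb @ Mb.T + 0.5 * np.eye(n))


@pytest.fixture()
def intensity_table():
    """Small two-group intensity table with a 6-metabolite planted block."""
    ints, groups, annot, truth = nd.generate_intensity_table(
        n_metabolites=24, samples_per_group=8, planted_block=6, seed=11
    )
    table = nd.IntensityTable(intensities=ints, groups=groups)
    return table, nd.PathwayAnnotation(membership=annot), truth


def head_overlap(ordering, tau, planted_idx):
    """Size of the intersection between the ordering's head run and a planted
    0-based index set."""
    return len(set(ordering.head(tau).tolist()) & set(np.asarray(planted_idx).tolist()))
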