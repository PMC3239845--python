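"""Cluster scoring and Monte-Carlo significance testing.

A candidate cluster is a set of ``tau`` nodes -- normally a contiguous run
taken from one end of a GSVD node ordering -- claimed to be densely connected
in one network of the pair (the *target*) but not the other.  Its quality
``c(A, B)`` compares the within-cluster density between the two networks, and
a p-value is assigned by comparing the observed quality against ``M``
randomizations of the pair.

Density measures
----------------
For a binary network the density of cluster ``s`` is ``|E(s)| / |s|`` where
``|E(s)|`` counts the undirected edges among the cluster's nodes (diagonal
excluded) and ``|s| = tau * (tau - 1) / 2`` is the maximum possible.  For a
weighted network the analogue is the mean off-diagonal weight within the
block.  On a binary matrix the two coincide.

Quality combiners
-----------------
``ratio``      : ``f_target / f_other`` (the ``|s|`` denominator cancels, so on
                 binary data this equals the ratio of raw edge counts).
``difference`` : ``f_target - f_other``.

The ratio is well behaved for binary and non-negative weights.  For *signed*
weights (correlation networks) the mean weight of a random null block can be
arbitrarily close to zero or negative, which makes the ratio's sign flip and
its magnitude explode; ``difference`` is the reliable choice there and is what
the pipeline uses for signed data.

Randomization schemes
---------------------
``permutation``    : one uniformly random node relabelling applied identically
                     to both networks; the first ``tau`` nodes of the new
                     ordering are scored.  Because the factorization is
                     permutation invariant, no GSVD recomputation is needed.
                     Valid for any weights.
``erdos_renyi``    : binary only; each replicate draws classical random graphs
                     with the original edge counts, refactorizes, and scores
                     the run at the candidate's own (column, end, offset).
``redistribution`` : binary only; shuffles the off-diagonal entries within
                     each row independently, symmetrizes by OR, refactorizes,
                     and scores as above.

The reported p-value is the raw exceedance proportion ``#{c_null >= c_obs}/M``
(ties and +inf count as exceedances, which is conservative); the
bias-corrected ``(x + 1)/(M + 1)`` variant is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .pair import NetworkPair
from . import gsvd as _gsvd

__all__ = [
    "ClusterCandidate",
    "ClusterQuality",
    "PermutationTestResult",
    "binary_density",
    "weighted_density",
    "cluster_quality",
    "permutation_pvalue",
    "candidate_clusters",
]

SCHEMES = ("permutation", "erdos_renyi", "redistribution")


@dataclass
class ClusterCandidate:
    """``tau`` nodes claimed exclusive to one network of a pair."""

    node_indices: np.ndarray
    target_network: str = "A"  # "A" or "B"
    source: Optional[tuple] = None  # (column, end, offset) within an ordering

    def __post_init__(self):
        self.node_indices = np.asarray(self.node_indices, dtype=int)
        if self.tau < 2:
            raise ValueError("a cluster needs at least 2 nodes")
        if len(np.unique(self.node_indices)) != self.tau:
            raise ValueError("cluster node indices must be distinct")
        if self.target_network not in ("A", "B"):
            raise ValueError("target_network must be 'A' or 'B'")

    @property
    def tau(self) -> int:
        return len(self.node_indices)


@dataclass
class ClusterQuality:
    f_target: float
    f_other: float
    c_value: float
    measure: str
    combiner: str


@dataclass
class PermutationTestResult:
    observed: ClusterQuality
    M: int
    scheme: str
    null_samples: np.ndarray
    p_value: float
    p_value_corrected: float
    seed: Optional[int] = None

    def report_pvalue(self) -> str:
        """Human-readable p-value; zero exceedances print as '< 1/M'."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.M:.3g}"
        return f"{self.p_value:.3g}"


def _block_mean(net: np.ndarray, idx: np.ndarray) -> float:
    sub = net[np.ix_(idx, idx)]
    tau = len(idx)
    return (sub.sum() - np.trace(sub)) / (tau * (tau - 1))


def _is_binary(net: np.ndarray) -> bool:
    return bool(np.isin(net, (0.0, 1.0)).all())


def binary_density(net: np.ndarray, cluster) -> float:
    """Edge density ``|E(s)| / |s|`` of a cluster in a binary network."""
    idx = cluster.node_indices if isinstance(cluster, ClusterCandidate) else np.asarray(cluster, int)
    if len(idx) < 2:
        raise ValueError("a cluster needs at least 2 nodes")
    net = np.asarray(net, dtype=float)
    if not _is_binary(net):
        raise ValueError("binary_density requires a 0/1 matrix; use weighted_density")
    return _block_mean(net, idx)


def weighted_density(net: np.ndarray, cluster, absolute: bool = False) -> float:
    """Mean off-diagonal weight within the cluster's block.

    ``absolute=True`` averages |w| instead, the variant needed for clusters
    dominated by strong *negative* weights.
    """
    idx = cluster.node_indices if isinstance(cluster, ClusterCandidate) else np.asarray(cluster, int)
    if len(idx) < 2:
        raise ValueError("a cluster needs at least 2 nodes")
    net = np.asarray(net, dtype=float)
    return _block_mean(np.abs(net) if absolute else net, idx)


def _combine(f_target: float, f_other: float, combiner: str) -> float:
    if combiner == "difference":
        return f_target - f_other
    if combiner == "ratio":
        if f_other == 0.0:
            # +inf sentinel; 0/0 carries no evidence of exclusivity
            return np.inf if f_target > 0.0 else 0.0
        return f_target / f_other
    raise ValueError(f"unknown combiner {combiner!r}")


def cluster_quality(
    pair: NetworkPair,
    cluster: ClusterCandidate,
    measure: str = "weighted",
    combiner: str = "ratio",
    abs_weights: bool = False,
) -> ClusterQuality:
    """Score a candidate: within-cluster density in the target network versus
    the other network, combined by ratio (default) or difference."""
    if measure not in ("binary", "weighted"):
        raise ValueError(f"unknown measure {measure!r}")
    if measure == "binary":
        dens = binary_density
    else:
        def dens(net, c):
            return weighted_density(net, c, absolute=abs_weights)
    target, other = (
        (pair.A, pair.B) if cluster.target_network == "A" else (pair.B, pair.A)
    )
    f_t = dens(target, cluster)
    f_o = dens(other, cluster)
    return ClusterQuality(
        f_target=f_t,
        f_other=f_o,
        c_value=_combine(f_t, f_o, combiner),
        measure=measure,
        combiner=combiner,
    )


def _null_permutation(pair, cluster, M, combiner, rng, abs_weights=False):
    """Vectorized permutation null: random tau-subsets scored in both nets."""
    target, other = (
        (pair.A, pair.B) if cluster.target_network == "A" else (pair.B, pair.A)
    )
    if abs_weights:
        target, other = np.abs(target), np.abs(other)
    n = pair.n_nodes
    tau = cluster.tau
    idx = np.argsort(rng.random((M, n)), axis=1)[:, :tau]  # M random tau-subsets
    denom = tau * (tau - 1)

    def block_means(net):
        sub = net[idx[:, :, None], idx[:, None, :]]  # (M, tau, tau)
        return (sub.sum(axis=(1, 2)) - np.trace(sub, axis1=1, axis2=2)) / denom

    f_t = block_means(target)
    f_o = block_means(other)
    if combiner == "difference":
        return f_t - f_o
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = f_t / f_o
    vals[(f_o == 0.0) & (f_t > 0.0)] = np.inf
    vals[(f_o == 0.0) & (f_t <= 0.0)] = 0.0
    return vals


def _randomized_binary(net, scheme, rng):
    n = net.shape[0]
    if scheme == "erdos_renyi":
        m_edges = int(np.triu(net, 1).sum())
        iu = np.triu_indices(n, 1)
        pick = rng.choice(len(iu[0]), size=m_edges, replace=False)
        W = np.zeros_like(net)
        W[iu[0][pick], iu[1][pick]] = 1.0
        return W + W.T
    # redistribution: shuffle off-diagonal entries within each row, OR-symmetrize
    W = np.zeros_like(net)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        W[i, others] = net[i, np.delete(np.arange(n), i)][rng.permutation(n - 1)]
    return ((W + W.T) > 0).astype(float)


def _null_refactorize(pair, cluster, M, measure, combiner, scheme, rng):
    """Graph-randomization null: re-factorize each replicate and score the run
    at the candidate's own (column, end, offset)."""
    if cluster.source is None:
        raise ValueError(
            f"scheme {scheme!r} rescores the candidate's (column, end, offset) "
            "run and needs a candidate built from a NodeOrdering"
        )
    column, end, offset = cluster.source
    tau = cluster.tau
    dens = binary_density if measure == "binary" else weighted_density
    out = np.empty(M)
    for r in range(M):
        Ar = _randomized_binary(pair.A, scheme, rng)
        Br = _randomized_binary(pair.B, scheme, rng)
        rpair = NetworkPair(A=Ar, B=Br, node_labels=list(pair.node_labels))
        ordering = _gsvd.reordering_vector(_gsvd.compute_gsvd(rpair), column, end)
        run = ordering.run(offset, tau)
        t_net, o_net = (Ar, Br) if cluster.target_network == "A" else (Br, Ar)
        out[r] = _combine(dens(t_net, run), dens(o_net, run), combiner)
    return out


def permutation_pvalue(
    pair: NetworkPair,
    cluster: ClusterCandidate,
    M: int = 1000,
    scheme: str = "permutation",
    seed: Optional[int] = None,
    measure: str = "weighted",
    combiner: str = "ratio",
    abs_weights: bool = False,
) -> PermutationTestResult:
    """Monte-Carlo p-value for a candidate cluster.

    The p-value is the proportion of ``M`` randomized qualities that equal or
    exceed the observed quality (see module notes on schemes and on ties).
    Bit-exactly reproducible given ``(seed, M, scheme)``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    rng = np.random.default_rng(seed)
    obs = cluster_quality(pair, cluster, measure=measure, combiner=combiner,
                          abs_weights=abs_weights)
    if scheme == "permutation":
        null = _null_permutation(pair, cluster, M, combiner, rng, abs_weights)
    else:
        if not (_is_binary(pair.A) and _is_binary(pair.B)):
            raise ValueError(f"scheme {scheme!r} applies to binary networks only")
        null = _null_refactorize(pair, cluster, M, measure, combiner, scheme, rng)
    exceed = int(np.count_nonzero(null >= obs.c_value))
    return PermutationTestResult(
        observed=obs,
        M=M,
        scheme=scheme,
        null_samples=null,
        p_value=exceed / M,
        p_value_corrected=(exceed + 1) / (M + 1),
        seed=seed,
    )


def candidate_clusters(
    ordering: _gsvd.NodeOrdering,
    taus: Sequence[int],
    ends: Iterable[str] = ("head", "tail"),
) -> list:
    """Contiguous-run candidates from a node ordering.

    One candidate per ``tau`` per requested end of the *sorted* ordering (head
    run at offset 0, tail run at offset ``N - tau``).  The target network is
    inferred from the ordering's spectrum end: first columns of ``X^-T`` favor
    clusters in ``B``, last columns favor clusters in ``A``.
    """
    if not taus:
        raise ValueError("taus must be non-empty")
    n = len(ordering)
    target = "B" if ordering.end == "first" else "A"
    out = []
    for tau in taus:
        if not 2 <= tau <= n:
            raise ValueError(f"tau must be in 2..{n}, got {tau}")
        for which in ends:
            offset = 0 if which == "head" else n - tau
            out.append(
                ClusterCandidate(
                    node_indices=ordering.run(offset, tau),
                    target_network=target,
                    source=(ordering.source_column + 1 if ordering.end == "first"
                            else n - ordering.source_column,
                            ordering.end, offset),
                )
            )
    return out
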