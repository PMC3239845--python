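"""Synthetic benchmark generators with planted ground truth.

Two network designs are provided, plus a two-group metabolite-intensity
generator for exercising the full pipeline.  All three carry their planted
structure along so recovery can be checked programmatically.

Binary planted-cluster pair
    20 nodes.  Nodes 1-5 form a cluster in both networks; nodes 6-15 form a
    cluster only in ``A``; nodes 15-20 form a cluster only in ``B`` (node 15
    belongs to both planted clusters).  Within-cluster edges appear with
    probability ``p_in`` and background edges with ``p_out``, so clusters have
    missing edges (false negatives) and the background has spurious edges
    (false positives).

Signal-mixing correlation pair
    Correlation matrices of two 20 x 50 data matrices ``D_a`` and ``D_b``
    built from nine length-50 signals v1..v9 (seven sinusoids of distinct
    frequency and phase, a square wave, and a ramp).  Rows 1-5 of both are
    positive linear combinations of v1..v7; rows 6-15 of ``D_a`` combine v7
    and v8 (the A-exclusive block); rows 15-20 of ``D_b`` combine v4 and v9
    (the B-exclusive block); all remaining rows are Gaussian noise.  Mixing
    coefficients are Uniform(0.5, 1.5) -- strictly positive so the planted
    correlations are positive -- and signal rows receive additive Gaussian
    noise of scale 0.2.

Intensity table
    Log-normal metabolite peak intensities for two groups of samples, with an
    optional block of metabolites driven by a shared latent factor in the
    first group only, and a pathway annotation in which the planted block
    shares one pathway.  Defaults mirror a small two-group LC-MS study:
    98 metabolites, 5 samples per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pair import NetworkPair

__all__ = [
    "PlantedBinarySpec",
    "SignalMixingSpec",
    "generate_binary_pair",
    "generate_correlation_pair",
    "shuffle_pair",
    "make_signals",
    "generate_intensity_table",
]


@dataclass
class PlantedBinarySpec:
    """Design of the 20-node planted binary pair (1-based node numbers)."""

    n_nodes: int = 20
    shared_cluster: Tuple[int, ...] = tuple(range(1, 6))
    a_cluster: Tuple[int, ...] = tuple(range(6, 16))
    b_cluster: Tuple[int, ...] = tuple(range(15, 21))
    p_in: float = 0.85
    p_out: float = 0.08
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for name in ("shared_cluster", "a_cluster", "b_cluster"):
            nodes = getattr(self, name)
            if not all(1 <= v <= self.n_nodes for v in nodes):
                raise ValueError(f"{name} contains nodes outside 1..{self.n_nodes}")

    # 0-based index arrays for programmatic use
    @property
    def shared_idx(self) -> np.ndarray:
        return np.asarray(self.shared_cluster, int) - 1

    @property
    def a_idx(self) -> np.ndarray:
        return np.asarray(self.a_cluster, int) - 1

    @property
    def b_idx(self) -> np.ndarray:
        return np.asarray(self.b_cluster, int) - 1


def _planted_binary(n, clusters, p_in, p_out, rng):
    W = rng.random((n, n)) < p_out
    for idx in clusters:
        k = len(idx)
        W[np.ix_(idx, idx)] = rng.random((k, k)) < p_in
    W = np.triu(W, 1)
    return (W | W.T).astype(float)


def generate_binary_pair(spec: PlantedBinarySpec = None, seed=None) -> NetworkPair:
    """Draw one binary pair from the planted design (symmetric, zero diagonal)."""
    spec = spec or PlantedBinarySpec()
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    A = _planted_binary(spec.n_nodes, [spec.shared_idx, spec.a_idx],
                        spec.p_in, spec.p_out, rng)
    B = _planted_binary(spec.n_nodes, [spec.shared_idx, spec.b_idx],
                        spec.p_in, spec.p_out, rng)
    return NetworkPair(A=A, B=B)


def make_signals(n_samples: int = 50) -> np.ndarray:
    """The nine length-``n_samples`` source signals (rows of a 9 x n matrix)."""
    t = np.arange(n_samples)
    freqs_phases = [(1, 0.0), (2, 0.7), (3, 1.4), (4, 2.1),
                    (5, 2.8), (6, 3.5), (7, 4.2)]
    rows = [np.sin(2 * np.pi * f * t / n_samples + ph) for f, ph in freqs_phases]
    rows.append(np.sign(np.sin(2 * np.pi * 2.5 * t / n_samples)))  # square wave
    rows.append(np.linspace(-1.0, 1.0, n_samples))                 # ramp
    return np.array(rows)


@dataclass
class SignalMixingSpec:
    """Design of the 20-node signal-mixing correlation pair."""

    n_nodes: int = 20
    n_samples: int = 50
    signals: np.ndarray = None
    coeff_low: float = 0.5
    coeff_high: float = 1.5
    noise_scale: float = 0.2
    seed: Optional[int] = None

    # mixing plan (1-based row ranges, fixed by the design)
    shared_rows: Tuple[int, int] = (1, 5)    # combos of v1..v7 in both
    a_block_rows: Tuple[int, int] = (6, 15)  # combos of v7, v8 in D_a
    b_block_rows: Tuple[int, int] = (15, 20)  # combos of v4, v9 in D_b

    def __post_init__(self):
        if self.signals is None:
            self.signals = make_signals(self.n_samples)
        self.signals = np.asarray(self.signals, float)
        if self.signals.shape != (9, self.n_samples):
            raise ValueError(f"signals must be 9 x {self.n_samples}")

    @property
    def a_idx(self) -> np.ndarray:
        lo, hi = self.a_block_rows
        return np.arange(lo - 1, hi)

    @property
    def b_idx(self) -> np.ndarray:
        lo, hi = self.b_block_rows
        return np.arange(lo - 1, hi)


def generate_correlation_pair(spec: SignalMixingSpec = None, seed=None,
                              return_data: bool = False):
    """Draw one correlation pair (and optionally ``D_a``, ``D_b``) from the
    signal-mixing design.  Diagonals are exactly 1 and entries lie in [-1, 1].
    """
    spec = spec or SignalMixingSpec()
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    V = spec.signals
    m = spec.n_samples

    def combo(sig_indices):
        coeff = rng.uniform(spec.coeff_low, spec.coeff_high, size=len(sig_indices))
        return coeff @ V[sig_indices] + spec.noise_scale * rng.standard_normal(m)

    n = spec.n_nodes
    Da = np.empty((n, m))
    Db = np.empty((n, m))
    sh_lo, sh_hi = spec.shared_rows
    for r in range(sh_lo - 1, sh_hi):
        Da[r] = combo(np.arange(7))
        Db[r] = combo(np.arange(7))
    for r in spec.a_idx:
        Da[r] = combo(np.array([6, 7]))  # v7, v8
    for r in spec.b_idx:
        Db[r] = combo(np.array([3, 8]))  # v4, v9
    noise_a = np.setdiff1d(np.arange(n), np.r_[np.arange(sh_lo - 1, sh_hi), spec.a_idx])
    noise_b = np.setdiff1d(np.arange(n), np.r_[np.arange(sh_lo - 1, sh_hi), spec.b_idx])
    Da[noise_a] = rng.standard_normal((len(noise_a), m))
    Db[noise_b] = rng.standard_normal((len(noise_b), m))

    if (Da.std(axis=1) == 0).any() or (Db.std(axis=1) == 0).any():
        raise ValueError("a data row has zero variance")
    A = np.corrcoef(Da)
    B = np.corrcoef(Db)
    np.fill_diagonal(A, 1.0)
    np.fill_diagonal(B, 1.0)
    A = (A + A.T) / 2.0
    B = (B + B.T) / 2.0
    pair = NetworkPair(A=A, B=B)
    if return_data:
        return pair, Da, Db
    return pair


def shuffle_pair(pair: NetworkPair, seed=None):
    """Apply one random relabelling identically to both matrices.

    Returns ``(shuffled_pair, perm)`` where ``perm[k]`` is the original index
    of the node placed at position ``k`` (so ``shuffled.permuted(argsort(perm))``
    restores the original).
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pair.n_nodes)
    return pair.permuted(perm), perm


def generate_intensity_table(
    n_metabolites: int = 98,
    samples_per_group: int = 5,
    planted_block: int = 10,
    group_names: Sequence[str] = ("control", "treated"),
    effect: float = 0.4,
    noise_scale: float = 0.15,
    n_pathways: int = 8,
    seed=None,
):
    """Two-group synthetic LC-MS peak-intensity table with a planted block.

    The first ``planted_block`` metabolites share a latent per-sample factor
    in the *first* group only (coefficient ``effect`` on the log10 scale), so
    they are mutually correlated there and uncorrelated in the second group.
    ``planted_block=0`` gives a null table (both groups exchangeable).

    Returns ``(intensities, groups, annotation, truth)`` where ``intensities``
    is a samples x metabolites DataFrame, ``groups`` a parallel Series,
    ``annotation`` a metabolite -> pathway-id-set mapping in which the planted
    metabolites share pathway ``"path_planted"`` (others are assigned to
    ``n_pathways`` decoy pathways or left unannotated), and ``truth`` the
    planted metabolite ids.
    """
    rng = np.random.default_rng(seed)
    mets = [f"met{i + 1}" for i in range(n_metabolites)]
    samples = [f"{g}_{i + 1}" for g in group_names for i in range(samples_per_group)]
    groups = pd.Series(
        [group_names[0]] * samples_per_group + [group_names[1]] * samples_per_group,
        index=samples, name="group",
    )
    base = rng.uniform(4.0, 7.0, size=n_metabolites)  # log10 peak intensity
    log_int = base + noise_scale * rng.standard_normal(
        (2 * samples_per_group, n_metabolites)
    )
    if planted_block:
        factor = rng.standard_normal(samples_per_group)
        loadings = rng.uniform(0.75, 1.25, size=planted_block) * effect
        log_int[:samples_per_group, :planted_block] += np.outer(factor, loadings)
    intensities = pd.DataFrame(10.0 ** log_int, index=samples, columns=mets)

    annotation = {}
    for j, met in enumerate(mets):
        if j < planted_block:
            annotation[met] = {"path_planted"}
        elif rng.random() < 0.7:
            annotation[met] = {f"path{rng.integers(1, n_pathways + 1)}"}
        else:
            annotation[met] = set()  # unannotated ("NA")
    truth = mets[:planted_block]
    return intensities, groups, annotation, truth
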