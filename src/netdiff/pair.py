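"""Paired-network container.

A :class:`NetworkPair` holds two symmetric weight matrices ``A`` and ``B``
defined on a single, shared, ordered node set.  The two matrices describe two
different kinds of (or conditions for) pairwise association between the same
nodes -- e.g. within-group metabolite correlations for a control and a treated
group -- and are the sole required input of the reordering algorithm.

Weights may be binary {0, 1}, non-negative, or signed (correlations or
Fisher-transformed correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["NetworkPair"]

#: Absolute tolerance used when checking that an input matrix is symmetric.
SYMMETRY_ATOL = 1e-8


def _as_checked_matrix(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square 2-D matrix, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains NaN or Inf entries")
    if not np.allclose(M, M.T, atol=SYMMETRY_ATOL, rtol=0.0):
        raise ValueError(
            f"{name} is not symmetric to within {SYMMETRY_ATOL:g}; "
            "pass symmetrize=True (or --symmetrize) to average (W + W.T)/2"
        )
    return M


@dataclass
class NetworkPair:
    """Two symmetric weight matrices on one labelled node set.

    Parameters
    ----------
    A, B
        ``N x N`` real symmetric weight matrices.
    node_labels
        ``N`` distinct node identifiers, in matrix row/column order.  When
        omitted, labels ``"n1" .. "nN"`` are generated.
    """

    A: np.ndarray
    B: np.ndarray
    node_labels: list = field(default=None)

    def __post_init__(self):
        self.A = _as_checked_matrix(self.A, "A")
        self.B = _as_checked_matrix(self.B, "B")
        if self.A.shape != self.B.shape:
            raise ValueError(
                f"A and B must have equal shapes, got {self.A.shape} vs {self.B.shape}"
            )
        n = self.A.shape[0]
        if self.node_labels is None:
            self.node_labels = [f"n{i + 1}" for i in range(n)]
        else:
            self.node_labels = list(self.node_labels)
        if len(self.node_labels) != n:
            raise ValueError(
                f"expected {n} node labels, got {len(self.node_labels)}"
            )
        if len(set(self.node_labels)) != n:
            raise ValueError("node labels contain duplicates")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def permuted(self, perm: Sequence[int]) -> "NetworkPair":
        """Return a copy with both matrices symmetrically permuted by ``perm``.

        ``perm[k]`` is the original index of the node placed at position ``k``;
        labels travel with their rows/columns.
        """
        perm = np.asarray(perm, dtype=int)
        n = self.n_nodes
        if perm.shape != (n,) or sorted(perm.tolist()) != list(range(n)):
            raise ValueError(f"perm must be a permutation of 0..{n - 1}")
        return NetworkPair(
            A=self.A[np.ix_(perm, perm)],
            B=self.B[np.ix_(perm, perm)],
            node_labels=[self.node_labels[i] for i in perm],
        )

    def with_zero_diagonal(self) -> "NetworkPair":
        """Return a copy with both diagonals set to zero (self-loops removed)."""
        A = self.A.copy()
        B = self.B.copy()
        np.fill_diagonal(A, 0.0)
        np.fill_diagonal(B, 0.0)
        return NetworkPair(A=A, B=B, node_labels=list(self.node_labels))
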