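"""Generalized singular value decomposition of a network pair and the node
orderings derived from it.

Given symmetric weight matrices ``A`` and ``B`` on a common node set, the GSVD
factorizes them simultaneously as ::

    A = U @ diag(c) @ inv(X)        B = V @ diag(s) @ inv(X)

with ``U`` and ``V`` orthogonal, ``X`` invertible, and the diagonals ordered so
that ``c`` is nondecreasing and ``s`` is nonincreasing.  The generalized
singular values ``lam_i = c_i / s_i`` are the stationary values of
``||A x|| / ||B x||``: directions with small ``lam`` look like structure in
``B`` but not ``A``, and vice versa for large ``lam``.

For symmetric inputs, sorting the components of a column of ``X^-T`` gives a
node relabelling under which exclusive clusters -- node subsets densely
connected in one network only -- become contiguous blocks: the first few
columns favor clusters in ``B``, the last few favor clusters in ``A``.

The factorization is computed from a full QR of the stacked matrix ``[A; B]``
followed by the cosine-sine decomposition of the orthogonal factor, which is
numerically stable and well defined even when ``A`` or ``B`` is singular (no
matrix is ever inverted to obtain the reordering vectors: with this route
``X^-T`` is available directly as ``(V1h @ R).T``).

Degenerate pairs
----------------
When a network is exactly rank deficient the pair has repeated generalized
singular values (e.g. ``s_i = 0`` for every direction in ``null(B)``), and the
factorization is unique only up to an orthogonal rotation within each tied
block.  The library canonicalizes tied blocks by rotating them to extremize the
Rayleigh quotient ``x' A x`` (for ties at the large-``lam`` end) or ``x' B x``
(small-``lam`` end), the natural extension of the ``||Ax||/||Bx||``
stationarity objective; without this, the extreme columns of ``X^-T`` are an
arbitrary basis of a null space and carry no ordering information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .pair import NetworkPair

__all__ = [
    "GSVDFactorization",
    "NodeOrdering",
    "compute_gsvd",
    "reordering_vector",
    "reorder_pair",
]

#: Blocks of generalized singular value pairs whose angle atan2(c, s) agrees to
#: within this tolerance are treated as exactly tied and canonicalized.
TIE_TOL = 1e-9

#: Condition estimate of X above which a warning is emitted and least-squares
#: solves are used where an explicit X is requested.
ILL_CONDITION_THRESHOLD = 1e12


@dataclass
class GSVDFactorization:
    """GSVD of a :class:`~netdiff.pair.NetworkPair`.

    Attributes
    ----------
    U, V
        ``N x N`` orthogonal factors for ``A`` and ``B`` respectively.
    x_inv
        ``inv(X)``, the shared right factor, stored directly (this is the
        numerically primary object; ``X`` itself is derived on demand).
    c, s
        Diagonals of ``C`` and ``S``; ``c`` nondecreasing, ``s`` nonincreasing,
        ``c**2 + s**2 == 1`` elementwise.
    node_labels
        Labels carried over from the input pair.
    """

    U: np.ndarray
    V: np.ndarray
    x_inv: np.ndarray
    c: np.ndarray
    s: np.ndarray
    node_labels: list = field(default=None)

    @property
    def n_nodes(self) -> int:
        return self.x_inv.shape[0]

    @property
    def lam(self) -> np.ndarray:
        """Generalized singular values ``c / s``, with ``inf`` where ``s == 0``."""
        with np.errstate(divide="ignore"):
            return np.where(self.s > 0.0, self.c / np.where(self.s > 0, self.s, 1.0),
                            np.inf)

    @property
    def x_inv_t(self) -> np.ndarray:
        """``X^-T``; its sorted columns define the node orderings."""
        return self.x_inv.T

    @property
    def X(self) -> np.ndarray:
        """The (possibly ill-conditioned) third factor, solved from ``x_inv``."""
        cond = np.linalg.cond(self.x_inv)
        if not np.isfinite(cond) or cond > ILL_CONDITION_THRESHOLD:
            warnings.warn(
                f"X is numerically singular (condition estimate {cond:.2e}); "
                "using a pseudo-inverse",
                RuntimeWarning,
            )
            return np.linalg.pinv(self.x_inv)
        return np.linalg.solve(self.x_inv, np.eye(self.n_nodes))

    def reconstruction_residuals(self, pair: NetworkPair) -> tuple:
        """Relative residuals of ``A - U C X^-1`` and ``B - V S X^-1``."""
        ra = np.linalg.norm(pair.A - self.U @ (self.c[:, None] * self.x_inv))
        rb = np.linalg.norm(pair.B - self.V @ (self.s[:, None] * self.x_inv))
        na = np.linalg.norm(pair.A) or 1.0
        nb = np.linalg.norm(pair.B) or 1.0
        return ra / na, rb / nb


@dataclass
class NodeOrdering:
    """A node relabelling obtained by sorting one column of ``X^-T``.

    ``permutation[k]`` is the original (0-based) node index placed at position
    ``k`` of the new ordering.  ``values`` are the sorted components of the
    reordering vector, descending; ties are broken by original index.
    """

    permutation: np.ndarray
    source_column: int
    end: str
    values: np.ndarray
    node_labels: list = field(default=None)

    def __len__(self) -> int:
        return len(self.permutation)

    def head(self, tau: int) -> np.ndarray:
        """Original indices of the first ``tau`` nodes of the ordering."""
        return self.permutation[:tau].copy()

    def tail(self, tau: int) -> np.ndarray:
        """Original indices of the last ``tau`` nodes of the ordering."""
        return self.permutation[-tau:].copy()

    def run(self, offset: int, tau: int) -> np.ndarray:
        """Original indices of the contiguous run ``[offset, offset + tau)``."""
        if offset < 0 or offset + tau > len(self):
            raise ValueError("run exceeds ordering bounds")
        return self.permutation[offset:offset + tau].copy()

    @property
    def labels_in_order(self) -> list:
        if self.node_labels is None:
            return [str(i + 1) for i in self.permutation]
        return [self.node_labels[i] for i in self.permutation]


def _canonicalize_ties(xt, U, V, A, B, c, s, tie_tol=TIE_TOL):
    """Rotate exactly-tied (c, s) blocks to a canonical, informative basis.

    Within a tied block the factorization is invariant under ``Y -> Y W`` for
    orthogonal ``W`` (applied consistently to the corresponding columns of U
    and V), because C and S act as scalars there.  We pick W to diagonalize
    the block's Rayleigh quotient in the network the block's end favors.
    """
    n = len(c)
    theta = np.arctan2(c, s)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs(theta[j + 1] - theta[i]) < tie_tol:
            j += 1
        if j > i:
            blk = slice(i, j + 1)
            Y = xt[:, blk]
            target = A if s[i] < c[i] else B
            Q = Y.T @ target @ Y
            _, W = np.linalg.eigh((Q + Q.T) / 2.0)
            if s[i] >= c[i]:
                # B-favoring end: put the strongest B direction first
                W = W[:, ::-1]
            xt[:, blk] = Y @ W
            U[:, blk] = U[:, blk] @ W
            V[:, blk] = V[:, blk] @ W
        i = j + 1


def compute_gsvd(pair: NetworkPair) -> GSVDFactorization:
    """Compute the GSVD of a network pair.

    Applies to singular (non-invertible) inputs as well; see the module notes
    on the canonicalization of tied generalized singular values.

    Raises
    ------
    ValueError
        If the pair has fewer than two nodes (shape/finite-entry violations are
        rejected by :class:`~netdiff.pair.NetworkPair` itself).
    """
    n = pair.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    A, B = pair.A, pair.B

    Q, R = sla.qr(np.vstack([A, B]))  # Q: 2n x 2n orthogonal, R: 2n x n
    R = R[:n, :]
    u, cs, vh = sla.cossin(Q, p=n, q=n)
    # Q11 = u[:n,:n] @ cs[:n,:n] @ vh[:n,:n]; Q21 = u[n:,n:] @ cs[n:,:n] @ vh[:n,:n]
    U = u[:n, :n].copy()
    V = u[n:, n:].copy()
    c = np.diag(cs[:n, :n]).copy()
    s = np.diag(cs[n:, :n]).copy()
    x_inv = vh[:n, :n] @ R

    order = np.argsort(c, kind="stable")  # c ascending <=> s descending
    U, V = U[:, order], V[:, order]
    c, s = c[order], s[order]
    x_inv = np.ascontiguousarray(x_inv[order, :])

    xt = x_inv.T.copy()
    _canonicalize_ties(xt, U, V, A, B, c, s)

    return GSVDFactorization(
        U=U, V=V, x_inv=np.ascontiguousarray(xt.T), c=c, s=s,
        node_labels=list(pair.node_labels),
    )


def reordering_vector(
    fact: GSVDFactorization, column: int = 1, end: str = "first"
) -> NodeOrdering:
    """Node ordering from one column of ``X^-T``.

    Parameters
    ----------
    fact
        A factorization from :func:`compute_gsvd`.
    column
        1-based column offset from the chosen end of the spectrum:
        ``(column=k, end="first")`` selects column ``k`` of ``X^-T`` (these
        favor clusters exclusive to ``B``); ``(column=k, end="last")`` selects
        column ``N + 1 - k`` (clusters exclusive to ``A``).
    end
        ``"first"`` or ``"last"``.

    Notes
    -----
    Each column is sign-normalized so its largest-magnitude component is
    positive (removing the +-x ambiguity of any singular-vector basis), then
    sorted descending with ties broken by original node index.  A cluster may
    legitimately appear at either end of the sorted vector; candidate
    generation always offers both ends.
    """
    n = fact.n_nodes
    if end not in ("first", "last"):
        raise ValueError(f"end must be 'first' or 'last', got {end!r}")
    if not 1 <= column <= n:
        raise ValueError(f"column must be in 1..{n}, got {column}")
    j = column - 1 if end == "first" else n - column
    v = fact.x_inv_t[:, j].copy()
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    perm = np.argsort(-v, kind="stable")
    return NodeOrdering(
        permutation=perm,
        source_column=j,
        end=end,
        values=v[perm],
        node_labels=list(fact.node_labels) if fact.node_labels else None,
    )


def reorder_pair(pair: NetworkPair, ordering) -> NetworkPair:
    """Symmetrically permute both matrices of ``pair`` by ``ordering``.

    ``ordering`` may be a :class:`NodeOrdering` or a plain permutation of
    ``0..N-1``; labels travel with rows/columns.
    """
    perm = ordering.permutation if isinstance(ordering, NodeOrdering) else ordering
    return pair.permuted(perm)
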