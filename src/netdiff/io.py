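"""Labelled-matrix I/O and basic heatmap export.

Canonical on-disk form: TSV (UTF-8, '.' decimal) with a header row of node
labels and the same labels in the first column; CSV is accepted on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pair import NetworkPair, SYMMETRY_ATOL

__all__ = [
    "read_labeled_matrix",
    "write_labeled_matrix",
    "load_fisher_pair",
    "export_heatmap",
    "write_permutation_table",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_labeled_matrix(path, symmetrize: bool = False):
    """Read a square labelled matrix.

    Returns ``(labels, matrix)``.  Errors on ragged rows, duplicate labels,
    non-numeric cells, non-square shape, and asymmetry beyond 1e-8 unless
    ``symmetrize=True``, which averages ``(W + W.T)/2`` with a warning.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: could not parse ({exc})") from exc
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"{path}: matrix is {frame.shape[0]}x{frame.shape[1]}, not square")
    labels = [str(x) for x in frame.index]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate node labels")
    if [str(c) for c in frame.columns] != labels:
        raise ValueError(f"{path}: header labels differ from first-column labels")
    try:
        M = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{path}: NaN or Inf entries")
    if not np.allclose(M, M.T, atol=SYMMETRY_ATOL, rtol=0.0):
        if not symmetrize:
            raise ValueError(
                f"{path}: matrix is not symmetric (tolerance {SYMMETRY_ATOL:g}); "
                "pass symmetrize=True / --symmetrize to average (W + W.T)/2"
            )
        warnings.warn(f"{path}: symmetrizing asymmetric matrix", RuntimeWarning)
        M = (M + M.T) / 2.0
    return labels, M


def write_labeled_matrix(path, labels: Sequence, matrix: np.ndarray) -> None:
    path = Path(path)
    frame = pd.DataFrame(np.asarray(matrix, float), index=list(labels),
                         columns=list(labels))
    frame.to_csv(path, sep=_sep_for(path))


def load_fisher_pair(path_a, path_b, align_labels: bool = False,
                     symmetrize: bool = False) -> NetworkPair:
    """Load two labelled matrices (e.g. per-group Fisher-z correlation
    matrices) as a :class:`~netdiff.pair.NetworkPair`.

    Both files must carry identical label sets in identical order;
    ``align_labels=True`` permits reordering the second matrix's labels to
    match the first.
    """
    labels_a, A = read_labeled_matrix(path_a, symmetrize=symmetrize)
    labels_b, B = read_labeled_matrix(path_b, symmetrize=symmetrize)
    if labels_a != labels_b:
        if not align_labels or set(labels_a) != set(labels_b):
            raise ValueError(
                "label sets/orders differ between the two matrices"
                + ("" if set(labels_a) == set(labels_b)
                   else " (and the sets themselves differ)")
            )
        pos = {lab: i for i, lab in enumerate(labels_b)}
        perm = [pos[lab] for lab in labels_a]
        B = B[np.ix_(perm, perm)]
    return NetworkPair(A=A, B=B, node_labels=labels_a)


def export_heatmap(matrix, labels: Optional[Sequence] = None, path=None,
                   title: Optional[str] = None) -> None:
    """Raster image of a weight matrix, diverging colormap centered at 0.

    Deterministic: the same input produces byte-identical files.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    M = np.asarray(matrix, float)
    vmax = max(np.abs(M).max(), 1e-12)
    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    im = ax.imshow(M, cmap="RdBu_r", norm=TwoSlopeNorm(0.0, -vmax, vmax),
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.85)
    if labels is not None and len(labels) <= 30:
        ax.set_xticks(range(len(labels)), [str(x) for x in labels],
                      rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), [str(x) for x in labels], fontsize=6)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, metadata={"Software": "netdiff"})
    plt.close(fig)


def write_permutation_table(positions: pd.DataFrame, path) -> None:
    """Write the metabolite-position table (original position, label, and the
    node's position in the first- and final-column reorderings)."""
    positions.to_csv(path, sep=_sep_for(Path(path)), index=False)
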