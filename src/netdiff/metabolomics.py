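"""Two-group metabolomics layer: differential screen, correlation networks,
and pathway over-representation.

The workflow mirrors a two-group LC-MS study.  Peak intensities (samples x
metabolites, with a two-level group factor) yield, per group, an all-pairs
Pearson correlation matrix across that group's samples; the correlations are
optionally Fisher transformed (``z = arctanh(r)``, variance stabilizing) and
the two matrices become a :class:`~netdiff.pair.NetworkPair` for the GSVD
reordering.  Clusters exclusive to one group that survive the permutation
test are screened for over-representation of annotated pathways with the
upper-tail hypergeometric test: with ``N`` detected metabolites of which
``m`` belong to a pathway, the probability of observing at least ``k``
pathway members in a cluster of ``n`` is ``P(X >= k)`` for
``X ~ Hypergeometric(N, m, n)``.

A per-metabolite screen of overt intensity change (fold ratio of group means
plus Welch's unequal-variance two-sample test) is included for reporting; it
plays no role in the network construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .pair import NetworkPair
from .gsvd import compute_gsvd, reordering_vector
from .clusters import ClusterCandidate, candidate_clusters, permutation_pvalue

__all__ = [
    "IntensityTable",
    "PathwayAnnotation",
    "differential_metabolites",
    "correlation_pair",
    "fisher_z",
    "hypergeometric_tail",
    "pathway_enrichment",
    "run_pipeline",
]

#: |r| is clipped to this before arctanh so duplicated metabolites stay finite.
FISHER_CLIP = 1.0 - 1e-12


@dataclass
class IntensityTable:
    """Samples x metabolites peak intensities with a two-level group factor."""

    intensities: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        self.intensities = self.intensities.astype(float)
        self.groups = self.groups.reindex(self.intensities.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if (self.intensities < 0).any().any():
            raise ValueError("intensities must be non-negative")
        if (self.intensities == 0).all(axis=0).any():
            bad = self.intensities.columns[(self.intensities == 0).all(axis=0)]
            raise ValueError(f"all-zero metabolite column(s): {list(bad)}")

    @property
    def group_levels(self) -> list:
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def metabolite_ids(self) -> list:
        return list(self.intensities.columns)

    def group_frame(self, level) -> pd.DataFrame:
        return self.intensities.loc[self.groups == level]


@dataclass
class PathwayAnnotation:
    """Metabolite -> set of pathway ids, plus optional display names.

    Metabolites with no pathway (annotated ``NA``) are allowed; they stay in
    the enrichment universe ``N`` but belong to no pathway.
    """

    membership: Dict[str, Set[str]]
    pathway_names: Dict[str, str] = field(default_factory=dict)

    def pathways_of(self, metabolite: str) -> Set[str]:
        return set(self.membership.get(metabolite, set()))

    def all_pathways(self) -> Set[str]:
        out = set()
        for s in self.membership.values():
            out |= s
        return out

    @classmethod
    def from_table(cls, frame: pd.DataFrame, names: Optional[Mapping] = None):
        """Build from a two-column table ``metabolite_id, pathway_ids`` where
        the second column is a comma-separated list ("NA" = unannotated)."""
        membership = {}
        met_col, path_col = frame.columns[:2]
        for _, row in frame.iterrows():
            raw = str(row[path_col]).strip()
            if raw.upper() in ("NA", "NAN", ""):
                membership[str(row[met_col])] = set()
            else:
                membership[str(row[met_col])] = {
                    p.strip() for p in raw.split(",") if p.strip()
                }
        return cls(membership=membership, pathway_names=dict(names or {}))


def differential_metabolites(
    table: IntensityTable,
    log_transform: bool = True,
    alpha: float = 0.05,
    ratio_bounds: tuple = (0.5, 2.0),
    mode: str = "either",
) -> pd.DataFrame:
    """Per-metabolite fold change and Welch two-sample p-value.

    ``ratio`` is the second-group / first-group ratio of mean raw intensities
    (treated over control when groups appear in that order).  The p-value is
    Welch's unequal-variance t-test on log10 intensities by default.
    Significance: ``mode="either"`` flags ``p < alpha`` and/or a ratio outside
    ``ratio_bounds``; ``"both"`` requires both; ``"p"``/``"ratio"`` use one
    criterion alone.
    """
    levels = table.group_levels
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    ctrl = table.group_frame(levels[0])
    trt = table.group_frame(levels[1])
    ratio = trt.mean(axis=0) / ctrl.mean(axis=0)

    x = np.log10(np.maximum(trt.to_numpy(), 1e-300)) if log_transform else trt.to_numpy()
    y = np.log10(np.maximum(ctrl.to_numpy(), 1e-300)) if log_transform else ctrl.to_numpy()
    res = stats.ttest_ind(x, y, axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # degenerate zero-variance columns: identical groups carry no evidence
    degenerate = np.isnan(pvals)
    if degenerate.any():
        same = np.isclose(x.mean(axis=0), y.mean(axis=0))
        pvals[degenerate & same] = 1.0
        pvals[degenerate & ~same] = 0.0

    lo, hi = ratio_bounds
    by_p = pvals < alpha
    by_ratio = (ratio < lo) | (ratio > hi)
    if mode == "either":
        sig = by_p | by_ratio
    elif mode == "both":
        sig = by_p & by_ratio
    elif mode == "p":
        sig = by_p
    elif mode == "ratio":
        sig = by_ratio
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        {
            "metabolite_id": table.metabolite_ids,
            "ratio": ratio.to_numpy(),
            "p_value": pvals,
            "significant": np.asarray(sig),
        }
    ).set_index("metabolite_id")


def fisher_z(r):
    """Fisher transform ``z = arctanh(r)`` with |r| clipped away from 1."""
    r = np.clip(np.asarray(r, dtype=float), -FISHER_CLIP, FISHER_CLIP)
    return np.arctanh(r)


def _group_correlation(frame: pd.DataFrame, level, log_transform: bool) -> np.ndarray:
    if len(frame) < 3:
        raise ValueError(
            f"group {level!r} has {len(frame)} samples; need >= 3 for correlations"
        )
    X = frame.to_numpy()
    if log_transform:
        X = np.log10(np.maximum(X, 1e-300))
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = frame.columns[sd == 0]
        raise ValueError(
            f"constant metabolite(s) within group {level!r}: {list(bad)}"
        )
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def _partialize(R: np.ndarray) -> np.ndarray:
    """Precision-matrix partial correlations from a correlation matrix."""
    P = np.linalg.pinv(R)
    d = np.sqrt(np.abs(np.diag(P)))
    out = -P / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return np.clip((out + out.T) / 2.0, -1.0, 1.0)


def correlation_pair(
    table: IntensityTable,
    fisher: bool = True,
    log_transform: bool = True,
    partial: bool = False,
) -> NetworkPair:
    """Per-group all-pairs Pearson correlation matrices as a network pair.

    ``A`` is the first group level (in order of appearance), ``B`` the second.
    With ``fisher=True`` every off-diagonal ``r`` is replaced by ``arctanh(r)``
    (clipped); diagonals are kept at 1 as given.  ``partial=True`` converts
    each matrix to precision-matrix partial correlations first (off by
    default; plain pairwise Pearson is the standard construction here).
    """
    levels = table.group_levels
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    mats = []
    for level in levels:
        R = _group_correlation(table.group_frame(level), level, log_transform)
        if partial:
            R = _partialize(R)
        if fisher:
            Z = fisher_z(R)
            np.fill_diagonal(Z, np.diag(R))
            R = Z
        mats.append(R)
    return NetworkPair(A=mats[0], B=mats[1], node_labels=table.metabolite_ids)


def hypergeometric_tail(N: int, n: int, m: int, k: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``N`` detected items, ``m`` of them marked (pathway members), ``n`` drawn
    (cluster size), ``k`` marked items observed in the draw.
    """
    N, n, m, k = int(N), int(n), int(m), int(k)
    if min(N, n, m, k) < 0 or n > N or m > N:
        raise ValueError(f"infeasible counts N={N}, n={n}, m={m}, k={k}")
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n={n}, m={m})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def pathway_enrichment(
    cluster,
    annot: PathwayAnnotation,
    N: int,
    metabolite_ids: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every pathway with at least one
    member in the cluster.

    ``cluster`` is a :class:`~netdiff.clusters.ClusterCandidate` together with
    ``metabolite_ids`` (universe labels, index-aligned), or directly an
    iterable of metabolite ids.  ``N`` is the total number of detected
    metabolites (the universe includes unannotated ones); ``m`` counts
    detected pathway members, ``k`` the cluster's.  A plain 0.05 threshold
    flags significance; a Benjamini-Hochberg column is reported alongside but
    not used for the flag.
    """
    if isinstance(cluster, ClusterCandidate):
        if metabolite_ids is None:
            raise ValueError("metabolite_ids needed to resolve cluster indices")
        cluster_mets = [metabolite_ids[i] for i in cluster.node_indices]
    else:
        cluster_mets = list(cluster)
    n = len(cluster_mets)
    if N < n:
        raise ValueError(f"universe N={N} smaller than cluster n={n}")
    universe = list(metabolite_ids) if metabolite_ids is not None else list(
        annot.membership
    )

    m_counts: Dict[str, int] = {}
    for met in universe:
        for p in annot.pathways_of(met):
            m_counts[p] = m_counts.get(p, 0) + 1
    k_counts: Dict[str, int] = {}
    for met in cluster_mets:
        for p in annot.pathways_of(met):
            k_counts[p] = k_counts.get(p, 0) + 1

    rows = []
    for pid in sorted(k_counts):
        k, m = k_counts[pid], m_counts[pid]
        p_upper = hypergeometric_tail(N, n, m, k)
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": annot.pathway_names.get(pid, pid),
                "k": k,
                "n": n,
                "m": m,
                "N": N,
                "p_upper": p_upper,
                "significant": p_upper < alpha,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["pathway_id", "pathway_name", "k", "n", "m", "N",
                 "p_upper", "significant"],
    )
    if len(frame):
        frame["p_bh"] = stats.false_discovery_control(frame["p_upper"], method="bh")
    else:
        frame["p_bh"] = pd.Series(dtype=float)
    return frame.set_index("pathway_id")


def run_pipeline(
    table: IntensityTable,
    annot: Optional[PathwayAnnotation] = None,
    taus: Sequence[int] = (),
    M: int = 1000,
    scheme: str = "permutation",
    combiner: str = "difference",
    fisher: bool = True,
    log_transform: bool = True,
    alpha: float = 0.05,
    n_columns: int = 1,
    seed: Optional[int] = None,
) -> dict:
    """End-to-end two-group analysis.

    Differential screen -> per-group (Fisher-transformed) correlation pair ->
    GSVD -> orderings from ``n_columns`` columns at each spectrum end ->
    head/tail candidates at each ``tau`` -> permutation p-values -> pathway
    enrichment for clusters passing ``alpha``.  ``combiner="difference"`` is
    the default because the correlation weights are signed.

    Returns a dict with keys ``differential`` (DataFrame), ``pair``,
    ``factorization``, ``positions`` (DataFrame mapping each metabolite's
    original position to its position in the first- and final-column
    orderings), ``clusters`` (list of dicts) and ``enrichment`` (dict keyed by
    cluster id).
    """
    if not taus:
        raise ValueError("taus must be a non-empty list of cluster sizes "
                         "(automatic size selection is out of scope)")
    diff = differential_metabolites(table, log_transform=log_transform, alpha=alpha)
    pair = correlation_pair(table, fisher=fisher, log_transform=log_transform)
    fact = compute_gsvd(pair)
    n = pair.n_nodes
    rng = np.random.default_rng(seed)

    orderings = []
    for col in range(1, n_columns + 1):
        orderings.append(reordering_vector(fact, col, "first"))
        orderings.append(reordering_vector(fact, col, "last"))

    first = reordering_vector(fact, 1, "first")
    final = reordering_vector(fact, 1, "last")
    inv_first = np.argsort(first.permutation)
    inv_final = np.argsort(final.permutation)
    positions = pd.DataFrame(
        {
            "original_position": np.arange(1, n + 1),
            "label": pair.node_labels,
            "position_first_column": inv_first + 1,
            "position_final_column": inv_final + 1,
        }
    )

    clusters = []
    enrichment = {}
    for ordering in orderings:
        for cand in candidate_clusters(ordering, taus):
            test = permutation_pvalue(
                pair, cand, M=M, scheme=scheme,
                seed=int(rng.integers(2 ** 31)),
                measure="weighted", combiner=combiner,
            )
            col1, end, offset = cand.source
            cid = f"{end}_col{col1}_off{offset}_tau{cand.tau}"
            entry = {
                "cluster_id": cid,
                "target_network": cand.target_network,
                "tau": cand.tau,
                "source": cand.source,
                "node_indices": cand.node_indices.tolist(),
                "metabolites": [pair.node_labels[i] for i in cand.node_indices],
                "f_target": test.observed.f_target,
                "f_other": test.observed.f_other,
                "c_value": test.observed.c_value,
                "p_value": test.p_value,
                "p_value_corrected": test.p_value_corrected,
                "M": M,
                "scheme": scheme,
                "significant": test.p_value < alpha,
            }
            clusters.append(entry)
            if entry["significant"] and annot is not None:
                enrichment[cid] = pathway_enrichment(
                    cand, annot, N=n, metabolite_ids=pair.node_labels, alpha=alpha
                )
    return {
        "differential": diff,
        "pair": pair,
        "factorization": fact,
        "positions": positions,
        "clusters": clusters,
        "enrichment": enrichment,
        "config": {
            "taus": list(taus), "M": M, "scheme": scheme, "combiner": combiner,
            "fisher": fisher, "log_transform": log_transform, "alpha": alpha,
            "n_columns": n_columns, "seed": seed,
        },
    }
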