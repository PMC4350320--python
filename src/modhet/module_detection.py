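"""Module detection: topological overlap, UPGMA clustering, dendrogram cutting.

The adjacency matrix is converted to a topological overlap matrix (TOM, a
normalized shared-neighbour similarity), 1 - TOM serves as the clustering
dissimilarity, average-linkage hierarchical clustering builds the dendrogram,
and an adaptive (dynamic-hybrid-style) cut labels branches as modules.
Modules are named from a fixed colour palette by decreasing size; leftover
genes are labelled ``grey``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

UNASSIGNED = "grey"

#: Fixed ordered palette; modules get colours by decreasing size.
MODULE_COLORS = (
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
    "greenyellow",
    "tan",
    "salmon",
    "cyan",
    "midnightblue",
    "lightcyan",
    "grey60",
    "lightgreen",
    "lightyellow",
    "royalblue",
)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM: omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    l_ij = sum over u != i,j of a_iu * a_uj counts shared (weighted)
    neighbours; k_i is connectivity with the self-loop excluded. The
    diagonal is 1 by convention.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # includes u = i and u = j terms only via zeroed diagonal: none
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (l + a) / denom
    omega = np.nan_to_num(omega, nan=0.0)
    np.fill_diagonal(omega, 1.0)
    omega = np.clip(omega, 0.0, 1.0)
    return pd.DataFrame(omega, index=adjacency.index, columns=adjacency.columns)


def tom_dissimilarity(tom: pd.DataFrame) -> pd.DataFrame:
    """d = 1 - TOM, a [0, 1] dissimilarity with zero diagonal."""
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=tom.index, columns=tom.columns)


def average_linkage(dissimilarity: pd.DataFrame) -> np.ndarray:
    """UPGMA merge tree (scipy linkage matrix) from a square dissimilarity.

    Ties merge lowest-index pair first (scipy's deterministic nn-chain
    order), so trees are reproducible.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    condensed = squareform(d, checks=False)
    return linkage(condensed, method="average")


#: deep_split -> cut height as a fraction of the merge-height range; the
#: default (2) is the conventional 99% adaptive cut, higher levels cut lower
#: to resolve finer substructure.
_DEEP_SPLIT_FRACTION = {0: 0.997, 1: 0.994, 2: 0.99, 3: 0.98, 4: 0.96}


def dynamic_hybrid_cut(
    tree: np.ndarray,
    dissimilarity: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
    pam_stage: bool = True,
) -> pd.Series:
    """Cut the dendrogram into modules (adaptive-height core of Dynamic Hybrid).

    Stage 1 cuts the tree at an adaptive height — a fraction of the merge
    height range controlled by ``deep_split`` (0 = shallow, 4 = deep) — and
    keeps branches of at least ``min_module_size`` leaves as candidate
    modules. Stage 2 (the PAM-like step, if ``pam_stage``) assigns each
    leftover gene to the module with smallest average dissimilarity,
    provided it is no farther than that module's most peripheral member.

    Returns a gene -> colour label Series; unassigned genes get ``grey``.
    """
    if deep_split not in _DEEP_SPLIT_FRACTION:
        raise ValueError("deep_split must be in {0, 1, 2, 3, 4}")
    genes = dissimilarity.index
    n = len(genes)
    if min_module_size > n:
        return pd.Series(UNASSIGNED, index=genes, name="module_label")
    d = dissimilarity.to_numpy(dtype=float)
    heights = tree[:, 2]
    h_lo, h_hi = float(heights.min()), float(heights.max())
    cut = h_lo + _DEEP_SPLIT_FRACTION[deep_split] * (h_hi - h_lo)
    flat = fcluster(tree, t=cut, criterion="distance")
    labels = np.full(n, -1, dtype=int)
    module_members: list[np.ndarray] = []
    for cid in np.unique(flat):
        members = np.flatnonzero(flat == cid)
        if members.size >= min_module_size:
            labels[members] = len(module_members)
            module_members.append(members)
    if pam_stage and module_members:
        _pam_assign(d, labels, module_members)
    return _colour_labels(labels, genes)


def _pam_assign(d: np.ndarray, labels: np.ndarray, modules: list[np.ndarray]) -> None:
    """Assign unlabeled genes to the nearest module within its joining radius."""
    thresholds = []
    mean_to_module = []
    for members in modules:
        inner = d[np.ix_(members, members)]
        # average distance of each member to the rest of its module
        member_avg = inner.sum(axis=1) / (members.size - 1)
        thresholds.append(member_avg.max())
        mean_to_module.append(d[:, members].mean(axis=1))
    mean_to_module = np.column_stack(mean_to_module)
    thresholds = np.asarray(thresholds)
    for i in np.flatnonzero(labels < 0):
        best = int(np.argmin(mean_to_module[i]))
        if mean_to_module[i, best] <= thresholds[best]:
            labels[i] = best


def _colour_labels(labels: np.ndarray, genes: pd.Index) -> pd.Series:
    sizes = pd.Series(labels[labels >= 0]).value_counts()
    # decreasing size, stable for equal sizes by original module id
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    names = {}
    for rank, mid in enumerate(order):
        if rank < len(MODULE_COLORS):
            names[mid] = MODULE_COLORS[rank]
        else:
            names[mid] = f"module_{rank + 1}"
    out = [names[m] if m >= 0 else UNASSIGNED for m in labels]
    return pd.Series(out, index=genes, name="module_label")


def module_sizes(assignment: pd.Series) -> pd.Series:
    """Per-module gene counts, largest first, excluding the unassigned label."""
    sizes = assignment[assignment != UNASSIGNED].value_counts()
    return sizes.sort_values(ascending=False)
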