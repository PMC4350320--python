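"""Beta-diversity via multivariate analysis of dispersion (PERMDISP).

A group's beta-diversity is the mean distance of its samples to the group
centre (spatial median or centroid) in the principal-coordinate embedding of
a dissimilarity matrix. Equality of dispersions between groups is tested by
one-way ANOVA on those distances, with significance from permutation of the
least-squares residuals, and Benjamini-Hochberg FDR over the comparison
family.

For non-Euclidean dissimilarities the embedding has negative eigenvalues;
the corresponding "imaginary" axes contribute negatively to squared
distances (z^2 = d_real^2 - d_imag^2, floored at 0), following Anderson's
dispersion method. For Euclidean input the whole path reduces to plain
geometry in the original space.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

CENTER_TYPES = ("spatial_median", "centroid")


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples (columns) of a gene matrix."""
    coords = matrix.to_numpy(dtype=float).T
    d = squareform(pdist(coords, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass
class PCoAEmbedding:
    """Principal-coordinate embedding with real and imaginary axis blocks."""

    real: np.ndarray  # samples x n_pos
    imag: np.ndarray  # samples x n_neg (axes of negative eigenvalues)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    sample_ids: pd.Index


def pcoa_embed(d: pd.DataFrame, negligible_rtol: float = 1e-8) -> PCoAEmbedding:
    """Gower-centre -0.5 d^2 and eigendecompose.

    Axes with eigenvalues below ``negligible_rtol`` times the largest
    eigenvalue in magnitude are dropped. Negative-eigenvalue axes are kept
    in a separate block scaled by sqrt(-lambda).
    """
    dm = d.to_numpy(dtype=float)
    n = dm.shape[0]
    if dm.shape[1] != n or not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    a = -0.5 * dm**2
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    evals, evecs = eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = negligible_rtol * max(np.abs(evals).max(), 1.0)
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return PCoAEmbedding(real=real, imag=imag, eigenvalues=evals, sample_ids=d.index)


def _spatial_median(points: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Geometric median by Weiszfeld iteration with a coincidence guard."""
    if points.shape[0] == 1:
        return points[0].copy()
    center = points.mean(axis=0)
    for _ in range(max_iter):
        delta = points - center
        dist = np.sqrt(np.sum(delta**2, axis=1))
        at_point = dist < 1e-12
        if at_point.any():
            # Vardi-Zhang adjustment: treat the coincident point separately
            dist = np.where(at_point, np.inf, dist)
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if at_point.any():
            # pull toward the coincident data point unless it is optimal
            r = np.linalg.norm(((points - center) * w[:, None]).sum(axis=0))
            eta = at_point.sum()
            if r <= eta:
                return center
            new = max(0.0, 1.0 - eta / r) * new + min(1.0, eta / r) * center
        if np.linalg.norm(new - center) < tol:
            return new
        center = new
    return center


def group_center(
    coords: np.ndarray, members: np.ndarray, center_type: str = "spatial_median"
) -> np.ndarray:
    """Centre of a group of rows: coordinate mean or geometric median."""
    if center_type not in CENTER_TYPES:
        raise ValueError(f"center_type must be one of {CENTER_TYPES}")
    pts = coords[members]
    if pts.shape[0] == 0:
        raise ValueError("empty member set")
    if center_type == "centroid":
        return pts.mean(axis=0)
    return _spatial_median(pts)


def distances_to_center(
    embedding: PCoAEmbedding,
    groups: pd.Series,
    center_type: str = "spatial_median",
    bias_adjust: bool = True,
) -> pd.Series:
    """Per-sample distance z to its own group centre.

    Real axes contribute positively and imaginary axes negatively:
    z^2 = d_real^2 - d_imag^2, floored at 0. For Euclidean dissimilarities
    the imaginary block is empty and z is the plain Euclidean distance.

    ``bias_adjust`` multiplies each group's distances by sqrt(n/(n-1)),
    correcting the downward bias of distances to a fitted centre; with
    strongly unbalanced group sizes (5 vs 80 samples) the uncorrected bias
    alone can masquerade as a dispersion difference.
    """
    groups = groups.reindex(embedding.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    z2 = np.zeros(len(groups))
    for label in groups.unique():
        members = np.flatnonzero((groups == label).to_numpy())
        d2 = np.zeros(members.size)
        for block, sign in ((embedding.real, 1.0), (embedding.imag, -1.0)):
            if block.shape[1] == 0:
                continue
            center = group_center(block, members, center_type)
            d2 += sign * np.sum((block[members] - center) ** 2, axis=1)
        d2 = np.maximum(d2, 0.0)
        if bias_adjust and members.size > 1:
            d2 *= members.size / (members.size - 1)
        z2[members] = d2
    z = np.sqrt(z2)
    return pd.Series(z, index=embedding.sample_ids, name="distance_to_center")


def beta_diversity(z: pd.Series, groups: pd.Series) -> pd.Series:
    """Per-group beta-diversity: the mean distance-to-centre of its samples."""
    groups = groups.reindex(z.index)
    return z.groupby(groups, sort=False).mean().rename("beta_diversity")


def _anova_f(z: np.ndarray, group_idx: np.ndarray, n_groups: int) -> float:
    n = z.size
    counts = np.bincount(group_idx, minlength=n_groups).astype(float)
    means = np.bincount(group_idx, weights=z, minlength=n_groups) / counts
    grand = z.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((z - means[group_idx]) ** 2))
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


@dataclass
class ComparisonResult:
    """Pairwise dispersion test between two groups."""

    group_a: str
    group_b: str
    beta_div_a: float
    beta_div_b: float
    f_statistic: float
    p_value: float
    n_permutations: int
    fdr_adjusted_p: float | None = None


def permdisp_test(
    z: pd.Series,
    groups: pd.Series,
    n_permutations: int = 10_000,
    seed: int | np.random.SeedSequence | None = 0,
    scheme: str = "residuals",
) -> ComparisonResult:
    """Permutation ANOVA on distances-to-centre for exactly two groups.

    The observed statistic is the one-way ANOVA F on z. The null
    distribution permutes the least-squares residuals of the group model
    (z minus its own group mean) across all samples of the two groups and
    recomputes F on the permuted residuals, so any true between-group
    difference is removed from the null.
    p = (1 + #{F* >= F_obs}) / (1 + n_permutations), so the smallest
    attainable p is 1/(n_permutations + 1).

    ``scheme="labels"`` instead permutes the raw distances across the two
    groups (classical label permutation); both are valid under the null.
    """
    groups = groups.reindex(z.index)
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("permdisp_test compares exactly 2 groups")
    zv = z.to_numpy(dtype=float)
    gidx = (groups == labels[1]).to_numpy().astype(int)
    counts = np.bincount(gidx, minlength=2)
    if counts.min() < 2:
        raise ValueError("each group needs >= 2 members for a testable comparison")
    if scheme not in ("residuals", "labels"):
        raise ValueError("scheme must be 'residuals' or 'labels'")
    f_obs = _anova_f(zv, gidx, 2)
    means = np.bincount(gidx, weights=zv, minlength=2) / counts
    source = zv - means[gidx] if scheme == "residuals" else zv
    rng = np.random.default_rng(seed)
    zstar = rng.permuted(np.tile(source, (n_permutations, 1)), axis=1)
    n = zv.size
    counts_f = counts.astype(float)
    in_b = (gidx == 1).astype(float)
    sum_b = zstar @ in_b
    sum_a = zstar.sum(axis=1) - sum_b
    mean_a, mean_b = sum_a / counts_f[0], sum_b / counts_f[1]
    grand = zstar.mean(axis=1)
    ssb = counts_f[0] * (mean_a - grand) ** 2 + counts_f[1] * (mean_b - grand) ** 2
    sst = np.sum((zstar - grand[:, None]) ** 2, axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = ssb / (ssw / (n - 2))
    f_star = np.where(ssw <= 1e-300, np.where(ssb > 0, np.inf, 0.0), f_star)
    p = (1.0 + np.sum(f_star >= f_obs - 1e-12)) / (1.0 + n_permutations)
    bd = beta_diversity(z, groups)
    return ComparisonResult(
        group_a=str(labels[0]),
        group_b=str(labels[1]),
        beta_div_a=float(bd[labels[0]]),
        beta_div_b=float(bd[labels[1]]),
        f_statistic=float(f_obs),
        p_value=float(p),
        n_permutations=int(n_permutations),
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order of input restored."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def comparison_seed(master_seed: int, *context: str) -> np.random.SeedSequence:
    """Deterministic per-comparison seed from the master seed and context labels.

    Comparisons are independent yet reproducible: the same (master seed,
    module label, group pair) always yields the same stream.
    """
    digest = zlib.crc32("\x1f".join(context).encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, digest])
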