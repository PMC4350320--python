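"""Signed weighted co-expression network construction.

Pipeline: biweight midcorrelation between all gene pairs -> signed
similarity s_ij = (1 + cor_ij)/2 in [0, 1] -> soft-thresholded adjacency
a_ij = s_ij**beta, with beta chosen so the connectivity distribution
approximates scale-free topology (R^2 of the log-log degree fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def bicor_matrix(matrix: pd.DataFrame, pearson_fallback: bool = False) -> pd.DataFrame:
    """Biweight midcorrelation between all pairs of genes (rows).

    Each observation is weighted by w = (1 - u^2)^2 with
    u = (x - median) / (9 * madn), madn the unscaled MAD, and w = 0 outside
    |u| < 1, which makes the coefficient robust to single large outliers
    while closely tracking Pearson on clean data.

    Rows with zero MAD (constant rows or a strict majority of identical
    values) cannot be weighted; they raise unless ``pearson_fallback`` is
    set, in which case those rows fall back to plain centred deviations.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 4:
        raise ValueError("biweight midcorrelation needs at least 4 samples")
    med = np.median(x, axis=1, keepdims=True)
    dev = x - med
    madn = np.median(np.abs(dev), axis=1, keepdims=True)
    degenerate = madn[:, 0] == 0
    if degenerate.any() and not pearson_fallback:
        offender = matrix.index[np.flatnonzero(degenerate)[0]]
        raise ValueError(
            f"gene {offender!r} has zero MAD; enable pearson_fallback or drop it"
        )
    safe_mad = np.where(madn == 0, 1.0, madn)
    u = dev / (9.0 * safe_mad)
    w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    if degenerate.any():
        # Pearson weighting (all ones) around the mean for degenerate rows
        dev = np.where(degenerate[:, None], x - x.mean(axis=1, keepdims=True), dev)
        w = np.where(degenerate[:, None], 1.0, w)
    weighted = dev * w
    norms = np.sqrt(np.sum(np.square(weighted), axis=1, keepdims=True))
    if (norms == 0).any():
        offender = matrix.index[np.flatnonzero(norms[:, 0] == 0)[0]]
        raise ValueError(f"gene {offender!r} is constant; correlation undefined")
    unit = weighted / norms
    cor = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=matrix.index, columns=matrix.index)


def to_similarity(cor: pd.DataFrame) -> pd.DataFrame:
    """Signed similarity s_ij = (1 + cor_ij) / 2, mapping [-1, 1] onto [0, 1]."""
    values = cor.to_numpy(dtype=float)
    if values.min() < -1 - 1e-12 or values.max() > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    return (1.0 + cor) / 2.0


def to_adjacency(similarity: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Power adjacency a_ij = s_ij**beta (soft thresholding).

    The diagonal is stored as 1 and excluded from connectivity sums.
    """
    if beta < 1:
        raise ValueError("soft threshold beta must be a positive integer")
    adj = np.power(np.abs(similarity.to_numpy(dtype=float)), beta)
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=similarity.index, columns=similarity.columns)


def connectivity(adjacency: pd.DataFrame) -> pd.Series:
    """k_i = sum of weighted connections of node i to all other nodes."""
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=adjacency.index, name="connectivity")


def scale_free_fit(k: np.ndarray | pd.Series, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free fitting index R^2 and slope of the log-log degree fit.

    Connectivities are histogrammed into ``n_bins`` equal-width bins;
    p(k) is the fraction of nodes per occupied bin and k-bar the mean
    connectivity there; the regression is log10(p) on log10(k-bar).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        raise ValueError("scale-free fit needs at least 2 positive connectivities")
    if np.allclose(k, k[0]):
        raise ValueError("all connectivities equal; log-log fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    occupied = counts > 0
    if occupied.sum() < 2:
        raise ValueError("fewer than 2 occupied bins; increase data or reduce bins")
    k_bar = np.bincount(which, weights=k, minlength=n_bins)[occupied] / counts[occupied]
    p = counts[occupied] / k.size
    log_k, log_p = np.log10(k_bar), np.log10(p)
    if np.allclose(log_k, log_k[0]) or np.allclose(log_p, log_p[0]):
        raise ValueError("degenerate binned distribution; fit undefined")
    r = np.corrcoef(log_k, log_p)[0, 1]
    slope = np.polyfit(log_k, log_p, 1)[0]
    return float(r * r), float(slope)


@dataclass
class SoftThresholdReport:
    """Scan of candidate soft thresholds with the chosen beta.

    ``table`` has one row per candidate: beta, r_squared, slope and
    mean/median/max connectivity.
    """

    table: pd.DataFrame
    chosen_beta: int

    def to_json_dict(self) -> dict:
        return {
            "chosen_beta": int(self.chosen_beta),
            "scan": self.table.to_dict(orient="records"),
        }


def pick_soft_threshold(
    similarity: pd.DataFrame,
    betas: range | list[int] = range(1, 31),
    r2_target: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Scan soft thresholds and pick the smallest beta reaching the R^2 target.

    A candidate qualifies only if the log-log fit has negative slope
    (scale-free topology requires a decreasing p(k)). If no candidate reaches
    ``r2_target``, the qualifying beta with maximal R^2 is chosen; if no
    candidate has negative slope at all, the overall argmax R^2 is returned.
    """
    betas = list(betas)
    if not betas:
        raise ValueError("empty beta candidate list")
    if not (0 < r2_target <= 1):
        raise ValueError("r2_target must be in (0, 1]")
    rows = []
    for beta in betas:
        adj = to_adjacency(similarity, beta)
        k = connectivity(adj).to_numpy()
        try:
            r2, slope = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2, slope = np.nan, np.nan
        rows.append(
            {
                "beta": beta,
                "r_squared": r2,
                "slope": slope,
                "mean_k": float(np.mean(k)),
                "median_k": float(np.median(k)),
                "max_k": float(np.max(k)),
            }
        )
    table = pd.DataFrame(rows)
    valid = table[(table["slope"] < 0) & table["r_squared"].notna()]
    hit = valid[valid["r_squared"] >= r2_target]
    if len(hit):
        chosen = int(hit["beta"].iloc[0])
    elif len(valid):
        chosen = int(valid.loc[valid["r_squared"].idxmax(), "beta"])
    else:
        chosen = int(table.loc[table["r_squared"].idxmax(), "beta"])
    return SoftThresholdReport(table=table, chosen_beta=chosen)
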