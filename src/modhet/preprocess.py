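"""Probe-level log-ratio data -> filtered, comparable gene x sample matrix.

The pipeline order is: collapse probes to genes, select samples (driven by
the annotation file, not computed here), quantile-normalize the arrays,
filter genes by median absolute deviation (MAD), and — per analysis —
robust-standardize each gene to median 0 / MAD 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: scipy/R consistency constant making MAD unbiased for the s.d. of a normal.
MAD_SCALE = 1.4826


def mad(values: np.ndarray, axis: int = -1, constant: float = MAD_SCALE) -> np.ndarray:
    """Median absolute deviation along ``axis``, scaled by ``constant``."""
    med = np.median(values, axis=axis, keepdims=True)
    return constant * np.median(np.abs(values - med), axis=axis)


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Average probe rows mapping to the same gene symbol; drop unmapped probes.

    Parameters
    ----------
    probe_matrix : probes x samples matrix.
    probe_map : probe_id -> gene symbol; probes absent from the map or with a
        null symbol are discarded.

    Returns
    -------
    Gene x samples matrix with one row per distinct mapped symbol, the
    arithmetic mean of the gene's probe rows. Rows are ordered by first
    appearance of each gene among the probes.
    """
    genes = probe_map.reindex(probe_matrix.index)
    mapped = genes.notna()
    if not mapped.any():
        raise ValueError("no probe maps to a gene symbol; nothing to collapse")
    kept = probe_matrix.loc[mapped]
    symbols = genes[mapped]
    collapsed = kept.groupby(symbols, sort=False).mean()
    collapsed.index.name = "gene_id"
    return collapsed


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    After normalization each column, sorted, equals the across-column mean of
    order statistics; within-column ranks are preserved. Tied values within a
    column receive the mean of the reference values over their tied ranks.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.isfinite(values).all():
        raise ValueError("quantile normalization rejects missing/non-finite values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = _qn_column(values[:, j], reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _qn_column(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="stable")
    sorted_vals = col[order]
    out = np.empty_like(reference)
    # runs of equal values share the mean of the reference over their ranks
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(col)]))
    for lo, hi in zip(starts, stops):
        out[order[lo:hi]] = reference[lo:hi].mean()
    return out


def mad_filter(matrix: pd.DataFrame, q: float = 0.75) -> pd.DataFrame:
    """Keep genes whose MAD strictly exceeds the upper quartile of all MADs.

    The quartile uses linear interpolation (R type 7). The strict inequality
    means that on a continuous MAD distribution just under 25% of genes
    survive, and that a degenerate all-equal input keeps nothing.
    """
    if matrix.shape[0] < 4:
        raise ValueError("MAD filter needs at least 4 genes to define a quartile")
    mads = mad(matrix.to_numpy(dtype=float), axis=1)
    q3 = np.quantile(mads, q, method="linear")
    return matrix.loc[mads > q3]


def robust_standardize(
    matrix: pd.DataFrame, constant: float = MAD_SCALE
) -> pd.DataFrame:
    """Per gene: subtract the median and divide by the MAD.

    Every row of the result has median 0 and MAD 1, so each transcript
    contributes equally to between-sample Euclidean distances. Rows with zero
    MAD cannot be standardized and raise, naming the first offending gene.
    """
    values = matrix.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    scale = mad(values, axis=1, constant=constant)
    zero = scale == 0
    if zero.any():
        offender = matrix.index[np.flatnonzero(zero)[0]]
        raise ValueError(f"gene {offender!r} has zero MAD; cannot robust-standardize")
    out = (values - med) / scale[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocessing_report(
    n_probes: int,
    n_mapped: int,
    n_genes: int,
    n_samples: int,
    n_filtered: int,
) -> str:
    """Plain-text accounting of row/column counts at each preprocessing step."""
    lines = [
        f"probes in input\t{n_probes}",
        f"probes with gene mapping\t{n_mapped}",
        f"genes after collapsing probes\t{n_genes}",
        f"samples analysed\t{n_samples}",
        f"genes retained by MAD filter\t{n_filtered}",
    ]
    return "\n".join(lines) + "\n"
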