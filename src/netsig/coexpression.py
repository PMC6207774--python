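"""Pearson correlation and CLR background adjustment.

The Context Likelihood of Relatedness step turns each absolute correlation
|r_ij| into a signed background-corrected score: every row i of |r| is
z-scored against its own off-diagonal mean and standard deviation, and the
score of a pair is the mean of the two marginal z-scores,

    z_ij = ( (|r_ij| - mu_i)/sigma_i + (|r_ij| - mu_j)/sigma_j ) / 2 .

Scores can be negative (pairs weaker than their genes' backgrounds) or
positive; only positive scores survive thresholding and carry edge weights.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["pearson_matrix", "clr_adjust", "threshold_positive", "threshold_matrix"]


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation of a genes-x-samples matrix.

    Zero-variance genes get correlation 0 to every other gene (diagonal stays
    1) with a warning, so matrix dimensions stay aligned across tumours.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    x = expr.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("expression matrix contains missing or non-finite values")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(x)
    if flat.size:
        warnings.warn(f"{flat.size} zero-variance gene(s); correlations set to 0", stacklevel=2)
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def clr_adjust(corr: pd.DataFrame) -> pd.DataFrame:
    """Signed CLR scores from a correlation matrix.

    Background mean/sd are taken over the off-diagonal entries of each row of
    |r| (population sd); a zero-sd row contributes marginal scores of 0. The
    diagonal of the returned matrix is set to 0 (self-scores are undefined).
    """
    n = corr.shape[0]
    if n < 3:
        raise ValueError("CLR background undefined for fewer than 3 genes")
    x = np.abs(corr.to_numpy(dtype=float)).copy()
    np.fill_diagonal(x, np.nan)
    mu = np.nanmean(x, axis=1)
    sd = np.nanstd(x, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = (x - mu[:, None]) / sd[:, None]
    m[sd == 0, :] = 0.0
    m = np.nan_to_num(m, nan=0.0, posinf=0.0, neginf=0.0)
    z = (m + m.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=corr.index, columns=corr.columns)


def threshold_positive(z: pd.DataFrame) -> dict:
    """Sparse symmetric weight map of the strictly positive scores.

    Returns ``{(gene_a, gene_b): z_ab}`` with ``gene_a < gene_b`` by the input
    matrix order; absent pairs have weight 0.
    """
    genes = list(z.index)
    vals = z.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = vals[iu, ju] > 0
    return {(genes[i], genes[j]): float(vals[i, j]) for i, j in zip(iu[keep], ju[keep])}


def threshold_matrix(z: pd.DataFrame) -> pd.DataFrame:
    """Dense zero-filled view of the thresholded scores (z>0 kept, else 0)."""
    out = z.where(z > 0, 0.0).astype(float)
    np.fill_diagonal(out.values, 0.0)
    return out
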