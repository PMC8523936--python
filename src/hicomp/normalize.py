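"""Matrix balancing, cross-sample normalization and replicability.

Three independent normalization layers used by the pipeline:

* :func:`ice_balance` — Imakaev-style iterative correction of one
  chromosome's cis matrix, equalizing bin marginals and returning the
  multiplicative per-bin biases.
* :func:`cyclic_loess` — csaw/edgeR-style pairwise MA-loess normalization
  across samples, producing per-(feature, sample) additive offsets on the
  natural-log scale for use in count GLMs.
* :func:`scc_replicability` — stratum-adjusted correlation coefficient
  between two contact maps (distance-stratified Pearson correlations
  combined with Cochran stratum weights), used as a replicability index.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.ndimage import uniform_filter
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome_io import ContactMap

__all__ = ["ice_balance", "ice_balance_dense", "cyclic_loess", "scc_replicability"]


def ice_balance_dense(
    mat: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-5,
    low_coverage_quantile: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a dense symmetric matrix; returns (normalized, bias).

    Bins with zero marginal, or with marginal below the given quantile of
    the non-zero marginals, are masked (bias NaN, matrix rows/cols NaN).
    Iteration stops when the relative CV of the unmasked marginals falls
    below ``tol``.  Biases are rescaled to geometric mean 1 and the
    normalized matrix is raw / (bias_i * bias_j).
    """
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    marg = mat.sum(axis=1)
    mask = marg <= 0
    nonzero = marg[~mask]
    if len(nonzero):
        cutoff = np.quantile(nonzero, low_coverage_quantile)
        mask |= marg < cutoff
    if mask.all():
        raise ValueError("all bins masked by coverage filter")
    work = mat.copy()
    work[mask, :] = 0.0
    work[:, mask] = 0.0
    bias = np.ones(n)
    for _ in range(max_iter):
        s = work.sum(axis=1)
        live = s[~mask]
        mean = live.mean()
        if mean == 0:
            raise ValueError("all bins masked by coverage filter")
        cv = live.std() / mean
        if cv < tol:
            break
        db = np.where(mask, 1.0, s / mean)
        db[db == 0] = 1.0
        work /= np.outer(db, db)
        bias *= db
    bias[mask] = np.nan
    gmean = np.exp(np.nanmean(np.log(bias)))
    bias /= gmean
    norm = mat / np.outer(bias, bias)
    norm[mask, :] = np.nan
    norm[:, mask] = np.nan
    return norm, bias


def ice_balance(
    cmap: ContactMap,
    chrom: str | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
    low_coverage_quantile: float = 0.02,
) -> tuple[ContactMap, np.ndarray]:
    """ICE-balance the cis matrix of one chromosome of a contact map.

    Returns the normalized map (records touching masked bins dropped) and
    the bias vector over that chromosome's bins (NaN where masked).
    """
    chroms = cmap.bins.chrom_names
    if chrom is None:
        if len(chroms) != 1:
            raise ValueError("multi-chromosome map: specify chrom")
        chrom = chroms[0]
    lo, hi = cmap.bins.bin_range(chrom)
    dense = cmap.cis(chrom).to_dense(chrom)
    norm, bias = ice_balance_dense(dense, max_iter=max_iter, tol=tol,
                                   low_coverage_quantile=low_coverage_quantile)
    sub = cmap.cis(chrom)
    vals = norm[sub.bin1 - lo, sub.bin2 - lo]
    keep = ~np.isnan(vals)
    out = ContactMap(cmap.bins, sub.bin1[keep], sub.bin2[keep], vals[keep],
                     normalized=True)
    return out, bias


def cyclic_loess(
    counts: np.ndarray,
    span: float = 0.3,
    iterations: int = 2,
    prior_count: float = 0.5,
) -> np.ndarray:
    """Cyclic-loess offsets for a feature x sample count matrix.

    For every sample pair, the loess trend of M (log ratio) against A
    (average log abundance) of offset-corrected counts is split evenly
    between the two samples' offsets; offsets are re-centered per feature
    after each cycle.  Returned offsets are on the natural-log scale
    (feature x sample, row means 0): a sample with systematically doubled
    counts ends up with an offset difference of ln 2.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a feature x sample matrix with >= 2 samples")
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("sample with all-zero counts")
    y = np.log(counts + prior_count)
    nfeat, nsamp = counts.shape
    offsets = np.zeros_like(y)
    for _ in range(iterations):
        # all pairwise fits are taken from the same offset state and
        # applied together, so the result is invariant to sample order
        delta_off = np.zeros_like(offsets)
        for i, j in itertools.combinations(range(nsamp), 2):
            yi = y[:, i] - offsets[:, i]
            yj = y[:, j] - offsets[:, j]
            m = yi - yj
            a = 0.5 * (yi + yj)
            delta = 0.01 * (a.max() - a.min())
            fit = lowess(m, a, frac=span, delta=delta, return_sorted=False)
            # splitting the trend raises the offset of the higher-count
            # sample, so corrected log ratios have a flat ~0 trend
            delta_off[:, i] += fit / 2.0
            delta_off[:, j] -= fit / 2.0
        offsets += delta_off / max(nsamp - 1, 1)
        offsets -= offsets.mean(axis=1, keepdims=True)
    return offsets


def _stratum_vectors(cmapA: ContactMap, cmapB: ContactMap,
                     half_window: int, max_dist_bins: int):
    """Concatenated smoothed per-diagonal vectors across chromosomes."""
    size = 2 * half_window + 1
    per_d: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for chrom in cmapA.bins.chrom_names:
        a = uniform_filter(cmapA.cis(chrom).to_dense(chrom), size=size, mode="nearest")
        b = uniform_filter(cmapB.cis(chrom).to_dense(chrom), size=size, mode="nearest")
        n = a.shape[0]
        for d in range(1, min(max_dist_bins, n - 1) + 1):
            per_d.setdefault(d, []).append((np.diagonal(a, d), np.diagonal(b, d)))
    for d, chunks in per_d.items():
        yield (np.concatenate([x for x, _ in chunks]),
               np.concatenate([y for _, y in chunks]))


def scc_replicability(
    cmapA: ContactMap,
    cmapB: ContactMap,
    smooth_half_window: int = 1,
    max_distance: int = 5_000_000,
) -> float:
    """Stratum-adjusted correlation coefficient between two cis maps.

    Both maps are 2D-mean-filter smoothed, Pearson correlations are taken
    per genomic-distance stratum (1 bin .. max_distance), and combined
    with Cochran weights N_d * sd(X_d) * sd(Y_d).
    """
    if not cmapA.bins.equals(cmapB.bins):
        raise ValueError("maps must share one bin table")
    max_d = max(1, int(max_distance // cmapA.resolution))
    num = den = 0.0
    used = 0
    for x, y in _stratum_vectors(cmapA, cmapB, smooth_half_window, max_d):
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0 or len(x) < 2:
            continue
        r = np.corrcoef(x, y)[0, 1]
        w = len(x) * sx * sy
        num += w * r
        den += w
        used += 1
    if used < 2:
        raise ValueError("fewer than 2 strata with variance")
    return float(num / den)
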