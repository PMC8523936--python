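"""Blocks Of Differential Interactions (BODIs).

A bin touched by significant cis differential interactions is classified
by the prevalence of their logFC signs: *positive* (*negative*) when the
majority sign outnumbers the minority at least ``ratio``:1 (default
10:1), *undefined* when both signs occur without such prevalence, *none*
when the bin is touched by no DI.  Genomically adjacent bins with the
same sign (positive, negative or undefined) merge into BODIs; a *none*
bin terminates a block.  Block-size enrichment is assessed by shuffling
logFC values genome-wide across the fixed DI keys; composition against
A/B compartment segments uses a Fisher exact test, and gene expression
in negative vs positive blocks a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .genome_io import BinTable

__all__ = [
    "classify_bins", "merge_bodis", "bodi_permutation_test",
    "bodi_compartment_composition", "bodi_expression_compare",
]


def _sign_from_counts(n_pos: np.ndarray, n_neg: np.ndarray,
                      ratio: float) -> np.ndarray:
    sign = np.full(len(n_pos), "none", dtype=object)
    touched = (n_pos + n_neg) > 0
    tie = touched & (n_pos == n_neg)
    # ratio * 0 is NaN for ratio = inf, so the zero-minority case is explicit
    with np.errstate(invalid="ignore"):
        pos = touched & (n_pos > n_neg) & np.where(
            n_neg == 0, True, n_pos >= np.multiply(ratio, n_neg, dtype=float))
        neg = touched & (n_neg > n_pos) & np.where(
            n_pos == 0, True, n_neg >= np.multiply(ratio, n_pos, dtype=float))
    sign[touched] = "undefined"
    sign[pos] = "positive"
    sign[neg] = "negative"
    sign[tie] = "undefined"
    return sign


def classify_bins(ditable: pd.DataFrame, n_bins: int,
                  ratio: float = 10.0) -> pd.DataFrame:
    """Per-bin DI sign prevalence from the significant cis DIs.

    Every cis DI increments both of its endpoint bins.  Returns a frame
    with ``n_pos``, ``n_neg`` and ``sign`` for all ``n_bins`` bins.
    """
    cis = ditable[ditable["cis"] & (ditable["significant"] == True)]  # noqa: E712
    n_pos = np.zeros(n_bins, dtype=np.int64)
    n_neg = np.zeros(n_bins, dtype=np.int64)
    pos = cis["logFC"].to_numpy(dtype=float) > 0
    for col in ("bin1", "bin2"):
        b = cis[col].to_numpy(dtype=np.int64)
        np.add.at(n_pos, b[pos], 1)
        np.add.at(n_neg, b[~pos], 1)
    return pd.DataFrame({
        "bin": np.arange(n_bins),
        "n_pos": n_pos,
        "n_neg": n_neg,
        "sign": _sign_from_counts(n_pos, n_neg, ratio),
    })


def merge_bodis(binsigns: pd.DataFrame, bins: BinTable) -> pd.DataFrame:
    """Maximal runs of adjacent same-sign bins, per chromosome.

    The output partitions exactly the non-*none* bins; runs never span a
    chromosome border or a *none* bin.
    """
    sign = binsigns.sort_values("bin")["sign"].to_numpy()
    rows = []
    for chrom in bins.chrom_names:
        lo, hi = bins.bin_range(chrom)
        i = lo
        while i < hi:
            if sign[i] == "none":
                i += 1
                continue
            j = i
            while j < hi and sign[j] == sign[i]:
                j += 1
            rows.append({
                "chrom": chrom,
                "start": int(bins.starts[i]),
                "end": int(bins.ends[j - 1]),
                "sign": sign[i],
                "n_bins": j - i,
                "size": int(bins.ends[j - 1] - bins.starts[i]),
            })
            i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sign",
                                       "n_bins", "size"])


def _cumulative_size_counts(bodis: pd.DataFrame, max_size: int) -> dict[str, np.ndarray]:
    """count[sign][s-1] = number of blocks of that sign with >= s bins."""
    out = {}
    for sign in ("positive", "negative", "undefined"):
        sizes = bodis.loc[bodis["sign"] == sign, "n_bins"].to_numpy()
        hist = np.zeros(max_size, dtype=np.int64)
        for s in sizes:
            hist[: min(s, max_size)] += 1
        out[sign] = hist
    return out


def bodi_permutation_test(
    ditable: pd.DataFrame,
    bins: BinTable,
    n_perm: int = 100,
    ratio: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical enrichment p-values per (sign, size) block class.

    Each permutation shuffles the logFC values over the fixed significant
    cis DI keys, re-classifies bins and re-merges blocks.  For each sign
    and size s the p-value is the add-one-smoothed fraction of
    permutations whose count of blocks of that sign with >= s bins
    reaches the observed count.
    """
    cis = ditable[ditable["cis"] & (ditable["significant"] == True)]  # noqa: E712
    cis = cis.reset_index(drop=True)
    observed = merge_bodis(classify_bins(cis.assign(significant=True),
                                         len(bins), ratio), bins)
    max_size = int(observed["n_bins"].max()) if len(observed) else 1
    obs_counts = _cumulative_size_counts(observed, max_size)
    rng = np.random.default_rng(seed)
    ge = {s: np.zeros(max_size, dtype=np.int64) for s in obs_counts}
    logfc = cis["logFC"].to_numpy()
    for _ in range(n_perm):
        shuffled = cis.copy()
        shuffled["logFC"] = rng.permutation(logfc)
        blocks = merge_bodis(classify_bins(shuffled, len(bins), ratio), bins)
        perm_counts = _cumulative_size_counts(blocks, max_size)
        for s in ge:
            ge[s] += perm_counts[s] >= obs_counts[s]
    rows = []
    for sign in ("positive", "negative", "undefined"):
        for s in range(1, max_size + 1):
            if obs_counts[sign][s - 1] == 0:
                continue
            rows.append({
                "sign": sign,
                "min_size_bins": s,
                "observed": int(obs_counts[sign][s - 1]),
                "pvalue": (1 + int(ge[sign][s - 1])) / (1 + n_perm),
            })
    return pd.DataFrame(rows, columns=["sign", "min_size_bins", "observed",
                                       "pvalue"])


def _overlap_bp(intervals_a: pd.DataFrame, intervals_b: pd.DataFrame) -> int:
    total = 0
    for _, a in intervals_a.iterrows():
        sub = intervals_b[intervals_b["chrom"] == a["chrom"]]
        ov = np.minimum(sub["end"].to_numpy(), a["end"]) \
            - np.maximum(sub["start"].to_numpy(), a["start"])
        total += int(ov[ov > 0].sum())
    return total


def bodi_compartment_composition(bodis: pd.DataFrame,
                                 segments: pd.DataFrame,
                                 bin_size: int = 500_000) -> dict:
    """A/B genomic-space composition of positive vs negative BODIs.

    Overlaps are measured in bp; the Fisher exact test runs on the 2x2
    table of covered space expressed in bins (bp // bin_size) to keep
    counts integer-valued.
    """
    comp: dict[str, dict[str, int]] = {}
    for sign in ("positive", "negative", "undefined"):
        blocks = bodis[bodis["sign"] == sign]
        comp[sign] = {lab: _overlap_bp(blocks, segments[segments["label"] == lab])
                      for lab in ("A", "B")}
    table = np.array([
        [comp["positive"]["A"] // bin_size, comp["positive"]["B"] // bin_size],
        [comp["negative"]["A"] // bin_size, comp["negative"]["B"] // bin_size],
    ])
    result = {"composition_bp": comp}
    for sign in ("positive", "negative"):
        tot = comp[sign]["A"] + comp[sign]["B"]
        result[f"{sign}_A_fraction"] = comp[sign]["A"] / tot if tot else np.nan
    if table.sum() and table.sum(axis=1).all():
        result["fisher_pvalue"] = float(
            scipy.stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        result["fisher_pvalue"] = np.nan
    result["table_bins"] = table
    return result


def bodi_expression_compare(bodis: pd.DataFrame, genes: pd.DataFrame) -> dict:
    """Wilcoxon comparison of gene logFC in negative vs positive BODIs."""
    assignments = []
    for _, gene in genes.iterrows():
        mid = (gene["start"] + gene["end"]) // 2
        hit = bodis[(bodis["chrom"] == gene["chrom"])
                    & (bodis["start"] <= mid) & (bodis["end"] > mid)]
        assignments.append(hit["sign"].iloc[0] if len(hit) else None)
    table = genes.assign(bodi_sign=assignments)
    neg = table.loc[table["bodi_sign"] == "negative", "logFC"]
    pos = table.loc[table["bodi_sign"] == "positive", "logFC"]
    out = {"n_genes_negative": int(len(neg)), "n_genes_positive": int(len(pos))}
    if len(neg) and len(pos):
        out["pvalue"] = float(scipy.stats.mannwhitneyu(
            neg, pos, alternative="two-sided").pvalue)
        out["median_logFC_negative"] = float(neg.median())
        out["median_logFC_positive"] = float(pos.median())
    else:
        warnings.warn("no genes in one BODI class; expression test skipped",
                      stacklevel=2)
        out["pvalue"] = np.nan
    return out
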