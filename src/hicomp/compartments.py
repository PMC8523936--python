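"""A/B compartment calling and group comparison.

Compartments are called per chromosome with the classic eigenvector
recipe: ICE balancing, observed/expected by genomic distance, Pearson
correlation matrix, leading eigenvector, sign oriented by an external
covariate (gene density by default) so that positive values mark the
active A state.  Downstream: segment counting with optional NA bridging,
a Poisson GLM comparing per-chromosome segment counts between groups
(compartment fragmentation), consistent-switch detection (AAA -> BBB),
a segment-shuffling permutation test of cross-sample consistency, and
integration with gene density / expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .genome_io import BinTable, ContactMap
from .normalize import ice_balance_dense

__all__ = [
    "call_compartments", "call_genome", "segment_track", "fragmentation_test",
    "detect_switches", "consistency_test", "compartment_expression",
    "switch_expression", "gene_density_track",
]


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def _oe(balanced: np.ndarray) -> np.ndarray:
    """Observed/expected: divide each diagonal by its unmasked mean."""
    n = balanced.shape[0]
    oe = np.full_like(balanced, np.nan)
    for d in range(n):
        diag = np.diagonal(balanced, d)
        ok = ~np.isnan(diag)
        if ok.sum() == 0:
            continue
        mean = diag[ok].mean()
        if mean == 0:
            continue
        vals = diag / mean
        idx = np.arange(n - d)
        oe[idx, idx + d] = vals
        oe[idx + d, idx] = vals
    return oe


def call_compartments(
    cmap: ContactMap,
    chrom: str,
    orientation: np.ndarray,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Per-bin eigenvector values and A/B labels for one chromosome.

    ``orientation`` is a per-bin covariate over the chromosome's bins
    (e.g. gene density); the eigenvector sign is flipped if needed so
    that positive-E1 bins have the higher mean covariate.  Returns a
    track frame (chrom, start, end, E1, label) with NaN/NA on masked
    bins.  The output is invariant to scaling the input map.
    """
    lo, hi = cmap.bins.bin_range(chrom)
    n = hi - lo
    orientation = np.asarray(orientation, dtype=float)
    if len(orientation) != n:
        raise ValueError("orientation covariate does not cover the chromosome")
    dense = cmap.cis(chrom).to_dense(chrom)
    balanced, _ = ice_balance_dense(dense)
    masked = np.isnan(balanced).all(axis=1)
    if (~masked).sum() < 10:
        raise ValueError("fewer than 10 unmasked bins")
    oe = _oe(balanced)
    sub = oe[np.ix_(~masked, ~masked)]
    sub = np.where(np.isnan(sub), 1.0, sub)  # residual NaN cells are neutral
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if np.isnan(corr).all() or np.nanstd(corr) == 0:
        raise ValueError("zero-variance correlation matrix")
    corr = np.nan_to_num(corr, nan=0.0)
    w, v = np.linalg.eigh(corr)
    e1_sub = v[:, -1]
    e1 = np.full(n, np.nan)
    e1[~masked] = e1_sub
    pos, neg = e1 > 0, e1 < 0
    if pos.any() and neg.any():
        if np.nanmean(orientation[pos]) < np.nanmean(orientation[neg]):
            e1 = -e1
            pos, neg = neg, pos
    label = np.full(n, None, dtype=object)
    label[pos] = "A"
    label[neg] = "B"
    return pd.DataFrame({
        "chrom": chrom,
        "start": cmap.bins.starts[lo:hi],
        "end": cmap.bins.ends[lo:hi],
        "E1": e1,
        "label": label,
        "sample_id": sample_id,
    })


def gene_density_track(bins: BinTable, genes: pd.DataFrame) -> np.ndarray:
    """Distinct genes overlapping each bin (midpoint assignment)."""
    density = np.zeros(len(bins))
    mids = (genes["start"] + genes["end"]) // 2
    for chrom in bins.chrom_names:
        lo, hi = bins.bin_range(chrom)
        sub = genes[genes["chrom"] == chrom]
        if not len(sub):
            continue
        idx = lo + np.searchsorted(bins.starts[lo:hi],
                                   mids[genes["chrom"] == chrom], side="right") - 1
        np.add.at(density, idx, 1)
    return density


def call_genome(cmap: ContactMap, orientation_track: np.ndarray,
                sample_id: str | None = None) -> pd.DataFrame:
    """Concatenated compartment tracks over every chromosome."""
    tracks = []
    for chrom in cmap.bins.chrom_names:
        lo, hi = cmap.bins.bin_range(chrom)
        tracks.append(call_compartments(cmap, chrom, orientation_track[lo:hi],
                                        sample_id=sample_id))
    return pd.concat(tracks, ignore_index=True)


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------


def _runs(labels: list) -> list[tuple[int, int, object]]:
    """Maximal runs [(start_idx, end_idx, label)] of a label sequence."""
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((i, j, labels[i]))
        i = j
    return runs


def segment_track(track: pd.DataFrame, bridge_na: bool = True) -> pd.DataFrame:
    """Maximal same-label runs as segments (chrom, start, end, label).

    With ``bridge_na`` an NA run flanked by the same label on both sides
    is absorbed into a single segment; otherwise NA splits segments.
    NA runs at chromosome edges are never part of a segment.
    """
    segments = []
    for chrom, sub in track.groupby("chrom", sort=False):
        labels = list(sub["label"])
        if bridge_na:
            runs = _runs(labels)
            for k, (i, j, lab) in enumerate(runs):
                if lab is None and 0 < k < len(runs) - 1 \
                        and runs[k - 1][2] == runs[k + 1][2] is not None:
                    for t in range(i, j):
                        labels[t] = runs[k - 1][2]
            # re-run after bridging so chained bridges coalesce
        for i, j, lab in _runs(labels):
            if lab is None:
                continue
            segments.append({"chrom": chrom,
                             "start": int(sub["start"].iloc[i]),
                             "end": int(sub["end"].iloc[j - 1]),
                             "label": lab})
    return pd.DataFrame(segments, columns=["chrom", "start", "end", "label"])


def segment_counts(track: pd.DataFrame, bridge_na: bool = True) -> pd.Series:
    """Number of segments per chromosome."""
    seg = segment_track(track, bridge_na=bridge_na)
    counts = seg.groupby("chrom").size() if len(seg) else pd.Series(dtype=int)
    return counts.reindex(track["chrom"].unique(), fill_value=0)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def fragmentation_test(counts: pd.DataFrame) -> dict:
    """Poisson GLM of segment counts on interaction totals and group.

    ``counts`` needs columns ``count`` (segments per chromosome/sample),
    ``covariate`` (total valid interactions, any scale) and ``group``.
    The covariate is rescaled to millions; the group effect is tested
    with a Wald z-test (log link).
    """
    y = counts["count"].to_numpy()
    if np.any(y != np.round(y)) or np.any(y < 0):
        raise ValueError("segment counts must be non-negative integers")
    c = counts["covariate"].to_numpy(dtype=float) / 1e6
    # reference level = first-seen group, so beta is the second group's effect
    group = pd.Categorical(counts["group"],
                           categories=pd.unique(counts["group"]))
    x = pd.DataFrame({"covariate_m": c,
                      "group": (group.codes == 1).astype(float)})
    x = sm.add_constant(x)
    fit = sm.GLM(y, x, family=sm.families.Poisson()).fit()
    return {
        "alpha": float(fit.params["covariate_m"]),
        "beta": float(fit.params["group"]),
        "beta_se": float(fit.bse["group"]),
        "pvalue": float(fit.pvalues["group"]),
        "reference": str(group.categories[0]),
        "other": str(group.categories[1]),
    }


def _label_matrix(tracks: list[pd.DataFrame]) -> tuple[pd.DataFrame, np.ndarray]:
    """Align per-sample labels on (chrom, start); returns coords + matrix."""
    base = tracks[0][["chrom", "start", "end"]].reset_index(drop=True)
    mat = np.empty((len(base), len(tracks)), dtype=object)
    for k, tr in enumerate(tracks):
        tr = tr.reset_index(drop=True)
        if not (tr["chrom"].equals(base["chrom"]) and tr["start"].equals(base["start"])):
            raise ValueError("tracks are not aligned on the same bins")
        mat[:, k] = tr["label"].to_numpy()
    return base, mat


def detect_switches(d90_tracks: list[pd.DataFrame],
                    d110_tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Bins with a consistent compartment switch across all replicates.

    A bin switches A->B when every d90 replicate labels it A and every
    d110 replicate labels it B (symmetrically for B->A).  Bins lacking a
    label in any sample are excluded (category NA).
    """
    base, mat = _label_matrix(d90_tracks + d110_tracks)
    n90 = len(d90_tracks)
    assigned = np.all(mat != None, axis=1)  # noqa: E711
    m90, m110 = mat[:, :n90], mat[:, n90:]
    all_a90 = np.all(m90 == "A", axis=1)
    all_b90 = np.all(m90 == "B", axis=1)
    all_a110 = np.all(m110 == "A", axis=1)
    all_b110 = np.all(m110 == "B", axis=1)
    cat = np.full(len(base), "none", dtype=object)
    cat[all_a90 & all_b110] = "A->B"
    cat[all_b90 & all_a110] = "B->A"
    cat[~assigned] = None
    out = base.copy()
    out["category"] = cat
    return out


def consistency_test(d90_tracks: list[pd.DataFrame],
                     d110_tracks: list[pd.DataFrame],
                     n_perm: int = 1000, seed: int = 0) -> dict:
    """Fraction of fully-assigned bins labelled identically in all samples,
    with a segment-shuffling permutation null.

    The null preserves each sample's per-chromosome run-length structure
    and A/B totals: the order of its label segments (including NA runs)
    is shuffled independently per sample and chromosome.  The empirical
    p-value uses add-one smoothing, so it is never below 1/(n_perm + 1).
    """
    tracks = d90_tracks + d110_tracks
    base, mat = _label_matrix(tracks)
    chrom_codes = pd.Categorical(base["chrom"]).codes

    def fraction(m: np.ndarray) -> float:
        assigned = np.all(m != None, axis=1)  # noqa: E711
        if assigned.sum() == 0:
            return 0.0
        sub = m[assigned]
        same = np.all(sub == sub[:, [0]], axis=1)
        return float(same.mean())

    observed = fraction(mat)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = np.empty_like(mat)
        for k in range(mat.shape[1]):
            for c in np.unique(chrom_codes):
                idx = np.flatnonzero(chrom_codes == c)
                labels = list(mat[idx, k])
                runs = _runs(labels)
                order = rng.permutation(len(runs))
                shuffled = []
                for r in order:
                    i, j, lab = runs[r]
                    shuffled.extend([lab] * (j - i))
                perm[idx, k] = shuffled
        if fraction(perm) >= observed:
            n_ge += 1
    return {
        "fraction_consistent": observed,
        "pvalue": (1 + n_ge) / (1 + n_perm),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# Expression integration
# ---------------------------------------------------------------------------


def _genes_in_interval(genes: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    sub = genes[genes["chrom"] == chrom]
    return sub[(sub["end"] > start) & (sub["start"] < end)]


def compartment_expression(segments: pd.DataFrame, genes: pd.DataFrame,
                           expr_cols: tuple[str, str] = ("expr_d90", "expr_d110")) -> dict:
    """Per-segment gene density and mean expression, with A-vs-B Wilcoxon tests.

    Density = distinct overlapping genes / segment length (genes per Mb).
    Segments without genes have density 0 and are excluded from the
    expression comparison.
    """
    rows = []
    for _, seg in segments.iterrows():
        hits = _genes_in_interval(genes, seg["chrom"], seg["start"], seg["end"])
        n = hits["gene_id"].nunique()
        row = {"chrom": seg["chrom"], "start": seg["start"], "end": seg["end"],
               "label": seg["label"], "n_genes": n,
               "density_per_mb": n / ((seg["end"] - seg["start"]) / 1e6)}
        for col in expr_cols:
            row[f"mean_{col}"] = hits[col].mean() if n else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    stats: dict = {"segments": table}
    a = table[table["label"] == "A"]
    b = table[table["label"] == "B"]
    if len(a) and len(b):
        stats["density_pvalue"] = float(scipy.stats.mannwhitneyu(
            a["density_per_mb"], b["density_per_mb"],
            alternative="two-sided").pvalue)
        for col in expr_cols:
            av = a[f"mean_{col}"].dropna()
            bv = b[f"mean_{col}"].dropna()
            stats[f"{col}_pvalue"] = float(scipy.stats.mannwhitneyu(
                av, bv, alternative="two-sided").pvalue) if len(av) and len(bv) else np.nan
    return stats


def switch_expression(switches: pd.DataFrame, genes: pd.DataFrame) -> dict:
    """logFC distributions of genes by compartment-switch category.

    A gene takes the category of the bin containing its midpoint; genes
    on excluded (unassigned) bins are dropped.  Reports the two-sided
    Wilcoxon rank-sum p-value between the A->B and B->A categories.
    """
    cats = []
    for _, gene in genes.iterrows():
        mid = (gene["start"] + gene["end"]) // 2
        hit = switches[(switches["chrom"] == gene["chrom"])
                       & (switches["start"] <= mid) & (switches["end"] > mid)]
        cats.append(hit["category"].iloc[0] if len(hit) else None)
    table = genes.copy()
    table["category"] = cats
    table = table[table["category"].notna()]
    ab = table.loc[table["category"] == "A->B", "logFC"]
    ba = table.loc[table["category"] == "B->A", "logFC"]
    out = {
        "genes": table,
        "median_logFC": {c: float(table.loc[table["category"] == c, "logFC"].median())
                         for c in ("A->B", "none", "B->A")
                         if (table["category"] == c).any()},
    }
    if len(ab) and len(ba):
        out["ab_vs_ba_pvalue"] = float(scipy.stats.mannwhitneyu(
            ab, ba, alternative="two-sided").pvalue)
    else:
        out["ab_vs_ba_pvalue"] = np.nan
    return out
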