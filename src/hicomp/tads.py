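"""TAD comparison, boundary insulation scores and motif profiles.

TAD calling itself is upstream (caller output is consumed as BED-like
interval frames).  This module compares TAD sets across replicates and
groups using reciprocal-overlap identity, computes the local interaction
score (IS) of TAD boundaries from 50 kb contact maps, normalizes IS
across samples by cyclic loess, and derives the between-group difference
of boundary insulation (delta-IS = mean over d110 - mean over d90).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .genome_io import SampleSet
from .normalize import cyclic_loess

__all__ = [
    "tad_identity", "has_identity_match", "stable_tads", "group_specific_tads",
    "interaction_score", "tad_boundaries", "delta_is", "motif_density_profile",
]


def tad_identity(a, b, f: float = 0.9) -> bool:
    """Reciprocal-overlap identity of two intervals.

    True iff the overlap covers at least fraction ``f`` of *both*
    intervals (bedtools ``-f 0.9 -r`` semantics).  Intervals are
    (chrom, start, end) triples or mappings with those keys.
    """
    ca, sa, ea = a["chrom"], a["start"], a["end"]
    cb, sb, eb = b["chrom"], b["start"], b["end"]
    if ca != cb:
        return False
    ov = min(ea, eb) - max(sa, sb)
    return ov >= f * (ea - sa) and ov >= f * (eb - sb)


def has_identity_match(interval, tadset: pd.DataFrame, f: float = 0.9) -> bool:
    """Whether any TAD in ``tadset`` is identical to ``interval``."""
    sub = tadset[tadset["chrom"] == interval["chrom"]]
    if not len(sub):
        return False
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    ov = np.minimum(e, interval["end"]) - np.maximum(s, interval["start"])
    la = interval["end"] - interval["start"]
    return bool(np.any((ov >= f * la) & (ov >= f * (e - s))))


def stable_tads(tadsets: list[pd.DataFrame], f: float = 0.9) -> pd.DataFrame:
    """TADs of the first sample with an identity match in every other set.

    Identity matching is not transitive, so the result is anchored on the
    first sample's intervals, which serve as representatives.
    """
    if len(tadsets) < 6:
        raise ValueError("six TAD sets (3 replicates x 2 groups) required")
    anchor = tadsets[0]
    keep = [all(has_identity_match(row, other, f) for other in tadsets[1:])
            for _, row in anchor.iterrows()]
    return anchor[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def _collapse_by_identity(tads: pd.DataFrame, f: float) -> pd.DataFrame:
    """Greedy de-duplication: drop intervals identical to an earlier one."""
    tads = tads.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    kept: list[int] = []
    kept_frame = tads.iloc[0:0]
    for i, row in tads.iterrows():
        if not len(kept_frame) or not has_identity_match(row, kept_frame, f):
            kept.append(i)
            kept_frame = tads.iloc[kept]
    return kept_frame.reset_index(drop=True)


def group_specific_tads(
    group_a_sets: list[pd.DataFrame],
    group_b_sets: list[pd.DataFrame],
    f: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TADs specific to each group.

    A TAD is group-specific when an identical TAD exists in all three
    replicates of its own group and in no replicate of the other group.
    Candidates are pooled over the group's replicates and duplicates
    collapsed by identity.
    """

    def specific(own: list[pd.DataFrame], other: list[pd.DataFrame]) -> pd.DataFrame:
        pool = pd.concat(own, ignore_index=True)[["chrom", "start", "end"]]
        keep = []
        for _, row in pool.iterrows():
            if all(has_identity_match(row, s, f) for s in own) \
                    and not any(has_identity_match(row, s, f) for s in other):
                keep.append(True)
            else:
                keep.append(False)
        pool = pool[np.asarray(keep, dtype=bool)]
        if not len(pool):
            return pool.reset_index(drop=True)
        return _collapse_by_identity(pool, f)

    return specific(group_a_sets, group_b_sets), specific(group_b_sets, group_a_sets)


# ---------------------------------------------------------------------------
# Interaction score
# ---------------------------------------------------------------------------


def interaction_score(dense: np.ndarray, boundary_bin: int, window_bins: int) -> float:
    """Proportion of local interactions crossing a boundary.

    ``dense`` is one chromosome's symmetric cis matrix; the boundary sits
    at the left edge of ``boundary_bin``.  The numerator sums pairs with
    one bin strictly left and one strictly right of the boundary, both
    within ``window_bins``; the denominator sums every pair (same-side
    and crossing, diagonal included) within the window.  Returns NaN if
    the window sticks out of the chromosome or the denominator is 0.
    The score is invariant to scaling the matrix.
    """
    n = dense.shape[0]
    lo = boundary_bin - window_bins
    hi = boundary_bin + window_bins
    if lo < 0 or hi > n:
        return np.nan
    block = dense[lo:hi, lo:hi]
    total = np.triu(block).sum()
    if total == 0:
        return np.nan
    cross = dense[lo:boundary_bin, boundary_bin:hi].sum()
    return float(cross / total)


def tad_boundaries(tads: pd.DataFrame, cls: str | None = None) -> pd.DataFrame:
    """Unique (chrom, pos) boundaries: both edges of every TAD."""
    rows = []
    for _, t in tads.iterrows():
        rows.append({"chrom": t["chrom"], "pos": int(t["start"])})
        rows.append({"chrom": t["chrom"], "pos": int(t["end"])})
    out = pd.DataFrame(rows, columns=["chrom", "pos"]).drop_duplicates()
    if cls is not None:
        out["class"] = cls
    return out.reset_index(drop=True)


def delta_is(
    boundaries: pd.DataFrame,
    samples: SampleSet,
    window: int = 500_000,
    group_order: tuple[str, str] = ("d90", "d110"),
    prior: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Per-boundary interaction scores, loess-normalized, and delta-IS.

    IS is computed per boundary and sample from the fine-resolution maps;
    boundaries whose window leaves the chromosome are dropped.  The
    boundary x sample IS matrix is normalized by cyclic loess on the log
    scale and delta-IS = mean(normalized IS, d110) - mean(d90).  If the
    boundary table carries a ``class`` column, the two classes' delta-IS
    distributions are compared with a two-sided Wilcoxon rank-sum test.
    """
    res = samples.bins.resolution
    w = int(window // res)
    dense = {sid: {c: m.cis(c).to_dense(c) for c in samples.bins.chrom_names}
             for sid, m in zip(samples.sample_ids, samples.maps)}
    scores = np.full((len(boundaries), len(samples.sample_ids)), np.nan)
    for i, (_, b) in enumerate(boundaries.iterrows()):
        bb = int(b["pos"]) // res
        for k, sid in enumerate(samples.sample_ids):
            scores[i, k] = interaction_score(dense[sid][b["chrom"]], bb, w)
    ok = ~np.isnan(scores).any(axis=1)
    table = boundaries[ok].reset_index(drop=True)
    scores = scores[ok]
    offsets = cyclic_loess(scores, prior_count=prior)
    norm = np.exp(np.log(scores + prior) - offsets) - prior
    groups = np.asarray(samples.groups)
    d90 = norm[:, groups == group_order[0]].mean(axis=1)
    d110 = norm[:, groups == group_order[1]].mean(axis=1)
    for k, sid in enumerate(samples.sample_ids):
        table[f"IS_{sid}"] = scores[:, k]
    table["delta_IS"] = d110 - d90
    stats: dict = {}
    if "class" in table.columns:
        classes = table["class"].unique()
        stats["mean_delta_IS"] = {c: float(table.loc[table["class"] == c, "delta_IS"].mean())
                                  for c in classes}
        if len(classes) == 2:
            x = table.loc[table["class"] == classes[0], "delta_IS"]
            y = table.loc[table["class"] == classes[1], "delta_IS"]
            stats["class_pvalue"] = float(scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided").pvalue)
    return table, stats


# ---------------------------------------------------------------------------
# Motif profiles
# ---------------------------------------------------------------------------


def motif_density_profile(
    tads: pd.DataFrame,
    motifs: pd.DataFrame,
    flank_bins: int = 20,
    bin_size: int = 50_000,
) -> pd.DataFrame:
    """Mean stranded motif density around TAD starts and ends.

    For each anchor (TAD start / TAD end) and strand, counts motifs per
    ``bin_size`` bin at relative positions -flank_bins..flank_bins-1 and
    averages over TADs.  Motifs are assigned by their start coordinate.
    """
    profiles = {("start", "+"): np.zeros(2 * flank_bins),
                ("start", "-"): np.zeros(2 * flank_bins),
                ("end", "+"): np.zeros(2 * flank_bins),
                ("end", "-"): np.zeros(2 * flank_bins)}
    if len(tads) == 0:
        n_tads = 1
    else:
        n_tads = len(tads)
        for _, tad in tads.iterrows():
            sub = motifs[motifs["chrom"] == tad["chrom"]]
            for anchor, apos in (("start", tad["start"]), ("end", tad["end"])):
                rel = (sub["start"].to_numpy() - apos) // bin_size
                inside = (rel >= -flank_bins) & (rel < flank_bins)
                for strand in "+-":
                    sel = inside & (sub["strand"].to_numpy() == strand)
                    np.add.at(profiles[(anchor, strand)],
                              (rel[sel] + flank_bins).astype(int), 1)
    rel_bins = np.arange(-flank_bins, flank_bins)
    return pd.DataFrame({
        "rel_bin": rel_bins,
        "start_fwd": profiles[("start", "+")] / n_tads,
        "start_rev": profiles[("start", "-")] / n_tads,
        "end_fwd": profiles[("end", "+")] / n_tads,
        "end_rev": profiles[("end", "-")] / n_tads,
    })
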