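"""Subtelomeric trans-interaction enrichment and 3D-FISH association.

Two independent lines of evidence for telomere clustering:

* from the differential-interaction table, an enrichment test of trans
  DIs touching the terminal windows of chromosome arms against the
  genome-wide fraction of subtelomeric bins (binomial test, split by
  logFC sign);
* from 3D-FISH signal coordinates, nucleus-level association calls
  (any heterologous probe pair within 1 um) and a grouped-binomial GLM
  comparing conditions with a likelihood-ratio chi-square test, the
  telomeric pair entering as a fixed covariate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .genome_io import BinTable

__all__ = [
    "subtelomeric_trans_enrichment", "fish_distances", "score_association",
    "association_table", "condition_effect_test",
]

DEFAULT_VOXEL = (0.06, 0.06, 0.3)  # um per pixel (x, y, z)


# ---------------------------------------------------------------------------
# Hi-C side
# ---------------------------------------------------------------------------


def _subtelomeric_bins(bins: BinTable, end_window: int) -> np.ndarray:
    """Boolean mask of bins within ``end_window`` of a chromosome end."""
    if end_window < bins.resolution:
        raise ValueError("end_window smaller than one bin")
    mask = np.zeros(len(bins), dtype=bool)
    for chrom, size in bins.chrom_sizes.items():
        lo, hi = bins.bin_range(chrom)
        s, e = bins.starts[lo:hi], bins.ends[lo:hi]
        mask[lo:hi] = (s < end_window) | (e > size - end_window)
    return mask


def subtelomeric_trans_enrichment(
    ditable: pd.DataFrame,
    bins: BinTable,
    end_window: int = 2_000_000,
) -> tuple[pd.DataFrame, dict]:
    """Enrichment of trans DIs at chromosome extremities.

    A trans DI is subtelomeric when either endpoint bin lies within
    ``end_window`` of a chromosome end.  The observed subtelomeric
    fraction (overall and per logFC sign) is tested against the expected
    fraction of random trans pairs touching a terminal window (one-sided
    binomial, greater).  Also returns per-chromosome-arm counts of
    positive/negative subtelomeric trans DIs.
    """
    sub = _subtelomeric_bins(bins, end_window)
    trans = ditable[(~ditable["cis"]) & (ditable["significant"] == True)]  # noqa: E712
    # expected fraction of trans pairs with >= 1 subtelomeric endpoint
    names = bins.chrom_names
    n_pairs = n_touch = 0
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            la, ha = bins.bin_range(names[a])
            lb, hb = bins.bin_range(names[b])
            na, nb = ha - la, hb - lb
            ta, tb = int(sub[la:ha].sum()), int(sub[lb:hb].sum())
            n_pairs += na * nb
            n_touch += na * nb - (na - ta) * (nb - tb)
    p0 = n_touch / n_pairs if n_pairs else np.nan
    arm_rows = []
    stats: dict = {"expected_fraction": p0, "n_trans_di": int(len(trans))}
    if len(trans):
        b1 = trans["bin1"].to_numpy()
        b2 = trans["bin2"].to_numpy()
        touches = sub[b1] | sub[b2]
        for label, sel in (("all", np.ones(len(trans), dtype=bool)),
                           ("negative", trans["logFC"].to_numpy() < 0),
                           ("positive", trans["logFC"].to_numpy() > 0)):
            n, k = int(sel.sum()), int((touches & sel).sum())
            stats[f"{label}_subtelomeric"] = k
            stats[f"{label}_total"] = n
            stats[f"{label}_pvalue"] = float(scipy.stats.binomtest(
                k, n, p0, alternative="greater").pvalue) if n else np.nan
        # per-arm tallies
        for chrom, size in bins.chrom_sizes.items():
            lo, hi = bins.bin_range(chrom)
            for arm, cond in (("p", lambda s: s < end_window),
                              ("q", lambda s: s >= size - end_window)):
                in_arm = np.zeros(len(bins), dtype=bool)
                in_arm[lo:hi] = cond(bins.starts[lo:hi])
                hit = in_arm[b1] | in_arm[b2]
                arm_rows.append({
                    "chrom": chrom, "arm": arm,
                    "n_negative": int((hit & (trans["logFC"].to_numpy() < 0)).sum()),
                    "n_positive": int((hit & (trans["logFC"].to_numpy() > 0)).sum()),
                })
    arm_table = pd.DataFrame(arm_rows, columns=["chrom", "arm",
                                                "n_negative", "n_positive"])
    return arm_table, stats


# ---------------------------------------------------------------------------
# FISH side
# ---------------------------------------------------------------------------


def fish_distances(nucleus: pd.DataFrame,
                   voxel: tuple[float, float, float] = DEFAULT_VOXEL) -> np.ndarray:
    """Pairwise heterologous (probe A vs probe B) distances in um.

    Coordinates are in pixels; each axis difference is scaled by its
    voxel size before the Euclidean norm.
    """
    probes = nucleus["probe"].unique()
    if len(probes) != 2:
        raise ValueError("nucleus must carry exactly two probes")
    a = nucleus[nucleus["probe"] == probes[0]][["x", "y", "z"]].to_numpy()
    b = nucleus[nucleus["probe"] == probes[1]][["x", "y", "z"]].to_numpy()
    v = np.asarray(voxel)
    diffs = (a[:, None, :] - b[None, :, :]) * v
    return np.sqrt((diffs ** 2).sum(axis=2)).ravel()


def score_association(nucleus: pd.DataFrame,
                      voxel: tuple[float, float, float] = DEFAULT_VOXEL,
                      cutoff: float = 1.0) -> bool | None:
    """Nucleus-level association verdict; None if not analyzable.

    Analyzable means exactly 4 signals, 2 per probe.  Associated when
    any heterologous pair lies at distance <= cutoff (um); homologous
    pairs never count.
    """
    if len(nucleus) != 4:
        return None
    per_probe = nucleus.groupby("probe").size()
    if len(per_probe) != 2 or not (per_probe == 2).all():
        return None
    return bool(fish_distances(nucleus, voxel).min() <= cutoff)


def association_table(nuclei: pd.DataFrame,
                      voxel: tuple[float, float, float] = DEFAULT_VOXEL,
                      cutoff: float = 1.0) -> pd.DataFrame:
    """Associated / total nucleus counts per combination and condition."""
    rows = []
    n_excluded = 0
    for (combo, cond), sub in nuclei.groupby(["combination", "condition"],
                                             sort=False):
        n_assoc = n_total = 0
        for _, nucleus in sub.groupby("nucleus_id", sort=False):
            verdict = score_association(nucleus, voxel, cutoff)
            if verdict is None:
                n_excluded += 1
                continue
            n_total += 1
            n_assoc += int(verdict)
        if n_total == 0:
            warnings.warn(f"no analyzable nuclei for {combo}/{cond}",
                          stacklevel=2)
            continue
        rows.append({"combination": combo, "condition": cond,
                     "n_associated": n_assoc, "n_total": n_total,
                     "proportion": n_assoc / n_total})
    if n_excluded:
        warnings.warn(f"{n_excluded} nuclei excluded (not 2+2 signals)",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["combination", "condition",
                                       "n_associated", "n_total", "proportion"])


def condition_effect_test(counts: pd.DataFrame,
                          reference: str | None = None) -> dict:
    """Grouped binomial GLM chi-square comparison of conditions.

    Fits logit models of associated/total counts with the telomeric pair
    as fixed covariate, with and without the condition, and reports the
    likelihood-ratio (deviance) chi-square with 1 df.  On separation
    (a cell with 0 or all associated) a continuity correction of 0.5 is
    applied to every cell and the result flagged.
    """
    counts = counts.copy()
    conditions = list(pd.unique(counts["condition"]))
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    if reference is None:
        reference = conditions[0]
    other = next(c for c in conditions if c != reference)
    corrected = False
    if ((counts["n_associated"] == 0)
            | (counts["n_associated"] == counts["n_total"])).any():
        corrected = True
        counts["n_associated"] = counts["n_associated"] + 0.5
        counts["n_total"] = counts["n_total"] + 1.0
    endog = np.column_stack([
        counts["n_associated"].to_numpy(dtype=float),
        (counts["n_total"] - counts["n_associated"]).to_numpy(dtype=float),
    ])
    pair = pd.get_dummies(counts["combination"], drop_first=True, dtype=float)
    x_null = sm.add_constant(pair, has_constant="add")
    x_full = x_null.copy()
    x_full["condition"] = (counts["condition"] == other).astype(float).to_numpy()
    fit_null = sm.GLM(endog, x_null, family=sm.families.Binomial()).fit()
    fit_full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit()
    lr = float(fit_null.deviance - fit_full.deviance)
    coef = float(fit_full.params["condition"])
    higher = other if coef > 0 else reference
    return {
        "statistic": lr,
        "df": 1,
        "pvalue": float(scipy.stats.chi2.sf(lr, df=1)),
        "condition_coef": coef,
        "reference": reference,
        "higher_association": higher,
        "continuity_corrected": corrected,
    }
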