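"""End-to-end orchestration of the comparative Hi-C analysis.

``run_pipeline`` simulates (or loads) a two-group, three-replicate
experiment, then runs every analysis stage in dependency order —
replicability and maximal resolution, A/B compartments (calling,
fragmentation, switches, consistency, expression), TAD comparison and
boundary delta-IS, differential interactions, BODIs, subtelomeric
enrichment and the FISH association test — writing each stage's tables
under the output directory together with a manifest of parameters,
seeds and file hashes.  ``validate_recovery`` scores the called
structures against the generator's planted truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import bodi as bodi_mod
from . import compartments as comp_mod
from . import diffint, genome_io, normalize, simulate, tads, telomere

__all__ = ["RunConfig", "run_pipeline", "validate_recovery"]


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    Defaults follow the study conventions: 500 kb differential-interaction
    resolution, 50 kb TAD resolution, a 30-read low-count filter, 90%
    reciprocal TAD overlap, the 10:1 BODI sign ratio, 100 block
    permutations, a 2 Mb subtelomeric window and a 1 um FISH cutoff.
    """

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    outdir: str = "hicomp_run"
    fdr: float = 0.05
    min_total: int = 30
    dispersion_mode: str = "common"
    tad_overlap_f: float = 0.9
    is_window: int = 500_000
    bodi_ratio: float = 10.0
    bodi_n_perm: int = 100
    consistency_n_perm: int = 1000
    end_window: int = 2_000_000
    fish_cutoff: float = 1.0
    resolution_candidates: tuple[int, ...] = (50_000, 100_000, 250_000, 500_000)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"sim": asdict(self.sim),
                            **{k: v for k, v in asdict(self).items() if k != "sim"}},
                           fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("tad_len_bins", "fish_voxel", "depths_d90", "depths_d110"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        if "resolution_candidates" in raw and isinstance(raw["resolution_candidates"], list):
            raw["resolution_candidates"] = tuple(raw["resolution_candidates"])
        return cls(sim=simulate.SimConfig(**sim_raw), **raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the in-memory results bundle.

    Stage outputs are written under ``config.outdir`` (contact matrices,
    tracks, tables, ground truth, report.json and manifest.json).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, fmt: str = "TSV") -> None:
        path = out / name
        genome_io.write_track(df, path, fmt) if fmt in ("BED",) \
            else df.to_csv(path, sep="\t", index=False)
        written.append(path)

    # --- simulation -------------------------------------------------------
    cfg = config.sim
    truth = simulate.plant_truth(cfg)
    samples, _ = simulate.simulate_contact_maps(cfg, truth)
    fine_samples, _ = simulate.simulate_contact_maps(cfg, truth, resolution="fine")
    tad_calls = simulate.simulate_tad_calls(cfg, truth)
    genes = simulate.simulate_expression(cfg, truth)
    fish = simulate.simulate_fish(cfg)
    truth.write(out / "ground_truth")
    bed = out / f"bins_{cfg.analysis_resolution}.bed"
    samples.bins.write_bed(bed)
    written.append(bed)
    for sid, cmap in zip(samples.sample_ids, samples.maps):
        path = out / f"{sid}_{cfg.analysis_resolution}.matrix"
        genome_io.write_contact_map(cmap, path)
        written.append(path)
    for sid, calls in tad_calls.items():
        save_df(calls, f"tads_{sid}.bed")
    save_df(genes, "expression.tsv")
    save_df(fish, "fish_signals.tsv")

    # --- replicability & maximal resolution -------------------------------
    scc = {}
    ids = samples.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            scc[f"{ids[i]}|{ids[j]}"] = normalize.scc_replicability(
                samples.maps[i], samples.maps[j])
    same = [v for k, v in scc.items()
            if k.split("|")[0].split("_")[0] == k.split("|")[1].split("_")[0]]
    diff = [v for k, v in scc.items()
            if k.split("|")[0].split("_")[0] != k.split("|")[1].split("_")[0]]
    max_res = {}
    for group in samples.group_levels:
        merged_fine = genome_io.merge_maps(
            [m for g, m in zip(fine_samples.groups, fine_samples.maps) if g == group])
        max_res[group] = genome_io.max_resolution(
            merged_fine, [r for r in config.resolution_candidates
                          if r % cfg.fine_resolution == 0])

    # --- compartments -----------------------------------------------------
    density = comp_mod.gene_density_track(samples.bins, genes)
    tracks = {sid: comp_mod.call_genome(m, density, sample_id=sid)
              for sid, m in zip(samples.sample_ids, samples.maps)}
    for sid, tr in tracks.items():
        save_df(tr, f"compartments_{sid}.tsv")
    merged_all = genome_io.merge_maps(samples.maps)
    merged_track = comp_mod.call_genome(merged_all, density, sample_id="merged")
    merged_segments = comp_mod.segment_track(merged_track)
    save_df(merged_segments, "compartment_segments_merged.tsv")
    count_rows = []
    for sid, grp, cmap in zip(samples.sample_ids, samples.groups, samples.maps):
        counts = comp_mod.segment_counts(tracks[sid])
        for chrom, c in counts.items():
            cis_total = cmap.cis(chrom).total()
            count_rows.append({"sample": sid, "group": grp, "chrom": chrom,
                               "count": int(c), "covariate": cis_total})
    seg_counts = pd.DataFrame(count_rows)
    save_df(seg_counts, "compartment_counts.tsv")
    frag = comp_mod.fragmentation_test(seg_counts)
    d90_tracks = [tracks[s] for s, g in zip(ids, samples.groups) if g == "d90"]
    d110_tracks = [tracks[s] for s, g in zip(ids, samples.groups) if g == "d110"]
    switches = comp_mod.detect_switches(d90_tracks, d110_tracks)
    save_df(switches.fillna("NA"), "switch_bins.tsv")
    consistency = comp_mod.consistency_test(
        d90_tracks, d110_tracks, n_perm=config.consistency_n_perm,
        seed=cfg.seed + 1)
    expr_stats = comp_mod.compartment_expression(merged_segments, genes)
    switch_expr = comp_mod.switch_expression(switches, genes)

    # --- TADs -------------------------------------------------------------
    call_list = [tad_calls[s] for s in ids]
    stable = tads.stable_tads(call_list, f=config.tad_overlap_f)
    d90_sets = [tad_calls[s] for s, g in zip(ids, samples.groups) if g == "d90"]
    d110_sets = [tad_calls[s] for s, g in zip(ids, samples.groups) if g == "d110"]
    spec90, spec110 = tads.group_specific_tads(d90_sets, d110_sets,
                                               f=config.tad_overlap_f)
    save_df(stable, "tads_stable.bed")
    save_df(spec90, "tads_d90_specific.bed")
    save_df(spec110, "tads_d110_specific.bed")
    boundaries = pd.concat([tads.tad_boundaries(spec90, cls="d90-specific"),
                            tads.tad_boundaries(spec110, cls="d110-specific")],
                           ignore_index=True)
    boundary_scores, dis_stats = tads.delta_is(boundaries, fine_samples,
                                               window=config.is_window)
    save_df(boundary_scores, "boundary_delta_is.tsv")
    tad_counts = np.array([len(tad_calls[s]) for s in ids], dtype=float)
    totals = np.array([m.total() for m in samples.maps])
    tad_corr_r, tad_corr_p = scipy.stats.pearsonr(totals, tad_counts)

    # --- differential interactions ----------------------------------------
    ditable = diffint.di_analysis(samples, min_total=config.min_total,
                                  fdr=config.fdr,
                                  dispersion_mode=config.dispersion_mode)
    save_df(_di_with_coords(ditable, samples.bins), "differential_interactions.tsv")
    di_summary = diffint.summarize_di(ditable, samples.bins)

    # --- BODIs ------------------------------------------------------------
    binsigns = bodi_mod.classify_bins(ditable, len(samples.bins),
                                      ratio=config.bodi_ratio)
    bodis = bodi_mod.merge_bodis(binsigns, samples.bins)
    save_df(bodis, "bodis.tsv")
    bodi_perm = bodi_mod.bodi_permutation_test(
        ditable, samples.bins, n_perm=config.bodi_n_perm,
        ratio=config.bodi_ratio, seed=cfg.seed + 2)
    save_df(bodi_perm, "bodi_permutation.tsv")
    composition = bodi_mod.bodi_compartment_composition(
        bodis, merged_segments, bin_size=cfg.analysis_resolution)
    bodi_expr = bodi_mod.bodi_expression_compare(bodis, genes)

    # --- telomeres & FISH --------------------------------------------------
    arm_table, telo_stats = telomere.subtelomeric_trans_enrichment(
        ditable, samples.bins, end_window=config.end_window)
    save_df(arm_table, "subtelomeric_arms.tsv")
    assoc = telomere.association_table(fish, voxel=cfg.fish_voxel,
                                       cutoff=config.fish_cutoff)
    save_df(assoc, "fish_association.tsv")
    fish_test = telomere.condition_effect_test(assoc, reference="d90")

    report = {
        "replicability": {"pairwise": scc,
                          "mean_within_group": float(np.mean(same)),
                          "mean_between_group": float(np.mean(diff))},
        "max_resolution": max_res,
        "compartments": {
            "segment_counts_by_group": {
                g: float(seg_counts[seg_counts["group"] == g]
                         .groupby("sample")["count"].sum().mean())
                for g in samples.group_levels},
            "fragmentation": frag,
            "consistency": consistency,
            "n_switch_bins": int((switches["category"].isin(["A->B", "B->A"])).sum()),
            "expression": {k: v for k, v in expr_stats.items() if k != "segments"},
            "switch_expression": {k: v for k, v in switch_expr.items() if k != "genes"},
        },
        "tads": {
            "per_sample_counts": {s: int(len(tad_calls[s])) for s in ids},
            "n_stable": int(len(stable)),
            "n_d90_specific": int(len(spec90)),
            "n_d110_specific": int(len(spec110)),
            "delta_is": dis_stats,
            "count_vs_interactions_pearson": {"r": float(tad_corr_r),
                                              "p": float(tad_corr_p)},
        },
        "differential_interactions": di_summary,
        "bodis": {
            "n_blocks": int(len(bodis)),
            "composition": {k: v for k, v in composition.items()
                            if k != "table_bins"},
            "expression": bodi_expr,
        },
        "telomeres": {"trans_enrichment": telo_stats, "fish": fish_test},
    }
    results = {
        "config": config, "truth": truth, "samples": samples,
        "fine_samples": fine_samples, "tad_calls": tad_calls,
        "genes": genes, "fish": fish, "tracks": tracks,
        "merged_track": merged_track, "merged_segments": merged_segments,
        "switches": switches, "stable_tads": stable,
        "spec90": spec90, "spec110": spec110,
        "boundary_scores": boundary_scores,
        "ditable": ditable, "bodis": bodis, "bodi_perm": bodi_perm,
        "assoc": assoc, "report": report,
    }
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    written.append(out / "report.json")
    manifest = {
        "seed": cfg.seed,
        "parameters": _jsonable({**{k: v for k, v in asdict(config).items()
                                    if k != "sim"}, "sim": asdict(cfg)}),
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _di_with_coords(ditable: pd.DataFrame, bins) -> pd.DataFrame:
    df = ditable.copy()
    for k in ("1", "2"):
        b = df[f"bin{k}"].to_numpy()
        df[f"chrom_{k}"] = bins.chroms[b]
        df[f"start_{k}"] = bins.starts[b]
        df[f"end_{k}"] = bins.ends[b]
    return df


# ---------------------------------------------------------------------------
# Recovery validation against planted truth
# ---------------------------------------------------------------------------


def _switch_metrics(switches: pd.DataFrame, truth: simulate.GroundTruth) -> dict:
    true_dir = truth.switch_direction()
    called = switches["category"].to_numpy()
    called_pos = pd.Series(called).isin(["A->B", "B->A"]).to_numpy()
    true_pos = true_dir != "none"
    match = called == true_dir
    tp = int((called_pos & true_pos & match).sum())
    precision = tp / called_pos.sum() if called_pos.sum() else np.nan
    recall = tp / true_pos.sum() if true_pos.sum() else np.nan
    return {"precision": float(precision), "recall": float(recall),
            "n_called": int(called_pos.sum()), "n_true": int(true_pos.sum())}


def _tad_metrics(called: pd.DataFrame, truth_tads: pd.DataFrame,
                 status: str, f: float) -> dict:
    truth_sub = truth_tads[truth_tads["status"] == status]
    hits = [tads.has_identity_match(row, truth_sub, f)
            for _, row in called.iterrows()]
    recovered = [tads.has_identity_match(row, called, f)
                 for _, row in truth_sub.iterrows()]
    precision = float(np.mean(hits)) if len(hits) else np.nan
    recall = float(np.mean(recovered)) if len(recovered) else np.nan
    return {"precision": precision, "recall": recall,
            "n_called": int(len(called)), "n_true": int(len(truth_sub))}


def _bodi_metrics(bodis: pd.DataFrame, bodi_perm: pd.DataFrame,
                  truth: simulate.GroundTruth) -> dict:
    recovered = []
    for _, planted in truth.bodis.iterrows():
        same = bodis[(bodis["chrom"] == planted["chrom"])
                     & (bodis["sign"] == planted["sign"])]
        ov = (np.minimum(same["end"], planted["end"])
              - np.maximum(same["start"], planted["start"])).clip(lower=0)
        recovered.append(bool((ov >= 0.5 * (planted["end"] - planted["start"])).any()))
    size = int(truth.bodis["end"].sub(truth.bodis["start"]).min()
               // truth.bins.resolution)
    pvals = {}
    for sign in ("positive", "negative"):
        sub = bodi_perm[(bodi_perm["sign"] == sign)
                        & (bodi_perm["min_size_bins"] <= size)]
        pvals[sign] = float(sub["pvalue"].iloc[-1]) if len(sub) else np.nan
    return {"recall": float(np.mean(recovered)),
            "planted_size_bins": size,
            "permutation_pvalue": pvals}


def validate_recovery(results: dict) -> dict:
    """Precision/recall of every planted structure class, plus key tests."""
    truth: simulate.GroundTruth = results["truth"]
    config: RunConfig = results["config"]
    samples = results["samples"]
    # compartment label agreement, per replicate against its group's truth
    agreements = []
    for sid, grp in zip(samples.sample_ids, samples.groups):
        tr = results["tracks"][sid]
        called = tr["label"].to_numpy()
        ok = pd.Series(called).notna().to_numpy()
        agreements.append(float((called[ok] == truth.labels[grp][ok]).mean()))
    truth_all = pd.concat([truth.tads["d90"], truth.tads["d110"]]
                          ).drop_duplicates(["chrom", "start", "end"])
    # delta-IS contrast measured at the planted group-specific boundaries
    # (the full planted classes, not just the recovered subset)
    planted_boundaries = pd.concat([
        tads.tad_boundaries(truth_all[truth_all["status"] == "d90"],
                            cls="d90-specific"),
        tads.tad_boundaries(truth_all[truth_all["status"] == "d110"],
                            cls="d110-specific"),
    ], ignore_index=True)
    planted_scores, planted_dis = tads.delta_is(
        planted_boundaries, results["fine_samples"], window=config.is_window)
    planted_dis["n_boundaries"] = {
        c: int((planted_scores["class"] == c).sum())
        for c in planted_scores["class"].unique()}
    di = results["ditable"]
    planted_pairs = _planted_block_pairs(truth)
    if len(planted_pairs):
        keys = {(int(r["bin1"]), int(r["bin2"]))
                for _, r in di[di["significant"] == True].iterrows()}  # noqa: E712
        di_recall = float(np.mean([p in keys for p in planted_pairs]))
    else:
        di_recall = np.nan
    report = results["report"]
    return {
        "compartment_agreement_mean": float(np.mean(agreements)),
        "switches": _switch_metrics(results["switches"], truth),
        "tads_d90_specific": _tad_metrics(results["spec90"], truth_all,
                                          "d90", config.tad_overlap_f),
        "tads_d110_specific": _tad_metrics(results["spec110"], truth_all,
                                           "d110", config.tad_overlap_f),
        "delta_is_called": report["tads"]["delta_is"],
        "delta_is_planted": planted_dis,
        "di_block_pair_recall": di_recall,
        "bodis": _bodi_metrics(results["bodis"], results["bodi_perm"], truth),
        "telomere_negative_trans_pvalue":
            report["telomeres"]["trans_enrichment"].get("negative_pvalue"),
        "fish": {"pvalue": report["telomeres"]["fish"]["pvalue"],
                 "higher_association":
                     report["telomeres"]["fish"]["higher_association"]},
    }


def _planted_block_pairs(truth: simulate.GroundTruth) -> list[tuple[int, int]]:
    pairs = []
    res = truth.bins.resolution
    for _, blk in truth.bodis.iterrows():
        lo, _ = truth.bins.bin_range(blk["chrom"])
        b0 = lo + int(blk["start"]) // res
        b1 = lo + int(blk["end"]) // res
        for i in range(b0, b1):
            for j in range(i + 1, b1):
                pairs.append((i, j))
    return pairs
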