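"""Seeded synthetic Hi-C data generator with planted ground truth.

The generator emulates a two-group (d90 vs d110 gestation), three-replicate
Hi-C design on a small toy genome and plants every structure the analysis
pipeline is meant to recover:

* A/B compartments with group-wise fragmentation and consistent switches,
* TADs with replicate boundary jitter, dropout and group-specific domains,
* blocks of differential interactions (BODIs) with a group effect,
* subtelomeric trans-interaction clustering boosted in the d90 group,
* compartment-linked gene expression and per-nucleus 3D-FISH signals.

Cis counts follow a distance-decay kernel modulated by compartment,
TAD-insulation and block effects::

    mu_ij = depth * K_ij / Z,
    K_ij  = (|i-j|+1)^(-alpha) * exp(gamma * e_i * e_j) * tau_ij * delta_ij

with e = +/-1 the planted compartment state, tau the within-TAD enrichment
(expressed only at the fine resolution, where the bin size resolves
domains) and delta the group-specific block effect (any cis pair touching
a block); trans counts have a flat mean ``depth * pi0`` with a
multiplicative boost on flagged subtelomeric pairs in the d90 group.
Counts are negative-binomial with variance mu + phi * mu^2
(gamma-Poisson mixture); phi -> 0 recovers Poisson.

All randomness derives from one root seed split per stage, so every
output is reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import BinTable, ContactMap, SampleSet

__all__ = ["SimConfig", "GroundTruth", "plant_truth", "simulate_contact_maps",
           "simulate_tad_calls", "simulate_expression", "simulate_fish",
           "GROUPS"]

GROUPS = ("d90", "d110")

# stage indices used to split the root seed
_STAGE_TRUTH, _STAGE_MAPS, _STAGE_TADS, _STAGE_EXPR, _STAGE_FISH = range(5)


def _rng(seed: int, stage: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage, extra]))


def _default_fish_p_assoc() -> dict:
    # association rates matching the observed proportions of the three
    # probed telomere combinations at each gestational stage
    return {
        "SSC9qter-SSC2pter": {"d90": 0.24, "d110": 0.15},
        "SSC9qter-SSC13qter": {"d90": 0.19, "d110": 0.15},
        "SSC9qter-SSC15qter": {"d90": 0.28, "d110": 0.20},
    }


def _default_fish_n() -> dict:
    return {
        "SSC9qter-SSC2pter": {"d90": 100, "d110": 100},
        "SSC9qter-SSC13qter": {"d90": 99, "d110": 100},
        "SSC9qter-SSC15qter": {"d90": 100, "d110": 97},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic two-group Hi-C experiment.

    The defaults describe the standard toy genome: 3 chromosomes of 30 Mb
    (60 bins at the 500 kb analysis resolution, 600 bins at the 50 kb fine
    resolution), about 2 M cis interactions per replicate, compartment
    segments of ~4 Mb fragmented by ~30% and switched on ~5% of bins in
    the d110 group, ~23 TADs of 1-1.4 Mb per chromosome of which 10 are
    d90-specific and 10 are d110-specific, one positive and one negative
    3 Mb differential block per chromosome (2-fold effect), and a 4-fold
    d90 boost on subtelomeric trans pairs.
    """

    seed: int = 0
    n_chrom: int = 3
    chrom_length: int = 30_000_000
    fine_resolution: int = 50_000
    analysis_resolution: int = 500_000
    # contact model
    decay_exponent: float = 1.0
    compartment_amplitude: float = 0.6
    nb_dispersion: float = 0.05
    depths_d90: tuple[float, ...] = (2.2e6, 2.0e6, 1.8e6)
    depths_d110: tuple[float, ...] = (2.1e6, 1.9e6, 1.7e6)
    # compartments
    seg_mean_bins: int = 8            # mean d90 segment length, analysis bins
    split_factor: float = 1.3         # d110 segment-count inflation
    switch_fraction: float = 0.03     # fraction of bins consistently switched
    # TADs (fine-resolution bins)
    tad_len_bins: tuple[int, int] = (20, 28)
    tad_gap_bins: int = 2
    n_d90_specific: int = 10          # per chromosome
    n_d110_specific: int = 10
    insulation_factor: float = 2.0
    jitter_sd: float = 1.0            # caller boundary jitter, fine bins
    dropout_prob: float = 0.05
    # differential blocks (analysis bins)
    bodi_n_bins: int = 6
    bodi_effect: float = 2.0
    # trans / telomeres
    trans_baseline: float = 1e-5      # per-pair mean = depth * pi0
    telomere_boost_d90: float = 4.0
    telomere_window_bins: int = 4     # terminal analysis bins per arm
    # expression
    n_genes: int = 1200
    gene_density_ratio: float = 2.0   # A:B gene placement weight
    mu_A: float = 6.0                 # log2 expression means
    mu_B: float = 4.0
    sigma: float = 1.0
    sigma_fc: float = 0.5
    switch_shift: float = 1.0         # |logFC| shift for switch genes
    # FISH
    fish_p_assoc: dict = field(default_factory=_default_fish_p_assoc)
    fish_n_nuclei: dict = field(default_factory=_default_fish_n)
    fish_voxel: tuple[float, float, float] = (0.06, 0.06, 0.3)
    fish_box_um: float = 10.0

    def __post_init__(self) -> None:
        if self.chrom_length < 2 * self.analysis_resolution:
            raise ValueError("chromosome shorter than 2 analysis bins")
        if self.split_factor < 1:
            raise ValueError("split_factor must be >= 1")
        if not (0 <= self.switch_fraction <= 1 and 0 <= self.dropout_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        for combo, by_cond in self.fish_p_assoc.items():
            for p in by_cond.values():
                if not 0 <= p <= 1:
                    raise ValueError(f"fish p_assoc out of [0, 1] for {combo}")
        if min(min(self.depths_d90), min(self.depths_d110)) <= 0:
            raise ValueError("depths must be positive")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}

    def analysis_bins(self) -> BinTable:
        return BinTable.from_chrom_sizes(self.chrom_sizes, self.analysis_resolution)

    def fine_bins(self) -> BinTable:
        return BinTable.from_chrom_sizes(self.chrom_sizes, self.fine_resolution)

    def depths(self) -> dict[str, tuple[float, ...]]:
        return {"d90": self.depths_d90, "d110": self.depths_d110}


@dataclass
class GroundTruth:
    """Planted structures, written alongside the simulated outputs."""

    bins: BinTable                       # analysis resolution
    labels: dict[str, np.ndarray]        # group -> per-bin 'A'/'B'
    switch: pd.DataFrame                 # chrom, start, end, direction
    tads: dict[str, pd.DataFrame]        # group -> chrom, start, end, status
    bodis: pd.DataFrame                  # chrom, start, end, sign
    telomere_pairs: np.ndarray           # (m, 2) boosted trans bin pairs
    genes: pd.DataFrame | None = None    # filled by simulate_expression

    def switch_direction(self) -> np.ndarray:
        """Per-analysis-bin switch category ('A->B', 'B->A' or 'none')."""
        a, b = self.labels["d90"], self.labels["d110"]
        out = np.full(len(a), "none", dtype=object)
        out[(a == "A") & (b == "B")] = "A->B"
        out[(a == "B") & (b == "A")] = "B->A"
        return out

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frame = self.bins.to_frame()
        for group, lab in self.labels.items():
            frame[f"label_{group}"] = lab
        frame["switch"] = self.switch_direction()
        frame.to_csv(directory / "compartments.tsv", sep="\t", index=False)
        self.switch.to_csv(directory / "switch_bins.tsv", sep="\t", index=False)
        for group, df in self.tads.items():
            df.to_csv(directory / f"tads_{group}.tsv", sep="\t", index=False)
        self.bodis.to_csv(directory / "bodis.tsv", sep="\t", index=False)
        pd.DataFrame(self.telomere_pairs, columns=["bin1", "bin2"]).to_csv(
            directory / "telomere_pairs.tsv", sep="\t", index=False)
        if self.genes is not None:
            self.genes.to_csv(directory / "genes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------


def _plant_segmentation(config: SimConfig, rng: np.random.Generator,
                        n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """d90 and d110 label arrays for one chromosome (analysis bins)."""
    # d90: alternating segments with log-normal-ish lengths around the mean
    lengths: list[int] = []
    total = 0
    while total < n_bins:
        ln = max(2, int(round(np.exp(rng.normal(np.log(config.seg_mean_bins), 0.35)))))
        lengths.append(min(ln, n_bins - total))
        total += lengths[-1]
    first = rng.choice(["A", "B"])
    labels90 = np.empty(n_bins, dtype=object)
    pos = 0
    for k, ln in enumerate(lengths):
        labels90[pos:pos + ln] = first if k % 2 == 0 else ("B" if first == "A" else "A")
        pos += ln
    # d110: interior flips fragment the segmentation and create switches
    labels110 = labels90.copy()
    n_seg = len(lengths)
    n_flip = max(1, int(round((config.split_factor - 1) * n_seg / 2)))
    block = max(1, int(round(config.switch_fraction * n_bins / n_flip)))
    starts = np.cumsum([0] + lengths[:-1])
    eligible = [k for k, ln in enumerate(lengths) if ln >= block + 2]
    if not eligible:
        eligible = [int(np.argmax(lengths))]
        block = max(1, lengths[eligible[0]] - 2)
    chosen = rng.choice(eligible, size=min(n_flip, len(eligible)), replace=False)
    for k in chosen:
        s0, ln = starts[k], lengths[k]
        off = rng.integers(1, ln - block)  # strictly interior
        seg = slice(s0 + off, s0 + off + block)
        labels110[seg] = "B" if labels90[s0] == "A" else "A"
    return labels90, labels110


def _plant_tads(config: SimConfig, rng: np.random.Generator,
                chrom: str, n_fine: int) -> pd.DataFrame:
    """Tile one chromosome with TAD slots and assign group statuses."""
    lo, hi = config.tad_len_bins
    res = config.fine_resolution
    slots = []
    pos = 0
    while True:
        ln = int(rng.integers(lo, hi + 1))
        if pos + ln > n_fine:
            break
        slots.append((pos, pos + ln))
        pos += ln + config.tad_gap_bins
    statuses = ["shared"] * len(slots)
    n_spec = config.n_d90_specific + config.n_d110_specific
    if n_spec > len(slots):
        raise ValueError("more group-specific TADs requested than TAD slots")
    idx = rng.permutation(len(slots))
    for i in idx[: config.n_d90_specific]:
        statuses[i] = "d90"
    for i in idx[config.n_d90_specific: n_spec]:
        statuses[i] = "d110"
    return pd.DataFrame({
        "chrom": chrom,
        "start": [s * res for s, _ in slots],
        "end": [e * res for _, e in slots],
        "status": statuses,
    })


def _plant_bodis(config: SimConfig, rng: np.random.Generator, chrom: str,
                 n_bins: int, labels90: np.ndarray,
                 labels110: np.ndarray) -> pd.DataFrame:
    """One positive and one negative block per chromosome, away from ends.

    Blocks avoid compartment-switch bins so the planted between-group
    block effect is not confounded by the switch-driven contact changes.
    """
    res = config.analysis_resolution
    k = config.bodi_n_bins
    margin = config.telomere_window_bins + 2

    def eligible(start_bin: int, require_neutral: bool) -> bool:
        if not require_neutral:
            return True
        return not np.any(labels90[start_bin:start_bin + k]
                          != labels110[start_bin:start_bin + k])

    half = (n_bins - 2 * margin) // 2
    rows = []
    for sign, lo in (("positive", margin), ("negative", margin + half)):
        candidates = np.arange(lo, lo + half - k + 1)
        for require_neutral in (True, False):
            pool = [s for s in candidates if eligible(int(s), require_neutral)]
            if pool:
                break
        start_bin = int(rng.choice(pool))
        rows.append({"chrom": chrom, "start": start_bin * res,
                     "end": (start_bin + k) * res, "sign": sign})
    return pd.DataFrame(rows)


def plant_truth(config: SimConfig) -> GroundTruth:
    """Draw every planted structure from the truth stage of the root seed."""
    rng = _rng(config.seed, _STAGE_TRUTH)
    bins = config.analysis_bins()
    labels = {g: np.empty(len(bins), dtype=object) for g in GROUPS}
    tads = {g: [] for g in GROUPS}
    bodis = []
    for chrom in bins.chrom_names:
        lo, hi = bins.bin_range(chrom)
        l90, l110 = _plant_segmentation(config, rng, hi - lo)
        labels["d90"][lo:hi] = l90
        labels["d110"][lo:hi] = l110
        n_fine = -(-config.chrom_sizes[chrom] // config.fine_resolution)
        chrom_tads = _plant_tads(config, rng, chrom, n_fine)
        tads["d90"].append(chrom_tads[chrom_tads["status"] != "d110"])
        tads["d110"].append(chrom_tads[chrom_tads["status"] != "d90"])
        bodis.append(_plant_bodis(config, rng, chrom, hi - lo, l90, l110))
    tad_frames = {g: pd.concat(t, ignore_index=True) for g, t in tads.items()}
    bodi_frame = pd.concat(bodis, ignore_index=True)

    direction = np.where(
        (labels["d90"] == "A") & (labels["d110"] == "B"), "A->B",
        np.where((labels["d90"] == "B") & (labels["d110"] == "A"), "B->A", "none"))
    switched = direction != "none"
    switch = bins.to_frame()[switched].copy()
    switch["direction"] = direction[switched]
    switch = switch.drop(columns="bin_id").reset_index(drop=True)

    telomere_pairs = _telomere_pairs(config, bins)
    return GroundTruth(bins=bins, labels=labels, switch=switch,
                       tads=tad_frames, bodis=bodi_frame,
                       telomere_pairs=telomere_pairs)


def _telomere_pairs(config: SimConfig, bins: BinTable) -> np.ndarray:
    """All trans pairs between terminal windows of different chromosomes."""
    k = config.telomere_window_bins
    terminal: dict[str, np.ndarray] = {}
    for chrom in bins.chrom_names:
        lo, hi = bins.bin_range(chrom)
        terminal[chrom] = np.r_[np.arange(lo, min(lo + k, hi)),
                                np.arange(max(hi - k, lo), hi)]
    names = bins.chrom_names
    pairs = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ta, tb = terminal[names[a]], terminal[names[b]]
            grid = np.array(np.meshgrid(ta, tb)).T.reshape(-1, 2)
            pairs.append(np.sort(grid, axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.vstack(pairs), axis=0)


# ---------------------------------------------------------------------------
# Contact-map generation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, var = mean + phi mean^2) via gamma-Poisson; phi=0 -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * np.clip(mean, 1e-300, None))
    lam[mean <= 0] = 0.0
    return rng.poisson(lam)


def _tad_membership(tads: pd.DataFrame, chrom: str, starts: np.ndarray,
                    resolution: int) -> np.ndarray:
    """TAD index (or -1) of each bin of one chromosome, by bin midpoint."""
    mids = starts + resolution // 2
    member = np.full(len(starts), -1, dtype=np.int64)
    sub = tads[tads["chrom"] == chrom]
    for t, (_, row) in enumerate(sub.iterrows()):
        member[(mids >= row["start"]) & (mids < row["end"])] = t
    return member


def _cis_kernel(config: SimConfig, truth: GroundTruth, group: str,
                chrom: str, bins: BinTable, with_tads: bool) -> np.ndarray:
    lo, hi = bins.bin_range(chrom)
    n = hi - lo
    starts = bins.starts[lo:hi]
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    kernel = (d + 1.0) ** (-config.decay_exponent)
    # compartment checkerboard, mapped down from analysis-resolution labels
    alo, _ = truth.bins.bin_range(chrom)
    abin = alo + starts // config.analysis_resolution
    e = np.where(truth.labels[group][abin] == "A", 1.0, -1.0)
    kernel *= np.exp(config.compartment_amplitude * np.outer(e, e))
    if with_tads:
        # within-TAD insulation enrichment; a sub-bin-scale effect only
        # expressed when the bin size resolves domains
        member = _tad_membership(truth.tads[group], chrom, starts,
                                 bins.resolution)
        same = (member[:, None] == member[None, :]) & (member[:, None] >= 0)
        kernel[same] *= config.insulation_factor
    # group-specific block effect (d110 side): a compacting (positive) or
    # de-condensing (negative) block shifts every cis interaction that
    # touches it, so its bins accrue many same-sign differential pairs
    if group == "d110":
        for _, row in truth.bodis[truth.bodis["chrom"] == chrom].iterrows():
            inb = (starts >= row["start"]) & (starts < row["end"])
            eff = config.bodi_effect if row["sign"] == "positive" else 1.0 / config.bodi_effect
            touch = inb[:, None] | inb[None, :]
            kernel[touch] *= eff
    return kernel


def simulate_contact_maps(
    config: SimConfig,
    truth: GroundTruth | None = None,
    resolution: str = "analysis",
) -> tuple[SampleSet, GroundTruth]:
    """Generate the 2 x 3 replicate contact maps.

    ``resolution="analysis"`` (default) generates cis and trans counts at
    the analysis bin size; ``resolution="fine"`` generates cis-only maps
    at the fine bin size (used for TAD-boundary insulation scores).
    """
    if truth is None:
        truth = plant_truth(config)
    fine = resolution == "fine"
    bins = config.fine_bins() if fine else config.analysis_bins()
    phi = config.nb_dispersion
    sample_ids, groups, maps = [], [], []
    rep_index = 0
    for group in GROUPS:
        for r, depth in enumerate(config.depths()[group]):
            rng = _rng(config.seed, _STAGE_MAPS, 100 * (fine + 1) + rep_index)
            rep_index += 1
            b1_all, b2_all, v_all = [], [], []
            # cis: normalize the kernel genome-wide so the expected cis
            # total equals the replicate depth
            kernels = {c: _cis_kernel(config, truth, group, c, bins,
                                      with_tads=fine)
                       for c in bins.chrom_names}
            z = sum(np.triu(k).sum() for k in kernels.values())
            for chrom in bins.chrom_names:
                lo, hi = bins.bin_range(chrom)
                n = hi - lo
                iu = np.triu_indices(n)
                mu = depth * kernels[chrom][iu] / z
                counts = _nb_draw(rng, mu, phi)
                nz = counts > 0
                b1_all.append(lo + iu[0][nz])
                b2_all.append(lo + iu[1][nz])
                v_all.append(counts[nz])
            if not fine:
                names = bins.chrom_names
                boosted = {tuple(p) for p in truth.telomere_pairs}
                for a in range(len(names)):
                    for b in range(a + 1, len(names)):
                        la, ha = bins.bin_range(names[a])
                        lb, hb = bins.bin_range(names[b])
                        ia, ib = np.meshgrid(np.arange(la, ha), np.arange(lb, hb),
                                             indexing="ij")
                        ia, ib = ia.ravel(), ib.ravel()
                        mu = np.full(len(ia), depth * config.trans_baseline)
                        if group == "d90":
                            flag = np.array([(x, y) in boosted
                                             for x, y in zip(ia, ib)])
                            mu[flag] *= config.telomere_boost_d90
                        counts = _nb_draw(rng, mu, phi)
                        nz = counts > 0
                        b1_all.append(ia[nz])
                        b2_all.append(ib[nz])
                        v_all.append(counts[nz])
            cmap = ContactMap.from_records(bins, np.concatenate(b1_all),
                                           np.concatenate(b2_all),
                                           np.concatenate(v_all),
                                           warn_duplicates=False)
            sample_ids.append(f"{group}_rep{r + 1}")
            groups.append(group)
            maps.append(cmap)
    return SampleSet(sample_ids, groups, maps), truth


# ---------------------------------------------------------------------------
# Derived observables
# ---------------------------------------------------------------------------


def simulate_tad_calls(config: SimConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Per-replicate TAD call sets: truth with boundary jitter and dropout."""
    res = config.fine_resolution
    calls: dict[str, pd.DataFrame] = {}
    rep_index = 0
    for group in GROUPS:
        for r in range(len(config.depths()[group])):
            rng = _rng(config.seed, _STAGE_TADS, rep_index)
            rep_index += 1
            rows = []
            for _, tad in truth.tads[group].iterrows():
                if rng.random() < config.dropout_prob:
                    continue
                size = config.chrom_sizes[tad["chrom"]]
                js, je = rng.normal(0, config.jitter_sd, size=2)
                start = int(tad["start"]) + int(round(js)) * res
                end = int(tad["end"]) + int(round(je)) * res
                start = max(0, start)
                end = min(size, end)
                if end - start < 2 * res:
                    continue
                rows.append({"chrom": tad["chrom"], "start": start, "end": end})
            calls[f"{group}_rep{r + 1}"] = pd.DataFrame(
                rows, columns=["chrom", "start", "end"])
    return calls


def simulate_expression(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Gene table with per-stage log2 expression, logFC and true category.

    Genes are placed with a ``gene_density_ratio`` preference for A bins
    (d90 labels), so gene density doubles as the compartment-orientation
    covariate.  Per-stage expression is drawn from the stage's planted
    label (N(mu_A, sigma) in A, N(mu_B, sigma) in B); logFC (110 vs 90) is
    N(0, sigma_fc) shifted by +shift for B->A genes and -shift for A->B.
    """
    rng = _rng(config.seed, _STAGE_EXPR)
    bins = truth.bins
    w = np.where(truth.labels["d90"] == "A", config.gene_density_ratio, 1.0)
    w = w / w.sum()
    gene_bins = rng.choice(len(bins), size=config.n_genes, p=w)
    gene_bins.sort()
    lengths = rng.integers(10_000, 50_001, size=config.n_genes)
    widths = bins.ends[gene_bins] - bins.starts[gene_bins]
    offsets = rng.integers(0, np.maximum(widths - 10_000, 1))
    starts = bins.starts[gene_bins] + offsets
    ends = np.minimum(starts + lengths, bins.ends[gene_bins])
    direction = truth.switch_direction()[gene_bins]
    mu = {"d90": None, "d110": None}
    for g in GROUPS:
        lab = truth.labels[g][gene_bins]
        mu[g] = np.where(lab == "A", config.mu_A, config.mu_B)
    expr90 = rng.normal(mu["d90"], config.sigma)
    expr110 = rng.normal(mu["d110"], config.sigma)
    shift = np.where(direction == "B->A", config.switch_shift,
                     np.where(direction == "A->B", -config.switch_shift, 0.0))
    logfc = rng.normal(0.0, config.sigma_fc, size=config.n_genes) + shift
    genes = pd.DataFrame({
        "gene_id": [f"G{i:05d}" for i in range(config.n_genes)],
        "chrom": bins.chroms[gene_bins],
        "start": starts.astype(np.int64),
        "end": ends.astype(np.int64),
        "expr_d90": expr90,
        "expr_d110": expr110,
        "logFC": logfc,
        "true_category": direction,
    })
    truth.genes = genes
    return genes


def _place_far(rng: np.random.Generator, anchors: np.ndarray, box: float,
               min_dist: float = 1.5) -> np.ndarray:
    """Uniform point in the box at >= min_dist (um) from every anchor."""
    for _ in range(10_000):
        p = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(p - a) >= min_dist for a in anchors):
            return p
    raise RuntimeError("could not place FISH signal away from anchors")


def simulate_fish(config: SimConfig) -> pd.DataFrame:
    """Per-nucleus FISH signal coordinates (pixels) for each combination.

    Each nucleus carries 4 signals (2 per probe).  With probability
    p_assoc one heterologous pair is placed at a distance U(0, 1) um;
    otherwise every heterologous distance is >= 1.5 um.
    """
    rng = _rng(config.seed, _STAGE_FISH)
    voxel = np.asarray(config.fish_voxel)
    box = config.fish_box_um
    rows = []
    for combo, by_cond in config.fish_p_assoc.items():
        probe_b, probe_a = combo.split("-")
        for cond, p_assoc in by_cond.items():
            n = config.fish_n_nuclei[combo][cond]
            for k in range(n):
                nucleus = f"{combo}:{cond}:{k:03d}"
                a1 = rng.uniform(0, box, size=3)
                a2 = _place_far(rng, np.array([a1]), box, 0.0)
                associated = rng.random() < p_assoc
                if associated:
                    d = rng.uniform(0, 1.0)
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    b1 = np.clip(a1 + d * u, 0, box)
                    b2 = _place_far(rng, np.array([a1, a2]), box)
                else:
                    b1 = _place_far(rng, np.array([a1, a2]), box)
                    b2 = _place_far(rng, np.array([a1, a2]), box)
                for probe, pt in ((probe_a, a1), (probe_a, a2),
                                  (probe_b, b1), (probe_b, b2)):
                    px = pt / voxel
                    rows.append({"nucleus_id": nucleus, "combination": combo,
                                 "condition": cond, "probe": probe,
                                 "x": px[0], "y": px[1], "z": px[2],
                                 "true_associated": associated})
    return pd.DataFrame(rows)
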