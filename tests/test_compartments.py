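"""Compartment calling, segmentation, group tests and expression links."""

import numpy as np
import pandas as pd
import pytest

from hicomp import compartments as comp
from hicomp import simulate
from hicomp.genome_io import BinTable, ContactMap


def _track(labels, chrom="chr1", res=500_000):
    labels = list(labels)
    return pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(len(labels)) * res,
        "end": (np.arange(len(labels)) + 1) * res,
        "E1": [0.0 if lab is None else (1.0 if lab == "A" else -1.0)
               for lab in labels],
        "label": labels,
    })


@pytest.fixture(scope="module")
def checkerboard():
    """Single-chromosome map with a planted two-state checkerboard."""
    cfg = simulate.SimConfig(seed=11, n_chrom=1)
    truth = simulate.plant_truth(cfg)
    samples, _ = simulate.simulate_contact_maps(cfg, truth)
    return cfg, truth, samples.maps[0]


class TestCallCompartments:
    def test_planted_labels_recovered(self, checkerboard):
        cfg, truth, cmap = checkerboard
        orientation = np.where(truth.labels["d90"] == "A", 2.0, 1.0)
        track = comp.call_compartments(cmap, "chr1", orientation)
        called = track["label"].to_numpy()
        ok = pd.Series(called).notna().to_numpy()
        agreement = (called[ok] == truth.labels["d90"][ok]).mean()
        assert agreement >= 0.95

    def test_invariant_to_scaling(self, checkerboard):
        cfg, truth, cmap = checkerboard
        orientation = np.where(truth.labels["d90"] == "A", 2.0, 1.0)
        track = comp.call_compartments(cmap, "chr1", orientation)
        scaled = ContactMap(cmap.bins, cmap.bin1, cmap.bin2, cmap.count * 7.3)
        track2 = comp.call_compartments(scaled, "chr1", orientation)
        assert track["label"].equals(track2["label"])

    def test_orientation_covariate_controls_sign(self, checkerboard):
        cfg, truth, cmap = checkerboard
        orientation = np.where(truth.labels["d90"] == "A", 2.0, 1.0)
        flipped = comp.call_compartments(cmap, "chr1", -orientation)
        straight = comp.call_compartments(cmap, "chr1", orientation)
        both = pd.notna(straight["label"]) & pd.notna(flipped["label"])
        assert (straight.loc[both, "label"]
                != flipped.loc[both, "label"]).all()

    def test_too_few_bins_rejected(self):
        res = 500_000
        bins = BinTable.from_chrom_sizes({"chr1": 5 * res}, res)
        iu = np.triu_indices(5)
        cmap = ContactMap.from_records(bins, iu[0], iu[1],
                                       np.full(len(iu[0]), 10.0),
                                       warn_duplicates=False)
        with pytest.raises(ValueError):
            comp.call_compartments(cmap, "chr1", np.ones(5))


class TestSegmentTrack:
    def test_two_segments(self):
        seg = comp.segment_track(_track(["A", "A", "B", "B"]))
        assert seg["label"].tolist() == ["A", "B"]
        assert seg["start"].tolist() == [0, 1_000_000]

    def test_na_bridging(self):
        track = _track(["A", None, "A"])
        assert len(comp.segment_track(track, bridge_na=True)) == 1
        assert len(comp.segment_track(track, bridge_na=False)) == 2

    def test_chained_na_bridging(self):
        track = _track(["A", None, "A", None, "A", "B"])
        seg = comp.segment_track(track, bridge_na=True)
        assert seg["label"].tolist() == ["A", "B"]

    def test_counts_match_scan_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.choice(["A", "B"], size=40)
            seg = comp.segment_track(_track(labels))
            oracle = 1 + int((labels[1:] != labels[:-1]).sum())
            assert len(seg) == oracle


class TestFragmentationTest:
    def _counts(self, rng, rate2, n_chrom=18, lam=33.0):
        rows = []
        for group, rate in (("d90", lam), ("d110", rate2)):
            for rep in range(3):
                for chrom in range(n_chrom):
                    rows.append({"group": group,
                                 "sample": f"{group}_r{rep}",
                                 "chrom": f"chr{chrom + 1}",
                                 "count": rng.poisson(rate),
                                 "covariate": rng.uniform(1e8, 3e8)})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        counts = self._counts(np.random.default_rng(0), rate2=33.0)
        d90 = counts[counts["group"] == "d90"].copy()
        d110 = d90.copy()
        d110["group"] = "d110"
        res = comp.fragmentation_test(pd.concat([d90, d110]))
        assert abs(res["beta"]) < 1e-8
        assert res["pvalue"] > 0.5

    def test_power_for_30_percent_increase(self):
        rng = np.random.default_rng(1)
        hits = sum(
            comp.fragmentation_test(self._counts(rng, rate2=33.0 * 1.3))
            ["pvalue"] < 0.05
            for _ in range(100))
        assert hits >= 90

    def test_planted_effect_within_two_se(self):
        rng = np.random.default_rng(2)
        beta_true = np.log(1.3)
        cover = sum(
            abs(comp.fragmentation_test(self._counts(rng, rate2=33.0 * 1.3))
                ["beta"] - beta_true)
            <= 2 * comp.fragmentation_test(self._counts(rng, rate2=33.0 * 1.3))
            ["beta_se"]
            for _ in range(25))
        assert cover >= 22

    def test_non_integer_counts_rejected(self):
        counts = self._counts(np.random.default_rng(3), rate2=33.0)
        counts.loc[0, "count"] = 3.5
        with pytest.raises(ValueError):
            comp.fragmentation_test(counts)


class TestDetectSwitches:
    def _tracks(self, labels_by_sample):
        return [_track(labels) for labels in labels_by_sample]

    def test_consistent_switch_called(self):
        d90 = self._tracks([["A", "B"]] * 3)
        d110 = self._tracks([["B", "B"]] * 3)
        out = comp.detect_switches(d90, d110)
        assert out["category"].tolist() == ["A->B", "none"]

    def test_inconsistent_replicate_blocks_call(self):
        d90 = self._tracks([["A"], ["A"], ["B"]])
        d110 = self._tracks([["B"], ["B"], ["B"]])
        out = comp.detect_switches(d90, d110)
        assert out["category"].tolist() == ["none"]

    def test_unassigned_bin_excluded(self):
        d90 = self._tracks([["A", None]] * 3)
        d110 = self._tracks([["B", "B"]] * 3)
        out = comp.detect_switches(d90, d110)
        assert out["category"].tolist() == ["A->B", None]


class TestConsistencyTest:
    def test_identical_tracks(self):
        tracks = [_track(["A", "B", "A", "B", "A", "A"])] * 3
        res = comp.consistency_test(tracks[:3], tracks[:3], n_perm=99, seed=0)
        assert res["fraction_consistent"] == 1.0
        assert res["pvalue"] == pytest.approx(1 / 100)

    def test_pvalue_lower_bound(self):
        tracks = [_track(["A", "B"] * 10)] * 3
        res = comp.consistency_test(tracks, tracks, n_perm=200, seed=0)
        assert res["pvalue"] >= 1 / 201

    def test_independent_tracks_not_significant(self):
        rng = np.random.default_rng(4)
        tracks = [_track(rng.choice(["A", "B"], size=60)) for _ in range(6)]
        res = comp.consistency_test(tracks[:3], tracks[3:], n_perm=200, seed=1)
        assert res["pvalue"] >= 0.05


class TestExpressionIntegration:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                           "expr_d90", "expr_d110", "logFC"])

    def test_empty_segment_zero_density(self):
        segments = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                 "end": [1_000_000], "label": ["A"]})
        out = comp.compartment_expression(segments, self._genes([]))
        assert out["segments"]["n_genes"].tolist() == [0]
        assert out["segments"]["density_per_mb"].tolist() == [0.0]

    def test_planted_expression_contrast(self, truth, genes):
        frame = truth.bins.to_frame()
        frame["label"] = truth.labels["d90"]
        segments = frame.rename(columns={"bin_id": "drop"}).drop(columns="drop")
        out = comp.compartment_expression(segments, genes)
        assert out["expr_d90_pvalue"] < 0.01
        assert out["density_pvalue"] < 0.01

    def test_switch_logfc_direction(self, truth, genes):
        switches = truth.bins.to_frame().drop(columns="bin_id")
        switches["category"] = truth.switch_direction()
        out = comp.switch_expression(switches, genes)
        assert out["median_logFC"]["B->A"] > out["median_logFC"]["A->B"]
        assert out["ab_vs_ba_pvalue"] < 0.01

    def test_gene_outside_called_bins_excluded(self):
        switches = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                 "end": [500_000], "category": ["none"]})
        genes = self._genes([("G1", "chr1", 600_000, 620_000, 1, 1, 0.5)])
        out = comp.switch_expression(switches, genes)
        assert len(out["genes"]) == 0
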