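"""Synthetic-data generator: determinism, moments and planted structure."""

import numpy as np
import pytest
from scipy.stats import binomtest

from hicomp import simulate
from hicomp.simulate import SimConfig, plant_truth, simulate_contact_maps


class TestConfigValidation:
    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_length=700_000)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(dropout_prob=1.5)

    def test_split_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(split_factor=0.8)


class TestDeterminism:
    def test_same_seed_identical(self):
        a, _ = simulate_contact_maps(SimConfig(seed=7))
        b, _ = simulate_contact_maps(SimConfig(seed=7))
        for ma, mb in zip(a.maps, b.maps):
            assert np.array_equal(ma.bin1, mb.bin1)
            assert np.array_equal(ma.count, mb.count)

    def test_distinct_seeds_differ(self):
        a, _ = simulate_contact_maps(SimConfig(seed=7))
        b, _ = simulate_contact_maps(SimConfig(seed=8))
        assert not np.array_equal(a.maps[0].count, b.maps[0].count)


class TestContactModel:
    def test_distance_decay_moments(self):
        # no compartments, no block effects: per-diagonal means must
        # follow (d+1)^-alpha within sampling error
        cfg = SimConfig(seed=0, compartment_amplitude=0.0, bodi_effect=1.0,
                        nb_dispersion=0.02)
        samples, _ = simulate_contact_maps(cfg)
        dense = samples.maps[0].cis("chr1").to_dense("chr1")
        n = dense.shape[0]
        means = np.array([np.diagonal(dense, d).mean() for d in range(n)])
        d = np.arange(1, 25)
        ratio = means[d] * (d + 1.0) / means[0]
        assert np.allclose(ratio, 1.0, atol=0.15)

    def test_poisson_limit_variance(self):
        cfg = SimConfig(seed=0, nb_dispersion=0.0,
                        compartment_amplitude=0.0, bodi_effect=1.0)
        samples, _ = simulate_contact_maps(cfg)
        dense = samples.maps[0].cis("chr1").to_dense("chr1")
        # far-diagonal cells share a nearly common mean; var ~ mean
        vals = np.concatenate([np.diagonal(dense, d) for d in range(40, 50)])
        assert vals.var() / vals.mean() == pytest.approx(1.0, rel=0.25)

    def test_telomere_boost_only_d90(self):
        cfg = SimConfig(seed=0)
        truth = plant_truth(cfg)
        samples, _ = simulate_contact_maps(cfg, truth)
        pairs = truth.telomere_pairs
        d90 = samples.by_group("d90")[0]
        d110 = samples.by_group("d110")[0]

        def mean_at(cmap):
            dense = cmap.to_dense()
            return dense[pairs[:, 0], pairs[:, 1]].mean()

        assert mean_at(d90) > 2.5 * mean_at(d110)


class TestTadCalls:
    def test_zero_noise_equals_truth(self):
        cfg = SimConfig(seed=0, jitter_sd=0.0, dropout_prob=0.0)
        truth = plant_truth(cfg)
        calls = simulate.simulate_tad_calls(cfg, truth)
        expected = truth.tads["d90"][["chrom", "start", "end"]]
        got = calls["d90_rep1"]
        assert got.reset_index(drop=True).equals(expected.reset_index(drop=True))

    def test_full_dropout_empty(self):
        cfg = SimConfig(seed=0, dropout_prob=1.0)
        truth = plant_truth(cfg)
        calls = simulate.simulate_tad_calls(cfg, truth)
        assert all(len(c) == 0 for c in calls.values())

    def test_jitter_sd_recovered(self):
        cfg = SimConfig(seed=0, jitter_sd=2.0, dropout_prob=0.0)
        truth = plant_truth(cfg)
        shifts = []
        for rep in range(50):
            cfg_rep = SimConfig(seed=rep, jitter_sd=2.0, dropout_prob=0.0)
            calls = simulate.simulate_tad_calls(cfg_rep, plant_truth(cfg_rep))
            t = plant_truth(cfg_rep).tads["d90"].reset_index(drop=True)
            c = calls["d90_rep1"].reset_index(drop=True)
            ok = (c["start"] > 0) & (c["end"] < cfg.chrom_length)
            shifts.extend(((c["start"] - t["start"])[ok]
                           // cfg.fine_resolution).tolist())
        assert np.std(shifts) == pytest.approx(2.0, rel=0.25)


class TestExpression:
    def test_switch_shift_zero_centers_logfc(self):
        cfg = SimConfig(seed=3, switch_shift=0.0)
        truth = plant_truth(cfg)
        genes = simulate.simulate_expression(cfg, truth)
        sw = genes[genes["true_category"] != "none"]
        assert len(sw) > 0
        assert abs(sw["logFC"].mean()) < 3 * cfg.sigma_fc / np.sqrt(len(sw))

    def test_compartment_means_recovered(self):
        cfg = SimConfig(seed=4)
        truth = plant_truth(cfg)
        genes = simulate.simulate_expression(cfg, truth)
        lo, hi = truth.bins.bin_range("chr1")
        labels = truth.labels["d90"]
        mids = (genes["start"] + genes["end"]) // 2
        res = cfg.analysis_resolution
        gene_bins = np.array([truth.bins.bin_range(c)[0] + m // res
                              for c, m in zip(genes["chrom"], mids)])
        for lab, mu in (("A", cfg.mu_A), ("B", cfg.mu_B)):
            vals = genes.loc[labels[gene_bins] == lab, "expr_d90"]
            assert vals.mean() == pytest.approx(
                mu, abs=2 * cfg.sigma / np.sqrt(len(vals)))

    def test_equal_means_give_no_compartment_contrast(self):
        cfg = SimConfig(seed=5, mu_A=5.0, mu_B=5.0)
        truth = plant_truth(cfg)
        genes = simulate.simulate_expression(cfg, truth)
        assert abs(genes["expr_d90"].mean() - 5.0) < 0.1


class TestFish:
    def _table(self, p, n=100, seed=0):
        cfg = SimConfig(
            seed=seed,
            fish_p_assoc={"P1-P2": {"d90": p, "d110": p}},
            fish_n_nuclei={"P1-P2": {"d90": n, "d110": n}})
        return simulate.simulate_fish(cfg)

    def test_zero_probability_none_associated(self):
        fish = self._table(0.0)
        assert not fish["true_associated"].any()

    def test_unit_probability_all_associated(self):
        fish = self._table(1.0)
        assert fish["true_associated"].all()

    def test_association_fraction_within_binomial_ci(self):
        fish = self._table(0.24)
        per_nucleus = fish.groupby("nucleus_id")["true_associated"].first()
        ci = binomtest(int(per_nucleus.sum()), len(per_nucleus)).proportion_ci()
        assert ci.low <= 0.24 <= ci.high

    def test_four_signals_two_per_probe(self):
        fish = self._table(0.5)
        sizes = fish.groupby("nucleus_id").size()
        assert (sizes == 4).all()
        per_probe = fish.groupby(["nucleus_id", "probe"]).size()
        assert (per_probe == 2).all()


class TestGroundTruth:
    def test_switch_bins_consistent_with_labels(self):
        truth = plant_truth(SimConfig(seed=6))
        direction = truth.switch_direction()
        n_switch = (direction != "none").sum()
        assert n_switch == len(truth.switch)
        assert n_switch > 0

    def test_d110_more_fragmented(self):
        # the d110 derivation inserts interior flips, so segment counts rise
        truth = plant_truth(SimConfig(seed=6))

        def n_segments(labels):
            return 1 + int((labels[1:] != labels[:-1]).sum())

        total90 = total110 = 0
        for chrom in truth.bins.chrom_names:
            lo, hi = truth.bins.bin_range(chrom)
            total90 += n_segments(truth.labels["d90"][lo:hi])
            total110 += n_segments(truth.labels["d110"][lo:hi])
        assert total110 > total90

    def test_written_files(self, tmp_path):
        cfg = SimConfig(seed=0)
        truth = plant_truth(cfg)
        simulate.simulate_expression(cfg, truth)
        truth.write(tmp_path)
        for name in ("compartments.tsv", "switch_bins.tsv", "tads_d90.tsv",
                     "bodis.tsv", "telomere_pairs.tsv", "genes.tsv"):
            assert (tmp_path / name).exists()
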