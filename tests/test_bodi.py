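"""BODI bin classification, block merging, permutation and composition."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hicomp import bodi
from hicomp.genome_io import BinTable


def _bins(n=20, res=500_000, chroms=1):
    per = n // chroms
    return BinTable.from_chrom_sizes(
        {f"chr{i + 1}": per * res for i in range(chroms)}, res)


def _ditable(rows):
    """rows: (bin1, bin2, logFC); all cis and significant."""
    df = pd.DataFrame(rows, columns=["bin1", "bin2", "logFC"])
    df["cis"] = True
    df["significant"] = True
    return df


class TestClassifyBins:
    @pytest.mark.parametrize("n_pos,n_neg,expected", [
        (5, 0, "positive"),
        (10, 1, "positive"),   # exactly 10:1 passes
        (9, 1, "undefined"),   # below the 10:1 rule
        (0, 5, "negative"),
        (1, 10, "negative"),
        (3, 3, "undefined"),   # tie
        (0, 0, "none"),
    ])
    def test_sign_rule(self, n_pos, n_neg, expected):
        rows = [(0, j + 1, 1.0) for j in range(n_pos)]
        rows += [(0, j + 1 + n_pos, -1.0) for j in range(n_neg)]
        out = bodi.classify_bins(_ditable(rows), n_bins=25)
        assert out.loc[0, "sign"] == expected
        assert out.loc[0, "n_pos"] == n_pos and out.loc[0, "n_neg"] == n_neg

    def test_both_endpoints_incremented(self):
        out = bodi.classify_bins(_ditable([(2, 7, 1.0)]), n_bins=10)
        assert out.loc[2, "n_pos"] == 1 and out.loc[7, "n_pos"] == 1

    def test_infinite_ratio_single_sign_only(self):
        rows = [(0, j + 1, 1.0) for j in range(20)] + [(0, 21, -1.0)]
        out = bodi.classify_bins(_ditable(rows), n_bins=25, ratio=np.inf)
        assert out.loc[0, "sign"] == "undefined"
        out2 = bodi.classify_bins(_ditable(rows[:-1]), n_bins=25, ratio=np.inf)
        assert out2.loc[0, "sign"] == "positive"

    def test_ratio_one_is_majority_rule(self):
        rows = [(0, 1, 1.0), (0, 2, 1.0), (0, 3, -1.0)]
        out = bodi.classify_bins(_ditable(rows), n_bins=5, ratio=1.0)
        assert out.loc[0, "sign"] == "positive"

    def test_trans_interactions_ignored(self):
        df = _ditable([(0, 1, 1.0)])
        df.loc[0, "cis"] = False
        out = bodi.classify_bins(df, n_bins=5)
        assert (out["sign"] == "none").all()


def _signs(seq, bins):
    return pd.DataFrame({"bin": np.arange(len(seq)), "sign": list(seq),
                         "n_pos": 0, "n_neg": 0})


class TestMergeBodis:
    def test_basic_runs(self):
        bins = _bins(3)
        seq = ["positive", "positive", "negative"]
        out = bodi.merge_bodis(_signs(seq, bins), bins)
        assert out["n_bins"].tolist() == [2, 1]
        assert out["sign"].tolist() == ["positive", "negative"]

    def test_none_terminates_run(self):
        bins = _bins(3)
        seq = ["positive", "none", "positive"]
        out = bodi.merge_bodis(_signs(seq, bins), bins)
        assert len(out) == 2
        assert (out["n_bins"] == 1).all()

    def test_runs_never_span_chromosomes(self):
        bins = _bins(20, chroms=2)
        seq = ["positive"] * 20
        out = bodi.merge_bodis(_signs(seq, bins), bins)
        assert out["n_bins"].tolist() == [10, 10]

    def test_matches_rle_oracle(self):
        rng = np.random.default_rng(0)
        bins = _bins(50)
        for _ in range(20):
            seq = rng.choice(["positive", "negative", "undefined", "none"],
                             size=50)
            out = bodi.merge_bodis(_signs(seq, bins), bins)
            # oracle: run-length encode, drop none
            runs = []
            i = 0
            while i < 50:
                j = i
                while j < 50 and seq[j] == seq[i]:
                    j += 1
                if seq[i] != "none":
                    runs.append((seq[i], j - i))
                i = j
            assert list(zip(out["sign"], out["n_bins"])) == runs

    def test_partition_covers_non_none_bins(self):
        rng = np.random.default_rng(1)
        bins = _bins(50)
        seq = rng.choice(["positive", "negative", "undefined", "none"], 50)
        out = bodi.merge_bodis(_signs(seq, bins), bins)
        assert out["n_bins"].sum() == int((seq != "none").sum())


class TestPermutationTest:
    def test_all_same_sign_never_enriched(self):
        rows = [(i, i + 5, 1.0) for i in range(5)]
        out = bodi.bodi_permutation_test(_ditable(rows), _bins(20), n_perm=20)
        assert (out["pvalue"] == 1.0).all()

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        rows = [(int(a), int(b), float(s))
                for a, b, s in zip(rng.integers(0, 20, 60),
                                   rng.integers(20, 40, 60),
                                   rng.choice([-1, 1], 60))]
        bins = _bins(40)
        a = bodi.bodi_permutation_test(_ditable(rows), bins, n_perm=30, seed=5)
        b = bodi.bodi_permutation_test(_ditable(rows), bins, n_perm=30, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_pvalues_bounded_below(self):
        rows = [(i, i + 1, 1.0) for i in range(6)] + \
               [(10 + i, 12 + i, -1.0) for i in range(4)]
        out = bodi.bodi_permutation_test(_ditable(rows), _bins(20), n_perm=50)
        assert (out["pvalue"] >= 1 / 51).all()


class TestComposition:
    def _segments(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

    def test_fisher_matches_hypergeometric_oracle(self):
        table = np.array([[8, 2], [1, 5]])
        p_scipy = scipy.stats.fisher_exact(table)[1]
        # enumeration oracle over the hypergeometric support
        a_total, row1 = table[:, 0].sum(), table[0].sum()
        n = table.sum()
        probs = [scipy.stats.hypergeom.pmf(k, n, a_total, row1)
                 for k in range(max(0, row1 + a_total - n),
                                min(row1, a_total) + 1)]
        p_obs = scipy.stats.hypergeom.pmf(table[0, 0], n, a_total, row1)
        p_enum = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert abs(p_scipy - p_enum) < 1e-12

    def test_blocks_entirely_in_a(self):
        bodis = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                              "end": [2_000_000], "sign": ["positive"],
                              "n_bins": [4], "size": [2_000_000]})
        segments = self._segments([("chr1", 0, 5_000_000, "A")])
        out = bodi.bodi_compartment_composition(bodis, segments)
        assert out["positive_A_fraction"] == 1.0

    def test_planted_association_direction(self):
        # positive blocks placed in B space, negative in A space
        segments = self._segments([("chr1", 0, 5_000_000, "B"),
                                   ("chr1", 5_000_000, 10_000_000, "A")])
        bodis = pd.DataFrame({
            "chrom": ["chr1"] * 4,
            "start": [0, 2_500_000, 5_000_000, 7_500_000],
            "end": [2_500_000, 5_000_000, 7_500_000, 10_000_000],
            "sign": ["positive", "positive", "negative", "negative"],
            "n_bins": [5] * 4, "size": [2_500_000] * 4})
        out = bodi.bodi_compartment_composition(bodis, segments)
        assert out["negative_A_fraction"] > out["positive_A_fraction"]
        assert out["fisher_pvalue"] < 0.05


class TestExpressionCompare:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start",
                                           "end", "logFC"])

    def _bodis(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [0, 5_000_000],
            "end": [2_000_000, 7_000_000],
            "sign": ["negative", "positive"],
            "n_bins": [4, 4], "size": [2_000_000, 2_000_000]})

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        rows = [(f"N{i}", "chr1", s, s + 10_000, rng.normal(1.0, 0.3))
                for i, s in enumerate(rng.integers(0, 1_990_000, 60))]
        rows += [(f"P{i}", "chr1", 5_000_000 + s, 5_000_000 + s + 10_000,
                  rng.normal(-1.0, 0.3))
                 for i, s in enumerate(rng.integers(0, 1_990_000, 60))]
        out = bodi.bodi_expression_compare(self._bodis(), self._genes(rows))
        assert out["pvalue"] < 0.01
        assert out["median_logFC_negative"] > out["median_logFC_positive"]

    def test_missing_class_warns_and_returns_nan(self):
        rows = [("G1", "chr1", 100, 200, 0.5)]
        with pytest.warns(UserWarning):
            out = bodi.bodi_expression_compare(self._bodis(), self._genes(rows))
        assert np.isnan(out["pvalue"])
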