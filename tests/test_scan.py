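"""Bin scans, Manhattan tables, gene matrices, clustering, DE merging."""

import numpy as np
import pandas as pd
import pytest

from hlbquant.coverage import CoverageTrack
from hlbquant.scan import (
    bin_scan,
    cluster_rows,
    gene_matrix,
    manhattan_table,
    merge_signal_with_de,
)


def make_track(values: dict, bin_size=2, state="hgc"):
    return CoverageTrack(
        values={c: np.asarray(v, dtype=float) for c, v in values.items()},
        chrom_lengths={c: len(v) * bin_size for c, v in values.items()},
        bin_size=bin_size,
        state=state,
    )


class TestBinScan:
    def test_uniform_track_all_bins_tied(self):
        # three 15,240-bp chromosomes of constant value 1 at 2-bp bins
        track = make_track({c: np.ones(7620) for c in "abc"})
        scan = bin_scan(track, bin_len=5080)
        assert len(scan) == 9
        assert np.allclose(scan["signal"], 5080.0)
        assert (scan["rank"] == 1).all()  # minimum-rank ties

    def test_hot_consensus_bin_ranks_first(self):
        track = make_track({"a": np.ones(7620), "chrHis": np.full(2540, 10.0)})
        scan = bin_scan(track)
        top = scan[scan["rank"] == 1]
        assert list(top["chrom"]) == ["chrHis"]

    def test_trailing_partial_bin_retained_and_flagged(self):
        track = make_track({"a": np.ones(6000)})  # 12,000 bp
        scan = bin_scan(track)
        assert scan["end"].tolist() == [5080, 10160, 12000]
        assert scan["partial"].tolist() == [False, False, True]
        assert scan["signal"].iloc[-1] == pytest.approx(12_000 - 10_160)

    def test_sums_invariant_to_track_bin_size(self):
        """Piecewise-constant signal aligned to edges gives identical sums."""
        fine = make_track({"a": np.repeat([1.0, 4.0, 0.5, 2.0], 1270)}, bin_size=2)
        coarse = make_track({"a": np.repeat([1.0, 4.0, 0.5, 2.0], 254)}, bin_size=10)
        s_fine = bin_scan(fine)["signal"]
        s_coarse = bin_scan(coarse)["signal"]
        np.testing.assert_allclose(s_fine, s_coarse, rtol=1e-12)

    def test_masked_bins_excluded_from_ranking(self):
        vals = np.ones(5080)
        vals[:2540] = np.nan
        track = make_track({"a": np.ones(2540), "b": vals})
        scan = bin_scan(track)
        masked = scan[scan["masked"]]
        assert len(masked) == 1
        assert masked["rank"].isna().all()

    def test_requires_hgc_state(self):
        with pytest.raises(ValueError, match="HGC"):
            bin_scan(make_track({"a": np.ones(2540)}, state="cpm"))

    def test_bin_len_validation(self):
        track = make_track({"a": np.ones(100)}, bin_size=3)
        with pytest.raises(ValueError, match="multiple"):
            bin_scan(track, bin_len=100)
        with pytest.raises(ValueError):
            bin_scan(track, bin_len=2)


class TestManhattan:
    def _scan(self):
        track = make_track({"a": np.ones(7620), "chrHis": np.full(2540, 10.0), "b": np.ones(5080)})
        return bin_scan(track)

    def test_single_chromosome_cumulative_equals_start(self):
        scan = bin_scan(make_track({"a": np.ones(7620)}))
        tab = manhattan_table(scan)
        assert tab["cum_pos"].tolist() == tab["start"].tolist()

    def test_consensus_ordered_last(self):
        tab = manhattan_table(self._scan())
        assert tab.iloc[-1]["chrom"] == "chrHis"
        assert tab["cum_pos"].is_monotonic_increasing

    def test_top_labels_are_largest_sums(self):
        tab = manhattan_table(self._scan(), top_k=2)
        labelled = tab[tab["label"] != ""]
        assert len(labelled) == 2
        assert labelled["signal"].min() >= tab.loc[tab["label"] == "", "signal"].max()

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            manhattan_table(pd.DataFrame())


class TestGeneMatrix:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    def test_constant_track_gives_constant_rows(self):
        track = make_track({"a": np.full(5000, 3.0)})
        genes = self._genes([("a", 1000, 4000, "g1", 0, "+"), ("a", 2000, 2600, "g2", 0, "-")])
        gm = gene_matrix(track, genes)
        assert gm.matrix.shape == (2, 300)
        np.testing.assert_allclose(gm.matrix, 3.0)

    def test_body_of_exact_length_identity_resampling(self):
        vals = np.zeros(3000)
        vals[:] = 0.0
        track = make_track({"a": vals}, bin_size=1)
        body = np.arange(2000, dtype=float)
        track.values["a"][500:2500] = body
        genes = self._genes([("a", 500, 2500, "g", 0, "+")])
        gm = gene_matrix(track, genes, n_body_bins=200, n_flank_bins=50)
        expected = body.reshape(200, 10).mean(axis=1)
        np.testing.assert_allclose(gm.matrix[0, 50:250], expected, rtol=1e-12)

    def test_linear_ramp_rescaling_matches_analytic(self):
        """A 3,000-bp linear ramp scaled to 200 columns equals the closed form."""
        n = 3000
        track = make_track({"a": np.arange(5000, dtype=float)}, bin_size=1)
        genes = self._genes([("a", 1000, 1000 + n, "g", 0, "+")])
        gm = gene_matrix(track, genes, n_body_bins=200, n_flank_bins=50)
        # column j averages ramp values over [j*n/200, (j+1)*n/200): closed form
        edges = np.floor(np.arange(201) * n / 200).astype(int)
        expected = np.array([(1000 + np.arange(edges[j], edges[j + 1])).mean() for j in range(200)])
        np.testing.assert_allclose(gm.matrix[0, 50:250], expected, atol=n / 200)

    def test_minus_strand_rows_reversed(self):
        track = make_track({"a": np.arange(5000, dtype=float)}, bin_size=1)
        genes = self._genes(
            [("a", 1000, 3000, "fwd", 0, "+"), ("a", 1000, 3000, "rev", 0, "-")]
        )
        gm = gene_matrix(track, genes)
        fwd = gm.matrix[gm.genes.index("fwd")]
        rev = gm.matrix[gm.genes.index("rev")]
        np.testing.assert_allclose(rev, fwd[::-1])

    def test_rows_sorted_by_total_signal(self):
        track = make_track({"a": np.concatenate([np.full(2500, 1.0), np.full(2500, 9.0)])}, bin_size=1)
        genes = self._genes([("a", 100, 600, "low", 0, "+"), ("a", 3000, 3500, "high", 0, "+")])
        gm = gene_matrix(track, genes)
        assert gm.genes == ["high", "low"]
        assert gm.totals[0] > gm.totals[1]

    def test_gene_outside_bounds_rejected(self):
        track = make_track({"a": np.ones(100)}, bin_size=1)
        with pytest.raises(ValueError, match="outside"):
            gene_matrix(track, self._genes([("a", 50, 200, "g", 0, "+")]))


class TestClusterRows:
    def test_two_point_masses_separate(self):
        """5 constant-100 rows vs 395 constant-0 rows split at k=2.

        Ward's first merges join identical rows at zero cost within each
        mass; the only costly merge is between the masses, so cutting at two
        clusters recovers them exactly.
        """
        X = np.zeros((400, 20))
        X[:5] = 100.0
        labels = cluster_rows(X, k=2)
        assert set(labels[:5]) == {1}  # canonical label 1 = strongest signal
        assert set(labels[5:]) == {2}

    def test_k_equals_n_every_row_alone(self):
        X = np.arange(12, dtype=float).reshape(4, 3)
        labels = cluster_rows(X, k=4)
        assert len(set(labels)) == 4

    def test_partition_invariant_to_row_permutation(self, rng):
        X = rng.normal(size=(30, 10))
        X[:6] += 8.0
        labels = cluster_rows(X, k=3)
        perm = rng.permutation(30)
        labels_perm = cluster_rows(X[perm], k=3)
        np.testing.assert_array_equal(labels_perm, labels[perm])

    def test_k_validation(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            cluster_rows(X, k=0)
        with pytest.raises(ValueError):
            cluster_rows(X, k=5)


class TestMergeDe:
    def test_disjoint_identifiers_error_with_counts(self):
        sig = pd.DataFrame({"gene": ["a", "b"], "signal": [1.0, 2.0]})
        de = pd.DataFrame({"gene": ["c"], "log2fc": [0.0], "padj": [1.0]})
        with pytest.raises(ValueError, match="signal-only: 2, DE-only: 1"):
            merge_signal_with_de(sig, de)

    def test_zero_log2fc_passthrough_and_sorting(self):
        sig = pd.DataFrame({"gene": list("abc"), "signal": [1.0, 5.0, 3.0]})
        de = pd.DataFrame({"gene": list("abc"), "log2fc": [0.0] * 3, "padj": [0.9] * 3})
        out = merge_signal_with_de(sig, de)
        assert (out["log2fc"] == 0).all()
        assert out["signal"].tolist() == [5.0, 3.0, 1.0]

    def test_array_genes_separate_on_signal_axis(self, rng):
        """High-signal array genes separate from all DEGs on the signal axis."""
        genes = [f"deg{i}" for i in range(100)] + ["H1", "H2a", "H2b", "H3", "H4"]
        signal = np.concatenate([rng.uniform(0, 1, 100), rng.uniform(50, 60, 5)])
        sig = pd.DataFrame({"gene": genes, "signal": signal})
        de = pd.DataFrame({"gene": genes, "log2fc": rng.normal(0, 2, 105), "padj": rng.uniform(0, 0.05, 105)})
        out = merge_signal_with_de(sig, de)
        top5 = set(out.head(5)["gene"])
        assert top5 == {"H1", "H2a", "H2b", "H3", "H4"}
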