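import numpy as np
import pandas as pd
import pytest

from cosplicex import counts_io
from cosplicex.counts_io import CountTableFormatError

from conftest import make_table


def _write(tmp_path, text, name="counts.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadExonCounts:
    def test_round_trip(self, tmp_path, tiny_table):
        path = tmp_path / "out.tsv"
        counts_io.write_exon_counts(tiny_table, path)
        back = counts_io.read_exon_counts(path)
        assert back.gene_ids == ["geneA", "geneB"]
        assert back.sample_ids == tiny_table.sample_ids
        pd.testing.assert_frame_equal(back.data, tiny_table.data)

    def test_gzip_round_trip(self, tmp_path, tiny_table):
        path = tmp_path / "out.tsv.gz"
        counts_io.write_exon_counts(tiny_table, path)
        back = counts_io.read_exon_counts(path)
        pd.testing.assert_frame_equal(back.data, tiny_table.data)

    def test_negative_count_names_cell(self, tmp_path):
        path = _write(tmp_path, "gene_id\texon_id\ts1\ts2\ngA\te1\t3\t-1\n")
        with pytest.raises(CountTableFormatError, match=r"negative.*s2"):
            counts_io.read_exon_counts(path)

    def test_duplicate_exon_is_format_error(self, tmp_path):
        path = _write(
            tmp_path, "gene_id\texon_id\ts1\ngA\te1\t3\ngA\te1\t4\n"
        )
        with pytest.raises(CountTableFormatError, match="duplicate"):
            counts_io.read_exon_counts(path)

    def test_non_numeric_cell_is_parse_error(self, tmp_path):
        path = _write(tmp_path, "gene_id\texon_id\ts1\ngA\te1\toops\n")
        with pytest.raises(CountTableFormatError, match="non-numeric"):
            counts_io.read_exon_counts(path)

    def test_missing_cell_is_parse_error(self, tmp_path):
        path = _write(tmp_path, "gene_id\texon_id\ts1\ts2\ngA\te1\t3\t\n")
        with pytest.raises(CountTableFormatError, match="missing"):
            counts_io.read_exon_counts(path)


class TestUpperQuartileNormalize:
    def test_identical_samples_unit_factors(self):
        table = make_table({"g1": [[10, 10], [4, 4]], "g2": [[7, 7]], "g3": [[30, 30]]})
        norm, factors = counts_io.upper_quartile_normalize(table)
        np.testing.assert_allclose(factors.factors, 1.0, atol=1e-12)
        np.testing.assert_allclose(norm.data.to_numpy(), table.data.to_numpy())

    def test_scaled_sample_equalized(self):
        # sample B is exactly 2x sample A: gene totals must coincide after normalization
        table = make_table({"g1": [[10, 20], [4, 8]], "g2": [[7, 14]], "g3": [[30, 60]]})
        norm, _ = counts_io.upper_quartile_normalize(table)
        totals = norm.gene_totals()
        np.testing.assert_allclose(totals.iloc[:, 0], totals.iloc[:, 1], rtol=1e-9)

    def test_factors_match_step_by_step_oracle(self):
        # independent step-by-step evaluation of the upper-quartile definition
        table = make_table(
            {
                "g1": [[100, 10, 55], [20, 5, 10]],
                "g2": [[300, 60, 200]],
                "g3": [[40, 800, 30], [0, 100, 0]],
                "g4": [[10, 20, 30]],
            }
        )
        totals = table.gene_totals().to_numpy()
        lib = totals.sum(axis=0)
        raw = np.array(
            [np.percentile(totals[:, j][totals[:, j] > 0], 75) for j in range(3)]
        ) / lib
        expected = raw / np.exp(np.mean(np.log(raw)))
        _, factors = counts_io.upper_quartile_normalize(table)
        np.testing.assert_allclose(factors.factors, expected, rtol=1e-12)
        assert abs(np.exp(np.mean(np.log(factors.factors))) - 1) < 1e-9

    def test_normalization_equalizes_upper_quartiles(self, rng):
        # after one pass every sample shares the same upper quartile of gene
        # totals, so a second pass can only rescale all samples by one constant
        counts = rng.poisson(50, size=(40, 5)).astype(float) * rng.lognormal(0, 1, size=(40, 1))
        table = make_table({f"g{i}": counts[i : i + 1] * [1, 2, 0.5, 3, 1.7] for i in range(40)})
        norm, _ = counts_io.upper_quartile_normalize(table)
        totals = norm.gene_totals().to_numpy()
        uq = [np.percentile(t[t > 0], 75) for t in totals.T]
        np.testing.assert_allclose(uq, uq[0], rtol=1e-9)
        twice, _ = counts_io.upper_quartile_normalize(norm)
        ratio = twice.data.to_numpy() / norm.data.to_numpy()
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)

    def test_all_zero_sample_is_error(self):
        table = make_table({"g1": [[10, 0], [5, 0]]})
        with pytest.raises(ValueError, match="all-zero"):
            counts_io.upper_quartile_normalize(table)


class TestLowCountFilter:
    def test_strict_threshold_boundary(self):
        table = make_table(
            {
                "g499": [[499, 499]],
                "g500": [[500, 500]],
                "g501": [[400, 602]],
            }
        )
        filtered, report = counts_io.filter_low_count_genes(table, threshold=500)
        assert filtered.gene_ids == ["g500", "g501"]
        assert report.genes_removed_low_count == 1
        assert report.genes_in == report.genes_removed_low_count + report.genes_retained

    def test_all_zero_gene_removed(self):
        table = make_table({"gz": [[0, 0]], "g": [[600, 700]]})
        filtered, _ = counts_io.filter_low_count_genes(table)
        assert filtered.gene_ids == ["g"]

    def test_zero_threshold_keeps_everything(self):
        table = make_table({"gz": [[0, 0]], "g": [[1, 2]]})
        filtered, report = counts_io.filter_low_count_genes(table, threshold=0)
        assert filtered.n_genes == 2
        assert report.genes_removed_low_count == 0

    def test_negative_threshold_is_error(self, tiny_table):
        with pytest.raises(ValueError):
            counts_io.filter_low_count_genes(tiny_table, threshold=-1)


class TestExonConnectivityFilter:
    def test_noise_gene_removed_matches_explicit_oracle(self, rng):
        # genes g0..g3 share one latent factor; gNOISE is independent noise
        n = 30
        factor = rng.normal(size=n)
        shared = {
            f"g{i}": np.vstack(
                [factor * (j + 1) + rng.normal(scale=0.05, size=n) + 10 for j in range(3)]
            )
            for i in range(4)
        }
        shared["gNOISE"] = rng.normal(size=(3, n)) + 10
        table = make_table(shared)
        filtered, report = counts_io.filter_low_connectivity_exons(table)

        # oracle: dense correlation matrix, row sums, 25th percentile cutoff
        vals = table.data.to_numpy()
        corr = np.abs(np.corrcoef(vals))
        conn = corr.sum(axis=1) - 1.0
        cutoff = np.percentile(conn, 25)
        genes = table.data.index.get_level_values(0)
        expect_removed = [
            g for g in table.gene_ids if (conn[genes == g] < cutoff).all()
        ]
        assert expect_removed == ["gNOISE"]
        assert filtered.gene_ids == [g for g in table.gene_ids if g != "gNOISE"]
        assert report.genes_removed_low_exon_connectivity == 1

    def test_duplicated_exons_maximally_connected_gene_kept(self, rng):
        base = rng.normal(size=20) + 5
        table = make_table(
            {
                "gdup": np.vstack([base, base]),
                **{f"g{i}": np.vstack([base, rng.normal(size=20) + 5]) for i in range(4)},
            }
        )
        filtered, _ = counts_io.filter_low_connectivity_exons(table)
        assert "gdup" in filtered.gene_ids

    def test_all_identical_exons_no_removal(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        table = make_table({f"g{i}": np.vstack([v, v]) for i in range(4)})
        filtered, report = counts_io.filter_low_connectivity_exons(table)
        assert filtered.n_genes == 4
        assert report.genes_removed_low_exon_connectivity == 0

    def test_zero_variance_exon_warns_not_errors(self, rng):
        table = make_table(
            {
                "gflat": np.vstack([np.full(10, 3.0), rng.normal(size=10) + 5]),
                **{f"g{i}": rng.normal(size=(3, 10)) + 5 for i in range(3)},
            }
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            counts_io.filter_low_connectivity_exons(table)

    def test_chunked_equals_dense(self, rng):
        table = make_table({f"g{i}": rng.poisson(20, size=(4, 15)).astype(float) for i in range(6)})
        f1, _ = counts_io.filter_low_connectivity_exons(table, block_size=3)
        f2, _ = counts_io.filter_low_connectivity_exons(table, block_size=10_000)
        assert f1.gene_ids == f2.gene_ids

    def test_sample_and_exon_order_preserved(self, rng):
        table = make_table({f"g{i}": rng.poisson(20, size=(3, 12)).astype(float) for i in range(4)})
        filtered, _ = counts_io.filter_low_connectivity_exons(table)
        assert filtered.sample_ids == table.sample_ids
        for g in filtered.gene_ids:
            assert list(filtered.data.loc[g].index) == list(table.data.loc[g].index)
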