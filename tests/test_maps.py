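import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smcoloc.maps import (
    CountMatrix,
    MapsEnrichment,
    bh_adjust,
    compute_fpkm,
    enrichment_table,
    exact_test_nodisp,
    replicate_fpkm_correlation,
)
from smcoloc.synthetic import simulate_maps_counts


def brute_force_bh(p):
    """Step-up definition evaluated literally: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_i, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestFpkm:
    def test_definition(self):
        assert compute_fpkm(10, 1000, 1e6) == pytest.approx(10.0)

    def test_zero_count(self):
        assert compute_fpkm(0, 500, 1e7) == 0.0

    def test_homogeneity_in_count_and_library(self):
        assert compute_fpkm(20, 1000, 2e6) == compute_fpkm(10, 1000, 1e6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_fpkm(1, 0, 1e6)
        with pytest.raises(ValueError):
            compute_fpkm(1, 100, 0)


class TestExactTest:
    def test_all_zero_counts_give_p_one(self):
        assert exact_test_nodisp([0], [0], [1e6], [1e6]) == 1.0

    def test_zero_versus_ten_equal_libraries(self):
        # conditional binomial with prob 1/2: only 0 and 10 are as unlikely
        p = exact_test_nodisp([0], [10], [1e6], [1e6])
        assert p == pytest.approx(2 * 0.5**10)

    def test_symmetric_under_group_swap(self, rng):
        for _ in range(20):
            a, b = rng.poisson(40, 2), rng.poisson(60, 2)
            la, lb = rng.uniform(5e5, 2e6, 2), rng.uniform(5e5, 2e6, 2)
            assert exact_test_nodisp(a, b, la, lb) == pytest.approx(
                exact_test_nodisp(b, a, lb, la)
            )

    def test_matches_scipy_binomtest_oracle(self, rng):
        # independent oracle: scipy's two-sided minimum-likelihood binomial
        # test on the pooled totals with equal libraries
        for _ in range(25):
            ya, yb = int(rng.poisson(30)), int(rng.poisson(50))
            p = exact_test_nodisp([ya], [yb], [1e6], [1e6])
            oracle = stats.binomtest(ya, ya + yb, 0.5).pvalue if ya + yb else 1.0
            assert p == pytest.approx(oracle, rel=1e-10)

    def test_unbalanced_replicates_shift_null_proportion(self):
        # 2 tagged vs 1 control replicates: null proportion 2/3
        p_equal = exact_test_nodisp([50, 50], [50], [1e6] * 2, [1e6])
        assert p_equal == pytest.approx(
            stats.binomtest(100, 150, 2 / 3).pvalue, rel=1e-10
        )

    def test_library_scaling_equalizes_depth(self):
        # same underlying rate sampled at 2x depth should not look enriched
        p = exact_test_nodisp([200], [100], [2e6], [1e6])
        assert p > 0.5


class TestBhAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=500)
        np.testing.assert_allclose(
            bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


@pytest.fixture
def small_matrix():
    counts = pd.DataFrame(
        {
            "tagged_1": [40, 10, 100],
            "tagged_2": [40, 10, 100],
            "control_1": [10, 10, 100],
            "control_2": [10, 10, 100],
        },
        index=pd.Index(["enriched", "flat_low", "flat_high"], name="gene"),
    )
    lengths = pd.Series([1000.0, 1000.0, 1000.0], index=counts.index)
    groups = {c: ("tagged" if c.startswith("tagged") else "control")
              for c in counts.columns}
    libs = {c: 1e6 for c in counts.columns}
    return CountMatrix(counts, lengths, groups, libs)


class TestEnrichmentTable:
    def test_fourfold_gene_has_log2_two(self, small_matrix):
        table = enrichment_table(small_matrix)
        row = table.loc["enriched"]
        assert row["log2_enrichment"] == pytest.approx(np.log2(40.5 / 10.5))
        assert row["q_value"] < 0.05
        assert row["flag_2x"]

    def test_identical_groups_unflagged(self, small_matrix):
        table = enrichment_table(small_matrix)
        for gene in ("flat_low", "flat_high"):
            assert table.loc[gene, "log2_enrichment"] == 0.0
            assert not table.loc[gene, "flag_2x"]
            assert not table.loc[gene, "flag_recovered_4x"]

    def test_gene_without_length_skipped_with_warning(self, small_matrix):
        lengths = small_matrix.lengths.copy()
        lengths.loc["flat_low"] = np.nan
        matrix = CountMatrix(small_matrix.counts, lengths,
                             small_matrix.groups, small_matrix.library_sizes)
        with pytest.warns(UserWarning, match="skipped"):
            res = MapsEnrichment(matrix).fit()
        assert "flat_low" not in res.table.index
        assert res.skipped_genes == ["flat_low"]

    def test_spiked_simulation_recovers_truth(self):
        counts, lengths, spiked = simulate_maps_counts(
            n_genes=1000, n_reps_per_group=2, baseline_mean=100.0,
            dispersion=0.05, spike_gene_count=5, spike_fold=8.0, seed=1,
        )
        groups = {c: ("tagged" if c.startswith("tagged") else "control")
                  for c in counts.columns}
        res = MapsEnrichment.from_dataframe(counts, lengths, groups).fit()
        assert res.table.loc[spiked, "flag_recovered_4x"].all()
        null_flags = res.table.loc[~spiked, "flag_recovered_4x"] | \
            res.table.loc[~spiked, "flag_2x"]
        assert (~null_flags).mean() >= 0.99

    def test_round_trip_through_tsv(self, small_matrix, tmp_path):
        counts_path = tmp_path / "counts.tsv"
        samples_path = tmp_path / "samples.json"
        table = small_matrix.counts.copy()
        table.insert(0, "length_bp", small_matrix.lengths)
        table.to_csv(counts_path, sep="\t")
        import json

        with open(samples_path, "w") as fh:
            json.dump({s: {"group": g, "library_size": 1e6}
                       for s, g in small_matrix.groups.items()}, fh)
        matrix = CountMatrix.from_tsv(counts_path, samples_path)
        pd.testing.assert_frame_equal(
            enrichment_table(matrix), enrichment_table(small_matrix)
        )

    def test_replicate_correlation_high_for_shared_means(self):
        counts, lengths, _ = simulate_maps_counts(
            n_genes=500, dispersion=0.05, spike_gene_count=0, seed=2)
        groups = {c: ("tagged" if c.startswith("tagged") else "control")
                  for c in counts.columns}
        matrix = CountMatrix(counts, lengths, groups)
        assert replicate_fpkm_correlation(matrix, "tagged") > 0.9

    def test_volcano_coordinates_match_table(self, small_matrix):
        res = MapsEnrichment(small_matrix).fit()
        xy = res.volcano_coordinates()
        np.testing.assert_allclose(
            xy["neg_log10_q"], -np.log10(res.table["q_value"]), atol=1e-12
        )

    def test_missing_group_rejected(self, small_matrix):
        groups = {s: "tagged" for s in small_matrix.counts.columns}
        with pytest.raises(ValueError, match="control"):
            CountMatrix(small_matrix.counts, small_matrix.lengths, groups)
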