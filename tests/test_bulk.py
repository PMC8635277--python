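import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h
from sklearn.metrics import adjusted_rand_score

import rppkit as rk
from rppkit.bulk import bh_fdr, classify_trend

from conftest import make_normalized


def brute_force_bh(pvals):
    """Independent step-up oracle: adj_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        adj_sorted[rank - 1] = running
    out = np.empty(n)
    out[order] = adj_sorted
    return out


class TestNormalizeFilter:
    def test_cpm_forced_by_definition(self):
        counts = pd.DataFrame({"s1": [1, 3]}, index=["a", "b"])
        nm = make_normalized(counts, ["mono_d0"])
        np.testing.assert_allclose(nm.cpm["s1"], [250000.0, 750000.0])

    def test_cpm_columns_sum_to_one_million(self, bulk_noisy):
        _, _, nm, _ = bulk_noisy
        np.testing.assert_allclose(nm.cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_threshold_edge_masks_low_cpm(self):
        # gene b sits at population-mean CPM 9.9 in every population
        counts = pd.DataFrame(
            {"s1": [9999901, 99], "s2": [9999901, 99]}, index=["a", "b"]
        )
        meta = pd.DataFrame(
            {"population": ["mono_d0", "ly6c_lo_d4"]}, index=["s1", "s2"]
        )
        cm = rk.CountMatrix(counts, meta, ["mono_d0", "ly6c_lo_d4"])
        nm = rk.normalize_and_filter(cm, cpm_min=10)
        assert not nm.keep["b"] and nm.reasons["b"] == "low_cpm"
        assert nm.keep["a"]

    def test_planted_low_expression_bookkeeping(self):
        # 12 genes below threshold among 100
        rng = np.random.default_rng(0)
        high = rng.integers(5000, 20000, size=(88, 6)).astype(float)
        low = rng.integers(1, 5, size=(12, 6)).astype(float)
        counts = pd.DataFrame(
            np.vstack([high, low]),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{j}" for j in range(6)],
        )
        meta = pd.DataFrame(
            {"population": ["mono_d0"] * 3 + ["ly6c_lo_d4"] * 3}, index=counts.columns
        )
        cm = rk.CountMatrix(counts, meta, ["mono_d0", "ly6c_lo_d4"])
        nm = rk.normalize_and_filter(cm, cpm_min=10)
        assert int(nm.keep.sum()) == 88
        assert (nm.reasons[~nm.keep] == "low_cpm").all()

    def test_non_coding_masked(self):
        counts = pd.DataFrame({"s1": [100, 100], "s2": [100, 100]}, index=["a", "b"])
        meta = pd.DataFrame({"population": ["mono_d0", "mono_d0"]}, index=["s1", "s2"])
        gm = pd.DataFrame({"gene_type": ["protein_coding", "lncRNA"]}, index=["a", "b"])
        cm = rk.CountMatrix(counts, meta, ["mono_d0"], gm)
        nm = rk.normalize_and_filter(cm, cpm_min=0, coding_only=True)
        assert nm.reasons["b"] == "non_coding" and nm.keep["a"]

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        meta = pd.DataFrame({"population": ["mono_d0", "mono_d0"]}, index=["s1", "s2"])
        cm = rk.CountMatrix(counts, meta, ["mono_d0"])
        with pytest.raises(ValueError, match="s2"):
            rk.normalize_and_filter(cm)


class TestDeTest:
    def _matrix(self, counts_a, counts_b, genes=None):
        counts_a, counts_b = np.atleast_2d(counts_a), np.atleast_2d(counts_b)
        n = counts_a.shape[0]
        genes = genes or [f"g{i}" for i in range(n)]
        cols = [f"a{j}" for j in range(counts_a.shape[1])] + [
            f"b{j}" for j in range(counts_b.shape[1])
        ]
        counts = pd.DataFrame(np.hstack([counts_a, counts_b]), index=genes, columns=cols)
        pops = ["mono_d0"] * counts_a.shape[1] + ["ly6c_lo_d4"] * counts_b.shape[1]
        meta = pd.DataFrame({"population": pops}, index=cols)
        cm = rk.CountMatrix(counts, meta, ["mono_d0", "ly6c_lo_d4"])
        nm = rk.normalize_and_filter(cm, cpm_min=0)
        return cm, nm, cols[: counts_a.shape[1]], cols[counts_a.shape[1]:]

    def test_null_case_no_de(self):
        base = np.tile([[100.0], [500.0], [50.0]], (1, 3))
        cm, nm, ga, gb = self._matrix(base, base)
        de = rk.de_test(nm, cm, ga, gb)
        assert int(de.table["is_de"].sum()) == 0
        assert (de.table["pvalue"] == 1.0).all()

    def test_power_on_planted_fourfold(self):
        # 50 four-fold genes among 450 unchanged ones keeping library sizes stable
        rng = np.random.default_rng(42)
        mu = rng.uniform(200, 2000, size=500)
        fold = np.ones(500)
        fold[:50] = 4.0
        disp = 0.05
        n = 1 / disp

        def draw(means):
            return rng.negative_binomial(n, n / (n + means))

        a = np.column_stack([draw(mu) for _ in range(3)]).astype(float)
        b = np.column_stack([draw(mu * fold) for _ in range(3)]).astype(float)
        cm, nm, ga, gb = self._matrix(a, b)
        de = rk.de_test(nm, cm, ga, gb)
        planted = de.table.iloc[:50]
        assert int(planted["is_de"].sum()) >= 45
        assert (planted.loc[planted["is_de"], "log2fc"] > 0).all()
        # false positives among the 450 nulls stay near the FDR target
        assert int(de.table.iloc[50:]["is_de"].sum()) <= 10

    def test_fold_change_gate(self):
        # large counts make p tiny, but fold 2**0.5 < 1.5: never flagged
        a = np.tile([[20000.0]], (1, 3))
        b = np.tile([[20000.0 * 2**0.5]], (1, 3))
        filler = np.tile([[1e6]], (1, 3))  # dominates the library size
        cm, nm, ga, gb = self._matrix(np.vstack([a, filler]), np.vstack([b, filler]))
        de = rk.de_test(nm, cm, ga, gb)
        row = de.table.loc["g0"]
        assert row["fdr"] < 0.05  # significant, so only the fold gate blocks it
        assert abs(row["log2fc"]) < np.log2(1.5)
        assert not row["is_de"]

    def test_overlapping_or_small_groups_rejected(self, bulk_noisy):
        cm, _, nm, _ = bulk_noisy
        a = cm.samples_of("mono_d0")
        with pytest.raises(ValueError, match="overlap"):
            rk.de_test(nm, cm, a, a)
        with pytest.raises(ValueError, match=">= 2"):
            rk.de_test(nm, cm, a[:1], cm.samples_of("ly6c_lo_d4"))

    def test_fdr_at_least_raw_p(self, bulk_noisy):
        cm, _, nm, _ = bulk_noisy
        de = rk.de_test(nm, cm, cm.samples_of("mono_d0"), cm.samples_of("ly6c_lo_d4"))
        assert (de.table["fdr"] >= de.table["pvalue"] - 1e-12).all()


class TestBhFdr:
    @given(
        st_h.lists(st_h.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=20)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=15)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestTrajectories:
    def test_z_row_forced_by_definition(self):
        counts = pd.DataFrame(
            {"s1": [2**1 * 100], "s2": [2**2 * 100], "s3": [2**3 * 100]},
            index=["a"],
        ).astype(float)
        # single gene: z-scaling is undefined only if constant; use 2 genes
        counts.loc["b"] = [1000.0, 1000.0, 1000.0]
        nm = make_normalized(counts, ["mono_d0", "ly6c_hi_d1", "ly6c_lo_d4"])
        tm = rk.build_trajectories(nm)
        row = tm.Z.loc["a"].to_numpy()
        assert abs(row.mean()) < 1e-8 and abs(row.std() - 1) < 1e-8
        assert row[0] < row[1] < row[2]

    def test_constant_gene_dropped_with_warning(self, caplog):
        # balanced library sizes keep 'const' at identical CPM in every state
        counts = pd.DataFrame(
            {"s1": [100.0, 500, 400], "s2": [200.0, 500, 300], "s3": [400.0, 500, 100]},
            index=["a", "const", "b"],
        )
        nm = make_normalized(counts, ["mono_d0", "ly6c_hi_d1", "ly6c_lo_d4"])
        with caplog.at_level("WARNING", logger="rppkit"):
            tm = rk.build_trajectories(nm)
        assert "const" not in tm.Z.index
        assert {"a", "b"} <= set(tm.Z.index)
        assert any("constant" in r.message for r in caplog.records)

    def test_rows_are_z_scored(self, bulk_noisy):
        *_, tm = bulk_noisy
        np.testing.assert_allclose(tm.Z.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(tm.Z.std(axis=1, ddof=0), 1.0, atol=1e-8)

    def test_noise_free_rows_match_planted_centroids(self, bulk_exact):
        # library-size differences between populations shift all genes by a
        # small shared per-population offset, so match by correlation: each
        # row must sit essentially on its own archetype and on no other
        _, truth, _, tm = bulk_exact
        zc = truth.z_centroids()
        corr = pd.DataFrame(
            np.corrcoef(tm.Z.to_numpy(), zc.to_numpy())[: len(tm.Z), len(tm.Z):],
            index=tm.Z.index,
            columns=zc.index,
        )
        for gene in tm.Z.index:
            own = truth.archetype[gene]
            assert corr.loc[gene, own] > 0.97
            assert corr.loc[gene].idxmax() == own

    def test_too_few_populations_rejected(self):
        counts = pd.DataFrame({"s1": [10.0], "s2": [20.0]}, index=["a"])
        nm = make_normalized(counts, ["mono_d0", "ly6c_lo_d4"])
        with pytest.raises(ValueError, match="3"):
            rk.build_trajectories(nm)


class TestSelectK:
    def _tm_from_blobs(self, centers, n_per, sd, seed):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(c, sd, size=(n_per, len(centers[0]))) for c in centers]
        )
        Z = pd.DataFrame(
            X,
            index=[f"g{i}" for i in range(X.shape[0])],
            columns=[f"p{j}" for j in range(X.shape[1])],
        )
        return rk.TrajectoryMatrix(
            Z, list(Z.columns), Z.mean(axis=1), Z.std(axis=1, ddof=0)
        )

    def test_three_separated_blobs(self):
        centers = [(0, 0, 0, 0), (10, 10, 0, 0), (0, 10, 10, 10)]
        tm = self._tm_from_blobs(centers, 40, 1.0, seed=2)
        k, diag = rk.select_k(tm, range(2, 7), B=20, seed=2)
        assert k == 3

    def test_single_blob_returns_lower_bound(self):
        tm = self._tm_from_blobs([(0, 0, 0, 0)], 60, 1.0, seed=3)
        k, _ = rk.select_k(tm, range(2, 6), B=20, seed=3)
        assert k == 2

    def test_wcss_non_increasing(self):
        tm = self._tm_from_blobs([(0, 0, 0, 0), (5, 5, 5, 5)], 40, 1.0, seed=4)
        _, diag = rk.select_k(tm, range(2, 8), B=10, seed=4)
        wcss = np.exp(diag["log_wcss"].to_numpy())
        assert (np.diff(wcss) <= 1e-6).all()

    def test_k_range_bound_rejected(self, bulk_noisy):
        *_, tm = bulk_noisy
        with pytest.raises(ValueError, match="upper bound"):
            rk.select_k(tm, range(2, len(tm.Z) + 1), B=10, seed=0)


class TestClusterTrajectories:
    def test_noise_free_recovery_is_exact(self, bulk_exact):
        _, truth, _, tm = bulk_exact
        model = rk.cluster_trajectories(tm, 7, seed=5)
        ari = adjusted_rand_score(truth.archetype.loc[tm.Z.index], model.assignments)
        assert ari == pytest.approx(1.0)

    def test_membership_one_for_gene_on_centroid(self, bulk_exact):
        _, _, _, tm = bulk_exact
        model = rk.cluster_trajectories(tm, 7, seed=5)
        assert model.membership.max() > 0.9999

    def test_noisy_recovery(self, bulk_noisy):
        _, truth, _, tm = bulk_noisy
        model = rk.cluster_trajectories(tm, 7, seed=6)
        ari = adjusted_rand_score(truth.archetype.loc[tm.Z.index], model.assignments)
        assert ari >= 0.8
        assert model.membership.median() >= 0.9

    def test_assignment_optimality(self, bulk_noisy):
        # every gene must sit closest to its own centroid
        *_, tm = bulk_noisy
        model = rk.cluster_trajectories(tm, 7, seed=7)
        X = tm.Z.to_numpy()
        C = model.centroids.to_numpy()
        d = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(d.argmin(axis=1), model.assignments.to_numpy())

    def test_no_empty_cluster_and_sizes_sum(self, bulk_noisy):
        *_, tm = bulk_noisy
        model = rk.cluster_trajectories(tm, 7, seed=8)
        sizes = model.sizes()
        assert len(sizes) == 7 and (sizes > 0).all()
        assert int(sizes.sum()) == len(tm.Z)

    def test_seed_determinism(self, bulk_noisy):
        *_, tm = bulk_noisy
        a = rk.cluster_trajectories(tm, 7, seed=9)
        b = rk.cluster_trajectories(tm, 7, seed=9)
        assert a.assignments.equals(b.assignments)


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "centroid,label",
        [
            ((-1.2, -0.4, 0.1, 0.6, 1.1), "monotone_up"),
            ((1.2, 0.4, -0.1, -0.6, -1.1), "monotone_down"),
            ((-1, 1.2, 0.9, -0.5, -0.8), "transient_up"),
            ((1, -1.2, -0.9, 0.5, 0.8), "transient_down"),
            ((0, 0.05, -0.05, 0.02, 0), "mixed"),  # all steps below eps
            ((-2, 0.8, 1.0, 1.1, 1.2), "monotone_up"),  # flat tail after rise
            ((0, 1, 0, 1, 0), "mixed"),  # two reversals
        ],
    )
    def test_labels(self, centroid, label):
        assert classify_trend(centroid, eps=0.1) == label

    @given(
        st_h.lists(st_h.integers(min_value=-12, max_value=12), min_size=3, max_size=8),
        st_h.integers(min_value=-20, max_value=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_invariant(self, quarters, shift_quarters):
        # quarter-unit grids keep successive differences exactly representable,
        # so the eps comparison cannot flip from rounding alone
        centroid = [q * 0.25 for q in quarters]
        shifted = [(q + shift_quarters) * 0.25 for q in quarters]
        assert classify_trend(centroid) == classify_trend(shifted)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            classify_trend((0, 1))


class TestSampleTree:
    def test_duplicate_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(10, 1000, size=20)
        counts = pd.DataFrame(
            {"s1": base, "s2": base, "s3": rng.uniform(10, 1000, size=20)},
            index=[f"g{i}" for i in range(20)],
        )
        nm = make_normalized(counts, ["mono_d0", "ly6c_hi_d1", "ly6c_lo_d4"])
        Z, samples = rk.sample_distance_tree(nm)
        assert {samples[int(Z[0, 0])], samples[int(Z[0, 1])]} == {"s1", "s2"}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_rank_reversed_sample_joins_at_two(self):
        vals = np.arange(1.0, 21.0)
        counts = pd.DataFrame(
            {"s1": vals, "s2": vals**2, "s3": vals[::-1].copy()},
            index=[f"g{i}" for i in range(20)],
        )
        nm = make_normalized(counts, ["mono_d0", "ly6c_hi_d1", "ly6c_lo_d4"])
        Z, samples = rk.sample_distance_tree(nm)
        # s1, s2 are rank-identical (Spearman 1 -> distance 0); s3 is the
        # rank reversal of both (Spearman -1 -> distance 2)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert Z[1, 2] == pytest.approx(2.0, abs=1e-9)

    def test_monotone_transform_leaves_tree_unchanged(self, bulk_noisy):
        _, _, nm, _ = bulk_noisy
        Z1, _ = rk.sample_distance_tree(nm)
        nm2 = rk.NormalizedMatrix(
            nm.cpm,
            nm.log2cpm.assign(**{nm.log2cpm.columns[0]: np.expm1(nm.log2cpm.iloc[:, 0])}),
            nm.keep,
            nm.reasons,
            nm.sample_meta,
            nm.population_order,
        )
        Z2, _ = rk.sample_distance_tree(nm2)
        np.testing.assert_allclose(Z1, Z2, atol=1e-9)
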