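import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panmethnet.correlation import (
    CorrelationThresholds,
    cluster_profiles,
    correlate_sets,
    correlation_grid,
    pearson,
)
from panmethnet.data_model import OmicsMatrix

from conftest import small_config


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_arithmetic_example(self):
        r, p, n = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert n == 4

    def test_constant_input_missing(self):
        r, p, n = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_pairs_missing(self):
        r, p, n = pearson([1.0, np.nan, 3.0], [np.nan, 2.0, 3.0])
        assert n < 3 and np.isnan(r)

    def test_matches_reference_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(3, 30)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, p, _ = pearson(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            assert r == pytest.approx(r_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-8)


class TestCorrelateSets:
    def _matrix(self, frame, kind="expression_log2fpkm"):
        return OmicsMatrix(frame, kind)

    def test_self_correlation_diagonal(self):
        m = self._matrix(pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["f"], columns=list("abcd")))
        table = correlate_sets(m, m)
        assert table.iloc[0]["r"] == pytest.approx(1.0)

    def test_symmetry_in_matrix_order(self, small_bundle):
        thr = CorrelationThresholds()
        ab = correlate_sets(small_bundle.expression, small_bundle.methylation,
                            small_bundle.metadata, mode="pooled",
                            thresholds=thr, source="tumor")
        ba = correlate_sets(small_bundle.methylation, small_bundle.expression,
                            small_bundle.metadata, mode="pooled",
                            thresholds=thr, source="tumor")
        key_ab = ab.set_index(["feature_a", "feature_b"])["r"]
        key_ba = ba.set_index(["feature_b", "feature_a"])["r"]
        joined = pd.concat([key_ab, key_ba], axis=1, join="inner")
        assert np.allclose(joined.iloc[:, 0], joined.iloc[:, 1])

    def test_planted_promoter_coupling_detected(self):
        from panmethnet.synthetic_cohort import generate

        hits = 0
        for seed in range(20):
            cfg = small_config(n_cohorts=1, n_tumor=200, n_normal=10,
                               seed=300 + seed)
            b = generate(cfg)
            table = correlate_sets(
                b.expression.subset_features(["SLC22A17"]),
                b.methylation.subset_features(["cg-SLC22A17-promoter-01"]),
                b.metadata, mode="per_cohort", source="tumor",
            )
            row = table.iloc[0]
            if row["significant"] and row["r"] < 0:
                hits += 1
        assert hits >= 19

    def test_protein_absent_from_cohort_panel_yields_no_row(self, small_bundle):
        table = correlate_sets(
            small_bundle.expression.subset_features(["LCN2"]),
            small_bundle.protein, small_bundle.metadata,
            mode="per_cohort", source="tumor",
        )
        prot = small_bundle.protein.values
        meta = small_bundle.metadata.set_index("sample_id")
        for cohort, sub in meta.groupby("cohort"):
            cols = [s for s in prot.columns if s in sub.index]
            absent = prot[cols].isna().all(axis=1)
            for pid in prot.index[absent]:
                assert table.query(
                    "feature_b == @pid and cohort == @cohort"
                ).empty

    def test_per_cohort_invariant_to_sample_shuffle(self, small_bundle):
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_bundle.expression.sample_ids)
        shuffled = small_bundle.expression.subset_samples(list(perm))
        thr = CorrelationThresholds()
        a = correlate_sets(small_bundle.expression.subset_features(["LCN2"]),
                           small_bundle.expression.subset_features(["MMP9"]),
                           small_bundle.metadata, mode="per_cohort",
                           thresholds=thr, source="tumor")
        b = correlate_sets(shuffled.subset_features(["LCN2"]),
                           small_bundle.expression.subset_features(["MMP9"]),
                           small_bundle.metadata, mode="per_cohort",
                           thresholds=thr, source="tumor")
        a = a.sort_values("cohort").reset_index(drop=True)
        b = b.sort_values("cohort").reset_index(drop=True)
        assert np.allclose(a["r"], b["r"])

    def test_no_shared_samples_errors(self):
        a = self._matrix(pd.DataFrame([[1.0]], index=["f"], columns=["s1"]))
        b = self._matrix(pd.DataFrame([[1.0]], index=["g"], columns=["s2"]))
        with pytest.raises(ValueError, match="no shared samples"):
            correlate_sets(a, b)


def average_linkage_oracle(points, k):
    """Exhaustive average-linkage agglomeration on ≤ 6 points."""
    clusters = [frozenset([i]) for i in range(len(points))]
    points = [np.asarray(p, float) for p in points]

    def avg_dist(ca, cb):
        return float(np.mean([
            np.linalg.norm(points[i] - points[j]) for i in ca for j in cb
        ]))

    while len(clusters) > k:
        best = min(
            itertools.combinations(range(len(clusters)), 2),
            key=lambda ij: avg_dist(clusters[ij[0]], clusters[ij[1]]),
        )
        i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    labels = np.empty(len(points), int)
    for lab, c in enumerate(clusters):
        for i in c:
            labels[i] = lab
    return labels


class TestClusterProfiles:
    def _grid(self, rows, index=None):
        arr = np.asarray(rows, float)
        idx = index or [f"f{i}" for i in range(arr.shape[0])]
        return pd.DataFrame(arr, index=idx,
                            columns=[f"p{j}" for j in range(arr.shape[1])])

    def test_k_equals_n_gives_singletons(self):
        grid = self._grid(np.eye(4))
        labels = cluster_profiles(grid, 4)
        assert labels.nunique() == 4

    def test_two_separated_blocks(self):
        grid = self._grid([[0, 0], [0, 0], [10, 10], [10, 10]])
        labels = cluster_profiles(grid, 2)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]
        assert labels.iloc[0] != labels.iloc[2]

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            pts = rng.normal(size=(n, 3))
            k = int(rng.integers(1, n + 1))
            labels = cluster_profiles(self._grid(pts), k).to_numpy()
            oracle = average_linkage_oracle(pts, k)
            # compare partitions up to label renaming
            def canon(ls):
                seen = {}
                return tuple(seen.setdefault(l, len(seen)) for l in ls)
            assert canon(labels) == canon(oracle)

    def test_merge_heights_non_decreasing(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(9)
        arr = rng.normal(size=(12, 4))
        tree = linkage(arr, method="average", metric="euclidean")
        heights = tree[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_validation(self):
        grid = self._grid(np.eye(3))
        with pytest.raises(ValueError):
            cluster_profiles(grid, 0)
        with pytest.raises(ValueError):
            cluster_profiles(grid, 4)

    def test_grid_pivot(self, small_bundle):
        table = correlate_sets(
            small_bundle.expression.subset_features(["LCN2", "MMP9"]),
            small_bundle.protein, small_bundle.metadata,
            mode="pooled", source="tumor",
        )
        grid = correlation_grid(table)
        assert grid.shape[0] == 2
        assert set(grid.index) == {"LCN2", "MMP9"}
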