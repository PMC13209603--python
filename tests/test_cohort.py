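import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriome.cohort import (
    binomial_ci,
    cluster_heatmap,
    dunn_index,
    feature_wilcoxon_bh,
    permanova,
    prevalence_ranking,
)


class TestBinomialCI:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (103, (0.446, 0.584)),  # 51.5%
            (90, (0.381, 0.519)),  # 45.0%
            (82, (0.342, 0.478)),  # 41.0%
            (77, (0.318, 0.452)),  # 38.5%
            (72, (0.293, 0.427)),  # 36.0%
        ],
    )
    def test_wald_at_n200(self, x, expected):
        low, high = binomial_ci(x, 200, method="wald")
        assert round(low, 3) == expected[0]
        assert round(high, 3) == expected[1]

    def test_wald_degenerate_at_zero(self):
        assert binomial_ci(0, 10, method="wald") == (0.0, 0.0)

    def test_modified_wald_at_zero(self):
        low, high = binomial_ci(0, 10, method="modified_wald")
        p = 2 / 14
        half = 1.959964 * np.sqrt(p * (1 - p) / 14)
        assert low == 0.0  # clamped
        assert high == pytest.approx(p + half)
        assert high == pytest.approx(0.326, abs=5e-4)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(1, 8))
    def test_interval_contains_estimate_and_shrinks(self, x, scale):
        n = 50
        low, high = binomial_ci(x, n)
        assert low <= x / n <= high
        low2, high2 = binomial_ci(x * scale, n * scale)
        assert (high2 - low2) <= (high - low) + 1e-12


class TestPrevalenceRanking:
    @staticmethod
    def _calls(labels_by_feature, n):
        rows = []
        for feature, labels in labels_by_feature.items():
            assert len(labels) == n
            for i, label in enumerate(labels):
                rows.append(
                    {"sample_id": f"s{i}", "feature_name": feature, "label": label}
                )
        return pd.DataFrame(rows)

    def test_all_neutral_gives_zero_proportions(self):
        calls = self._calls({"a": ["neutral"] * 6, "b": ["neutral"] * 6}, 6)
        ranking = prevalence_ranking(calls)
        assert (ranking["proportion"] == 0).all()

    def test_planted_counts_and_printed_ci(self):
        labels = ["moderate"] * 60 + ["high"] * 43 + ["neutral"] * 97
        calls = self._calls({"protein": labels, "quiet": ["neutral"] * 200}, 200)
        ranking = prevalence_ranking(calls, ci_method="wald")
        top = ranking.iloc[0]
        assert top["feature_name"] == "protein"
        assert top["x_dysregulated"] == 103
        assert top["proportion"] == pytest.approx(0.515)
        assert round(top["ci_low"], 3) == 0.446
        assert round(top["ci_high"], 3) == 0.584

    def test_ties_break_alphabetically(self):
        calls = self._calls(
            {"zeta": ["high"] * 3 + ["neutral"] * 3, "alpha": ["high"] * 3 + ["neutral"] * 3},
            6,
        )
        ranking = prevalence_ranking(calls)
        assert ranking["feature_name"].tolist() == ["alpha", "zeta"]

    def test_missing_pairs_rejected(self):
        calls = self._calls({"a": ["neutral"] * 4, "b": ["high"] * 4}, 4)
        calls = calls.iloc[:-1]  # feature b loses one sample
        with pytest.raises(ValueError, match="incomplete"):
            prevalence_ranking(calls)


class TestClustering:
    def test_two_blobs_recovered(self, rng):
        A = rng.normal(0, 1, size=(30, 8))
        B = rng.normal(4, 1, size=(30, 8))
        profiles = pd.DataFrame(np.vstack([A, B]), index=[f"s{i}" for i in range(60)])
        result = cluster_heatmap(profiles, seed=1)
        assert result.k == 2
        assert result.silhouette > 0.5
        truth = np.array([1] * 30 + [2] * 30)
        got = result.assignments.to_numpy()
        agreement = max((got == truth).mean(), (got == 3 - truth).mean())
        assert agreement == 1.0
        assert result.permanova_p == pytest.approx(0.001)
        assert 0 <= result.permanova_R2 <= 1

    def test_sample_order_invariance(self, rng):
        X = pd.DataFrame(
            np.vstack([rng.normal(0, 1, (15, 5)), rng.normal(5, 1, (15, 5))]),
            index=[f"s{i}" for i in range(30)],
        )
        r1 = cluster_heatmap(X, k_candidates=(2,), n_permutations=99, seed=0)
        shuffled = X.sample(frac=1, random_state=3)
        r2 = cluster_heatmap(shuffled, k_candidates=(2,), n_permutations=99, seed=0)
        a1 = r1.assignments.sort_index()
        a2 = r2.assignments.sort_index()
        same = (a1 == a2).all() or (a1 == 3 - a2).all()
        assert same

    def test_identical_samples_rejected(self):
        X = pd.DataFrame(np.ones((6, 4)))
        with pytest.raises(ValueError):
            cluster_heatmap(X)

    def test_null_data_low_silhouette(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        result = cluster_heatmap(X, k_candidates=(2,), n_permutations=99, seed=0)
        assert result.k == 2
        assert result.silhouette < 0.3

    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)))
        X["const"] = 1.0
        result = cluster_heatmap(X, k_candidates=(2,), n_permutations=99, seed=0)
        assert "const" not in result.scaled.columns

    def test_dunn_index_separated_blobs_above_one(self, rng):
        from scipy.spatial.distance import pdist, squareform

        A = rng.normal(0, 0.1, size=(10, 3))
        B = rng.normal(10, 0.1, size=(10, 3))
        dist = squareform(pdist(np.vstack([A, B])))
        labels = np.array([0] * 10 + [1] * 10)
        assert dunn_index(dist, labels) > 1.0


class TestPermanova:
    def test_perfect_separation_hits_p_floor(self, rng):
        A = rng.normal(0, 0.5, size=(10, 4))
        B = rng.normal(10, 0.5, size=(10, 4))
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(np.vstack([A, B])))
        F, R2, p = permanova(dist, ["a"] * 10 + ["b"] * 10, n_permutations=999, seed=0)
        # 1/1000 is the attainable floor; random permutation sampling can
        # redraw the mirrored labeling (F tie), giving at most 2/1000
        assert p <= 0.002
        assert F > 50
        assert 0.9 < R2 <= 1

    def test_r2_is_among_over_total(self, rng):
        X = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(X))
        F, R2, p = permanova(dist, ["a"] * 6 + ["b"] * 6, n_permutations=99, seed=1)
        assert 0 <= R2 <= 1
        n, k = 12, 2
        # F and R2 must be mutually consistent through the SS partition
        assert F == pytest.approx((R2 / (k - 1)) / ((1 - R2) / (n - k)))

    def test_singleton_group_rejected(self, rng):
        dist = np.abs(rng.normal(size=(5, 5)))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0)
        with pytest.raises(ValueError, match="singleton"):
            permanova(dist, ["a"] * 4 + ["b"], n_permutations=9)

    def test_degenerate_identical_points_rejected(self):
        dist = np.zeros((8, 8))
        with pytest.raises(ValueError, match="degenerate"):
            permanova(dist, ["a"] * 4 + ["b"] * 4, n_permutations=9)


class TestWilcoxonBH:
    def test_shifted_feature_detected(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(200, 10)))
        labels = np.array([1] * 100 + [2] * 100)
        profiles.iloc[100:, 3] += 3.0  # 3 pooled SDs
        out = feature_wilcoxon_bh(profiles, labels)
        row = out[out["feature_name"] == 3].iloc[0]
        assert row["adjusted_p"] < 0.05
        assert row["enriched_cluster"] == 2

    def test_bh_preserves_p_order_and_never_inflates(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(60, 32)))
        labels = np.array([1] * 30 + [2] * 30)
        out = feature_wilcoxon_bh(profiles, labels).sort_values("raw_p")
        assert out["adjusted_p"].is_monotonic_increasing
        assert (out["adjusted_p"] >= out["raw_p"] - 1e-12).all()
        assert out["significant"].sum() <= (out["raw_p"] < 0.05).sum()

    def test_more_than_two_clusters_rejected(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(9, 3)))
        with pytest.raises(ValueError):
            feature_wilcoxon_bh(profiles, np.array([1, 1, 1, 2, 2, 2, 3, 3, 3]))
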