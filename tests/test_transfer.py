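import numpy as np
import pandas as pd
import pytest

from autoqc import (
    ConfigError,
    covariate_variance,
    flag_unknown,
    knn_transfer,
    reassign_unknown,
)


class TestKnnTransfer:
    def test_self_transfer_k1_reproduces_labels_with_zero_uncertainty(
        self, blob_latents
    ):
        ref, labels, _, _ = blob_latents
        res = knn_transfer(ref, labels, ref, k=1)
        np.testing.assert_array_equal(res["predicted_label"].to_numpy(), labels)
        np.testing.assert_array_equal(res["uncertainty"].to_numpy(), 0.0)

    def test_unanimous_neighbourhood_has_zero_uncertainty(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 1, (50, 3))
        res = knn_transfer(ref, np.array(["B cell"] * 50), rng.normal(0, 1, (5, 3)), k=10)
        assert (res["predicted_label"] == "B cell").all()
        np.testing.assert_allclose(res["uncertainty"], 0.0, atol=1e-12)

    def test_equidistant_three_vs_two_vote(self):
        """Five reference points on a unit circle around the query: equal
        weights, labels 3xA + 2xB -> predicted A with uncertainty 0.4."""
        theta = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        ref = np.column_stack([np.cos(theta), np.sin(theta)])
        res = knn_transfer(ref, np.array(["A", "A", "A", "B", "B"]),
                           np.zeros((1, 2)), k=5)
        assert res["predicted_label"].iloc[0] == "A"
        assert res["uncertainty"].iloc[0] == pytest.approx(0.4)

    def test_two_blob_accuracy(self, blob_latents):
        ref, ref_labels, query, query_labels = blob_latents
        res = knn_transfer(ref, ref_labels, query, k=30)
        assert (res["predicted_label"].to_numpy() == query_labels).mean() >= 0.99

    def test_uncertainty_invariant_to_rotation_and_scaling(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 1, (120, 4))
        labels = rng.choice(["A", "B", "C"], 120)
        query = rng.normal(0, 1, (40, 4))
        base = knn_transfer(ref, labels, query, k=15)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        for transform in (lambda X: X @ Q, lambda X: 3.7 * X):
            res = knn_transfer(transform(ref), labels, transform(query), k=15)
            np.testing.assert_allclose(
                res["uncertainty"], base["uncertainty"], atol=1e-8
            )
            np.testing.assert_array_equal(
                res["predicted_label"], base["predicted_label"]
            )

    def test_k_larger_than_reference_raises(self):
        with pytest.raises(ConfigError):
            knn_transfer(np.zeros((5, 2)), np.array(["A"] * 5), np.zeros((1, 2)), k=6)


class TestFlagUnknown:
    def test_order_statistics_single_group(self):
        res = pd.DataFrame(
            {"predicted_label": ["A"] * 10, "uncertainty": np.arange(10) / 10}
        )
        out, thr = flag_unknown(res)
        assert thr["all"] == pytest.approx(0.81)  # linear-interpolation quantile
        np.testing.assert_array_equal(out["unknown"], np.arange(10) == 9)
        assert out["final_label"].iloc[9] == "unknown"

    def test_groups_flag_their_own_top_decile(self):
        n = 500
        rng = np.random.default_rng(4)
        res = pd.DataFrame(
            {
                "predicted_label": ["A"] * (2 * n),
                "uncertainty": np.concatenate(
                    [rng.uniform(0.0, 0.2, n), rng.uniform(0.6, 0.9, n)]
                ),
            }
        )
        groups = np.array(["low"] * n + ["high"] * n)
        out, _ = flag_unknown(res, groups)
        # Stratified: each group loses ~10%, not a pooled top 10%.
        assert out["unknown"][:n].mean() == pytest.approx(0.1, abs=0.02)
        assert out["unknown"][n:].mean() == pytest.approx(0.1, abs=0.02)

    def test_flagged_fraction_close_to_ten_percent(self):
        rng = np.random.default_rng(5)
        res = pd.DataFrame(
            {"predicted_label": ["A"] * 1000, "uncertainty": rng.beta(2, 5, 1000)}
        )
        out, _ = flag_unknown(res)
        assert abs(out["unknown"].mean() - 0.10) <= 0.02

    def test_raising_quantile_shrinks_unknown_set(self):
        rng = np.random.default_rng(6)
        res = pd.DataFrame(
            {"predicted_label": ["A"] * 300, "uncertainty": rng.random(300)}
        )
        sizes = [
            flag_unknown(res, quantile=q)[0]["unknown"].sum()
            for q in (0.90, 0.95, 0.99, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0


class TestReassignUnknown:
    def test_unknown_cell_takes_cluster_majority(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(0, 0.5, (30, 4))
        res = pd.DataFrame(
            {
                "predicted_label": ["Stem"] * 29 + ["Tuft"],
                "uncertainty": [0.1] * 29 + [0.9],
                "unknown": [False] * 29 + [True],
                "final_label": ["Stem"] * 29 + ["unknown"],
            }
        )
        out, unresolved = reassign_unknown(latent, res, seed=0)
        assert out["final_label"].iloc[29] == "Stem"
        assert unresolved == []

    def test_fully_unknown_cluster_stays_unknown_and_is_reported(self):
        rng = np.random.default_rng(8)
        latent = np.vstack(
            [rng.normal(0, 0.5, (25, 3)), rng.normal(20, 0.5, (25, 3))]
        )
        res = pd.DataFrame(
            {
                "predicted_label": ["Stem"] * 25 + ["Tuft"] * 25,
                "uncertainty": [0.1] * 25 + [0.9] * 25,
                "unknown": [False] * 25 + [True] * 25,
                "final_label": ["Stem"] * 25 + ["unknown"] * 25,
            }
        )
        out, unresolved = reassign_unknown(latent, res, seed=0)
        assert (out["final_label"].iloc[25:] == "unknown").all()
        assert len(unresolved) == 1

    def test_planted_blob_reassignments_match_truth(self, blob_latents):
        ref, ref_labels, query, query_labels = blob_latents
        res = knn_transfer(ref, ref_labels, query, k=30)
        res, _ = flag_unknown(res)
        out, _ = reassign_unknown(query, res, seed=0)
        reassigned = res["unknown"].to_numpy()
        if reassigned.any():
            match = (
                out.loc[reassigned, "final_label"].to_numpy()
                == query_labels[reassigned]
            )
            assert match.mean() >= 0.95


class TestCovariateVariance:
    def test_exact_linear_dimension_has_r2_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 200)
        latent = np.column_stack([2 * x + 3, rng.normal(0, 1, 200)])
        rep = covariate_variance(latent, x, "x")
        assert rep.r2_per_dim[0] == pytest.approx(1.0)

    def test_independent_covariate_explains_nothing(self):
        rng = np.random.default_rng(10)
        latent = rng.normal(0, 1, (5000, 10))
        rep = covariate_variance(latent, rng.normal(0, 1, 5000), "noise")
        assert rep.mean_r2 < 0.01

    def test_categorical_matches_anova_oracle(self):
        rng = np.random.default_rng(11)
        groups = rng.choice(["a", "b", "c"], 400)
        shifts = {"a": 0.0, "b": 1.5, "c": -0.7}
        y = np.array([shifts[g] for g in groups]) + rng.normal(0, 1, 400)
        rep = covariate_variance(y.reshape(-1, 1), groups, "group")
        # Brute-force group-mean ANOVA R^2 = SS_between / SS_total.
        grand = y.mean()
        ss_between = sum(
            (groups == g).sum() * (y[groups == g].mean() - grand) ** 2
            for g in "abc"
        )
        ss_total = ((y - grand) ** 2).sum()
        assert rep.r2_per_dim[0] == pytest.approx(ss_between / ss_total)

    def test_constant_covariate_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            rep = covariate_variance(np.random.default_rng(0).normal(size=(50, 3)),
                                     np.ones(50), "const")
        np.testing.assert_array_equal(rep.r2_per_dim, 0.0)
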