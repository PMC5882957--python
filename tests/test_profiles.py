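"""Profile clustering, PCA, PAM, condition correlations, wave summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from estronet import (
    choose_k,
    condition_corr_matrix,
    kmeans_profiles,
    log2fc_profiles,
    median_center,
    pam_samples,
    pca_samples,
    wave_summary,
)
from estronet.expression_io import ProfileMatrix, condition_label


class TestMedianCenter:
    def test_forced_examples(self):
        out = median_center(np.array([[1.0, 2.0, 9.0], [5.0, 5.0, 5.0]]))
        assert np.allclose(out[0], [-1.0, 0.0, 7.0])
        assert np.allclose(out[1], 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(6, 7))
        once = median_center(m)
        assert np.allclose(median_center(once), once)

    def test_row_medians_zero(self):
        rng = np.random.default_rng(1)
        out = median_center(rng.normal(size=(10, 9)))
        assert np.allclose(np.median(out, axis=1), 0.0)


def planted_profiles(n_copies=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    prototypes = np.array(
        [
            [4.0, 4.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 4.0, 4.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, -4.0, -4.0],
        ]
    )
    rows, labels = [], []
    for k, proto in enumerate(prototypes):
        for _ in range(n_copies):
            rows.append(proto + rng.normal(0, noise, proto.shape))
            labels.append(k)
    return np.array(rows), np.array(labels)


class TestKmeans:
    def test_exact_copies_recovered(self):
        values, labels = planted_profiles()
        res = kmeans_profiles(values, k=3, seed=5)
        assert adjusted_rand_score(labels, res.assignment) == 1.0

    def test_k1_centroid_is_column_mean(self):
        values, _ = planted_profiles()
        res = kmeans_profiles(values, k=1, seed=0, center=False)
        assert set(res.assignment) == {1}
        assert np.allclose(res.centroids[0], values.mean(axis=0))

    def test_deterministic_given_seed(self):
        values, _ = planted_profiles(noise=0.5)
        a = kmeans_profiles(values, k=3, seed=9).assignment
        b = kmeans_profiles(values, k=3, seed=9).assignment
        assert a.equals(b)

    def test_inertia_not_worse_than_initial_assignment(self):
        values, _ = planted_profiles(noise=1.0, n_copies=5)
        res = kmeans_profiles(values, k=3, seed=2, center=False)
        # objective of the converged solution is a fixed point: one more
        # Lloyd step changes nothing
        again = kmeans_profiles(values, k=3, seed=2, center=False, max_iter=res.n_iter + 5)
        assert again.inertia == pytest.approx(res.inertia)

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_profiles(np.ones((3, 2)), k=4)

    def test_dataframe_index_preserved(self):
        values, _ = planted_profiles()
        df = pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))])
        res = kmeans_profiles(df, k=3, seed=1)
        assert list(res.assignment.index) == list(df.index)


class TestChooseK:
    def test_recovers_planted_k(self):
        values, _ = planted_profiles(n_copies=8, noise=0.3, seed=3)
        best, table = choose_k(values, range(2, 7), seed=0)
        assert best == 3
        assert len(table) == 5
        assert list(table["k"]) == [2, 3, 4, 5, 6]

    def test_tie_prefers_smaller_k(self, monkeypatch):
        import estronet.profiles as mod

        monkeypatch.setattr(mod, "silhouette_score", lambda *a, **k: 0.5)
        values, _ = planted_profiles(n_copies=4)
        best, table = choose_k(values, range(2, 6), seed=0)
        assert best == 2
        assert (table["silhouette"] == 0.5).all()

    def test_degenerate_range_rejected(self):
        values, _ = planted_profiles()
        with pytest.raises(ValueError, match="range"):
            choose_k(values, range(2, 50), seed=0)


class TestPcaSamples:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 30))
        x = np.vstack([x, x[0]])
        scores, _ = pca_samples(x)
        assert np.allclose(scores[0], scores[-1], atol=1e-9)

    def test_explained_variance_fractions(self):
        rng = np.random.default_rng(5)
        _, frac = pca_samples(rng.normal(size=(10, 40)))
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)

    def test_distances_preserved_full_rank(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 20))
        scores, _ = pca_samples(x)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(scores), pdist(x), atol=1e-8)

    def test_tissues_separate_on_synthetic_data(self):
        """Samples cluster by tissue in the leading PCs of the default
        design (the planted tissue-specific baselines and temporal
        signals dominate)."""
        from estronet import SyntheticDesign, simulate_dataset

        expr, _, _ = simulate_dataset(SyntheticDesign(seed=2))
        log_expr = expr.log2_fpkm().T  # samples x genes
        scores, _ = pca_samples(log_expr, n_components=2)
        labels = expr.metadata.set_index("sample_id").loc[log_expr.index, "tissue"]
        assert silhouette_score(scores, labels) > 0.5

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            pca_samples(np.ones((1, 5)))


class TestPamSamples:
    def test_three_planted_groups(self):
        values, labels = planted_profiles(n_copies=6, noise=0.4, seed=8)
        res = pam_samples(values, k=3)
        assert adjusted_rand_score(labels, res.assignment) == 1.0

    def test_k_equals_samples(self):
        values, _ = planted_profiles(n_copies=1)
        res = pam_samples(values, k=3)
        assert sorted(res.assignment) == [1, 2, 3]
        assert res.inertia == pytest.approx(0.0)

    def test_deterministic(self):
        values, _ = planted_profiles(n_copies=5, noise=0.8, seed=10)
        a = pam_samples(values, k=3, seed=1)
        b = pam_samples(values, k=3, seed=1)
        assert a.assignment.equals(b.assignment)
        assert np.allclose(a.centroids, b.centroids)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pam_samples(np.ones((2, 3)), k=5)


def toy_profile_matrix():
    tissues = ("endometrium", "ovary")
    days = (0, 3, 6)
    cols = [condition_label(t, d) for t in tissues for d in days if d != 0]
    rng = np.random.default_rng(12)
    df = pd.DataFrame(
        rng.normal(size=(6, len(cols))),
        index=[f"g{i}" for i in range(6)],
        columns=cols,
    )
    return ProfileMatrix(df, tissues, days)


class TestConditionCorr:
    def test_diagonal_and_symmetry(self):
        prof = toy_profile_matrix()
        corr, flagged = condition_corr_matrix(prof, set(prof.genes))
        assert flagged == []
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T, atol=1e-12)

    def test_gene_order_invariance(self):
        prof = toy_profile_matrix()
        a, _ = condition_corr_matrix(prof, ["g0", "g2", "g4"])
        b, _ = condition_corr_matrix(prof, ["g4", "g0", "g2"])
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_zero_variance_condition_flagged(self):
        prof = toy_profile_matrix()
        prof.data["endometrium:3"] = 2.0  # constant column
        corr, flagged = condition_corr_matrix(prof, set(prof.genes))
        assert flagged == ["endometrium:3"]
        off = corr.loc["endometrium:3"].drop("endometrium:3")
        assert (off == 0).all()
        assert corr.loc["endometrium:3", "endometrium:3"] == 1.0

    def test_too_few_genes_rejected(self):
        prof = toy_profile_matrix()
        with pytest.raises(ValueError, match=">= 3 genes"):
            condition_corr_matrix(prof, ["g0", "g1"])

    def test_ovary_anticorrelated_with_other_tissues(self, small_dataset):
        """Planted bridging genes move oppositely in the ovary versus the
        endometrium and oviduct, so ovary condition columns anticorrelate
        with the other tissues' columns over the core gene set."""
        expr, _, truth = small_dataset
        prof = log2fc_profiles(expr)
        corr, _ = condition_corr_matrix(prof, truth.bridging_genes)
        conds = corr.index
        ovary = [c for c in conds if c.startswith("ovary")]
        other = [c for c in conds if not c.startswith("ovary")]
        cross = corr.loc[ovary, other].to_numpy()
        assert cross.mean() < 0


class TestWaveSummary:
    def test_single_gene_quartiles_collapse(self):
        prof = toy_profile_matrix()
        table = wave_summary(prof, ["g0"])
        for _, row in table.iterrows():
            v = prof.data.loc["g0", condition_label(row["tissue"], row["day"])]
            assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == pytest.approx(v)

    def test_highlight_strictly_above_threshold(self):
        tissues, days = ("ovary",), (0, 3)
        df = pd.DataFrame(
            {"ovary:3": [3.0, 3.01, -3.5]}, index=["a", "b", "c"]
        )
        prof = ProfileMatrix(df, tissues, days)
        table = wave_summary(prof, ["a", "b", "c"], highlight_abs_fc=3.0)
        assert table.loc[0, "n_highlight"] == 2  # 3.0 exactly is excluded

    def test_highlight_counts_peak_mid_cycle(self, small_dataset):
        expr, _, truth = small_dataset
        prof = log2fc_profiles(expr)
        table = wave_summary(prof, truth.structured_genes)
        by_day = table.groupby("day")["n_highlight"].sum()
        assert by_day.idxmax() in (6, 9, 12)

    def test_empty_gene_set_rejected(self):
        prof = toy_profile_matrix()
        with pytest.raises(ValueError, match="empty|disjoint"):
            wave_summary(prof, ["nope"])
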