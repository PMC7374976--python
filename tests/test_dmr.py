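"""Variance components, ranking, mutually exclusive classification and
per-DMR statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdiff import (
    between_group_variance,
    classification_counts,
    classify_dmrs,
    dmr_statistics,
    hierarchical_clustering,
    pca_embedding,
    quantile_normalize,
    rank_bins,
    shuffle_condition_labels,
)
from methdiff.dmr import CutoffPolicy, group_variance_components

from conftest import toy_matrix, toy_samples


class TestBetweenGroupVariance:
    def test_hand_computed_two_group_anova(self):
        # MSB = 1, MSW = 0, n0 = 2 -> component 0.5
        assert between_group_variance([0, 0, 1, 1], ["A", "A", "B", "B"]) == pytest.approx(0.5)

    def test_constant_values_give_zero(self):
        assert between_group_variance([2.0] * 6, ["A"] * 3 + ["B"] * 3) == 0.0

    def test_clamped_when_within_dominates(self):
        # between-group means equal, large within spread -> MSW > MSB -> 0
        values = [0, 10, 5, 0, 10, 5]
        assert between_group_variance(values, ["A", "A", "A", "B", "B", "B"]) == 0.0

    def test_unbalanced_design_matches_scalar_formula(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=7)
        groups = np.array(["A", "A", "B", "B", "B", "C", "C"])
        labels, sizes = np.unique(groups, return_counts=True)
        n, k = len(values), len(labels)
        gmeans = np.array([values[groups == g].mean() for g in labels])
        msb = (sizes * (gmeans - values.mean()) ** 2).sum() / (k - 1)
        msw = sum(((values[groups == g] - gm) ** 2).sum() for g, gm in zip(labels, gmeans)) / (n - k)
        n0 = (n - (sizes**2).sum() / n) / (k - 1)
        expected = max(0.0, (msb - msw) / n0)
        assert between_group_variance(values, groups) == pytest.approx(expected)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            between_group_variance([1, 2, 3], ["A", "A", "A"])

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(20, 6))
        groups = ["A", "B", "C"] * 2
        vec = group_variance_components(values, groups)
        for i in range(20):
            assert vec[i] == pytest.approx(between_group_variance(values[i], groups))


class TestRankBins:
    def test_single_planted_bin_ranks_first(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(50, size=(100, 8)).astype(float)
        samples = toy_samples(4, subtypes=("simple", "ductal", "complex"))
        tumor = (samples["condition"] == "tumor").to_numpy()
        counts[37, tumor] *= 8
        v = rank_bins(toy_matrix(counts, samples=samples))
        assert v.loc[37, "rank_condition"] == 1

    def test_tie_broken_by_genomic_order(self):
        counts = np.array([[10, 10, 20, 20], [10, 10, 20, 20], [10, 10, 10, 10]], dtype=float)
        v = rank_bins(toy_matrix(counts))
        # bins 0 and 1 identical -> earlier position wins
        assert v.loc[0, "rank_condition"] < v.loc[1, "rank_condition"]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(30, size=(50, 6)).astype(float)
        samples = toy_samples(3, subtypes=("simple", "ductal"))
        m = toy_matrix(counts, samples=samples)
        perm = rng.permutation(6)
        m2 = toy_matrix(counts[:, perm], samples=samples.iloc[perm].reset_index(drop=True))
        v1, v2 = rank_bins(m), rank_bins(m2)
        np.testing.assert_array_equal(v1["rank_condition"], v2["rank_condition"])
        np.testing.assert_array_equal(v1["rank_subtype"], v2["rank_subtype"])

    def test_percentiles_are_rank_over_n(self):
        rng = np.random.default_rng(7)
        v = rank_bins(toy_matrix(rng.poisson(30, size=(10, 4)).astype(float)))
        np.testing.assert_allclose(v["pct_condition"], v["rank_condition"] / 10)


def brute_force_classify(v: pd.DataFrame, q: float) -> list[str]:
    """Independent re-statement of the classification rule."""
    n = len(v)
    k = int(np.floor(q * n))
    top_c = set(v.sort_values(["priority_condition", "bin_id"], ascending=[False, True]).head(k)["bin_id"])
    top_s = set(v.sort_values(["priority_subtype", "bin_id"], ascending=[False, True]).head(k)["bin_id"])
    out = []
    for _, r in v.iterrows():
        b = r["bin_id"]
        if b in top_c and b not in top_s:
            out.append("condition")
        elif b in top_s and b not in top_c:
            out.append("subtype")
        elif b in top_c and b in top_s:
            out.append("condition" if r["pct_condition"] <= r["pct_subtype"] else "subtype")
        else:
            out.append("none")
    return out


class TestClassifyDmrs:
    def _random_rank_table(self, rng, n):
        v = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 500,
                "end": (np.arange(n) + 1) * 500,
                "bin_id": np.arange(n),
                "priority_condition": rng.gamma(1, 1, n),
                "priority_subtype": rng.gamma(1, 1, n),
            }
        )
        for name in ("condition", "subtype"):
            order = np.argsort(-v[f"priority_{name}"].to_numpy(), kind="mergesort")
            rank = np.empty(n, dtype=int)
            rank[order] = np.arange(1, n + 1)
            v[f"rank_{name}"] = rank
            v[f"pct_{name}"] = rank / n
        return v

    def test_disjoint_top_sets(self):
        rng = np.random.default_rng(8)
        v = self._random_rank_table(rng, 10)
        v["priority_condition"] = [9, 8, 1, 1, 1, 1, 1, 1, 0.5, 0.4]
        v["priority_subtype"] = [1, 1, 9, 8, 1, 1, 1, 1, 0.5, 0.4]
        for name in ("condition", "subtype"):
            order = np.argsort(-v[f"priority_{name}"].to_numpy(), kind="mergesort")
            rank = np.empty(10, dtype=int)
            rank[order] = np.arange(1, 11)
            v[f"rank_{name}"], v[f"pct_{name}"] = rank, rank / 10
        rec = classify_dmrs(v, 0.2)
        counts = classification_counts(rec)
        assert counts["n_condition"] == 2 and counts["n_subtype"] == 2

    def test_double_selection_resolved_by_percentile(self):
        rng = np.random.default_rng(9)
        v = self._random_rank_table(rng, 20)
        # force bin 0 to rank 1 in both schemes
        v.loc[0, ["priority_condition", "priority_subtype"]] = [100.0, 100.0]
        for name in ("condition", "subtype"):
            order = np.argsort(-v[f"priority_{name}"].to_numpy(), kind="mergesort")
            rank = np.empty(20, dtype=int)
            rank[order] = np.arange(1, 21)
            v[f"rank_{name}"], v[f"pct_{name}"] = rank, rank / 20
        rec = classify_dmrs(v, 0.1)
        assert rec.loc[0, "dmr_class"] == "condition"  # equal pct -> condition

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(10)
        for trial in range(200):
            n = int(rng.integers(10, 60))
            q = float(rng.uniform(0.05, 0.4))
            if int(np.floor(q * n)) < 1:
                continue
            v = self._random_rank_table(rng, n)
            got = classify_dmrs(v, q)["dmr_class"].tolist()
            assert got == brute_force_classify(v, q), f"trial {trial}"

    def test_mutual_exclusivity_bound(self):
        rng = np.random.default_rng(11)
        v = self._random_rank_table(rng, 200)
        rec = classify_dmrs(v, 0.05)
        c = classification_counts(rec)
        assert c["n_dmr_total"] <= 2 * int(np.ceil(0.05 * 200))

    def test_too_small_q_rejected(self):
        rng = np.random.default_rng(12)
        v = self._random_rank_table(rng, 10)
        with pytest.raises(ValueError):
            classify_dmrs(v, 0.05)

    def test_counts_report_arithmetic(self):
        rng = np.random.default_rng(13)
        v = self._random_rank_table(rng, 100)
        c = classification_counts(classify_dmrs(v, 0.1))
        assert c["n_dmr_total"] == c["n_condition"] + c["n_subtype"]
        assert c["n_dmr_total"] + c["n_none"] == c["n_bins"]


class TestDmrStatistics:
    def _records_for(self, m, cls="condition"):
        v = rank_bins(m)
        rec = v.copy()
        rec["dmr_class"] = cls
        rec["cutoff_used"] = 0.05
        return rec

    def test_equal_pairs_give_zero_fc_and_p_one(self):
        counts = np.tile([10.0, 10.0, 20.0, 20.0, 30.0, 30.0, 40.0, 40.0], (3, 1))
        m = toy_matrix(counts, samples=toy_samples(4))
        out = dmr_statistics(m, self._records_for(m))
        assert np.allclose(out["log2fc"], 0)
        assert np.allclose(out["p_value"], 1.0)

    def test_doubled_tumor_gives_log2fc_one_hyper(self):
        samples = toy_samples(4)
        normal = (samples["condition"] == "normal").to_numpy()
        counts = np.full((2, 8), 40.0)
        counts[:, normal] = 20.0
        m = toy_matrix(counts, samples=samples)
        out = dmr_statistics(m, self._records_for(m))
        assert np.allclose(out["log2fc"], 1.0)
        assert (out["direction"] == "hyper").all()

    def test_paired_t_matches_hand_computation(self):
        # pairs (tumor, normal) = (1,2),(1.1,2.2),(0.9,1.9),(1,2.1) on the
        # log2 scale; hand computation: t = -36.3731, p = 4.5704e-5
        tumor = np.array([1.0, 1.1, 0.9, 1.0])
        normal = np.array([2.0, 2.2, 1.9, 2.1])
        counts = np.empty((1, 8))
        samples = toy_samples(4)
        t_cols = np.flatnonzero((samples["condition"] == "tumor").to_numpy())
        n_cols = np.flatnonzero((samples["condition"] == "normal").to_numpy())
        counts[0, t_cols] = 2.0**tumor - 1  # so log2(count+1) recovers the values
        counts[0, n_cols] = 2.0**normal - 1
        m = toy_matrix(counts, samples=samples)
        out = dmr_statistics(m, self._records_for(m))
        assert out.loc[0, "p_value"] == pytest.approx(4.57036081408e-05, rel=1e-6)

    def test_few_pairs_warns_and_sets_missing(self):
        m = toy_matrix(np.array([[10.0, 12.0, 20.0, 25.0]]))  # 2 pairs
        with pytest.warns(UserWarning, match="pairs"):
            out = dmr_statistics(m, self._records_for(m))
        assert np.isnan(out.loc[0, "p_value"])

    def test_subtype_contrast_picks_extreme_subtype(self):
        samples = toy_samples(6, subtypes=("simple", "ductal", "complex"))
        counts = np.full((1, 12), 20.0)
        ductal = (samples["subtype"] == "ductal").to_numpy()
        counts[0, ductal] = 80.0
        m = toy_matrix(counts, samples=samples)
        out = dmr_statistics(m, self._records_for(m, cls="subtype"))
        assert out.loc[0, "extreme_subtype"] == "ductal"
        assert out.loc[0, "direction"] == "hyper"
        assert out.loc[0, "log2fc"] == pytest.approx(2.0)


class TestEmbeddings:
    def _planted_matrix(self, effect=6.0, n_bins=60, seed=20):
        rng = np.random.default_rng(seed)
        samples = toy_samples(6, subtypes=("simple", "ductal", "complex"))
        counts = rng.poisson(50, size=(n_bins, 12)).astype(float)
        tumor = (samples["condition"] == "tumor").to_numpy()
        counts[: n_bins // 2, tumor] *= effect
        m = toy_matrix(counts, samples=samples)
        rec = rank_bins(m)
        rec["dmr_class"] = np.where(rec["bin_id"] < n_bins // 2, "condition", "none")
        return m, rec, tumor

    def test_pca_separates_conditions(self):
        from sklearn.metrics import silhouette_score

        m, rec, tumor = self._planted_matrix()
        coords, evr = pca_embedding(m, rec, "condition")
        assert evr[0] >= evr[-1] and evr.sum() <= 1.0 + 1e-9
        labels = np.where(tumor, 1, 0)
        assert silhouette_score(coords.to_numpy(), labels) > 0

    def test_pca_sign_consistent_two_cluster_geometry(self):
        m, rec, tumor = self._planted_matrix()
        coords, _ = pca_embedding(m, rec, "condition")
        pc1 = coords["PC1"].to_numpy()
        assert len({np.sign(x) for x in pc1[tumor]}) == 1
        assert np.sign(pc1[tumor][0]) != np.sign(pc1[~tumor][0])

    def test_clustering_bipartition_matches_condition(self):
        from scipy.cluster.hierarchy import fcluster
        from sklearn.metrics import adjusted_rand_score

        m, rec, tumor = self._planted_matrix()
        res = hierarchical_clustering(m, rec, "condition")
        assert len(res["leaf_order"]) == m.n_samples
        two = fcluster(res["linkage"], 2, criterion="maxclust")
        assert adjusted_rand_score(two, tumor.astype(int)) == 1.0

    def test_duplicate_samples_merge_first_at_zero_height(self):
        samples = toy_samples(2)
        counts = np.array([[10.0, 10.0, 40.0, 20.0], [30.0, 30.0, 10.0, 50.0]])
        m = toy_matrix(counts, samples=samples)
        rec = rank_bins(m)
        rec["dmr_class"] = "condition"
        res = hierarchical_clustering(m, rec, "condition")
        first = res["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)
        assert res["newick"].count("P0") == 4


class TestNullCalibration:
    def test_balanced_shuffle_recovery_at_chance(self, small_dataset):
        from methdiff import filter_bins

        genome, matrix, truth = small_dataset
        fm = quantile_normalize(filter_bins(matrix, require_cg=False).matrix)
        cmt = truth.cmt_dmr_bins
        rng = np.random.default_rng(42)
        rates = []
        for _ in range(3):
            shuffled = dataclasses.replace(fm, samples=shuffle_condition_labels(fm.samples, rng))
            rec = classify_dmrs(rank_bins(shuffled), 0.05)
            key = dict(zip(zip(shuffled.bins["chrom"], shuffled.bins["start"]), rec["dmr_class"]))
            got = np.array([key.get((c, s), "absent") for c, s in zip(cmt["chrom"], cmt["start"])])
            rates.append(float((got == "condition").mean()))
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(cmt))
        assert np.mean(rates) <= bound
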