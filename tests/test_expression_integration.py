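import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

import octomethyl as om
from octomethyl import expression_integration as ei


def toy_tpm(values, samples=("a", "b")):
    return pd.DataFrame(
        values,
        index=pd.Index([f"t{i}" for i in range(len(values))], name="transcript_id"),
        columns=list(samples),
    )


class TestExpressedSet:
    def test_all_zero_empty(self):
        assert ei.expressed_set(toy_tpm([[0, 0], [0, 0]])) == set()

    def test_tiny_expression_included(self):
        assert ei.expressed_set(toy_tpm([[0.01, 0], [0, 0]])) == {"t0"}

    def test_partition(self):
        tpm = toy_tpm([[0, 0], [1, 0], [0, 2], [3, 4]])
        expressed = ei.expressed_set(tpm)
        assert len(expressed) + len(set(tpm.index) - expressed) == len(tpm)


class TestLogTransform:
    def test_monotone_and_invertible(self):
        tpm = toy_tpm([[0, 1], [10, 100], [2.5, 7]])
        e = ei.log_expression(tpm)
        assert (e.to_numpy() >= 0).all()
        assert ((e.to_numpy() == 0) == (tpm.to_numpy() == 0)).all()
        back = np.exp2(e) - 1
        assert np.allclose(back.to_numpy(), tpm.to_numpy(), atol=1e-9)


class TestPercentileCurve:
    def means(self, n, meth):
        return pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(n)], "body_mean": meth,
             "n_cpgs_body": 1}
        )

    def test_flat_methylation_gives_flat_curve(self):
        n = 50
        expr = pd.Series(np.linspace(0, 8, n), index=[f"t{i}" for i in range(n)])
        curve = ei.percentile_methylation_curve(expr, self.means(n, 42.0), n_groups=10)
        assert np.allclose(curve["mean_methylation"], 42.0)

    def test_group_sizes_differ_by_at_most_one(self):
        n = 103
        expr = pd.Series(np.arange(n, dtype=float), index=[f"t{i}" for i in range(n)])
        curve = ei.percentile_methylation_curve(expr, self.means(n, 1.0), n_groups=10)
        assert curve["n"].max() - curve["n"].min() <= 1
        assert curve["n"].sum() == n and len(curve) == 10

    def test_too_few_transcripts_rejected(self):
        expr = pd.Series([1.0, 2.0], index=["t0", "t1"])
        with pytest.raises(ValueError, match="n_groups"):
            ei.percentile_methylation_curve(expr, self.means(2, 1.0), n_groups=10)

    def test_coupled_data_gives_monotone_curve(self, study):
        loge = ei.log_expression(study["tpm"])
        curve = ei.percentile_methylation_curve(
            loge.iloc[:, 0], study["means"], n_groups=100
        )
        mid = curve[(curve.mean_expression >= 1.5) & (curve.mean_expression <= 4.5)]
        rho = spearmanr(mid["percentile"], mid["mean_methylation"]).statistic
        assert rho > 0.8


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        vals = np.tile(np.arange(10.0), 3)
        labels = np.repeat([1, 2, 3], 10)
        table = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(30)], "mp_label": labels}
        )
        expr = pd.Series(vals, index=table["transcript_id"])
        res = ei.mp_expression_test(expr, table)
        assert res["kw_h"] == pytest.approx(0.0, abs=1e-9)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(3, 1, 200)
        table = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(400)],
             "mp_label": np.repeat([1, 2], 200)}
        )
        expr = pd.Series(np.concatenate([a, b]), index=table["transcript_id"])
        res = ei.mp_expression_test(expr, table)
        assert res["pairwise"]["padj"].iloc[0] < 0.001

    def test_kw_matches_permutation_oracle(self):
        """The chi-square KW p agrees with a permutation p on small data."""
        from scipy.stats import kruskal

        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 10), rng.normal(0.8, 1, 10), rng.normal(0.3, 1, 10)]
        h_obs, p_chi2 = kruskal(*groups)
        pooled = np.concatenate(groups)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            h, _ = kruskal(perm[:10], perm[10:20], perm[20:])
            if h >= h_obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_perm - p_chi2) < 0.05

    def test_small_pattern_excluded_with_warning(self):
        table = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(21)],
             "mp_label": [1] * 10 + [2] * 10 + [3]}
        )
        expr = pd.Series(np.arange(21.0), index=table["transcript_id"])
        with pytest.warns(UserWarning):
            res = ei.mp_expression_test(expr, table)
        assert set(res["per_group"]["mp_label"]) == {1, 2}

    def test_pattern_expression_ordering(self, study):
        """High-methylation patterns are expressed above the unmethylated one."""
        loge = ei.log_expression(study["tpm"])
        table = study["assignment"].table
        for col in loge.columns:
            res = ei.mp_expression_test(loge[col], table)
            med = res["per_group"].set_index("mp_label")["median"]
            assert med[1] > med[4] and med[2] > med[4]


class TestZscoreCluster:
    def test_z_rows_normalized(self):
        rng = np.random.default_rng(1)
        tpm = toy_tpm(rng.uniform(0, 50, (30, 5)), samples=list("abcde"))
        z = ei.zscore_rows(ei.log_expression(tpm))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_identical_profiles_cluster_together(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 20, (10, 4))
        values = np.vstack([base, base[0]])  # row 10 duplicates row 0
        tpm = toy_tpm(values, samples=list("abcd"))
        labels, _ = ei.zscore_cluster(tpm, k=3)
        assert labels.loc["t0"] == labels.loc["t10"]

    def test_pairwise_distances_match_brute_force(self):
        rng = np.random.default_rng(3)
        tpm = toy_tpm(rng.uniform(0, 40, (20, 6)), samples=list("abcdef"))
        z = ei.zscore_rows(ei.log_expression(tpm)).to_numpy()
        fast = pdist(z, metric="euclidean")
        brute = [
            np.sqrt(((z[i] - z[j]) ** 2).sum())
            for i in range(len(z))
            for j in range(i + 1, len(z))
        ]
        assert np.allclose(fast, brute, atol=1e-9)

    def test_too_many_clusters_rejected(self):
        tpm = toy_tpm([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            ei.zscore_cluster(tpm, k=5)


class TestTopnOverlap:
    def test_identical_samples(self):
        rng = np.random.default_rng(4)
        tpm = toy_tpm(np.repeat(rng.uniform(1, 9, (50, 1)), 2, axis=1))
        res = ei.topn_overlap(tpm, n=10)
        assert len(res["union"]) == 10
        assert res["per_sample"]["a"] == res["per_sample"]["b"]

    def test_disjoint_top_sets(self):
        vals = np.zeros((30, 3))
        vals[:10, 0] = 5
        vals[10:20, 1] = 5
        vals[20:, 2] = 5
        res = ei.topn_overlap(toy_tpm(vals, samples=list("abc")), n=10)
        assert len(res["union"]) == 30

    def test_membership_counts_sum_to_union(self):
        rng = np.random.default_rng(5)
        tpm = toy_tpm(rng.uniform(0, 10, (60, 3)), samples=list("abc"))
        res = ei.topn_overlap(tpm, n=20)
        assert res["counts"]["n_transcripts"].sum() == len(res["union"])


class TestGoEnrichment:
    def test_exact_hypergeometric_value(self):
        """All four drawn genes carry the term: p = C(5,4)/C(10,4) = 5/210."""
        universe = {f"g{i}" for i in range(10)}
        term = {"T": {f"g{i}" for i in range(5)}}
        res = ei.go_enrichment({"g0", "g1", "g2", "g3"}, universe, term)
        assert res["p"].iloc[0] == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        term = {"T": {"g8", "g9"}}
        res = ei.go_enrichment({"g0", "g1"}, universe, term)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_bh_adjustment_matches_hand_computation(self):
        """padj follows the step-up rule: min over j>=i of p_(j)*m/j, capped at 1."""
        universe = {f"g{i}" for i in range(12)}
        terms = {
            "T1": {"g0", "g1", "g2"},
            "T2": {"g0", "g3", "g4", "g5"},
            "T3": {"g6", "g7"},
        }
        res = ei.go_enrichment({"g0", "g1", "g6"}, universe, terms)
        p = res["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            hand[order[rank]] = running
        assert np.allclose(res["padj"], hand, atol=1e-12)

    def test_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="zz"):
            ei.go_enrichment({"zz"}, {"g1"}, {"T": {"g1"}})

    def test_biased_terms_detected_on_synthetic(self, study):
        mapping = om.simulate_go_terms(study["ds"], seed=2)
        universe = set().union(*mapping.values())
        mp1 = set(
            study["ds"].genes.loc[study["ds"].genes.archetype == 1, "transcript_id"]
        ) & universe
        res = ei.go_enrichment(mp1, universe, mapping)
        assert res["significant"].any()
        assert (res["padj"] >= res["p"] - 1e-12).all()
        assert ((res["k_obs"] <= np.minimum(res["n_list"], res["K_universe"]))).all()
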