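"""PAM clustering, silhouettes, k-scan, heat-map normalization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regencycle.clustering import (
    heatmap_gene_order,
    normalize_for_heatmap,
    pam,
    profile_dissimilarity,
    scan_k,
    silhouette,
)


def random_dissimilarity(rng, n):
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0)
    return d


def brute_force_cost(d, k):
    n = d.shape[0]
    return min(d[:, list(c)].min(axis=1).sum()
               for c in itertools.combinations(range(n), k))


class TestProfileDissimilarity:
    def test_identical_profiles_zero(self):
        p = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        d = profile_dissimilarity(p)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_anticorrelated_profiles_two(self):
        p = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"])
        assert profile_dissimilarity(p).loc["a", "b"] == pytest.approx(2.0)

    def test_symmetry_property(self):
        rng = np.random.default_rng(2)
        p = pd.DataFrame(rng.normal(size=(15, 8)))
        d = profile_dissimilarity(p).to_numpy()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0)
        assert (d >= 0).all()

    def test_zero_variance_profile_warned_d_one(self):
        p = pd.DataFrame([[5, 5, 5], [1, 2, 3]], index=["flat", "var"])
        with pytest.warns(UserWarning, match="zero-variance"):
            d = profile_dissimilarity(p)
        assert d.loc["flat", "var"] == 1.0

    def test_euclidean_variant(self):
        p = pd.DataFrame([[0, 1, 2], [0, 2, 4]], index=["a", "b"])
        # z-scored profiles are identical → distance 0
        assert profile_dissimilarity(p, metric="euclidean").loc["a", "b"] == \
            pytest.approx(0.0)


class TestPam:
    def test_k_equals_n_cost_zero(self):
        d = random_dissimilarity(np.random.default_rng(0), 6)
        res = pam(d, 6)
        assert res.cost == 0
        assert set(res.medoid_indices) == set(range(6))

    def test_k_above_n_rejected(self):
        d = random_dissimilarity(np.random.default_rng(0), 5)
        with pytest.raises(ValueError):
            pam(d, 6)

    def test_two_separated_triplets(self):
        # 6 items, two tight far-apart triplets: exhaustive over C(6,2) pairs
        pts = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pam(d, 2)
        assert res.cost == pytest.approx(brute_force_cost(d, 2))
        groups = [frozenset(np.flatnonzero(res.labels == c)) for c in range(2)]
        assert set(groups) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_matches_exhaustive_on_most_random_instances(self):
        # PAM is a local search: it reaches the brute-force optimum on the
        # large majority of tiny random instances and never goes below it
        rng = np.random.default_rng(3)
        optimal = 0
        total = 40
        for _ in range(total):
            n = int(rng.integers(5, 13))
            k = int(rng.integers(1, 4))
            d = random_dissimilarity(rng, n)
            res = pam(d, k)
            best = brute_force_cost(d, k)
            assert res.cost >= best - 1e-9
            optimal += np.isclose(res.cost, best, atol=1e-9)
        assert optimal >= 0.8 * total

    def test_deterministic(self):
        d = random_dissimilarity(np.random.default_rng(5), 20)
        a, b = pam(d, 4), pam(d, 4)
        np.testing.assert_array_equal(a.medoid_indices, b.medoid_indices)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_medoids_assigned_to_own_cluster_and_cost_consistent(self):
        d = random_dissimilarity(np.random.default_rng(6), 25)
        res = pam(d, 5)
        for c, m in enumerate(res.medoid_indices):
            assert res.labels[m] == c
        implied = sum(d[i, res.medoid_indices[res.labels[i]]] for i in range(25))
        assert res.cost == pytest.approx(implied)

    def test_rejects_asymmetric_matrix(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pam(d, 1)

    def test_matches_reference_r_implementation(self, tmp_path):
        # dual-route check: our BUILD+SWAP reaches the same total cost as
        # the canonical R implementation (cluster::pam, swap phase) on
        # random instances, including any shared local optima
        import subprocess

        rng = np.random.default_rng(11)
        instances = [(random_dissimilarity(rng, int(rng.integers(6, 13))),
                      int(rng.integers(2, 4))) for _ in range(4)]
        script_lines = ["suppressMessages(library(cluster))"]
        for i, (d, k) in enumerate(instances):
            np.savetxt(tmp_path / f"d{i}.txt", d)
            script_lines.append(
                f'd <- as.matrix(read.table("{tmp_path}/d{i}.txt"));'
                f'p <- pam(as.dist(d), {k}, diss=TRUE);'
                f'cat(sprintf("%.12f\\n", p$objective["swap"] * nrow(d)))'
            )
        r = subprocess.run(["Rscript", "-e", "\n".join(script_lines)],
                           capture_output=True, text=True, timeout=120)
        assert r.returncode == 0, r.stderr
        ref_costs = [float(x) for x in r.stdout.split()]
        for (d, k), ref in zip(instances, ref_costs):
            assert pam(d, k).cost == pytest.approx(ref, abs=1e-8)


class TestSilhouette:
    def test_equidistant_item_scores_zero(self):
        # item 2 sits exactly between two pairs: a == b → s == 0
        d = np.array([
            [0, 1, 2, 9, 9],
            [1, 0, 2, 9, 9],
            [2, 2, 0, 2, 2],
            [9, 9, 2, 0, 1],
            [9, 9, 2, 1, 0],
        ], dtype=float)
        res = pam(d, 2)
        s = silhouette(res, d)
        mid = s["s"].iloc[2]
        assert mid == pytest.approx(0.0)

    def test_tight_far_clusters_approach_one(self):
        pts = np.array([0.0, 0.01, 0.02, 100.0, 100.01, 100.02])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pam(d, 2)
        assert silhouette(res, d)["s"].min() > 0.99

    def test_hand_computed_n4(self):
        # clusters {0,1} and {2,3}: d(0,1)=2, d(2,3)=2, cross distances 10
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 2.0
        d[2, 3] = d[3, 2] = 2.0
        res = pam(d, 2)
        s = silhouette(res, d)["s"]
        # a=2, b=10 for every item: s = (10-2)/10 = 0.8
        np.testing.assert_allclose(s, 0.8)

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(8)
        d = random_dissimilarity(rng, 30)
        res = pam(d, 4)
        s = silhouette(res, d)["s"]
        assert ((s >= -1) & (s <= 1)).all()

    def test_matches_sklearn_on_random_instance(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(9)
        d = random_dissimilarity(rng, 40)
        res = pam(d, 5)
        ours = silhouette(res, d)["s"].to_numpy()
        ref = silhouette_samples(d, res.labels, metric="precomputed")
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_medoid_variant_medoid_scores_one(self):
        pts = np.array([0.0, 0.5, 1.0, 10.0, 10.5, 11.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pam(d, 2)
        s = silhouette(res, d, variant="medoid")
        assert all(s["s"].iloc[m] == 1.0 for m in res.medoid_indices)

    def test_k1_error(self):
        d = random_dissimilarity(np.random.default_rng(1), 5)
        res = pam(d, 1)
        with pytest.raises(ValueError, match="silhouette undefined"):
            silhouette(res, d)


@pytest.fixture(scope="module")
def three_archetype_profiles():
    rng = np.random.default_rng(12)
    t = np.linspace(0, 1, 10)
    shapes = [np.sin(np.pi * t), t, 1 - t]
    rows, labels = [], []
    for c, shape in enumerate(shapes):
        for _ in range(20):
            rows.append(2 * shape + rng.normal(0, 0.1, t.size))
            labels.append(c)
    return pd.DataFrame(rows), np.array(labels)


class TestScanK:
    def test_recovers_planted_k(self, three_archetype_profiles):
        prof, truth = three_archetype_profiles
        d = profile_dissimilarity(prof)
        table, chosen, results = scan_k(d, range(2, 8))
        assert chosen == 3
        avg = table.set_index("k")["average_silhouette"]
        assert avg[3] > avg[2] and avg[3] > avg[4]

    def test_deterministic_across_runs(self, three_archetype_profiles):
        prof, _ = three_archetype_profiles
        d = profile_dissimilarity(prof)
        t1, c1, _ = scan_k(d, range(2, 6))
        t2, c2, _ = scan_k(d, range(2, 6))
        pd.testing.assert_frame_equal(t1, t2)
        assert c1 == c2

    def test_override_k(self, three_archetype_profiles):
        prof, _ = three_archetype_profiles
        d = profile_dissimilarity(prof)
        _, chosen, _ = scan_k(d, range(2, 6), chosen_k=5)
        assert chosen == 5


class TestHeatmapNormalization:
    def test_min_max_scaling(self):
        p = pd.DataFrame([[2.0, 4.0, 6.0]], index=["g"])
        np.testing.assert_allclose(normalize_for_heatmap(p).iloc[0], [0, 0.5, 1])

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        p = pd.DataFrame(rng.normal(size=(5, 7)))
        a = normalize_for_heatmap(p)
        b = normalize_for_heatmap(3.2 * p + 11.0)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_profile_half_with_warning(self):
        p = pd.DataFrame([[3.0, 3.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_for_heatmap(p)
        assert (out.iloc[0] == 0.5).all()

    def test_medoid_first_in_cluster_block(self):
        pts = np.array([0.0, 0.5, 1.0, 10.0, 10.5, 11.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pam(d, 2)
        order = heatmap_gene_order(res, d)
        # first element of each block is that cluster's medoid
        blocks = [order[:3], order[3:]]
        for block in blocks:
            c = res.labels[block[0]]
            assert block[0] == res.medoid_indices[c]
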