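"""Ward linkage, tree cutting, gap selection and ARI tests.

The linkage is checked against a naive O(n^3) oracle that recomputes every
pairwise Ward criterion from the raw coordinates at each agglomeration
step (no Lance-Williams update), and against SciPy on tie-free data.
"""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from phenoresp.cluster import (
    Dendrogram,
    adjusted_rand_index,
    cut_tree,
    dendrogram_to_newick,
    distance_matrix,
    select_k_by_gap,
    ward_linkage,
)


def naive_ward(points):
    """Brute-force Ward agglomeration from raw coordinates.

    Maintains explicit member lists; at each step evaluates
    sqrt(2 |A||B| / (|A|+|B|) * ||mean(A) - mean(B)||^2) for every active
    pair from scratch and merges the minimum, breaking ties by the smallest
    (left, right) node-id pair.  Independent of the Lance-Williams route.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}  # node id -> member leaf list
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma, mb = points[clusters[a]].mean(0), points[clusters[b]].mean(0)
            na, nb = len(clusters[a]), len(clusters[b])
            d = np.sqrt(2 * na * nb / (na + nb) * ((ma - mb) ** 2).sum())
            if best is None or d < best[0] - 1e-12 or (
                    abs(d - best[0]) <= 1e-12 and (a, b) < best[1:3]):
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return Dendrogram(n_leaves=n, merges=merges)


class TestDistanceMatrix:
    def test_closed_forms(self):
        rows = np.array([[1] * 12, [1] * 12, [3] * 12, [1] * 11 + [2]])
        d = distance_matrix(rows)
        assert d[0, 1] == 0.0
        assert d[0, 2] == pytest.approx(np.sqrt(48))
        assert d[0, 3] == pytest.approx(1.0)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_rejects_missing(self):
        with pytest.raises(ValueError, match="missing"):
            distance_matrix(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestWardLinkage:
    def test_three_point_closed_form(self):
        """1-D points {0, 1, 10}: merge (0,1) at 1, then at 9.5*sqrt(4/3)."""
        pts = np.array([[0.0], [1.0], [10.0]])
        dend = ward_linkage(distance_matrix(pts))
        (a0, b0, h0, s0), (a1, b1, h1, s1) = dend.merges
        assert (a0, b0, s0) == (0, 1, 2)
        assert h0 == pytest.approx(1.0)
        assert s1 == 3
        assert h1 == pytest.approx(9.5 * np.sqrt(4 / 3))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_oracle_on_coded_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        pts = rng.integers(1, 4, size=(n, 12)).astype(float)
        dend = ward_linkage(distance_matrix(pts))
        oracle = naive_ward(pts)
        for got, want in zip(dend.merges, oracle.merges):
            assert got[0] == want[0] and got[1] == want[1]
            assert got[2] == pytest.approx(want[2], abs=1e-9)
            assert got[3] == want[3]

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(30, 5))
        dend = ward_linkage(distance_matrix(pts))
        z = scipy_linkage(pts, method="ward")
        assert np.allclose(dend.to_linkage()[:, 2], z[:, 2], atol=1e-8)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        pts = rng.integers(1, 4, size=(40, 12)).astype(float)
        heights = ward_linkage(distance_matrix(pts)).heights
        assert np.all(np.diff(heights) >= -1e-12)

    def test_merged_sizes_conserved(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 3))
        dend = ward_linkage(distance_matrix(pts))
        assert dend.merges[-1][3] == 15

    def test_rejects_single_row(self):
        with pytest.raises(ValueError):
            ward_linkage(np.zeros((1, 1)))

    def test_permutation_invariance(self):
        """Shuffling input rows yields the same partition at every k.

        Stated for tie-free data: when two merges are exactly tied the
        partition itself is ambiguous and the deterministic node-id
        tie-break resolves it in input order.
        """
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(25, 6))
        names = [f"P{i}" for i in range(25)]
        dend = ward_linkage(distance_matrix(pts), leaf_names=names)
        perm = rng.permutation(25)
        dend_p = ward_linkage(distance_matrix(pts[perm]),
                              leaf_names=[names[i] for i in perm])
        for k in (2, 3, 5):
            a = cut_tree(dend, k).labels
            b = cut_tree(dend_p, k).labels
            assert adjusted_rand_index(a, b) == pytest.approx(1.0)


class TestCutTree:
    @pytest.fixture()
    def small_dend(self):
        pts = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [10.0]])
        return ward_linkage(distance_matrix(pts), leaf_names=list("abcdef"))

    def test_k_extremes(self, small_dend):
        singles = cut_tree(small_dend, 6)
        assert sorted(singles.sizes().values()) == [1] * 6
        one = cut_tree(small_dend, 1)
        assert one.sizes() == {1: 6}

    def test_labels_ordered_by_size(self, small_dend):
        assignment = cut_tree(small_dend, 3)
        assert assignment.labels["a"] == 1  # largest cluster (a,b,c)
        assert assignment.labels["d"] == 2
        assert assignment.labels["f"] == 3

    def test_k_out_of_range(self, small_dend):
        with pytest.raises(ValueError):
            cut_tree(small_dend, 0)
        with pytest.raises(ValueError):
            cut_tree(small_dend, 7)


class TestSelectK:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (20, 2)),
                         rng.normal(10, 0.1, (20, 2))])
        dend = ward_linkage(distance_matrix(pts))
        assert select_k_by_gap(dend, 8) == 2

    def test_equally_spaced_heights_tie_to_two(self):
        # synthetic dendrogram with heights 1, 2, ..., n-1
        merges = [(0, 1, 1.0, 2)]
        for step in range(1, 5):
            merges.append((step + 1, 5 + step, float(step + 1), step + 2))
        dend = Dendrogram(n_leaves=6, merges=merges)
        assert select_k_by_gap(dend, 5) == 2

    def test_relative_criterion_available(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (15, 2)),
                         rng.normal(10, 0.1, (15, 2))])
        dend = ward_linkage(distance_matrix(pts))
        assert select_k_by_gap(dend, 8, criterion="relative") == 2

    def test_rejects_bad_kmax(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        dend = ward_linkage(distance_matrix(pts))
        with pytest.raises(ValueError):
            select_k_by_gap(dend, 1)


class TestARI:
    def test_identical_partitions(self):
        a = {i: i % 3 for i in range(12)}
        assert adjusted_rand_index(a, dict(a)) == pytest.approx(1.0)

    def test_relabelled_partition(self):
        a = {i: i % 3 for i in range(12)}
        b = {i: (v + 1) % 3 for i, v in a.items()}
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_singletons_vs_one_cluster_is_chance(self):
        a = {i: i for i in range(6)}
        b = {i: 0 for i in range(6)}
        assert adjusted_rand_index(a, b) == pytest.approx(0.0)

    def test_brute_force_pair_counting(self):
        """Six-element example checked against direct pair enumeration."""
        a = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 2}
        b = {0: 0, 1: 0, 2: 1, 3: 1, 4: 1, 5: 2}
        same_a = {(i, j) for i, j in itertools.combinations(range(6), 2)
                  if a[i] == a[j]}
        same_b = {(i, j) for i, j in itertools.combinations(range(6), 2)
                  if b[i] == b[j]}
        n_pairs = 15
        n11 = len(same_a & same_b)
        expected = len(same_a) * len(same_b) / n_pairs
        max_index = (len(same_a) + len(same_b)) / 2
        want = (n11 - expected) / (max_index - expected)
        assert adjusted_rand_index(a, b) == pytest.approx(want)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(5)
        a = {i: int(v) for i, v in enumerate(rng.integers(0, 4, 50))}
        b = {i: int(v) for i, v in enumerate(rng.integers(0, 3, 50))}
        want = adjusted_rand_score([a[i] for i in range(50)],
                                   [b[i] for i in range(50)])
        assert adjusted_rand_index(a, b) == pytest.approx(want)

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index({1: 0}, {2: 0})


class TestNewick:
    def test_branch_lengths_and_leaves(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        dend = ward_linkage(distance_matrix(pts), leaf_names=["x", "y", "z"])
        nwk = dendrogram_to_newick(dend)
        assert nwk.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in nwk
        # first merge at height 1: both leaves get branch length 1
        assert "x:1" in nwk and "y:1" in nwk


class TestRecovery:
    def test_planted_partition_recovered_exactly_at_noise_zero(self, complete_cohort):
        """Ward + k=4 cut on the noise-free default cohort recovers the
        planted archetypes perfectly (ARI 1.0, exact sizes)."""
        _, result = complete_cohort
        from test_synthetic import classify_cohort
        matrix, _ = classify_cohort(result)
        dend = ward_linkage(distance_matrix(matrix), leaf_names=matrix.patient_ids)
        assignment = cut_tree(dend, 4)
        truth = result["truth"].set_index("patient_id")["archetype"].to_dict()
        ari = adjusted_rand_index(assignment.labels,
                                  {p: truth[p] for p in assignment.labels})
        assert ari == pytest.approx(1.0)
        assert sorted(assignment.sizes().values()) == [58, 64, 87, 138]

    def test_recovery_degrades_with_noise(self):
        """ARI is 1 at noise 0 and decreases as categories are resampled."""
        from test_synthetic import classify_cohort
        from phenoresp.synthetic import SimulationConfig, simulate_cohort
        aris = []
        for noise in (0.0, 0.1, 0.4):
            config = SimulationConfig(n_enrolled=347, missing_rate=0.0,
                                      noise_rate=noise, seed=13)
            result = simulate_cohort(config)
            matrix, _ = classify_cohort(result)
            dend = ward_linkage(distance_matrix(matrix),
                                leaf_names=matrix.patient_ids)
            assignment = cut_tree(dend, 4)
            truth = result["truth"].set_index("patient_id")["archetype"].to_dict()
            aris.append(adjusted_rand_index(
                assignment.labels, {p: truth[p] for p in assignment.labels}))
        assert aris[0] == pytest.approx(1.0)
        assert aris[0] > aris[1] > aris[2]
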