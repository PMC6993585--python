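"""Edge clustering, validity scan, group relabeling, reproducibility."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nirsdyn.clustering import (
    ClusterSolution,
    elbow_k,
    kmeans_edges,
    match_atlases,
    ratio_a,
    relabel_group,
    reproducibility_split,
    validity_scan,
)


def planted_matrix(rng, n_per=20, k=2, sep=10.0, t=40):
    """Edge time courses in k well-separated groups."""
    centers = rng.standard_normal((k, t)) * sep
    X = np.vstack([centers[g] + rng.standard_normal((n_per, t)) for g in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestKMeans:
    def test_k1_degenerate(self, rng):
        X, _ = planted_matrix(rng)
        sol = kmeans_edges(X, k=1)
        assert np.all(sol.labels == 0)
        assert np.isnan(sol.ratio_a)

    def test_planted_groups_recovered_exactly(self, rng):
        X, truth = planted_matrix(rng, sep=10.0)
        sol = kmeans_edges(X, k=2, restarts=10, seed=0)
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_best_of_restarts_no_worse_than_single_run(self, rng):
        X, _ = planted_matrix(rng, k=4, sep=1.0)
        multi = kmeans_edges(X, k=4, restarts=20, seed=0)
        singles = [kmeans_edges(X, k=4, restarts=1, seed=s).inertia for s in range(5)]
        assert multi.inertia <= min(singles) + 1e-9

    def test_centroids_are_member_means(self, rng):
        X, _ = planted_matrix(rng)
        sol = kmeans_edges(X, k=2, restarts=5, seed=1)
        for c in range(2):
            assert np.allclose(sol.centroids[c], X[sol.labels == c].mean(0))

    def test_ratio_a_formula(self, rng):
        X, _ = planted_matrix(rng, k=3, n_per=10)
        sol = kmeans_edges(X, k=3, restarts=5, seed=2)
        # independent recomputation
        cents = sol.centroids
        iu = np.triu_indices(3, 1)
        between = np.mean(
            [np.linalg.norm(cents[i] - cents[j]) for i, j in zip(*iu)]
        )
        within = np.mean(np.linalg.norm(X - cents[sol.labels], axis=1))
        assert sol.ratio_a == pytest.approx(between / within)

    def test_k_exceeding_edges_rejected(self, rng):
        X, _ = planted_matrix(rng, n_per=2)
        with pytest.raises(ValueError):
            kmeans_edges(X, k=10)


class TestValidityScan:
    def test_identical_subjects_have_zero_validity(self, rng):
        # k restricted to at most the true structure so best-of-restarts
        # reaches the same (data-determined) optimum for every subject;
        # beyond the true k, near-tied noise splits differ per restart
        # stream and identical data need not give identical solutions
        X, _ = planted_matrix(rng, k=3, n_per=15)
        scan = validity_scan([X, X.copy(), X.copy()], k_range=range(2, 4),
                             restarts=60, seed=0)
        assert np.allclose(scan.sd_a, 0.0, atol=1e-12)
        assert np.allclose(scan.validity, 0.0, atol=1e-12)

    def test_validity_is_sd_over_mean_of_stored_a(self, rng):
        subjects = [planted_matrix(rng, k=3, n_per=12, sep=2.0)[0] for _ in range(4)]
        scan = validity_scan(subjects, k_range=range(2, 5), restarts=5, seed=0)
        for i in range(len(scan.k_values)):
            a = scan.a_values[i]
            assert scan.validity[i] == pytest.approx(a.std(ddof=1) / a.mean())

    def test_elbow_maximum_curvature_tie_to_smaller_k(self):
        ks = np.arange(2, 8)
        v = np.array([0.01, 0.012, 0.05, 0.09, 0.13, 0.17])
        # curvature maximal at k=3 (bend before linear rise)
        assert elbow_k(ks, v) == 3
        v_tie = np.array([0.0, 0.0, 0.1, 0.2, 0.4, 0.6])
        # curvatures at k=3 and k=6 both 0.1 -> smaller k wins
        assert elbow_k(ks, v_tie) == 3


def _solution(labels, k):
    labels = np.asarray(labels)
    X = np.eye(k)[labels]  # dummy centroid source
    cents = np.stack([X[labels == c].mean(0) if np.any(labels == c) else np.zeros(k)
                      for c in range(k)])
    return ClusterSolution(labels=labels, centroids=cents, inertia=0.0,
                           ratio_a=1.0, k=k, seed=None, restarts=1)


class TestRelabeling:
    def test_permuted_subjects_agree_after_relabeling(self, rng):
        base = rng.integers(0, 3, size=60)
        sols = []
        for _ in range(5):
            perm = rng.permutation(3)
            sols.append(_solution(perm[base], 3))
        atlas = relabel_group(sols)
        for s in range(1, 5):
            assert adjusted_rand_score(atlas.labels[0], atlas.labels[s]) == 1.0
        assert set(np.unique(atlas.occurrence_prob)) <= {0.0, 1.0}

    def test_occurrence_probability_counting_oracle(self, rng):
        sols = [_solution(rng.integers(0, 2, size=30), 2) for _ in range(6)]
        atlas = relabel_group(sols)
        for c in range(2):
            for e in range(30):
                count = sum(atlas.labels[s, e] == c for s in range(6))
                assert atlas.occurrence_prob[c, e] == pytest.approx(count / 6)

    def test_relabeling_preserves_partitions(self, rng):
        sols = [_solution(rng.integers(0, 3, size=40), 3) for _ in range(4)]
        atlas = relabel_group(sols)
        for s in range(4):
            assert adjusted_rand_score(sols[s].labels, atlas.labels[s]) == 1.0

    def test_template_subject_does_not_matter_for_separated_groups(self, rng):
        base = rng.integers(0, 3, size=60)
        sols = [_solution(np.random.default_rng(s).permutation(3)[base], 3)
                for s in range(6)]
        atlases = [relabel_group(sols, template_subject=t) for t in range(6)]
        for a in atlases[1:]:
            # same partition structure; occurrence maps identical up to
            # a global label permutation
            m = match_atlases(atlases[0], a)
            assert np.allclose(m, 1.0)


class TestReproducibilitySplit:
    def test_identical_subjects_reproduce_exactly(self, rng):
        X, _ = planted_matrix(rng, k=3, n_per=15, sep=8.0)
        subjects = [X.copy() for _ in range(6)]
        a1, a2, corr = reproducibility_split(subjects, k=3, restarts=5, seed=0)
        assert np.allclose(corr, 1.0)

    def test_split_sizes(self, rng):
        X, _ = planted_matrix(rng, k=2, n_per=10, sep=8.0)
        subjects = [X.copy() for _ in range(7)]
        a1, a2, _ = reproducibility_split(subjects, k=2, restarts=3, seed=0)
        assert a1.labels.shape[0] == 4  # odd cohort: extra subject first half
        assert a2.labels.shape[0] == 3


class TestSyntheticReproducibility:
    """Split-half and window-length robustness on planted cohorts."""

    def _cohort_series(self, n, seed, window_s=20.0, step=12):
        from nirsdyn.connectivity import sliding_window_corr
        from nirsdyn.preprocess import preprocess_chain
        from nirsdyn.synthetic import SynthConfig, simulate_subject

        out = []
        for s in range(n):
            sub = simulate_subject(SynthConfig(seed=seed + s), seed=seed + s)
            clean = preprocess_chain(sub.hemo)
            out.append(sliding_window_corr(clean, window_s=window_s,
                                           step_samples=step))
        return out

    def test_split_half_occurrence_maps_agree(self):
        series = self._cohort_series(8, seed=600)
        a1, a2, corr = reproducibility_split(series, k=4, restarts=15, seed=0)
        # at least the three modulated networks reproduce strongly
        assert np.sort(corr)[-3:].min() >= 0.8

    def test_window_length_robustness(self):
        s20 = self._cohort_series(6, seed=700, window_s=20.0)
        s30 = self._cohort_series(6, seed=700, window_s=30.0)
        atlases = []
        for series in (s20, s30):
            sols = [kmeans_edges(d, 4, restarts=15, seed=i)
                    for i, d in enumerate(series)]
            atlases.append(relabel_group(sols))
        corr = match_atlases(atlases[0], atlases[1])
        assert np.sort(corr)[-3:].min() >= 0.7
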