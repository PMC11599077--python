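"""Correlation matrices, Ward clustering, silhouette and k-selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from emsig.factors import (
    ClusterPartition,
    CorrelationMatrix,
    centroid_silhouette,
    compute_factor_scores,
    pcc_matrix,
    select_k,
    ward_linkage,
    ward_partition,
)
from emsig.schema import reverse_score

from conftest import tiny_dataset


def block_corr(sizes, within, between):
    """Block-diagonal correlation matrix with constant within/between values."""
    n = sum(sizes)
    mat = np.full((n, n), between)
    start = 0
    for size in sizes:
        mat[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(mat, 1.0)
    items = [f"q{i}" for i in range(n)]
    return CorrelationMatrix(item_ids=tuple(items), values=mat)


def ward_lance_williams(dissimilarity):
    """Brute-force Ward agglomeration via the Lance-Williams recursion.

    Returns the merge sequence [(idx_a, idx_b, height)] in scipy linkage
    conventions (cluster m + n labels for merged clusters, heights equal to
    the Ward distance at merge time).
    """
    d = np.array(dissimilarity, dtype=float)
    n = len(d)
    active = {i: (d[i].copy(), 1) for i in range(n)}
    dist = {
        frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_label = n
    while len(sizes) > 1:
        pair = min(dist, key=lambda p: (dist[p], sorted(p)))
        i, j = sorted(pair)
        h = dist[pair]
        ni, nj = sizes[i], sizes[j]
        merges.append((i, j, h))
        new = next_label
        next_label += 1
        del sizes[i], sizes[j]
        for k in list(sizes):
            nk = sizes[k]
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            dij = h
            # Ward update on Euclidean-style distances (scipy convention:
            # distances combined in the squared domain)
            dist[frozenset((new, k))] = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
        for p in [p for p in dist if i in p or j in p]:
            del dist[p]
        sizes[new] = ni + nj
    return merges


class TestPccMatrix:
    def test_hand_computed_pearson(self):
        ds = tiny_dataset({"S_a": [1, 2, 3, 4], "S_b": [1, 3, 2, 4]})
        corr = pcc_matrix(ds, "S")
        assert corr.values[0, 1] == pytest.approx(0.8)

    def test_duplicate_and_reflected_items(self):
        x = [1, 2, 3, 4, 5]
        ds = tiny_dataset(
            {"S_a": x, "S_b": x, "S_c": [6 - v for v in x]}
        )
        corr = pcc_matrix(ds, "S")
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[0, 2] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self, study_scored):
        dataset, _, _, _ = study_scored
        corr = pcc_matrix(dataset, "CoVaH")
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert np.all(np.abs(corr.values) <= 1 + 1e-12)

    def test_zero_variance_item_named(self):
        ds = tiny_dataset({"S_a": [1, 2, 3], "S_b": [2, 2, 2]})
        with pytest.raises(ValueError, match="S_b"):
            pcc_matrix(ds, "S")


class TestWardPartition:
    def test_recovers_perfect_blocks(self):
        corr = block_corr([3, 4], within=1.0, between=0.0)
        part = ward_partition(corr, 2)
        labels = part.labels_for(corr.item_ids)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1, 1], labels) == 1.0

    def test_all_singletons_at_k_equals_n(self):
        corr = block_corr([2, 3], within=0.9, between=0.1)
        part = ward_partition(corr, 5)
        assert part.k == 5
        assert sorted(part.assignment.values()) == [0, 1, 2, 3, 4]

    def test_k_out_of_range(self):
        corr = block_corr([2, 2], within=0.9, between=0.1)
        with pytest.raises(ValueError):
            ward_partition(corr, 0)
        with pytest.raises(ValueError):
            ward_partition(corr, 5)

    def test_merge_order_matches_lance_williams_recursion(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(-0.3, 0.9, size=(5, 5))
        mat = np.clip((base + base.T) / 2, -1, 1)
        np.fill_diagonal(mat, 1.0)
        corr = CorrelationMatrix(
            item_ids=("a", "b", "c", "d", "e"), values=mat
        )
        merge_tree = ward_linkage(corr)
        oracle = ward_lance_williams(corr.dissimilarity())
        for row, (i, j, h) in zip(merge_tree, oracle):
            assert sorted(row[:2].astype(int)) == sorted((i, j))
            assert row[2] == pytest.approx(h, abs=1e-10)

    def test_invariant_to_item_order(self):
        corr = block_corr([3, 3, 4], within=0.8, between=0.1)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.01, size=corr.values.shape)
        noisy = np.clip(corr.values + (noise + noise.T) / 2, -1, 1)
        np.fill_diagonal(noisy, 1.0)
        corr = CorrelationMatrix(item_ids=corr.item_ids, values=noisy)
        part = ward_partition(corr, 3)
        perm = rng.permutation(corr.n_items)
        corr_p = CorrelationMatrix(
            item_ids=tuple(corr.item_ids[i] for i in perm),
            values=corr.values[np.ix_(perm, perm)],
        )
        part_p = ward_partition(corr_p, 3)
        a = part.labels_for(corr.item_ids)
        b = part_p.labels_for(corr.item_ids)
        assert adjusted_rand_score(a, b) == 1.0


class TestCentroidSilhouette:
    def test_one_dimensional_example(self):
        # own centroid at 0 (items at +/-1), other at 10 -> a'=1, b'=9
        coords = pd.DataFrame({"x": [1.0, -1.0, 10.0, 10.0]}, index=list("abcd"))
        part = ClusterPartition(k=2, assignment={"a": 0, "b": 0, "c": 1, "d": 1})
        a, b, s, sc = centroid_silhouette(part, coords)
        assert a["a"] == pytest.approx(1.0)
        assert b["a"] == pytest.approx(9.0)
        assert s["a"] == pytest.approx(8.0 / 9.0)

    def test_equidistant_item_scores_zero(self):
        # c at 5: own centroid (a=-5, c=5) -> 0, other centroid (d=e=10)
        # -> a'(c) = b'(c) = 5 -> s'(c) = 0
        coords = pd.DataFrame(
            {"x": [-5.0, 5.0, 10.0, 10.0]}, index=list("acde")
        )
        part = ClusterPartition(k=2, assignment={"a": 0, "c": 0, "d": 1, "e": 1})
        a, b, s, sc = centroid_silhouette(part, coords)
        assert a["c"] == pytest.approx(5.0)
        assert b["c"] == pytest.approx(5.0)
        assert s["c"] == pytest.approx(0.0)

    def test_tight_separated_clusters_approach_one(self):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame(
            np.vstack(
                [rng.normal(0, 0.01, (5, 2)), rng.normal(50, 0.01, (5, 2))]
            ),
            index=[f"q{i}" for i in range(10)],
        )
        part = ClusterPartition(
            k=2, assignment={f"q{i}": int(i >= 5) for i in range(10)}
        )
        *_, sc = centroid_silhouette(part, coords)
        assert sc > 0.99

    def test_single_cluster_rejected(self):
        coords = pd.DataFrame({"x": [0.0, 1.0]}, index=["a", "b"])
        part = ClusterPartition(k=1, assignment={"a": 0, "b": 0})
        with pytest.raises(ValueError):
            centroid_silhouette(part, coords)

    def test_silhouette_bounded_on_real_solution(self, study_scored):
        dataset, _, solutions, _ = study_scored
        for sol in solutions.values():
            for q in sol.quality.values():
                assert np.all(q.per_item_s.to_numpy() <= 1 + 1e-12)
                assert np.all(q.per_item_s.to_numpy() >= -1 - 1e-12)


class TestSelectK:
    def test_planted_blocks_recovered(self, study_scored):
        dataset, truth, solutions, _ = study_scored
        expected = {"CoVaH": 4, "T-DiG": 5, "TRUST-Ph": 3, "TiPHA": 4}
        for scale_id, sol in solutions.items():
            assert sol.chosen_k == expected[scale_id]
            true_part = truth.item_partition[scale_id]
            items = list(true_part)
            ari = adjusted_rand_score(
                [true_part[i] for i in items],
                [sol.partition.assignment[i] for i in items],
            )
            assert ari == 1.0

    def test_two_perfect_blocks(self):
        corr = block_corr([4, 4], within=0.95, between=0.05)
        sol = select_k(corr, pcc_floor=0.5)
        assert sol.chosen_k == 2

    def test_planted_sc_exceeds_weak_threshold(self, study_scored):
        *_, solutions, _ = study_scored
        for sol in solutions.values():
            assert sol.quality[sol.chosen_k].sc >= 0.25

    def test_no_admissible_k_reports_quality(self):
        corr = block_corr([4, 4], within=0.5, between=0.1)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.005, size=corr.values.shape)
        vals = np.clip(corr.values + (noise + noise.T) / 2, -1, 1)
        np.fill_diagonal(vals, 1.0)  # break merge-height ties
        corr = CorrelationMatrix(item_ids=corr.item_ids, values=vals)
        sol = select_k(corr, pcc_floor=0.99)
        assert sol.chosen_k is None
        assert sol.partition is None
        assert set(sol.quality) == set(range(2, 9))
        assert not sol.quality_table()["admissible"].any()


class TestFactorScores:
    def _solution(self, ds, assignment, k):
        from emsig.factors import FactorSolution

        return {
            "S": FactorSolution(
                scale_id="S",
                chosen_k=k,
                partition=ClusterPartition(k=k, assignment=assignment),
                quality={},
                prefix="S",
            )
        }

    def test_mean_sum_and_singleton(self):
        ds = tiny_dataset({"S_a": [4], "S_b": [5], "S_c": [3], "S_d": [2]})
        ds = reverse_score(ds)  # no reverse items: marks alignment done
        sols = self._solution(
            ds, {"S_a": 0, "S_b": 0, "S_c": 0, "S_d": 1}, 2
        )
        mean_scores = compute_factor_scores(ds, sols, aggregator="mean")
        sum_scores = compute_factor_scores(ds, sols, aggregator="sum")
        assert mean_scores.loc[0, "S-c1"] == pytest.approx(4.0)
        assert sum_scores.loc[0, "S-c1"] == pytest.approx(12.0)
        assert mean_scores.loc[0, "S-c2"] == pytest.approx(2.0)  # singleton

    def test_mean_invariant_under_item_duplication(self):
        ds1 = tiny_dataset({"S_a": [2, 4], "S_b": [4, 2]})
        ds2 = tiny_dataset(
            {"S_a": [2, 4], "S_b": [4, 2], "S_c": [2, 4], "S_d": [4, 2]}
        )
        s1 = compute_factor_scores(
            reverse_score(ds1), self._solution(ds1, {"S_a": 0, "S_b": 0}, 1)
        )
        s2 = compute_factor_scores(
            reverse_score(ds2),
            self._solution(ds2, {"S_a": 0, "S_b": 0, "S_c": 0, "S_d": 0}, 1),
        )
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_requires_reverse_scoring_first(self):
        ds = tiny_dataset({"S_a": [1, 2]})
        with pytest.raises(ValueError, match="reverse"):
            compute_factor_scores(ds, self._solution(ds, {"S_a": 0}, 1))
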