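import itertools
import random

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from completelink import (
    BlockingSpec,
    Config,
    agglomerate,
    build_block_index,
    complete_linkage_cluster,
    expand,
    find_exact_clusters,
    is_exceeds,
    priority_score,
    record_distance,
    refine_clusters,
)
from completelink.datasets_io import corpus_records
from completelink.pipeline import cluster_components, representatives
from completelink.single_linkage import (
    Component,
    build_edges,
    connected_components,
)

from conftest import make_dataset, random_string


def worked_state(worked_example):
    datasets, config = worked_example
    corpus = corpus_records(datasets)
    exact = find_exact_clusters(datasets)
    reps = representatives(exact, corpus)
    return datasets, config, corpus, exact, reps


class TestAgglomerate:
    def test_tied_component_never_merges_all_three(self, worked_example):
        _, config, _, _, reps = worked_state(worked_example)
        comp = Component([("A", 0), ("A", 1), ("B", 1)])  # Bale, Bolt, Balt
        clusters = complete_linkage_cluster(comp, reps, config)
        assert len(clusters) == 2
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 2]
        # Balt pairs with exactly one of Bale/Bolt
        paired = next(c for c in clusters if len(c) == 2)
        assert ("B", 1) in paired

    def test_chaining_fixture_splits(self, chaining_example):
        datasets, config = chaining_example
        corpus = corpus_records(datasets)
        exact = find_exact_clusters(datasets)
        reps = representatives(exact, corpus)
        comp = Component(sorted(reps))
        clusters = complete_linkage_cluster(comp, reps, config)
        assert sorted(len(c) for c in clusters) == [1, 2]

    def test_singleton_component_unchanged(self, worked_example):
        _, config, _, _, reps = worked_state(worked_example)
        comp = Component([("A", 2)])
        assert complete_linkage_cluster(comp, reps, config) == [[("A", 2)]]

    def test_merge_distances_non_decreasing(self):
        rng = random.Random(3)
        for _ in range(20):
            n = rng.randint(2, 8)
            ids = [("x", i) for i in range(n)]
            dist = {
                (a, b): rng.uniform(0, 10)
                for i, a in enumerate(ids)
                for b in ids[i + 1 :]
            }
            history: list[float] = []
            agglomerate(ids, dist, tau=rng.uniform(0, 10), merge_history=history)
            assert history == sorted(history)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_complete_linkage_cut(self, seed):
        """On distinct distances the tau-cut partition is unique, so the
        hand-rolled agglomeration must equal scipy's dendrogram cut."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        condensed = rng.permutation(np.arange(1, n * (n - 1) // 2 + 1)) + \
            rng.uniform(0, 0.5, n * (n - 1) // 2)
        tau = float(rng.uniform(0, condensed.max()))
        square = squareform(condensed)
        ids = [("x", i) for i in range(n)]
        dist = {
            (ids[i], ids[j]): float(square[i, j])
            for i in range(n)
            for j in range(i + 1, n)
        }
        ours = agglomerate(ids, dist, tau)
        labels = fcluster(linkage(condensed, "complete"), t=tau,
                          criterion="distance")
        expected: dict[int, list] = {}
        for i, lab in enumerate(labels):
            expected.setdefault(lab, []).append(ids[i])
        expected_sets = sorted(sorted(c) for c in expected.values())
        assert sorted(ours) == expected_sets


def _priority_config(priority, tau=1):
    return Config(
        blocking_specs=[BlockingSpec("first_name", 3)],
        comparison_attributes=["first_name", "last_name"],
        threshold=tau,
        priority_attributes=priority,
    )


class TestPriorityScore:
    def test_dob_tie_break_scores(self, worked_example):
        _, _, _, _, reps = worked_state(worked_example)
        balt = reps[("B", 1)]
        assert priority_score(balt, [("A", 0)], reps, ["dob"]) == 1  # Bale
        assert priority_score(balt, [("A", 1)], reps, ["dob"]) == 0  # Bolt

    def test_empty_priority_list(self, worked_example):
        _, _, _, _, reps = worked_state(worked_example)
        assert priority_score(reps[("B", 1)], [("A", 0)], reps, []) == 0

    def test_higher_rank_dominates(self):
        ds = make_dataset(
            "D",
            ["first_name", "last_name", "p1", "p2"],
            [("A", "B", "X", "Y"), ("A", "B", "X", "Z"), ("A", "B", "Q", "Y")],
        )
        reps = {r.rid: r for r in ds.records}
        record = reps[("D", 0)]
        high_only = priority_score(record, [("D", 1)], reps, ["p1", "p2"])
        low_only = priority_score(record, [("D", 2)], reps, ["p1", "p2"])
        assert high_only == 2 > low_only == 1


class TestRefineClusters:
    def test_worked_example_tie_resolved_by_dob(self, worked_example):
        _, config, _, _, reps = worked_state(worked_example)
        # adversarial start: Balt glued to Bolt, Bale alone
        clusters = [[("A", 0)], [("A", 1), ("B", 1)]]
        refined = refine_clusters(clusters, reps, config)
        assert [("A", 0), ("B", 1)] in refined  # Balt moved next to Bale
        assert [("A", 1)] in refined

    def test_empty_priority_is_identity(self, worked_example):
        _, _, _, _, reps = worked_state(worked_example)
        config = _priority_config([])
        clusters = [[("A", 0)], [("A", 1), ("B", 1)]]
        assert refine_clusters(clusters, reps, config) == clusters

    @pytest.mark.parametrize("seed", range(8))
    def test_moves_never_break_diameter(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 6)
        rows = [
            (
                random_string(rng, "AB", 2, 4),
                random_string(rng, "AB", 2, 4),
                random_string(rng, "XY", 1, 1),
            )
            for _ in range(n)
        ]
        ds = make_dataset("D", ["first_name", "last_name", "dob"], rows)
        reps = {r.rid: r for r in ds.records}
        config = _priority_config(["dob"], tau=rng.randint(0, 3))
        index = build_block_index(reps.values(), BlockingSpec("first_name", 2))
        graph = build_edges([index], reps, config)
        for comp in connected_components(graph):
            clusters = complete_linkage_cluster(comp, reps, config)
            refined = refine_clusters(clusters, reps, config)
            assert sorted(r for c in refined for r in c) == sorted(comp.members)
            for cluster in refined:
                for a, b in itertools.combinations(cluster, 2):
                    assert not is_exceeds(
                        record_distance(reps[a], reps[b], config)
                    )


class TestExpand:
    def test_worked_example_membership(self, worked_example):
        datasets, config, corpus, exact, reps = worked_state(worked_example)
        indexes = [
            build_block_index(reps.values(), spec)
            for spec in config.blocking_specs
        ]
        graph = build_edges(indexes, reps, config)
        comps = connected_components(graph)
        rep_clusters = cluster_components(comps, reps, config)
        final = expand(rep_clusters, exact)
        assert sorted(len(c) for c in final.clusters) == [1, 2, 2]
        assert final.n_records == 5
        assert [("A", 2), ("B", 0)] in final.clusters  # both Thors

    def test_all_singleton_exact_clusters_identity(self):
        ds = make_dataset("D", ["n"], [("A",), ("B",)])
        exact = find_exact_clusters([ds])
        final = expand([[("D", 0)], [("D", 1)]], exact)
        assert final.clusters == [[("D", 0)], [("D", 1)]]

    def test_unknown_representative_rejected(self):
        ds = make_dataset("D", ["n"], [("A",)])
        exact = find_exact_clusters([ds])
        with pytest.raises(KeyError):
            expand([[("D", 9)]], exact)
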