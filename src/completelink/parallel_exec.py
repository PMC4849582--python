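"""Deterministic work partitioning and a parallel pipeline executor.

The parallel executor mirrors a master/worker design: the master reads the
data, workers handle partitioned phases, and the master merges between
phases.  Partitioning strategies:

* exact matching — records are sharded by the prefix of their sort key
  (26^prefix_length cells split into contiguous near-equal groups), so
  equal keys always land on the same worker;
* blocking — representatives are sharded nearly uniformly and the partial
  indexes merged;
* edge construction — blocks are grouped by greedy longest-processing-time
  scheduling with cost = (block size)^2, the dominant distance-calculation
  load;
* complete linkage — components are grouped the same way; component
  discovery itself stays centralized.

The executor's only correctness claim is result equivalence: for every
input, configuration and worker count the final clustering is identical to
the sequential pipeline's (speedup is hardware-dependent and not asserted).
"""

from __future__ import annotations

import heapq
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from joblib import Parallel, delayed

from .blocking import BlockIndex, build_block_index, merge_block_indexes
from .complete_linkage import FinalClustering, expand
from .datasets_io import Config, Dataset, Record, RecordId, corpus_records
from .exact_match import (
    MergeTask,
    cluster_set_from_groups,
    merge_groups_for_task,
    merge_tasks,
)
from .pipeline import cluster_components, representatives
from .single_linkage import (
    Component,
    ThresholdGraph,
    connected_components,
    edges_for_pairs,
)


@dataclass(slots=True)
class WorkPartition:
    """Work units split into groups with per-group aggregate load."""

    groups: list[set]
    load: dict[int, float] = field(default_factory=dict)


def partition_prefix_ranges(
    alphabet_size: int, prefix_length: int, p: int
) -> WorkPartition:
    """Split the alphabet_size**prefix_length prefix cells into p contiguous
    groups whose sizes differ by at most one."""
    if p < 1:
        raise ValueError("need at least one group")
    cells = alphabet_size**prefix_length
    base, rem = divmod(cells, p)
    groups: list[set] = []
    load: dict[int, float] = {}
    start = 0
    for g in range(p):
        size = base + (1 if g < rem else 0)
        groups.append(set(range(start, start + size)))
        load[g] = float(size)
        start += size
    return WorkPartition(groups, load)


def group_blocks_balanced(block_sizes: Mapping, p: int) -> WorkPartition:
    """Greedy longest-processing-time grouping with cost = record count ** 2.

    Blocks are taken in descending cost order (key order breaking ties) and
    each goes to the currently lightest group, so the final load spread is
    at most the largest single block cost.
    """
    if p < 1:
        raise ValueError("need at least one group")
    groups: list[set] = [set() for _ in range(p)]
    load = {g: 0.0 for g in range(p)}
    heap = [(0.0, g) for g in range(p)]
    heapq.heapify(heap)
    items = sorted(block_sizes.items(), key=lambda kv: (-kv[1] ** 2, kv[0]))
    for key, count in items:
        cost = float(count) ** 2
        current, g = heapq.heappop(heap)
        groups[g].add(key)
        load[g] = current + cost
        heapq.heappush(heap, (load[g], g))
    return WorkPartition(groups, load)


# --- worker bodies (top-level for pickling) ---------------------------------

def _exact_worker(subtasks: list[MergeTask]) -> list[list[RecordId]]:
    groups: list[list[RecordId]] = []
    for task in subtasks:
        groups.extend(merge_groups_for_task(task))
    return groups


def _blocking_worker(records: list[Record], spec) -> BlockIndex:
    return build_block_index(records, spec)


def _edges_worker(
    blocks: list[list[RecordId]],
    reps: dict[RecordId, Record],
    config: Config,
) -> list[tuple[RecordId, RecordId]]:
    seen: set[tuple[RecordId, RecordId]] = set()
    for members in blocks:
        ordered = sorted(members)
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                seen.add((u, v))
    return edges_for_pairs(sorted(seen), reps, config)


def _linkage_worker(
    comps: list[tuple[int, list[RecordId]]],
    reps: dict[RecordId, Record],
    config: Config,
) -> list[tuple[int, list[list[RecordId]]]]:
    out = []
    for idx, members in comps:
        clusters = cluster_components([Component(members)], reps, config)
        out.append((idx, clusters))
    return out


def _cell_of_key(key: str, prefix_length: int) -> int:
    cell = 0
    for i in range(prefix_length):
        code = (ord(key[i]) - 65) % 26 if i < len(key) else 0
        cell = cell * 26 + code
    return cell


def run_parallel(
    datasets: Sequence[Dataset], config: Config, workers: int
) -> FinalClustering:
    """Run the pipeline with the phases partitioned across worker processes.

    Produces a clustering identical to :func:`completelink.pipeline.link`
    on the same inputs; a worker failure surfaces as a run failure, never a
    partial result.
    """
    if workers < 1:
        raise ValueError("need at least one worker")
    corpus = corpus_records(datasets)

    # phase 1: exact matching, sharded by sort-key prefix cells
    prefix_length = 3
    part = partition_prefix_ranges(26, prefix_length, workers)
    boundaries = []
    upto = 0
    for g in range(workers):
        upto += len(part.groups[g])
        boundaries.append(upto)
    shards: list[list[MergeTask]] = [[] for _ in range(workers)]
    for task in merge_tasks(datasets):
        per_group: dict[int, tuple[list[RecordId], list[str]]] = {}
        for rid, key in zip(task.rids, task.keys):
            g = bisect_right(boundaries, _cell_of_key(key, prefix_length))
            rids, keys = per_group.setdefault(g, ([], []))
            rids.append(rid)
            keys.append(key)
        for g, (rids, keys) in per_group.items():
            shards[g].append(MergeTask(rids, keys, task.witness))
    with Parallel(n_jobs=workers) as parallel:
        group_lists = parallel(
            delayed(_exact_worker)(shard) for shard in shards
        )
        all_groups = [g for lst in group_lists for g in lst]
        exact = cluster_set_from_groups(corpus, all_groups)
        reps = representatives(exact, corpus)

        # phase 2: blocking over representative shards
        rep_list = [reps[rid] for rid in sorted(reps)]
        base, rem = divmod(len(rep_list), workers)
        rec_shards = []
        start = 0
        for g in range(workers):
            size = base + (1 if g < rem else 0)
            rec_shards.append(rep_list[start : start + size])
            start += size
        indexes: list[BlockIndex] = []
        for spec in config.blocking_specs:
            parts = parallel(
                delayed(_blocking_worker)(shard, spec) for shard in rec_shards
            )
            indexes.append(merge_block_indexes(parts))

        # phase 3: edges over balanced block groups
        block_sizes = {
            (si, attr, mer): len(members)
            for si, index in enumerate(indexes)
            for (attr, mer), members in index.blocks.items()
        }
        bpart = group_blocks_balanced(block_sizes, workers)
        block_shards = []
        for group in bpart.groups:
            block_shards.append(
                [
                    sorted(indexes[si].blocks[(attr, mer)])
                    for si, attr, mer in sorted(group)
                ]
            )
        edge_lists = parallel(
            delayed(_edges_worker)(shard, reps, config)
            for shard in block_shards
        )
        graph = ThresholdGraph(nodes=set(reps.keys()))
        for edges in edge_lists:
            for u, v in edges:
                graph.add_edge(u, v)

        # phase 4: components centrally, complete linkage over shards
        components = connected_components(graph)
        cpart = group_blocks_balanced(
            {i: len(c) for i, c in enumerate(components)}, workers
        )
        comp_shards = [
            [(i, components[i].members) for i in sorted(group)]
            for group in cpart.groups
        ]
        linkage_lists = parallel(
            delayed(_linkage_worker)(shard, reps, config)
            for shard in comp_shards
        )
    indexed = sorted(
        (pair for lst in linkage_lists for pair in lst), key=lambda t: t[0]
    )
    rep_clusters = [cluster for _, clusters in indexed for cluster in clusters]
    return expand(rep_clusters, exact)
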