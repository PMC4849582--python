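"""Exact-duplicate elimination across comparable dataset pairs.

Two datasets are *comparable* when one schema is a subset of the other;
records of a comparable pair that agree on every common attribute are
byte-identical duplicates and collapse into one cluster, from which a single
representative carries on to the approximate phases.  Sorting (a radix sort
over the concatenated common attributes) makes duplicates adjacent, and a
union-find structure accumulates the transitive closure of merges across all
pairs.

Datasets with identical schemas are sorted jointly in one pass, which yields
exactly the pairwise-merge closure for every pair among them (including
within-dataset self-pairs).  For a proper-subset pair S ⊂ T, an equal-key run
merges only when it contains at least one S-side record: two T records that
agree merely on the S attributes are not duplicates of each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from .datasets_io import SEPARATOR, Dataset, Record, RecordId, corpus_records


class DisjointSet:
    """Union-find with path halving and union by size."""

    def __init__(self, items: Iterable = ()) -> None:
        self._parent: dict = {}
        self._size: dict = {}
        for it in items:
            self.add(it)

    def add(self, item) -> None:
        if item not in self._parent:
            self._parent[item] = item
            self._size[item] = 1

    def find(self, item):
        parent = self._parent
        root = item
        while parent[root] != root:
            parent[root] = parent[parent[root]]
            root = parent[root]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self._size[ra] < self._size[rb]:
            ra, rb = rb, ra
        self._parent[rb] = ra
        self._size[ra] += self._size[rb]

    def groups(self) -> dict:
        out: dict = {}
        for item in self._parent:
            out.setdefault(self.find(item), []).append(item)
        return out


@dataclass(slots=True)
class ExactClusterSet:
    """Partition of the corpus into identical-record groups.

    ``clusters`` are sorted member lists ordered by smallest member id;
    ``representative`` maps cluster index to the chosen representative id.
    The number of clusters is the reduced corpus size handed to blocking.
    """

    clusters: list[list[RecordId]]
    representative: dict[int, RecordId]

    def __len__(self) -> int:
        return len(self.clusters)

    def members_of_representative(self) -> dict[RecordId, list[RecordId]]:
        return {self.representative[i]: members
                for i, members in enumerate(self.clusters)}


def comparable_pairs(datasets: Sequence[Dataset]) -> list[tuple[str, str]]:
    """Ordered dataset-id pairs (X, Y) with attributes(X) ⊆ attributes(Y).

    Self-pairs are included so within-dataset duplicates are caught.  Order
    follows the input dataset order, so the result is deterministic.
    """
    pairs: list[tuple[str, str]] = []
    for x in datasets:
        for y in datasets:
            if x.attribute_set <= y.attribute_set:
                pairs.append((x.dataset_id, y.dataset_id))
    return pairs


def sort_key(record: Record, common_attributes: Sequence[str]) -> str:
    """Concatenate the folded common-attribute values with the reserved separator."""
    parts = []
    for attr in common_attributes:
        if attr not in record.folded:
            raise KeyError(
                f"record {record.rid} has no attribute {attr!r}"
            )
        value = record.folded[attr]
        if SEPARATOR in value:
            raise ValueError(
                f"record {record.rid} attribute {attr!r} contains the "
                "reserved separator character"
            )
        parts.append(value)
    return SEPARATOR.join(parts)


def radix_sort(keys: Sequence[str], alphabet: str | None = None) -> list[int]:
    """Stable lexicographic sort; returns the permutation of input indices.

    MSD radix sort over UTF-8 bytes: at each depth keys are bucketed by one
    byte, exhausted keys come first, and equal keys keep their input order.
    When ``alphabet`` is given, any key character outside it (separator
    excluded) is an error naming the character.
    """
    if alphabet is not None:
        allowed = set(alphabet) | {SEPARATOR}
        for key in keys:
            for ch in key:
                if ch not in allowed:
                    raise ValueError(
                        f"character {ch!r} outside declared alphabet"
                    )
    encoded = [k.encode("utf-8") for k in keys]
    order: list[int] = []
    stack: list[tuple[list[int], int]] = [(list(range(len(keys))), 0)]
    while stack:
        idxs, depth = stack.pop()
        if len(idxs) <= 1:
            order.extend(idxs)
            continue
        buckets: dict[int, list[int]] = {}
        for i in idxs:
            key = encoded[i]
            if len(key) <= depth:
                order.append(i)  # prefix sorts before any extension
            else:
                buckets.setdefault(key[depth], []).append(i)
        for byte in sorted(buckets, reverse=True):
            stack.append((buckets[byte], depth + 1))
    return order


def _equal_runs(keys: Sequence[str], order: Sequence[int]) -> Iterator[list[int]]:
    """Yield runs of indices with equal keys from a sorted order."""
    run: list[int] = []
    prev: str | None = None
    for i in order:
        if prev is not None and keys[i] == prev:
            run.append(i)
        else:
            if len(run) > 1:
                yield run
            run = [i]
            prev = keys[i]
    if len(run) > 1:
        yield run


@dataclass(slots=True)
class MergeTask:
    """One sorting unit: records, their sort keys, and an optional witness set.

    When ``witness`` is None every equal-key run merges outright (identical
    schemas).  Otherwise a run merges only if it contains a witness record —
    the subset-schema side of a proper-subset dataset pair — and the merge is
    then licensed pairwise through that witness.
    """

    rids: list[RecordId]
    keys: list[str]
    witness: set[RecordId] | None = None


def merge_tasks(datasets: Sequence[Dataset]) -> list[MergeTask]:
    """Build the sorting units covering every comparable dataset pair."""
    by_schema: dict[frozenset[str], list[Dataset]] = {}
    schema_order: list[frozenset[str]] = []
    for ds in datasets:
        if ds.attribute_set not in by_schema:
            by_schema[ds.attribute_set] = []
            schema_order.append(ds.attribute_set)
        by_schema[ds.attribute_set].append(ds)

    tasks: list[MergeTask] = []
    for schema in schema_order:
        members = by_schema[schema]
        attrs = sorted(schema)
        rids: list[RecordId] = []
        keys: list[str] = []
        for ds in members:
            for rec in ds.records:
                rids.append(rec.rid)
                keys.append(sort_key(rec, attrs))
        tasks.append(MergeTask(rids, keys))
    for s in schema_order:
        for t in schema_order:
            if s < t:  # proper subset
                attrs = sorted(s)
                rids = []
                keys = []
                witness: set[RecordId] = set()
                for ds in by_schema[s]:
                    for rec in ds.records:
                        rids.append(rec.rid)
                        keys.append(sort_key(rec, attrs))
                        witness.add(rec.rid)
                for ds in by_schema[t]:
                    for rec in ds.records:
                        rids.append(rec.rid)
                        keys.append(sort_key(rec, attrs))
                tasks.append(MergeTask(rids, keys, witness))
    return tasks


def merge_groups_for_task(task: MergeTask) -> list[list[RecordId]]:
    """Equal-key record groups of one task that are licensed to merge."""
    order = radix_sort(task.keys)
    groups: list[list[RecordId]] = []
    for run in _equal_runs(task.keys, order):
        if task.witness is not None and not any(
            task.rids[i] in task.witness for i in run
        ):
            continue
        groups.append([task.rids[i] for i in run])
    return groups


def cluster_set_from_groups(
    corpus: Mapping[RecordId, Record],
    groups: Iterable[Iterable[RecordId]],
) -> ExactClusterSet:
    """Union merge groups transitively and pick representatives."""
    dsu = DisjointSet(corpus.keys())
    for group in groups:
        it = iter(group)
        first = next(it)
        for other in it:
            dsu.union(first, other)
    clusters = sorted((sorted(g) for g in dsu.groups().values()),
                      key=lambda c: c[0])
    representative = {
        i: choose_representative(members, corpus)
        for i, members in enumerate(clusters)
    }
    return ExactClusterSet(clusters, representative)


def find_exact_clusters(datasets: Sequence[Dataset]) -> ExactClusterSet:
    """Collapse exact duplicates across all comparable dataset pairs.

    Result is the transitive closure of equal-on-common-attributes merges
    over every comparable pair; it partitions the corpus.
    """
    corpus = corpus_records(datasets)
    groups: list[list[RecordId]] = []
    for task in merge_tasks(datasets):
        groups.extend(merge_groups_for_task(task))
    return cluster_set_from_groups(corpus, groups)


def choose_representative(
    cluster: Sequence[RecordId], corpus: Mapping[RecordId, Record]
) -> RecordId:
    """Representative = member with the most attributes; ties -> smallest id.

    Retaining the widest-schema member preserves the most comparison power
    for the distance phases.
    """
    if not cluster:
        raise ValueError("cannot choose a representative of an empty cluster")
    return min(cluster, key=lambda rid: (-len(corpus[rid].values), rid))
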