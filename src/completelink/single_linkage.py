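"""Threshold graph construction and connected components (single linkage).

Representatives are vertices; an edge joins two representatives that meet in
at least one block of at least one blocking attribute and whose record
distance is within the threshold.  Connected components of this graph are
the single-linkage clusters.  Because components chain transitively, a
component may contain pairs whose direct distance exceeds the threshold —
the chaining defect that the complete-linkage phase repairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .blocking import BlockIndex
from .datasets_io import Config, Record, RecordId
from .distances import is_exceeds, record_distance
from .exact_match import DisjointSet


@dataclass(slots=True)
class ThresholdGraph:
    """Simple undirected graph over representative ids.

    Edges are stored as sorted id pairs, so there are no self-loops or
    multi-edges by construction.
    """

    nodes: set[RecordId] = field(default_factory=set)
    edges: set[tuple[RecordId, RecordId]] = field(default_factory=set)

    def add_edge(self, u: RecordId, v: RecordId) -> None:
        if u == v:
            return
        self.edges.add((u, v) if u < v else (v, u))


@dataclass(slots=True)
class Component:
    """One single-linkage cluster: a connected component of the graph."""

    members: list[RecordId]

    def __len__(self) -> int:
        return len(self.members)


def candidate_pairs(
    indexes: Iterable[BlockIndex],
) -> list[tuple[RecordId, RecordId]]:
    """Unordered representative pairs co-occurring in >= 1 block of any index.

    Each pair is listed once however many blocks it shares, so downstream
    distance tests run at most once per pair.
    """
    seen: set[tuple[RecordId, RecordId]] = set()
    for index in indexes:
        for members in index.blocks.values():
            ordered = sorted(members)
            for i, u in enumerate(ordered):
                for v in ordered[i + 1 :]:
                    seen.add((u, v))
    return sorted(seen)


def edges_for_pairs(
    pairs: Iterable[tuple[RecordId, RecordId]],
    reps: Mapping[RecordId, Record],
    config: Config,
) -> list[tuple[RecordId, RecordId]]:
    """Distance-test candidate pairs; keep those within the threshold."""
    out: list[tuple[RecordId, RecordId]] = []
    for u, v in pairs:
        d = record_distance(reps[u], reps[v], config)
        if not is_exceeds(d):
            out.append((u, v))
    return out


def build_edges(
    indexes: Iterable[BlockIndex] | BlockIndex,
    reps: Mapping[RecordId, Record],
    config: Config,
) -> ThresholdGraph:
    """Build the threshold graph over all representatives.

    Pairs sharing no block of any blocking attribute are never compared;
    isolated representatives stay in the graph as nodes.
    """
    if isinstance(indexes, BlockIndex):
        indexes = [indexes]
    graph = ThresholdGraph(nodes=set(reps.keys()))
    for u, v in edges_for_pairs(candidate_pairs(indexes), reps, config):
        graph.add_edge(u, v)
    return graph


def connected_components(graph: ThresholdGraph) -> list[Component]:
    """Connected components, ordered by smallest member id, members sorted."""
    dsu = DisjointSet(graph.nodes)
    for u, v in graph.edges:
        dsu.union(u, v)
    comps = sorted((sorted(g) for g in dsu.groups().values()),
                   key=lambda m: m[0])
    return [Component(members) for members in comps]
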