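"""Sequential end-to-end linkage pipeline.

Phases, in order: exact-duplicate elimination → k-mer blocking of the
representatives → threshold-graph edges and connected components (single
linkage) → complete-linkage agglomeration with priority refinement inside
each component → expansion of representatives back to all records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .blocking import BlockIndex, build_block_index
from .complete_linkage import (
    FinalClustering,
    complete_linkage_cluster,
    expand,
    refine_clusters,
)
from .datasets_io import Config, Dataset, Record, RecordId, corpus_records
from .exact_match import ExactClusterSet, find_exact_clusters
from .single_linkage import Component, build_edges, connected_components


@dataclass(slots=True)
class PhaseCounts:
    """Per-phase sizes logged into the run manifest."""

    n_records: int = 0
    n_exact_clusters: int = 0
    n_blocks: int = 0
    n_edges: int = 0
    n_components: int = 0
    n_final_clusters: int = 0

    def to_dict(self) -> dict[str, int]:
        return {
            "records": self.n_records,
            "exact_clusters": self.n_exact_clusters,
            "blocks": self.n_blocks,
            "edges": self.n_edges,
            "components": self.n_components,
            "final_clusters": self.n_final_clusters,
        }


def representatives(
    exact: ExactClusterSet, corpus: Mapping[RecordId, Record]
) -> dict[RecordId, Record]:
    """Representative records keyed by id, for blocking and distances."""
    return {
        rep: corpus[rep] for rep in exact.representative.values()
    }


def cluster_components(
    components: Sequence[Component],
    reps: Mapping[RecordId, Record],
    config: Config,
) -> list[list[RecordId]]:
    """Complete linkage + priority refinement applied per component."""
    rep_clusters: list[list[RecordId]] = []
    for comp in components:
        clusters = complete_linkage_cluster(comp, reps, config)
        rep_clusters.extend(refine_clusters(clusters, reps, config))
    return rep_clusters


def link(
    datasets: Sequence[Dataset], config: Config
) -> tuple[FinalClustering, PhaseCounts]:
    """Run the full pipeline; returns the clustering and per-phase counts."""
    counts = PhaseCounts()
    corpus = corpus_records(datasets)
    counts.n_records = len(corpus)

    exact = find_exact_clusters(datasets)
    counts.n_exact_clusters = len(exact)
    reps = representatives(exact, corpus)

    indexes: list[BlockIndex] = [
        build_block_index(reps.values(), spec) for spec in config.blocking_specs
    ]
    counts.n_blocks = sum(ix.n_blocks() for ix in indexes)

    graph = build_edges(indexes, reps, config)
    counts.n_edges = len(graph.edges)
    components = connected_components(graph)
    counts.n_components = len(components)

    rep_clusters = cluster_components(components, reps, config)
    final = expand(rep_clusters, exact)
    counts.n_final_clusters = len(final)
    return final, counts
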