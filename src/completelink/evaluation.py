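"""Cluster-quality evaluation against a ground-truth individual id.

Output clusters are sorted into four categories.  Type I clusters are
perfect: all the records of one individual and nothing else.  Type II
clusters are pure but incomplete (records of a single individual, not all
of them).  Type III clusters contain every record of at least one
individual mixed with strays from others.  Type IV clusters are fragments
of several individuals.  A cluster's label is inherited by each of its
records, and counts are reported over records.  A cluster that could be
read as more than one category gets the best applicable label
(precedence I > II > III > IV).

Accuracy extends two-class ROC accuracy to many classes: each cluster is
owned by the individual holding the majority of its records, a record is
correctly labeled iff it belongs to its cluster's owner, and accuracy is
(correct labels) / (total records).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .complete_linkage import FinalClustering
from .datasets_io import Dataset, RecordId

TYPE_LABELS = ("I", "II", "III", "IV")


@dataclass(slots=True)
class EvaluationReport:
    n_records: int
    type_counts: dict[str, int]
    correct_labels: int
    n_clusters: int = 0

    @property
    def type_percentages(self) -> dict[str, float]:
        return {
            t: 100.0 * self.type_counts[t] / self.n_records
            for t in TYPE_LABELS
        }

    @property
    def accuracy(self) -> float:
        return self.correct_labels / self.n_records

    def to_text(self) -> str:
        lines = [
            f"records:  {self.n_records}",
            f"clusters: {self.n_clusters}",
        ]
        for t in TYPE_LABELS:
            lines.append(
                f"type {t + ':':4s}{self.type_counts[t]:>10d}"
                f"  ({self.type_percentages[t]:6.2f}%)"
            )
        lines.append(f"correct labels: {self.correct_labels}")
        lines.append(f"accuracy: {self.accuracy:.6f}")
        return "\n".join(lines)

    def to_kv(self) -> str:
        pairs: list[tuple[str, object]] = [
            ("records", self.n_records),
            ("clusters", self.n_clusters),
        ]
        for t in TYPE_LABELS:
            pairs.append((f"type_{t}_records", self.type_counts[t]))
            pairs.append((f"type_{t}_percent", f"{self.type_percentages[t]:.4f}"))
        pairs.append(("correct_labels", self.correct_labels))
        pairs.append(("accuracy", f"{self.accuracy:.6f}"))
        return "\n".join(f"{k} = {v}" for k, v in pairs) + "\n"


def _check_truth(
    clustering: FinalClustering, truth: Mapping[RecordId, str]
) -> None:
    for cluster in clustering.clusters:
        for rid in cluster:
            if rid not in truth:
                raise KeyError(f"record {rid} missing from the truth mapping")


def classify_cluster(
    cluster: Sequence[RecordId],
    truth: Mapping[RecordId, str],
    totals: Mapping[str, int],
) -> str:
    """Label one cluster I/II/III/IV given per-individual record totals."""
    counts = Counter(truth[rid] for rid in cluster)
    pure = len(counts) == 1
    complete = any(counts[ind] == totals[ind] for ind in counts)
    if pure:
        return "I" if complete else "II"
    return "III" if complete else "IV"


def classify_clusters(
    clustering: FinalClustering, truth: Mapping[RecordId, str]
) -> EvaluationReport:
    """Per-record Type I–IV counts plus the correct-label (accuracy) count."""
    _check_truth(clustering, truth)
    totals = Counter(truth.values())
    type_counts = {t: 0 for t in TYPE_LABELS}
    correct = 0
    n = 0
    for cluster in clustering.clusters:
        label = classify_cluster(cluster, truth, totals)
        type_counts[label] += len(cluster)
        n += len(cluster)
        correct += _correct_in_cluster(cluster, truth)
    return EvaluationReport(
        n_records=n,
        type_counts=type_counts,
        correct_labels=correct,
        n_clusters=len(clustering.clusters),
    )


def _correct_in_cluster(
    cluster: Sequence[RecordId], truth: Mapping[RecordId, str]
) -> int:
    counts = Counter(truth[rid] for rid in cluster)
    top = max(counts.values())
    owner = min(ind for ind, c in counts.items() if c == top)
    return counts[owner]


def roc_accuracy(
    clustering: FinalClustering, truth: Mapping[RecordId, str]
) -> float:
    """Majority-owner correct-label fraction over all records.

    Ownership ties break to the smallest individual id (the tied counts make
    the correct-label count identical either way).
    """
    _check_truth(clustering, truth)
    n = clustering.n_records
    if n == 0:
        raise ValueError("cannot evaluate an empty clustering")
    correct = sum(
        _correct_in_cluster(c, truth) for c in clustering.clusters
    )
    return correct / n


def truth_from_datasets(
    datasets: Sequence[Dataset], attribute: str
) -> dict[RecordId, str]:
    """Ground truth from a unique-per-individual attribute (e.g. an SSN)."""
    truth: dict[RecordId, str] = {}
    for ds in datasets:
        for rec in ds.records:
            if attribute not in rec.folded:
                raise KeyError(
                    f"record {rec.rid} lacks truth attribute {attribute!r}"
                )
            truth[rec.rid] = rec.folded[attribute]
    return truth


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write the machine-readable key-value form of a report."""
    Path(path).write_text(report.to_kv(), encoding="utf-8")
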