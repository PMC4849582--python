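"""Record datasets, cluster files, and run configuration.

Datasets are plain CSV files with a header row (RFC-4180 style, UTF-8).
Every later stage of the pipeline works on :class:`Record` objects produced
here, so this module fixes the data model once: a record is one row of one
dataset, addressed corpus-wide by the pair ``(dataset_id, row_index)``.

Attribute values are case-folded to upper case at load time for all matching
purposes (blocking, distances, exact matching); the original casing is kept
for output.  Row indices are 0-based both internally and in output files.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: Corpus-wide record identifier.
RecordId = tuple[str, int]

#: Reserved separator used when concatenating attribute values into sort
#: keys; outside every supported blocking alphabet.
SEPARATOR = "\x1f"

#: Reserved pad character for k-mer keys built from values shorter than k.
PAD = "#"

#: Supported blocking alphabets (values are the allowed characters after
#: upper-case folding).
ALPHABETS: dict[str, str] = {
    "letters26": "ABCDEFGHIJKLMNOPQRSTUVWXYZ",
    "digits10": "0123456789",
    "alnum36": "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789",
}

DISTANCE_METHODS = ("edit", "reversal", "truncation")


class DatasetFormatError(ValueError):
    """Raised for malformed dataset files (duplicate headers, ragged rows...)."""


class ConfigError(ValueError):
    """Raised for unparsable or invalid configuration."""


@dataclass(slots=True)
class Record:
    """One row of one dataset.

    ``values`` holds the attribute values verbatim as read; ``folded`` holds
    the upper-cased versions used for matching.  Both map attribute name to
    string and cover exactly the owning dataset's schema (empty strings are
    legal values).
    """

    dataset_id: str
    row_index: int
    values: dict[str, str]
    folded: dict[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.folded is None:
            self.folded = {a: v.upper() for a, v in self.values.items()}

    @property
    def rid(self) -> RecordId:
        return (self.dataset_id, self.row_index)


@dataclass(slots=True)
class Dataset:
    """An ordered collection of records sharing one attribute schema."""

    dataset_id: str
    attributes: list[str]
    records: list[Record]

    @property
    def attribute_set(self) -> frozenset[str]:
        return frozenset(self.attributes)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True, slots=True)
class BlockingSpec:
    """One blocking attribute with its k-mer window and alphabet."""

    attribute: str
    k: int = 3
    alphabet: str = "letters26"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"blocking k must be >= 1, got {self.k}")
        if self.alphabet not in ALPHABETS:
            raise ConfigError(
                f"unknown alphabet {self.alphabet!r}; choose from {sorted(ALPHABETS)}"
            )


@dataclass(slots=True)
class Config:
    """Full run configuration.

    ``threshold`` is the maximum total number of edit errors tolerated
    between two records that are considered a match; ``proportional_ratio``,
    when set, replaces it per record pair with ``ceil(ratio * min aggregated
    value length)``.
    """

    blocking_specs: list[BlockingSpec]
    comparison_attributes: list[str]
    threshold: int
    distance_method: str = "edit"
    priority_attributes: list[str] = field(default_factory=list)
    truth_attribute: str | None = None
    proportional_ratio: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.threshold < 0:
            raise ConfigError(f"threshold must be >= 0, got {self.threshold}")
        if not self.comparison_attributes:
            raise ConfigError("at least one comparison attribute is required")
        if not self.blocking_specs:
            raise ConfigError("at least one blocking attribute is required")
        if self.distance_method not in DISTANCE_METHODS:
            raise ConfigError(
                f"unknown distance method {self.distance_method!r}; "
                f"choose from {DISTANCE_METHODS}"
            )
        if self.proportional_ratio is not None and not 0 < self.proportional_ratio:
            raise ConfigError("proportional ratio must be positive")

    def pair_threshold(self, len_a: int, len_b: int) -> int:
        """Effective threshold for a record pair with aggregated value lengths."""
        if self.proportional_ratio is None:
            return self.threshold
        return math.ceil(self.proportional_ratio * min(len_a, len_b))

    def to_dict(self) -> dict:
        return {
            "blocking": [
                f"{s.attribute}:{s.k}:{s.alphabet}" for s in self.blocking_specs
            ],
            "comparison": list(self.comparison_attributes),
            "method": self.distance_method,
            "threshold": self.threshold,
            "priority": list(self.priority_attributes),
            "truth": self.truth_attribute,
            "proportional": self.proportional_ratio,
        }


def read_dataset(path: str | Path, dataset_id: str | None = None,
                 case_fold: bool = True) -> Dataset:
    """Read a CSV dataset (header row of attribute names, one record per row).

    Values are preserved verbatim; when ``case_fold`` (the default) the
    folded copies used for matching are upper-cased.  Ragged rows and
    duplicate header names are reported with their location.
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetFormatError(f"{path}: empty file, header row required")
        seen: set[str] = set()
        for name in header:
            if name in seen:
                raise DatasetFormatError(f"{path}: duplicate header name {name!r}")
            seen.add(name)
        records: list[Record] = []
        for i, row in enumerate(reader):
            if len(row) != len(header):
                raise DatasetFormatError(
                    f"{path}: row {i} has {len(row)} fields, expected {len(header)}"
                )
            values = dict(zip(header, row))
            folded = {a: v.upper() for a, v in values.items()} if case_fold \
                else dict(values)
            records.append(Record(dataset_id, i, values, folded))
    return Dataset(dataset_id, list(header), records)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to CSV (original, unfolded values)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(dataset.attributes)
        for rec in dataset.records:
            writer.writerow([rec.values[a] for a in dataset.attributes])


_CLUSTER_HEADER = ["cluster_id", "dataset_id", "row_index"]


def write_clusters(clusters: Iterable[Iterable[RecordId]], path: str | Path) -> None:
    """Write a clustering as CSV: one line per record.

    Clusters are numbered 0.. in order of their smallest member id and lines
    are sorted by (cluster_id, dataset_id, row_index), so equal partitions
    always serialize to byte-identical files.
    """
    ordered = sorted((sorted(c) for c in clusters), key=lambda c: c[0])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CLUSTER_HEADER)
        for cid, members in enumerate(ordered):
            for ds, row in members:
                writer.writerow([cid, ds, row])


def read_clusters(path: str | Path) -> list[list[RecordId]]:
    """Read a cluster file written by :func:`write_clusters`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cluster file not found: {path}")
    groups: dict[str, list[RecordId]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _CLUSTER_HEADER:
            raise DatasetFormatError(f"{path}: unexpected header {header}")
        for i, row in enumerate(reader):
            if len(row) != 3:
                raise DatasetFormatError(f"{path}: row {i} malformed")
            cid, ds, idx = row
            groups.setdefault(cid, []).append((ds, int(idx)))
    return sorted((sorted(g) for g in groups.values()), key=lambda c: c[0])


def write_truth(truth: Mapping[RecordId, str], path: str | Path) -> None:
    """Write a ground-truth mapping (record id -> individual id) as CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dataset_id", "row_index", "individual"])
        for (ds, idx), ind in sorted(truth.items()):
            writer.writerow([ds, idx, ind])


def read_truth(path: str | Path) -> dict[RecordId, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"truth file not found: {path}")
    truth: dict[RecordId, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            truth[(row[0], int(row[1]))] = row[2]
    return truth


# --- configuration file -----------------------------------------------------
#
# Flat key = value lines; '#' starts a comment; keys:
#   blocking    = attr[:k[:alphabet]] [, attr[:k[:alphabet]] ...]   (required)
#   comparison  = attr [, attr ...]                                 (required)
#   threshold   = non-negative integer                              (required)
#   method      = edit | reversal | truncation          (default: edit)
#   priority    = attr [, attr ...]                     (default: empty)
#   truth       = attr                                  (default: none)
#   proportional = ratio in (0, 1]                      (default: off)

_CONFIG_KEYS = {"blocking", "comparison", "threshold", "method", "priority",
                "truth", "proportional"}


def _parse_blocking(text: str) -> BlockingSpec:
    parts = text.split(":")
    if len(parts) > 3 or not parts[0]:
        raise ConfigError(f"bad blocking spec {text!r} (attr[:k[:alphabet]])")
    attr = parts[0]
    try:
        k = int(parts[1]) if len(parts) > 1 else 3
    except ValueError:
        raise ConfigError(f"bad blocking k in {text!r}")
    alphabet = parts[2] if len(parts) > 2 else "letters26"
    return BlockingSpec(attr, k, alphabet)


def read_config(path: str | Path) -> Config:
    """Parse a configuration file in the flat key = value format above."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        if key not in _CONFIG_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        if key in raw:
            raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
        raw[key] = value.strip()
    return config_from_strings(raw)


def config_from_strings(raw: Mapping[str, str]) -> Config:
    """Build a Config from string-valued settings (shared by file + CLI paths)."""
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for required in ("blocking", "comparison", "threshold"):
        if required not in raw or not raw[required]:
            raise ConfigError(f"missing required config key {required!r}")
    blocking = [_parse_blocking(t.strip()) for t in raw["blocking"].split(",")]
    comparison = [t.strip() for t in raw["comparison"].split(",") if t.strip()]
    try:
        threshold = int(raw["threshold"])
    except ValueError:
        raise ConfigError(f"threshold must be an integer, got {raw['threshold']!r}")
    priority = [t.strip() for t in raw.get("priority", "").split(",") if t.strip()]
    proportional = None
    if raw.get("proportional"):
        try:
            proportional = float(raw["proportional"])
        except ValueError:
            raise ConfigError(f"bad proportional ratio {raw['proportional']!r}")
    return Config(
        blocking_specs=blocking,
        comparison_attributes=comparison,
        threshold=threshold,
        distance_method=raw.get("method", "edit") or "edit",
        priority_attributes=priority,
        truth_attribute=raw.get("truth") or None,
        proportional_ratio=proportional,
    )


def corpus_records(datasets: Sequence[Dataset]) -> dict[RecordId, Record]:
    """Index every record of a dataset collection by its corpus-wide id."""
    corpus: dict[RecordId, Record] = {}
    for ds in datasets:
        for rec in ds.records:
            if rec.rid in corpus:
                raise DatasetFormatError(f"duplicate record id {rec.rid}")
            corpus[rec.rid] = rec
    return corpus
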