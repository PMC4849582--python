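"""k-mer blocking of representative records.

All-pairs comparison is quadratic; blocking restricts candidate pairs to
records sharing at least one k-mer (length-k substring) of a blocking
attribute.  A value of length l contributes l − k + 1 k-mers, so over a
26-, 10- or 36-character alphabet at most 26^k, 10^k or 36^k blocks exist.
Two slightly different spellings of the same attribute almost always keep a
k-mer in common and therefore still meet in at least one block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .datasets_io import ALPHABETS, PAD, BlockingSpec, Record, RecordId

#: Block key for records whose normalized blocking value is empty; such
#: records are never silently dropped.
OVERFLOW_KEY = "\x00overflow"

def _normalize(value: str, alphabet: str) -> str:
    allowed = ALPHABETS[alphabet]
    return "".join(ch for ch in value.upper() if ch in allowed)


def kmers(value: str, k: int, alphabet: str = "letters26") -> list[str]:
    """Distinct k-mers of a normalized value, in first-occurrence order.

    Characters outside the declared alphabet are removed before windowing.
    A non-empty value shorter than k yields one key padded to length k with
    the reserved pad character; an empty normalized value yields no keys
    (the caller files the record under the overflow block).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    cleaned = _normalize(value, alphabet)
    if not cleaned:
        return []
    if len(cleaned) < k:
        return [cleaned.ljust(k, PAD)]
    seen: set[str] = set()
    out: list[str] = []
    for i in range(len(cleaned) - k + 1):
        mer = cleaned[i : i + k]
        if mer not in seen:
            seen.add(mer)
            out.append(mer)
    return out


@dataclass(slots=True)
class BlockIndex:
    """Mapping (attribute, k-mer) -> set of representative ids for one spec."""

    spec: BlockingSpec
    blocks: dict[tuple[str, str], set[RecordId]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def alphabet(self) -> str:
        return self.spec.alphabet

    def n_blocks(self) -> int:
        return len(self.blocks)

    def total_entries(self) -> int:
        return sum(len(members) for members in self.blocks.values())


def build_block_index(
    representatives: Iterable[Record], spec: BlockingSpec
) -> BlockIndex:
    """Index representatives by the k-mers of one blocking attribute.

    Records lacking the attribute are skipped for this spec; records whose
    normalized value is empty go to a single overflow block instead.
    Duplicate k-mers within one value insert once, so block sizes count
    distinct records.
    """
    index = BlockIndex(spec)
    blocks = index.blocks
    attr = spec.attribute
    for rec in representatives:
        value = rec.folded.get(attr)
        if value is None:
            continue
        mers = kmers(value, spec.k, spec.alphabet)
        if not mers:
            blocks.setdefault((attr, OVERFLOW_KEY), set()).add(rec.rid)
            continue
        for mer in mers:
            blocks.setdefault((attr, mer), set()).add(rec.rid)
    return index


def merge_block_indexes(parts: Sequence[BlockIndex]) -> BlockIndex:
    """Union partial indexes built from shards of the representative set."""
    if not parts:
        raise ValueError("no partial indexes to merge")
    merged = BlockIndex(parts[0].spec)
    for part in parts:
        if part.spec != merged.spec:
            raise ValueError("cannot merge indexes with different specs")
        for key, members in part.blocks.items():
            merged.blocks.setdefault(key, set()).update(members)
    return merged


def block_capacity(alphabet_size: int, k: int) -> int:
    """Number of possible blocks: alphabet_size ** k."""
    if alphabet_size not in (26, 10, 36):
        raise ValueError(f"unsupported alphabet size {alphabet_size}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return alphabet_size**k

def expected_block_load(
    n_records: int, value_length: int, alphabet_size: int, k: int
) -> float:
    """Average records per block if every possible block were populated.

    Each record enters value_length − k + 1 blocks, so the expected load is
    n_records * (value_length − k + 1) / alphabet_size**k.
    """
    if value_length < k:
        raise ValueError(
            f"value length {value_length} shorter than k={k}"
        )
    return n_records * (value_length - k + 1) / block_capacity(alphabet_size, k)
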