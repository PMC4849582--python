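"""Synthetic multi-source corpora with known ground truth.

Three generation schemes emulate increasingly hostile conditions, all built
from one base population whose records carry first_name, last_name, ssn and
dob attributes (the SSN is unique per individual and serves as ground
truth; corruption never touches it):

* type 1 — the base dataset replicated ``copies`` times; in every copy each
  record's last name independently receives one random insertion, deletion
  or substitution with probability ``error_probability`` (default 0.15).
* type 2 — a high-error mixture: four clean replicas plus two
  fully-corrupted replicas (every record edited once) used three times
  each, ten datasets in all.
* type 3 — three attribute-reduced replicas with distinct schemas, every
  record's last name edited once, and each replica cloned verbatim, so the
  exact-matching phase can halve the representative count.

Last names are synthesized, not sampled from name lists: each individual
gets a codeword over five disjoint per-position alphabets (base-5 payload
repeated five times), which guarantees pairwise Levenshtein distance >= 5
between distinct individuals.  With at most one edit per generated record,
records of different individuals stay at distance >= 3 while records of the
same individual stay within 2, so a threshold of 2 separates them exactly;
accuracy properties of the pipeline become provable instead of depending on
an (unknowable) real name distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets_io import Config, Dataset, Record

#: Disjoint per-position alphabets for coded last names; a cycle of five
#: means any alignment offset of 1–4 pairs characters from disjoint sets.
POSITION_ALPHABETS = ("AEIOU", "BCDFG", "HJKLM", "NPQRS", "TVWXZ")

#: Each base-5 payload is repeated this many times, making the pairwise
#: Hamming (hence Levenshtein) distance between distinct codes >= REPEAT.
REPEAT = 5

#: Characters drawn for insertion / substitution errors.
CORRUPTION_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

BASE_SCHEMA = ["first_name", "last_name", "ssn", "dob"]

#: Minimum pairwise distance between distinct individuals' comparison
#: strings; must exceed 2 * the documented default threshold (tau = 2).
MIN_SEPARATION = REPEAT


@dataclass(slots=True)
class GeneratorSpec:
    """Parameters of one synthetic corpus."""

    n_individuals: int
    copies: int = 10
    error_probability: float = 0.15
    seed: int = 0
    schema: list[str] = field(default_factory=lambda: list(BASE_SCHEMA))
    attribute_drop_plan: list[list[str]] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.copies < 1:
            raise ValueError("need at least one copy")
        if not 0 <= self.error_probability <= 1:
            raise ValueError("error probability must be in [0, 1]")


def _digits(value: int, base: int, width: int) -> list[int]:
    out = []
    for _ in range(width):
        out.append(value % base)
        value //= base
    return out[::-1]


def _coded_last_name(index: int, width: int) -> str:
    """Codeword with pairwise Levenshtein >= REPEAT between distinct indices."""
    payload = _digits(index, 5, width)
    chars = []
    for rep in range(REPEAT):
        for t, d in enumerate(payload):
            j = rep * width + t
            chars.append(POSITION_ALPHABETS[j % 5][d])
    return "".join(chars)


def _first_name(index: int, width: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return "".join(letters[d] for d in _digits(index, 26, width))


def generate_base(
    n: int,
    seed: int,
    code_digits: int | None = None,
    first_len: int | None = None,
) -> Dataset:
    """The error-free base population: one record per individual.

    Attributes: first_name (unique), last_name (unique, pairwise distance
    >= 5), ssn (unique 9-digit, the truth key), dob.  Deterministic under
    the seed.  Passing ``code_digits`` explicitly caps the last-name pool at
    5**code_digits individuals.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    if code_digits is None:
        code_digits = max(4, math.ceil(math.log(max(n, 2), 5)))
    if 5**code_digits < n:
        raise ValueError(
            f"{n} individuals exceed the {5**code_digits}-name capacity of "
            f"code_digits={code_digits}; increase code_digits for a larger pool"
        )
    if first_len is None:
        first_len = max(4, math.ceil(math.log(max(n, 2), 26)))
    if 26**first_len < n:
        raise ValueError(
            f"{n} individuals exceed the {26 ** first_len}-name capacity of "
            f"first_len={first_len}; increase first_len for a larger pool"
        )
    rng = np.random.default_rng(seed)
    last_idx = rng.permutation(5**code_digits)[:n]
    first_idx = rng.permutation(26**first_len)[:n]
    # affine bijection on 9-digit numbers -> unique SSNs
    a = int(rng.integers(1, 10**9))
    while math.gcd(a, 10**9) != 1:
        a += 1
    b = int(rng.integers(0, 10**9))
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    years = rng.integers(1940, 2006, size=n)
    records = []
    for i in range(n):
        values = {
            "first_name": _first_name(int(first_idx[i]), first_len),
            "last_name": _coded_last_name(int(last_idx[i]), code_digits),
            "ssn": f"{(a * i + b) % 10**9:09d}",
            "dob": f"{months[i]:02d}{days[i]:02d}{years[i]}",
        }
        records.append(Record("base", i, values))
    return Dataset("base", list(BASE_SCHEMA), records)


def corrupt_one_edit(
    value: str, rng: np.random.Generator, alphabet: str = CORRUPTION_ALPHABET
) -> str:
    """Apply exactly one random edit; the result is at distance 1.

    The operation (insertion, deletion, substitution), position and
    character are uniform over the valid choices; substitution always picks
    a character different from the original, and a deletion drawn for an
    empty string is re-drawn.
    """
    while True:
        op = int(rng.integers(3))
        if op != 1 or value:
            break
    if op == 0:  # insertion
        pos = int(rng.integers(len(value) + 1))
        ch = alphabet[int(rng.integers(len(alphabet)))]
        return value[:pos] + ch + value[pos:]
    if op == 1:  # deletion
        pos = int(rng.integers(len(value)))
        return value[:pos] + value[pos + 1 :]
    if not value:
        raise ValueError("cannot substitute in an empty value")
    pos = int(rng.integers(len(value)))
    choices = alphabet.replace(value[pos], "") or alphabet
    ch = choices[int(rng.integers(len(choices)))]
    return value[:pos] + ch + value[pos:][1:]


def _replicate(
    base: Dataset,
    dataset_id: str,
    rng: np.random.Generator,
    error_probability: float,
    attributes: list[str] | None = None,
) -> Dataset:
    """Copy the base dataset, corrupting last names at the given rate."""
    attrs = list(base.attributes) if attributes is None else list(attributes)
    if error_probability > 0:
        mask = rng.random(len(base.records)) < error_probability
    else:
        mask = np.zeros(len(base.records), dtype=bool)
    records = []
    for i, rec in enumerate(base.records):
        values = {a: rec.values[a] for a in attrs}
        if mask[i] and "last_name" in values:
            values["last_name"] = corrupt_one_edit(values["last_name"], rng)
        records.append(Record(dataset_id, i, values))
    return Dataset(dataset_id, attrs, records)


def generate_type1(spec: GeneratorSpec) -> list[Dataset]:
    """``copies`` replicas with per-record corruption probability p."""
    base = generate_base(spec.n_individuals, spec.seed)
    rng = np.random.default_rng([spec.seed, 1])
    return [
        _replicate(base, f"t1_{c:02d}", rng, spec.error_probability)
        for c in range(spec.copies)
    ]


def generate_type2(spec: GeneratorSpec) -> list[Dataset]:
    """High-error mixture: 4 clean replicas + 2 fully-corrupted ones x 3.

    The mixture plan is fixed at ten datasets; every record of a corrupted
    replica differs from its original by exactly one last-name edit.
    """
    base = generate_base(spec.n_individuals, spec.seed)
    rng = np.random.default_rng([spec.seed, 2])
    corrupted = [
        _replicate(base, f"corrupt{v}", rng, 1.0) for v in range(2)
    ]
    datasets = []
    plan = [None, None, None, None, 0, 0, 0, 1, 1, 1]
    for c, which in enumerate(plan):
        ds_id = f"t2_{c:02d}"
        if which is None:
            source = base
        else:
            source = corrupted[which]
        records = [
            Record(ds_id, r.row_index, dict(r.values)) for r in source.records
        ]
        datasets.append(Dataset(ds_id, list(source.attributes), records))
    return datasets


DEFAULT_DROP_PLAN = [
    ["first_name", "last_name", "ssn", "dob"],
    ["first_name", "last_name", "ssn"],
    ["first_name", "last_name"],
]


def generate_type3(spec: GeneratorSpec) -> list[Dataset]:
    """Three schema-reduced fully-corrupted replicas, each cloned verbatim.

    The drop plan gives each replica a distinct attribute subset (default:
    a chain, so every pair of schemas is comparable); cloning makes every
    record an exact duplicate of its twin, which the exact-matching phase
    collapses.
    """
    plan = spec.attribute_drop_plan or DEFAULT_DROP_PLAN
    if len({frozenset(attrs) for attrs in plan}) != len(plan):
        raise ValueError("attribute drop plan schemas must be pairwise distinct")
    kept_everywhere = set.intersection(*(set(p) for p in plan))
    if "last_name" not in kept_everywhere or "first_name" not in kept_everywhere:
        warnings.warn(
            "drop plan removes a comparison-critical attribute from some "
            "copies; linkage quality will degrade",
            stacklevel=2,
        )
    base = generate_base(spec.n_individuals, spec.seed)
    rng = np.random.default_rng([spec.seed, 3])
    datasets = []
    for v, attrs in enumerate(plan):
        reduced = _replicate(base, f"t3_{v}", rng, 1.0, attributes=attrs)
        datasets.append(reduced)
        clone_id = f"t3_{v}c"
        clone_records = [
            Record(clone_id, r.row_index, dict(r.values))
            for r in reduced.records
        ]
        datasets.append(Dataset(clone_id, list(attrs), clone_records))
    return datasets


def simulation_config(threshold: int = 2, k: int = 3,
                      priority: list[str] | None = None) -> Config:
    """The standard linkage configuration for the synthetic corpora."""
    from .datasets_io import BlockingSpec

    return Config(
        blocking_specs=[BlockingSpec("first_name", k, "letters26")],
        comparison_attributes=["first_name", "last_name"],
        threshold=threshold,
        priority_attributes=list(priority) if priority else [],
        truth_attribute="ssn",
    )


def worked_example_fixture() -> tuple[list[Dataset], Config]:
    """The five-record two-dataset example and its stated configuration.

    Dataset A: Cade Bale, Cade Bolt, Thor Glenn; dataset B: Thor Glenn,
    Cade Balt.  Blocking on 3-mers of the first name, comparison on first
    and last name with threshold 1, date of birth as the priority field.
    """
    from .datasets_io import BlockingSpec

    a_rows = [
        ("Cade", "Bale", "05011976"),
        ("Cade", "Bolt", "05021986"),
        ("Thor", "Glenn", "12011990"),
    ]
    b_rows = [
        ("Thor", "Glenn", "12011990"),
        ("Cade", "Balt", "05011976"),
    ]
    attrs = ["first_name", "last_name", "dob"]

    def build(ds_id: str, rows) -> Dataset:
        return Dataset(
            ds_id,
            list(attrs),
            [
                Record(ds_id, i, dict(zip(attrs, row)))
                for i, row in enumerate(rows)
            ],
        )

    config = Config(
        blocking_specs=[BlockingSpec("first_name", 3, "letters26")],
        comparison_attributes=["first_name", "last_name"],
        threshold=1,
        priority_attributes=["dob"],
    )
    return [build("A", a_rows), build("B", b_rows)], config


def worked_example_truth() -> dict:
    """Per-individual ground truth for the worked example's five records."""
    return {
        ("A", 0): "cade-bale",
        ("A", 1): "cade-bolt",
        ("A", 2): "thor-glenn",
        ("B", 0): "thor-glenn",
        ("B", 1): "cade-bale",
    }
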