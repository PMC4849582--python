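import random

import pytest
from hypothesis import settings

from completelink import (
    BlockingSpec,
    Config,
    Dataset,
    Record,
    worked_example_fixture,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60
)
settings.load_profile("suite")


def dp_levenshtein(a: str, b: str) -> int:
    """Full O(n*m) dynamic-programming edit distance (independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (ca != cb),
                )
            )
        prev = cur
    return prev[-1]


def make_dataset(ds_id, attrs, rows):
    return Dataset(
        ds_id,
        list(attrs),
        [Record(ds_id, i, dict(zip(attrs, row))) for i, row in enumerate(rows)],
    )


def random_string(rng: random.Random, alphabet: str, lo: int, hi: int) -> str:
    return "".join(
        rng.choice(alphabet) for _ in range(rng.randint(lo, hi))
    )


@pytest.fixture
def worked_example():
    return worked_example_fixture()


@pytest.fixture
def chaining_example():
    """Three records whose distances are 1-1-2: the chaining fixture."""
    ds = make_dataset("S", ["status"], [("sweat",), ("sheat",), ("heat",)])
    config = Config(
        blocking_specs=[BlockingSpec("status", 3, "letters26")],
        comparison_attributes=["status"],
        threshold=1,
    )
    return [ds], config
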