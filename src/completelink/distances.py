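"""Threshold-bounded string and record distances.

Every comparison is bounded by the user threshold τ: once a distance can no
longer come in at or under τ the computation short-circuits and returns the
distinguished :data:`EXCEEDS` token instead of a number.  The bounded
Levenshtein computation itself is delegated to edlib's banded bit-vector
alignment (O(τ·min(len)) instead of the full O(len²) dynamic program).

Record distance is the SUM of per-attribute distances over the shared
comparison attributes, capped by a single global τ with early abort — not a
concatenated-string distance, which could create spurious cross-boundary
alignments.

Two distance variants reduce to plain edit distance: reversal edit distance
takes the better of the two orientations of the first string, and truncation
edit distance first truncates the longer value to the length of the shorter
(the truncation itself is free).
"""

from __future__ import annotations

import edlib

from .datasets_io import Config, Record


class Exceeds:
    """Distinguished token for a distance that exceeds the threshold."""

    __slots__ = ("reason",)

    def __init__(self, reason: str) -> None:
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"EXCEEDS({self.reason})"


#: The distance surpassed the threshold.
EXCEEDS = Exceeds("threshold")
#: The two records share no configured comparison attribute.
NO_SHARED_ATTRIBUTES = Exceeds("no shared comparison attribute")

BoundedDistance = "int | Exceeds"


def is_exceeds(d) -> bool:
    return isinstance(d, Exceeds)


def edit_distance_bounded(a: str, b: str, tau: int):
    """Levenshtein distance if ≤ τ, else EXCEEDS.

    Unit-cost insertions, deletions and substitutions.  Degenerate inputs
    (equal or empty strings, length gap beyond τ) are resolved without
    running the aligner.
    """
    if tau < 0:
        raise ValueError(f"threshold must be >= 0, got {tau}")
    if a == b:
        return 0
    gap = abs(len(a) - len(b))
    if gap > tau:
        return EXCEEDS
    if not a or not b:
        # distance is the other string's length; edlib mishandles empty input
        return gap
    d = edlib.align(a, b, mode="NW", task="distance", k=tau)["editDistance"]
    if d < 0 or d > tau:
        return EXCEEDS
    return d


def reversal_edit_distance(a: str, b: str, tau: int):
    """min(edit(a, b), edit(reverse(a), b)), bounded by τ."""
    d1 = edit_distance_bounded(a, b, tau)
    d2 = edit_distance_bounded(a[::-1], b, tau)
    numeric = [d for d in (d1, d2) if not is_exceeds(d)]
    return min(numeric) if numeric else EXCEEDS


def truncation_edit_distance(a: str, b: str, tau: int):
    """Edit distance after freely truncating the longer string, bounded by τ."""
    if len(a) > len(b):
        a = a[: len(b)]
    elif len(b) > len(a):
        b = b[: len(a)]
    return edit_distance_bounded(a, b, tau)


_METHODS = {
    "edit": edit_distance_bounded,
    "reversal": reversal_edit_distance,
    "truncation": truncation_edit_distance,
}


def record_distance(r1: Record, r2: Record, config: Config):
    """Summed per-attribute bounded distance between two records.

    Only comparison attributes present in both schemas are compared; with no
    shared attribute the result is EXCEEDS carrying that reason.  The running
    sum aborts to EXCEEDS as soon as it cannot stay within the (possibly
    proportional) pair threshold.
    """
    shared = [
        a
        for a in config.comparison_attributes
        if a in r1.folded and a in r2.folded
    ]
    if not shared:
        return NO_SHARED_ATTRIBUTES
    per_attr = _METHODS[config.distance_method]
    if config.proportional_ratio is not None:
        len1 = sum(len(r1.folded[a]) for a in shared)
        len2 = sum(len(r2.folded[a]) for a in shared)
        tau = config.pair_threshold(len1, len2)
    else:
        tau = config.threshold
    total = 0
    for attr in shared:
        d = per_attr(r1.folded[attr], r2.folded[attr], tau - total)
        if is_exceeds(d):
            return EXCEEDS
        total += d
    return total
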