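"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def round_sig(x: float, digits: int = 2) -> float:
    """Round ``x`` to ``digits`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, digits - 1 - exponent)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq))


def merge_intervals(intervals):
    """Merge overlapping/adjacent 1-based inclusive (start, end) intervals."""
    if not intervals:
        return []
    ordered = sorted((int(a), int(b)) for a, b in intervals)
    merged = [list(ordered[0])]
    for start, end in ordered[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def rng_from(seed) -> np.random.Generator:
    """Accept an int seed, ``None`` or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
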