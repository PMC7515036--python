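"""Independent brute-force oracles for the test suite.

Everything here avoids the package's bit machinery on purpose: patterns
are labelled by rank permutations (tuples), words by tuples of those, and
frequencies come from ``collections.Counter``.
"""

from __future__ import annotations

import math
from collections import Counter


def rank_pattern(window) -> tuple[int, ...]:
    """Canonical label of a window's ordinal pattern.

    The argsort of (value, index) is shared by two windows exactly when
    every pairwise comparison — with ties broken toward the earlier
    index — agrees.
    """
    w = list(window)
    return tuple(sorted(range(len(w)), key=lambda i: (w[i], i)))


def naive_binary(window) -> tuple[int, ...]:
    """Direct evaluation of the comparison-bit encoding."""
    d = len(window) - 1
    return tuple(
        sum(2**l for l in range(k) if window[l] > window[k])
        for k in range(1, d + 1)
    )


def naive_words(x, d: int, m: int) -> list[tuple]:
    """All ordinal words of configuration (d, m), unpadded."""
    x = list(x)
    return [
        tuple(rank_pattern(x[n + j : n + j + d + 1]) for j in range(m))
        for n in range(len(x) - d - m + 1)
    ]


def naive_counts(x, d: int, m: int) -> Counter:
    return Counter(naive_words(x, d, m))


def naive_entropy(x, d: int, m: int) -> float:
    """Empirical Shannon entropy of configuration (d, m) from raw counting."""
    counts = naive_counts(x, d, m)
    n_real = len(x) - d - m + 1
    assert sum(counts.values()) == n_real
    return math.log(n_real) - sum(h * math.log(h) for h in counts.values()) / n_real


def entropy_of_counts(counts, n: int) -> float:
    return math.log(n) - sum(h * math.log(h) for h in counts) / n
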