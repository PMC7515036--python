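"""Ordinal-word transformations and sort-based frequency counting.

An ordinal word of configuration ``(d, m)`` is a run of ``m`` successive
order-``d`` patterns.  Because successive patterns overlap, the word is
representable as the order-``(d+m-1)`` pattern of the covering window with
some comparison bits discarded: entry ``k > d`` keeps only its top ``d``
bits (the comparisons reaching back further than ``d`` steps do not belong
to any of the ``m`` constituent patterns).  Two bulk transformations
therefore generate every word configuration from the single order-``D``
pattern array:

* :func:`order_down` — ``(d, m) -> (d-1, m+1)`` by zeroing one more low
  bit in each trailing entry (a right shift followed by a left shift);
* :func:`truncate_length` — ``(d, m) -> (d, m')`` by dropping trailing
  entries.

Counting runs on a *padded* array: the series is conceptually continued by
``D - 1`` maximal elements so that every configuration has all its words
among the same ``N`` rows, and the trailing rows that carry artificial
information are overwritten with sentinel values ``2**k`` — one above the
largest legal entry — which keeps each of them unique under every later
transformation.  Unique rows have frequency 1 and ``1·ln 1 = 0``, so they
drop out of the entropy sum without ever being removed (the frequency
trick).

Frequencies for *all* word lengths at one order come from a single
lexicographic sort: after sorting, a change within the first
``d + m - 1`` entries between adjacent rows marks a block boundary for
length ``m``, and boundaries for shorter lengths are prefixes of the same
comparison, so one cumulative OR over the per-entry inequalities serves
every length at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import PatternArray, all_patterns


@dataclass
class FrequencyTable:
    """Absolute frequencies of the distinct words of one configuration.

    ``counts`` includes the sentinel-derived singletons of the padded
    pipeline; ``n_real`` is the number of words free of artificial
    information (``N - d - m + 2``), the normaliser of the entropy formula.
    """

    order: int
    word_length: int
    counts: np.ndarray
    n_real: int


def pad_and_adjust(patterns: PatternArray, n: int) -> PatternArray:
    """Overwrite the artificial entries of an extended pattern array.

    ``patterns`` must hold the order-``D`` patterns of a series continued
    by ``D - 1`` artificial maximal elements — ``n`` rows in total, where
    ``n`` is the series' last index (points minus one).  Row
    ``n - D + j`` (``j = 1..D-1``) has its last ``j`` entries replaced by
    the sentinel values ``2**k`` at columns ``k = D-j+1..D``.  Each entry
    exceeds the largest legal value ``2**k - 1`` at its column, so every
    sentinel row — and every word later derived from it that still touches
    artificial data — is unique in any frequency count.
    """
    D = patterns.order
    if n < D:
        raise ValueError(f"need n >= D, got n={n}, D={D}")
    if patterns.word_length != 1:
        raise ValueError("padding applies to pure pattern arrays (m=1)")
    if patterns.n_rows != n:
        raise ValueError(
            f"extended array must have {n} rows, got {patterns.n_rows}"
        )
    data = patterns.data.copy()
    for j in range(1, D):
        row = n - D + j
        for k in range(D - j + 1, D + 1):
            data[row, k - 1] = np.uint64(1) << np.uint64(k)
    return PatternArray(data, order=D, sentinel_rows=D - 1)


def padded_patterns(series, max_order: int) -> PatternArray:
    """Padded order-``D`` pattern array of a series: the pipeline's input."""
    x = np.asarray(series)
    ext = all_patterns(x, max_order, extend=True)
    return pad_and_adjust(ext, x.size - 1)


def order_down(words: PatternArray) -> PatternArray:
    """Transform configuration ``(d, m)`` into ``(d-1, m+1)``.

    Zeroes the lowest ``k - (d - 1)`` bits of every entry ``k > d - 1`` —
    the comparisons that reach back further than ``d - 1`` steps.  The
    vector length is unchanged.  Bit masking is monotone, so sentinel
    entries stay strictly above every real entry at the same column.
    """
    d = words.order
    if d < 2:
        raise ValueError("cannot reduce below order 1")
    data = words.data.copy()
    for k in range(d, words.vector_length + 1):
        s = np.uint64(k - (d - 1))
        data[:, k - 1] = (data[:, k - 1] >> s) << s
    return PatternArray(
        data,
        order=d - 1,
        word_length=words.word_length + 1,
        sentinel_rows=words.sentinel_rows,
    )


def truncate_length(words: PatternArray, m_new: int) -> PatternArray:
    """Drop trailing entries: configuration ``(d, m)`` to ``(d, m_new)``."""
    if not 1 <= m_new <= words.word_length:
        raise ValueError(
            f"m_new must be in [1, {words.word_length}], got {m_new}"
        )
    d = words.order
    return PatternArray(
        words.data[:, : d + m_new - 1].copy(),
        order=d,
        word_length=m_new,
        sentinel_rows=words.sentinel_rows,
    )


def sort_and_count(words: PatternArray, n: int) -> dict[int, FrequencyTable]:
    """Word frequencies for every length ``m' = 1..m`` from one sort.

    ``words`` is a padded array at configuration ``(d, m)`` with ``n``
    rows; ``n`` is the series' last index.  Rows are sorted
    lexicographically with entry 1 most significant.  Adjacent sorted rows
    are then compared entrywise; the cumulative OR of the inequalities over
    the first ``d + m' - 1`` entries marks the block boundaries for length
    ``m'`` — a change in an early entry separates words of every length,
    which is what the shared sort exploits.

    Returns ``{m': FrequencyTable}`` with ``n_real = N - d - m' + 2``
    words free of artificial information (``N = n``, the series' last
    index).
    """
    data = words.data
    d = words.order
    rows = data.shape[0]
    if rows != n:
        raise ValueError(f"padded array must have {n} rows, got {rows}")
    # lexsort: last key is primary, so feed columns in reverse
    order = np.lexsort(tuple(data[:, j] for j in range(data.shape[1] - 1, -1, -1)))
    s = data[order]
    neq = s[1:] != s[:-1]
    change = np.logical_or.accumulate(neq, axis=1)
    out: dict[int, FrequencyTable] = {}
    for m in range(1, words.word_length + 1):
        width = d + m - 1
        boundaries = np.flatnonzero(change[:, width - 1]) + 1
        edges = np.concatenate(([0], boundaries, [rows]))
        counts = np.diff(edges)
        out[m] = FrequencyTable(
            order=d, word_length=m, counts=counts, n_real=n - d - m + 2
        )
    return out
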