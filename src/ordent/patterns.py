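"""Binary-vector encoding of ordinal patterns.

An ordinal pattern of order ``d`` is the equivalence class of a window of
``d + 1`` consecutive values under order isomorphism: two windows share a
pattern iff every pairwise comparison comes out the same way.  There are
``(d+1)!`` such classes, and a window of ``d + 1`` points carries
``(d+1)d/2`` atomic comparisons.

The representation used throughout this package packs, for each window
position ``k = 1..d``, the ``k`` comparison bits of that point against all
earlier points into one unsigned integer::

    b_k = sum_{0 <= l < k} [x_l > x_k] * 2**l

with the least-significant bit referring to the earliest point.  Ties
contribute zero bits (the comparison is strict).  The pay-off of this
encoding is that the pattern of the next overlapping window is obtained by
right bit shifts — the comparisons against the dropped first point are
exactly the low bits — so a whole series can be encoded column by column
with one vectorised comparison sweep plus shifts.

Entries are stored as ``uint64``.  A pattern entry needs up to ``d`` bits
and the sentinel values used by the padded counting pipeline need one more,
so the order is capped at 62.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Largest supported pattern order: entries use up to ORDER_CAP bits and the
#: sentinel padding scheme needs one extra bit within uint64 storage.
ORDER_CAP = 62


class CapacityError(ValueError):
    """Requested order exceeds the bit width of the pattern storage."""


@dataclass
class PatternArray:
    """All ordinal patterns or words of a series for one configuration.

    Rows correspond to window start indices ``n``; columns hold the entries
    of the binary-vector representation.  For a word configuration
    ``(d, m)`` the vector length is ``d + m - 1``: a word of ``m``
    successive order-``d`` patterns is stored as the bit-masked prefix of
    the order-``(d+m-1)`` pattern, where every entry ``k > d`` has its
    lowest ``k - d`` bits zeroed.

    ``sentinel_rows`` counts trailing rows that carry artificial
    information from the padded counting pipeline; those rows contain
    entries equal to ``2**k`` (one above the largest legal value at column
    ``k``), which keeps them unique in any frequency count.
    """

    data: np.ndarray
    order: int
    word_length: int = 1
    sentinel_rows: int = 0

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.uint64)
        if self.data.ndim != 2:
            raise ValueError("pattern data must be a 2-D array")
        if self.vector_length != self.data.shape[1]:
            raise ValueError(
                f"config ({self.order},{self.word_length}) needs "
                f"{self.vector_length} columns, got {self.data.shape[1]}"
            )

    @property
    def vector_length(self) -> int:
        return self.order + self.word_length - 1

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


def _check_order(d: int) -> None:
    if d < 1:
        raise ValueError(f"pattern order must be >= 1, got {d}")
    if d > ORDER_CAP:
        raise CapacityError(f"order {d} exceeds the cap of {ORDER_CAP} bits")


def encode_window(window) -> np.ndarray:
    """Encode one window of ``d + 1`` values as a binary pattern vector.

    Returns a length-``d`` ``uint64`` array with
    ``b_k = sum_{l<k} [x_l > x_k] 2**l``.  Ties give zero bits.
    """
    w = np.asarray(window)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("window must be one-dimensional with at least 2 values")
    d = w.size - 1
    _check_order(d)
    out = np.zeros(d, dtype=np.uint64)
    for k in range(1, d + 1):
        b = 0
        for l in range(k):
            if w[l] > w[k]:
                b |= 1 << l
        out[k - 1] = b
    return out


def _pattern_matrix(x: np.ndarray, order: int, n_rows: int) -> np.ndarray:
    """Column-wise bulk pattern computation.

    Fills an ``(n_rows, order)`` uint64 matrix where row ``n`` is the
    pattern of the window starting at ``x_n``.  Windows reaching past the
    end of ``x`` are treated as continued by values larger than every real
    value, whose comparison bits are all zero; this is how the padded
    pipeline requests ``n_rows`` beyond the last full window.

    The last column is computed by direct vectorised comparisons; every
    earlier column is derived from the next column of the preceding row by
    one right bit shift (the dropped low bit is the comparison against the
    point that left the window).  Only row 0 of each column needs direct
    evaluation.
    """
    D = order
    P = np.zeros((n_rows, D), dtype=np.uint64)
    L = x.size
    # last column: compare x[n+l] > x[n+D] for l = 0..D-1, real targets only
    r = min(n_rows, L - D)
    if r > 0:
        col = np.zeros(r, dtype=np.uint64)
        tgt = x[D:D + r]
        for l in range(D):
            col |= (x[l:l + r] > tgt).astype(np.uint64) << np.uint64(l)
        P[:r, D - 1] = col
    for k in range(D - 1, 0, -1):
        P[1:, k - 1] = P[:-1, k] >> np.uint64(1)
        if k < L:  # row 0, direct
            b = 0
            for l in range(k):
                if x[l] > x[k]:
                    b |= 1 << l
            P[0, k - 1] = b
    return P


def all_patterns(series, max_order: int, *, extend: bool = False) -> PatternArray:
    """Compute the ordinal patterns of every window of a series.

    With ``extend=False`` (the default) the result has one row per full
    window, ``N - D + 1`` rows for a series of ``N + 1`` points.  With
    ``extend=True`` the series is conceptually continued by ``D - 1``
    artificial maximal elements and all ``N`` rows are produced; entries
    that would compare a real point against an artificial one are zero
    (the artificial elements exceed everything, so no real point inverts
    them).  The extended form is the input to
    :func:`ordent.words.pad_and_adjust`.
    """
    x = np.asarray(series)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    D = max_order
    _check_order(D)
    if x.size < D + 1:
        raise ValueError(
            f"series of {x.size} points is too short for order {D} "
            f"(needs at least {D + 1})"
        )
    n_last = x.size - 1  # N: last index of the series
    n_rows = n_last if extend else n_last - D + 1
    return PatternArray(_pattern_matrix(x, D, n_rows), order=D)


def advance_pattern(current, old_window_tail, new_value) -> np.ndarray:
    """Slide a single pattern one step forward (streaming update).

    ``current`` encodes the window ``(x_n, ..., x_{n+d})``;
    ``old_window_tail`` are the ``d`` shared values ``x_{n+1..n+d}`` and
    ``new_value`` is ``x_{n+d+1}``.  The update drops the first entry,
    right-shifts the rest (discarding the comparisons against ``x_n``) and
    appends the ``d`` fresh comparisons against the new value.
    """
    cur = np.asarray(current, dtype=np.uint64)
    d = cur.size
    tail = np.asarray(old_window_tail)
    if tail.size != d:
        raise ValueError(f"window tail must have {d} values, got {tail.size}")
    out = np.empty(d, dtype=np.uint64)
    out[:-1] = cur[1:] >> np.uint64(1)
    b = 0
    for k in range(d):
        if tail[k] > new_value:
            b |= 1 << k
    out[-1] = b
    return out


def reduce_order(pattern, d_new: int) -> np.ndarray:
    """Pattern of the window's first ``d_new + 1`` points: a prefix."""
    p = np.asarray(pattern, dtype=np.uint64)
    if not 1 <= d_new <= p.size:
        raise ValueError(f"d_new must be in [1, {p.size}], got {d_new}")
    return p[:d_new].copy()


def to_inversion_vector(pattern) -> np.ndarray:
    """Inversion vector: ``i_k`` counts predecessors larger than ``x_k``.

    Each entry is the population count of the corresponding binary-vector
    entry — the set bits of ``b_k`` are exactly the inversions of ``x_k``.
    """
    p = np.asarray(pattern, dtype=np.uint64)
    return np.array([int(v).bit_count() for v in p], dtype=np.int64)


def to_permutation(pattern) -> np.ndarray:
    """Rank permutation ``pi`` with ``pi_k = #{l : x_l < x_k, or tied with l < k}``.

    Reconstructed from the comparison bits alone; ties are broken toward
    the earlier index, so the result is a permutation of ``{0, ..., d}``
    even for windows with equal values.
    """
    p = np.asarray(pattern, dtype=np.uint64)
    d = p.size
    # gt[k-1][l] == True iff x_l > x_k (strict), for l < k
    gt = [[bool((int(p[k - 1]) >> l) & 1) for l in range(k)] for k in range(1, d + 1)]
    pi = np.empty(d + 1, dtype=np.int64)
    for k in range(d + 1):
        rank = 0
        for l in range(d + 1):
            if l == k:
                continue
            if l < k:
                # x_l < x_k strictly, or tie (tie-break: earlier index first)
                rank += 0 if gt[k - 1][l] else 1
            else:
                # l > k: x_l < x_k strictly, i.e. bit k of b_l set
                rank += 1 if (int(p[l - 1]) >> k) & 1 else 0
        pi[k] = rank
    return pi


def to_factorial_number(iv) -> int:
    """Map an inversion vector to its factorial-number-system integer.

    ``sum_{l=1..d} l! * i_l`` is a bijection from inversion vectors of
    order ``d`` onto ``{0, ..., (d+1)! - 1}`` — the most compact single-
    integer pattern representation.
    """
    v = np.asarray(iv)
    total = 0
    fact = 1
    for l, i_l in enumerate(v, start=1):
        fact *= l
        i_l = int(i_l)
        if not 0 <= i_l <= l:
            raise ValueError(f"inversion vector entry {l} out of range: {i_l}")
        total += fact * i_l
    return total
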