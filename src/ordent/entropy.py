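"""Empirical Shannon entropies of ordinal words, ePE and eCE.

For a series of ``N + 1`` points, word configuration ``(d, m)`` and
absolute word frequencies ``h_w`` over the ``N - d - m + 2`` words, the
empirical Shannon entropy (in nats) is

    H(d, m) = ln(N - d - m + 2) - (1 / (N - d - m + 2)) * sum_w h_w ln h_w.

The *entropy triangle* collects ``H(d, m)`` for every configuration with
``d + m <= D + 1`` — all words spanning at most ``D + 1`` consecutive
points — computed from a single padded pattern array by the masking
transformations, with one lexicographic sort per order.

Two derived series estimate the Kolmogorov–Sinai entropy of a system that
generated the data:

* ePE, the empirical permutation entropy ``H(d, 1) / d``, bounded above by
  ``ln((d+1)!) / d``;
* eCE, the empirical conditional entropy of ordinal patterns
  ``H(d, 2) - H(d, 1)``, which in practice approaches the KS entropy much
  faster in ``d`` than ePE does.

Note on lengths: throughout, ``N`` denotes the series' *last index*; every
public function here takes the series itself and derives ``N = len - 1``
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import PatternArray, _check_order
from .words import FrequencyTable, order_down, padded_patterns, sort_and_count


@dataclass
class EntropyTriangle:
    """``H(d, m)`` in nats for all ``d + m <= max_order + 1``."""

    max_order: int
    values: dict[tuple[int, int], float]
    n_words: dict[tuple[int, int], int]

    def __getitem__(self, dm: tuple[int, int]) -> float:
        return self.values[dm]

    def __len__(self) -> int:
        return len(self.values)

    def epe(self, d: int) -> float:
        return self.values[(d, 1)] / d

    def ece(self, d: int) -> float:
        return self.values[(d, 2)] - self.values[(d, 1)]

    def as_dataframe(self) -> pd.DataFrame:
        rows = [
            (d, m, self.n_words[(d, m)], h)
            for (d, m), h in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["d", "m", "n_words", "H_nats"])


def shannon_entropy(counts: FrequencyTable) -> float:
    """Evaluate the entropy formula on one frequency table.

    Singleton counts contribute ``1 * ln 1 = 0``, so the sentinel-derived
    words of the padded pipeline need no removal.
    """
    if counts.n_real < 1:
        raise ValueError(f"no real words in configuration "
                         f"({counts.order},{counts.word_length})")
    n = counts.n_real
    h = np.asarray(counts.counts, dtype=np.float64)
    h = h[h > 1]  # h == 1 contributes zero
    if h.size == 0:
        return math.log(n)
    # algebraically ln n - sum(h ln h)/n, arranged so that the degenerate
    # cases (one word of frequency n; all singletons) cancel exactly
    log_n = math.log(n)
    return log_n * (1.0 - float(h.sum()) / n) - float(
        np.sum(h * (np.log(h) - log_n))
    ) / n


def _entropies_for_order(series, d: int, m_max: int) -> list[float]:
    """``[H(d, 1), ..., H(d, m_max)]`` via one padded pipeline and one sort."""
    x = np.asarray(series)
    D = d + m_max - 1
    _check_order(D)
    if x.size < D + 1:
        raise ValueError(
            f"series of {x.size} points is too short for configuration "
            f"({d},{m_max}) (needs at least {D + 1})"
        )
    pa = padded_patterns(x, D)
    while pa.order > d:
        pa = order_down(pa)
    tables = sort_and_count(pa, x.size - 1)
    return [shannon_entropy(tables[m]) for m in range(1, m_max + 1)]


def single_entropy(series, d: int, m: int = 1) -> float:
    """Empirical Shannon entropy ``H(d, m)`` of one configuration."""
    if m < 1:
        raise ValueError(f"word length must be >= 1, got {m}")
    return _entropies_for_order(series, d, m)[m - 1]


def entropy_triangle(series, max_order: int) -> EntropyTriangle:
    """All ``D (D + 1) / 2`` entropies ``H(d, m)``, ``d + m <= D + 1``.

    Starts from the padded order-``D`` pattern array and walks the word
    configurations ``(D, 1), (D-1, 2), ..., (1, D)``; at each stop one
    lexicographic sort yields the frequencies of every shorter word length
    by prefix comparison, so the whole triangle costs ``D`` sorts.
    """
    x = np.asarray(series)
    D = max_order
    _check_order(D)
    if x.size < D + 1:
        raise ValueError(
            f"series of {x.size} points is too short for max order {D}"
        )
    n = x.size - 1
    pa = padded_patterns(x, D)
    values: dict[tuple[int, int], float] = {}
    n_words: dict[tuple[int, int], int] = {}
    for d in range(D, 0, -1):
        tables = sort_and_count(pa, n)
        for m, ft in tables.items():
            values[(d, m)] = shannon_entropy(ft)
            n_words[(d, m)] = ft.n_real
        if d > 1:
            pa = order_down(pa)
    return EntropyTriangle(max_order=D, values=values, n_words=n_words)


def epe(series, d: int) -> float:
    """Empirical permutation entropy ``H(d, 1) / d`` in nats."""
    return _entropies_for_order(series, d, 1)[0] / d


def ece(series, d: int) -> float:
    """Empirical conditional entropy of ordinal patterns ``H(d,2) - H(d,1)``."""
    h1, h2 = _entropies_for_order(series, d, 2)
    return h2 - h1


def epe_bound(d: int) -> float:
    """Upper bound ``ln((d+1)!) / d`` of the ePE, via a log-domain sum.

    The bound grows only logarithmically: it is about 2.269 at ``d = 20``
    and still below 4 at ``d = 100``, which caps how large a
    Kolmogorov–Sinai entropy the ePE can ever report.
    """
    if d < 1:
        raise ValueError(f"order must be >= 1, got {d}")
    return sum(math.log(k) for k in range(2, d + 2)) / d
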