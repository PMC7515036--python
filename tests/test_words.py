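"""Padding, word transformations and sort-based frequency counting."""

from collections import Counter

import numpy as np
import pytest

import ordent as oe
from oracles import naive_counts

# configurations (d, m') reachable from max order D: d + m - 1 <= D
def configs(max_order):
    return [
        (d, m)
        for d in range(1, max_order + 1)
        for m in range(1, max_order - d + 2)
    ]


def padded_tables(x, max_order):
    """Counts of every configuration through the padded pipeline."""
    x = np.asarray(x, dtype=float)
    n = x.size - 1
    pa = oe.padded_patterns(x, max_order)
    out = {}
    for d in range(max_order, 0, -1):
        for m, ft in oe.sort_and_count(pa, n).items():
            out[(d, m)] = ft
        if d > 1:
            pa = oe.order_down(pa)
    return out


def test_pad_and_adjust_worked_example(example_series):
    pp = oe.padded_patterns(example_series, 4)
    assert pp.n_rows == 5 and pp.sentinel_rows == 3
    # first two rows untouched
    assert pp.data[:2].tolist() == [[1, 3, 1, 11], [1, 0, 5, 4]]
    # sentinel scheme: row N-D+j gets 2^k at its last j columns
    assert pp.data[2].tolist() == [0, 2, 2, 16]
    assert pp.data[3].tolist() == [1, 1, 8, 16]
    assert pp.data[4].tolist() == [0, 4, 8, 16]


def test_pad_and_adjust_smallest_case():
    pp = oe.padded_patterns([3.0, 1.0, 2.0], 2)
    # single sentinel row, last entry 2^2
    assert pp.sentinel_rows == 1
    assert pp.data[-1, -1] == 4


def test_pad_and_adjust_validation(example_series):
    ext = oe.all_patterns(example_series, 4, extend=True)
    with pytest.raises(ValueError):
        oe.pad_and_adjust(ext, 3)  # n < D
    unpadded = oe.all_patterns(example_series, 4)
    with pytest.raises(ValueError):
        oe.pad_and_adjust(unpadded, 5)  # wrong row count


def test_sentinel_rows_are_singletons_everywhere(rng):
    """Every artificially-informed word of every configuration has count 1."""
    x = rng.random(40)
    n = x.size - 1
    for (d, m), ft in padded_tables(x, 6).items():
        n_art = n - ft.n_real
        assert n_art == d + m - 2
        singles = int(np.sum(ft.counts == 1))
        # at least the artificial rows are singletons; uniqueness is
        # checked exactly against the naive counts below
        assert singles >= n_art


def test_counts_match_bruteforce_for_all_configs(rng):
    """Padded counts = unpadded brute-force counts + one singleton per
    artificial row, for every configuration."""
    for x in (rng.random(30), rng.integers(0, 3, size=35).astype(float)):
        tables = padded_tables(x, 5)
        for (d, m), ft in tables.items():
            expected = Counter(naive_counts(x, d, m).values())
            expected[1] += d + m - 2  # sentinel-derived singletons
            assert Counter(ft.counts.tolist()) == +expected, (d, m)


def test_conservation_total_counts(rng):
    """Under the frequency trick every configuration counts all N rows."""
    x = rng.random(25)
    n = x.size - 1
    for (d, m), ft in padded_tables(x, 6).items():
        assert int(ft.counts.sum()) == n


def test_order_down_masks_reachback_bits():
    """Going from (5,1) to (4,2) zeroes the comparison reaching 5 steps back."""
    w = [9, 1, 8, 2, 7, 3]
    pa = oe.PatternArray(oe.encode_window(w)[None, :], order=5)
    down = oe.order_down(pa)
    assert (down.order, down.word_length) == (4, 2)
    b5 = int(oe.encode_window(w)[4])
    assert down.data[0, :4].tolist() == pa.data[0, :4].tolist()
    assert down.data[0, 4] == (b5 >> 1) << 1  # bit for x0 vs x5 cleared


def test_order_down_repeated_masking_is_idempotent_per_bit(rng):
    x = rng.random(20)
    pa = oe.padded_patterns(x, 6)
    once = oe.order_down(pa)
    # re-masking at the same target changes nothing
    again = oe.PatternArray(
        once.data.copy(), order=once.order + 1, word_length=once.word_length - 1,
        sentinel_rows=once.sentinel_rows,
    )
    assert oe.order_down(again).data.tolist() == once.data.tolist()


def test_order_down_error_below_order_one():
    pa = oe.PatternArray(np.zeros((2, 1), np.uint64), order=1)
    with pytest.raises(ValueError):
        oe.order_down(pa)


def test_truncate_length_identity_and_bounds(example_series):
    pa = oe.padded_patterns(example_series, 4)
    t = oe.truncate_length(pa, 1)
    assert t.data.shape == (5, 4) and t.word_length == 1
    same = oe.truncate_length(pa, pa.word_length)
    assert same.data.tolist() == pa.data.tolist()
    with pytest.raises(ValueError):
        oe.truncate_length(pa, 0)
    with pytest.raises(ValueError):
        oe.truncate_length(pa, 2)


def test_truncation_recovers_lower_order_pattern_array(example_series):
    """Dropping the trailing entry of (4,2) words recovers p(.,4)."""
    pa = oe.padded_patterns(example_series, 5)
    words_42 = oe.order_down(pa)
    p4 = oe.truncate_length(words_42, 1)
    direct = oe.all_patterns(example_series, 4)
    assert p4.data[: direct.n_rows].tolist() == direct.data.tolist()


def test_sort_and_count_visible_duplicates():
    rows = np.array([[0, 0], [0, 0], [1, 3]], dtype=np.uint64)
    pa = oe.PatternArray(rows, order=2)
    ft = oe.sort_and_count(pa, 3)[1]
    assert sorted(ft.counts.tolist()) == [1, 2]


def test_sort_and_count_all_identical():
    pa = oe.PatternArray(np.zeros((7, 3), np.uint64), order=3)
    assert oe.sort_and_count(pa, 7)[1].counts.tolist() == [7]


def test_sort_and_count_matches_hash_oracle(rng):
    """One shared sort reproduces per-length hash-based counting."""
    rows = rng.integers(0, 3, size=(500, 6)).astype(np.uint64)
    pa = oe.PatternArray(rows, order=2, word_length=5)
    tables = oe.sort_and_count(pa, 500)
    for m in range(1, 6):
        width = 2 + m - 1
        expected = Counter(map(tuple, rows[:, :width].tolist()))
        assert sorted(tables[m].counts.tolist()) == sorted(expected.values())


def test_distinct_words_nondecreasing_in_length(rng):
    """Longer words refine shorter ones on the same window set."""
    x = rng.random(60)
    pa = oe.order_down(oe.order_down(oe.padded_patterns(x, 6)))  # (4,3)
    tables = oe.sort_and_count(pa, x.size - 1)
    distinct = [len(tables[m].counts) for m in (1, 2, 3)]
    assert distinct == sorted(distinct)
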