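# Methods

## Ordinal patterns and their representations

A window `(x_n, …, x_{n+d})` of a totally (pre)ordered series carries
`(d+1)d/2` atomic comparisons; the pattern is the set of *inversions*
(pairs `k < l` with `x_k > x_l`).  Four equivalent representations are
implemented and interconvertible:

* **binary vector** `b_k = Σ_{l<k} 1[x_l > x_k] 2^l` (`k = 1..d`) — the
  working representation: entry `k` holds the comparisons of point `k`
  against all earlier points, LSB first;
* **inversion vector** `i_k = popcount(b_k)`;
* **rank permutation** `π_k = #{l : x_l < x_k, or x_l = x_k with l < k}`;
* **factorial-system index** `Σ l!·i_l ∈ {0, …, (d+1)!−1}`.

Comparisons are strict, so tied values contribute no inversion; the
permutation breaks ties toward the earlier index.  This makes the
encoding well defined on data with repeated values (integer-valued or
quantised signals), where `x_l > x_k  ⇔  π_l > π_k` still holds exactly.

Entries are stored as `uint64`.  An entry needs `d` bits and the counting
sentinels need `d + 1`, so the maximum order is capped at 62.  (No
arbitrary-precision fallback is provided; beyond order ~20 the number of
pattern classes already dwarfs any realistic series length, so the cap is
not the binding constraint in practice.)

## Bulk encoding by bit shifts

Successive windows share all comparisons except those involving the point
that enters and the point that leaves.  In the binary representation this
is `b_k(n) = b_{k+1}(n−1) ≫ 1`: the dropped low bit is the comparison
against the departed point.  The bulk encoder therefore computes only the
*last* column of the pattern array by direct vectorised comparisons
(`O(D·N)` boolean ops) and derives every earlier column by one shift of
the previous row's next column; only row 0 of each column needs direct
evaluation.  A streaming single-pattern update (`advance_pattern`) is
provided for online use and is tested to agree with the bulk path
window by window.

## Words, masking, and the frequency trick

A word of configuration `(d, m)` — `m` successive order-`d` patterns — is
the order-`(d+m−1)` pattern of the covering window with entry `k > d`
masked to its top `d` bits: comparisons reaching back more than `d` steps
belong to none of the constituent patterns.  Two array transformations
generate all configurations from the order-`D` array: `order_down`
(`(d,m) → (d−1,m+1)`, one more low bit zeroed per trailing entry) and
`truncate_length` (`(d,m) → (d,m′)`, trailing entries dropped).

Shorter words exist at more window positions than the `N−D+1` full
windows.  Rather than recomputing, the series is conceptually continued
by `D−1` artificial maximal elements — comparisons against them are all
zero, so no special values are ever stored — giving `N` rows for every
configuration.  The trailing rows that carry artificial information are
then overwritten with sentinels: row `N−D+j` gets `2^k` at its last `j`
columns (`k = D−j+1..D`), one above the largest legal entry `2^k − 1`.
Bit masking is monotone and truncation only removes trailing entries, so
each sentinel-bearing row stays unique under every transformation.  A
unique row has frequency 1 and `1·ln 1 = 0`, so these rows drop out of
the entropy sum without bookkeeping (*frequency trick*).  Under it every
configuration counts all `N` rows: `Σ_w h_w = N`, of which
`N − d − m + 2` are words free of artificial information — the
normaliser of the entropy formula.

## Counting and the entropy triangle

At each order the rows are sorted lexicographically (numpy `lexsort`,
entry 1 most significant).  Adjacent sorted rows are compared entrywise
and a cumulative OR over columns marks, for every word length `m′` at
once, the block boundaries within the first `d+m′−1` entries — a change
in an early entry separates words of every length, which is why one sort
per order serves all lengths.  Block lengths are the absolute
frequencies.  (The boundary test "first differing entry" is equivalent to
taking signs of cumulated entry differences on sorted rows, but cannot
overflow.)  The triangle `{H(d,m) : d+m ≤ D+1}` costs `D` sorts,
`O(D²·N log N)` in total; a single configuration runs one sort,
`O(D·N log N)`.

`shannon_entropy` evaluates
`H = ln n_real − (1/n_real) Σ h ln h` with the terms grouped as
`ln n·(1 − Σ_{h>1}h/n) − Σ_{h>1} h(ln h − ln n)/n` so that the two
degenerate cases — a single word of frequency `n` (deterministic data)
and all-singleton counts — cancel to exactly `0` and exactly `ln n` in
floating point.  Entropies are natural-log throughout; no normalisation
by `ln((d+1)!)` is applied.  Equality with direct unpadded evaluation is
tested to `1e−12` per cell.

Length convention: the public API takes the series (point count `L`) and
uses `N = L − 1` internally, so `n_real = L − d − m + 1`; the TSV/JSON
output reports `n_words = n_real` per cell.

## KS-entropy estimators

`epe(x, d) = H(d,1)/d` and `ece(x, d) = H(d,2) − H(d,1)` estimate the
Kolmogorov–Sinai entropy of the generating system; `epe_bound(d) =
ln((d+1)!)/d = (Σ_{k≤d+1} ln k)/d` (computed in the log domain, no
factorial overflow) bounds the ePE, which caps how large a KS entropy the
estimator can report at a given order — about 2.269 nats at `d = 20`,
under 4 at `d = 100`.

## Simulators and what they emulate

`logistic_naive` iterates `L(x) = 4x(1−x)` (or `L∘k`) in float64.
Rounding feeds back into the orbit, which can collapse ordinal variety;
it is included as the contrast case.

`logistic_advanced` uses the conjugacy chain Bernoulli shift → angle
doubling → logistic map: `x_n = sin²(2π Σ_{j≤p} b_{kn+j} 2^{−j})` over an
iid fair-bit stream, advancing `k` bits per output for `L∘k`.  The
`p`-bit window is packed as an integer (exact arithmetic; for `p ≤ 53`
the binary fraction is exactly representable, so the readout rounds at
most once).  Defaults: `p = 52`, matching the double-precision mantissa;
`p` is configurable in `[1, 62]`.  Consecutive outputs satisfy
`|x_{n+1} − L∘k(x_n)| ≤ 2π·2^{k−p}` (≈ `3e−15` at `p = 52`, `k = 1`),
and the marginal law is exactly the arcsine density
`1/(π√(x(1−x)))` discretised on the `2^p` grid.  This emulates a system
that evolves exactly and is only *measured* at finite precision — the
situation real recordings are in — which is what the naive simulator
gets wrong.  What it does not emulate: observational noise, non-ergodic
drift, or any map other than the logistic family.

`iid_series` draws uniform or standard-normal data; for any continuous
iid law every order-`d` pattern has probability `1/(d+1)!`, the
maximum-entropy reference against which structure is judged.

## Problem sizes and study conditions

The KS-recovery experiments use shift-conjugate orbits of `10⁶` points at
`p = 52`: eCE at `d = 10` for `L` (target `ln 2`), `d = 7` for `L∘2`
(target `2 ln 2`), `d = 8` for `L∘3` (ceiling `3 ln 2`, not attained —
for that complexity the orders rich enough to express it are already
undersampled at this length, so the estimate sits well below the
ceiling).  These sizes keep a full run in seconds while leaving the first
two estimates on their plateaus; a tenfold longer orbit widens the
plateaus but does not move the plateau values appreciably.  Property
suites run at `N ≤ 500, D ≤ 12` (encoding equivalence) and
`N ≤ 300, D ≤ 8` (counting equivalence), which already exercise every
code path including sentinel handling at every configuration.

## Known limitations

* Time-delay (lagged) embeddings are not implemented.
* No streaming/online frequency maintenance: counting sorts a full array.
* Entropies come without confidence intervals; undersampling bias at
  large `d` relative to `N` is the user's to judge (the `L∘3` case above
  is the cautionary example).
* Orders above 62 are rejected rather than falling back to
  arbitrary-precision entries.
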