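"""Test-orbit generators: logistic map, shift-conjugate simulation, iid data.

The logistic map ``L(x) = 4x(1-x)`` on ``[0, 1]`` is the standard probe for
entropy estimators: its Kolmogorov–Sinai entropy is ``ln 2``, and the
``k``-th iterate ``L∘k`` has KS entropy ``k ln 2``.  Two generators are
provided.

*Naive simulation* iterates ``L`` in floating point.  Rounding feeds back
into the orbit, so after a few dozen steps the computed orbit has no
pointwise relation to a true one, and the finite value set can collapse the
variety of ordinal patterns (even into periodic cycles).

*Advanced simulation* exploits the conjugacy chain

    Bernoulli shift  --binary expansion-->  angle doubling  --sin^2-->  L

``L`` applied to ``sin^2(2*pi*beta)`` equals ``sin^2(2*pi*(2*beta))``, and
doubling an angle written in binary is a one-bit shift.  So an exact orbit
readout is ``x_n = sin^2(2*pi * 0.b_{n+1} b_{n+2} ...)`` for an iid fair
bit stream ``(b_j)``; truncating the expansion at ``p`` bits models a
measurement of precision ``p`` that does *not* feed back into the
dynamics.  One fresh random bit is appended per step (``k`` bits for
``L∘k``), mimicking a real system that evolves exactly and is only
measured with finite precision.  The invariant (arcsine) density
``1 / (pi * sqrt(x(1-x)))`` is reproduced exactly because the truncated
binary fraction is uniform on the ``2**p`` grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Largest supported window width: the packed bit window must fit in uint64,
#: and beyond 53 bits the sin^2 readout could not resolve the extra bits.
PRECISION_CAP = 62


@dataclass
class SimulationSpec:
    """Description of one generator run.

    mode: ``naive`` | ``advanced`` | ``iid_uniform`` | ``iid_normal``;
    ``iterate_k`` selects the map iterate ``L∘k`` (ignored for iid modes);
    ``precision_bits`` is the advanced simulation's window width ``p``;
    ``x0`` seeds the naive orbit; ``seed`` drives every random choice.
    """

    mode: str
    length: int
    iterate_k: int = 1
    precision_bits: int = 52
    seed: int | None = None
    x0: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("naive", "advanced", "iid_uniform", "iid_normal"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.iterate_k < 1:
            raise ValueError("iterate_k must be >= 1")
        if not 1 <= self.precision_bits <= PRECISION_CAP:
            raise ValueError(
                f"precision_bits must be in [1, {PRECISION_CAP}]"
            )


def logistic_naive(length: int, x0: float, iterate_k: int = 1) -> np.ndarray:
    """Floating-point orbit of ``L∘k`` starting at ``x0`` (included)."""
    if not 0.0 <= x0 <= 1.0:
        raise ValueError(f"x0 must lie in [0, 1], got {x0}")
    out = np.empty(length, dtype=np.float64)
    x = float(x0)
    for n in range(length):
        out[n] = x
        for _ in range(iterate_k):
            x = 4.0 * x * (1.0 - x)
    return out


def logistic_advanced(
    length: int,
    iterate_k: int = 1,
    precision_bits: int = 52,
    seed: int | None = None,
    bits: np.ndarray | None = None,
) -> np.ndarray:
    """Shift-conjugate orbit of ``L∘k`` read out at precision ``p``.

    Draws ``p + k*(length-1)`` iid fair bits, packs each sliding ``p``-bit
    window (advancing ``k`` bits per output) into an integer ``W_n`` and
    returns ``sin^2(2*pi * W_n / 2**p)``.  The packing is exact integer
    arithmetic; for ``p <= 53`` the binary fraction is exactly
    representable, so consecutive outputs satisfy the conjugacy
    ``x_{n+1} ≈ L∘k(x_n)`` up to the truncated tail of the expansion,
    about ``2*pi * 2**(k-p)``.

    ``bits`` overrides the random stream with an explicit 0/1 array (for
    deterministic experiments); otherwise ``seed`` makes the run
    reproducible.
    """
    p = precision_bits
    k = iterate_k
    spec = SimulationSpec(  # validation
        mode="advanced", length=length, iterate_k=k, precision_bits=p, seed=seed
    )
    n = spec.length
    n_bits = p + k * (n - 1)
    if bits is None:
        rng = np.random.default_rng(seed)
        bits = rng.integers(0, 2, size=n_bits, dtype=np.uint8)
    else:
        bits = np.asarray(bits, dtype=np.uint64)
        if bits.size < n_bits:
            raise ValueError(
                f"need at least {n_bits} bits for length {n}, got {bits.size}"
            )
    W = np.zeros(n, dtype=np.uint64)
    for j in range(p):  # bit j of the window carries weight 2^-(j+1)
        W |= bits[j : j + k * n : k][:n].astype(np.uint64) << np.uint64(p - 1 - j)
    frac = W.astype(np.float64) * 2.0 ** (-p)
    return np.sin(2.0 * np.pi * frac) ** 2


def iid_series(
    length: int, distribution: str = "uniform", seed: int | None = None
) -> np.ndarray:
    """iid reference data: ``uniform`` on [0, 1] or standard ``normal``.

    For iid data with a continuous distribution every ordinal pattern of
    order ``d`` is equally likely (probability ``1/(d+1)!``) regardless of
    the distribution — the maximum-entropy reference case.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        return rng.random(length)
    if distribution == "normal":
        return rng.standard_normal(length)
    raise ValueError(f"unknown distribution {distribution!r}")


def simulate(spec: SimulationSpec) -> np.ndarray:
    """Run the generator described by a :class:`SimulationSpec`."""
    if spec.mode == "naive":
        if spec.x0 is None:
            raise ValueError("naive mode requires x0")
        return logistic_naive(spec.length, spec.x0, spec.iterate_k)
    if spec.mode == "advanced":
        return logistic_advanced(
            spec.length, spec.iterate_k, spec.precision_bits, spec.seed
        )
    dist = "uniform" if spec.mode == "iid_uniform" else "normal"
    return iid_series(spec.length, dist, spec.seed)
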