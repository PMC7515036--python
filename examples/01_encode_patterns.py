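"""Encode a small series into binary ordinal-pattern vectors.

Each window of d+1 points maps to d integers; entry k packs the k
comparison bits of point k against all earlier points (LSB = earliest).
The pattern of the next overlapping window is one right bit shift away.
"""

import numpy as np

import ordent as oe

x = np.array([6.0, 3.0, 1.0, 5.0, 2.0, 4.0])
d = 4

pa = oe.all_patterns(x, d)
print(f"series: {x.tolist()}  (order d = {d})")
for n, row in enumerate(pa.data):
    print(f"  window {x[n:n + d + 1].tolist()} -> B = {tuple(int(v) for v in row)}")

# entry k of the second pattern is entry k+1 of the first, shifted right
print("shift relation b_k(1) == b_(k+1)(0) >> 1:",
      all(pa.data[1, k] == pa.data[0, k + 1] >> 1 for k in range(d - 1)))

p = pa.data[0]
print("inversion vector (popcounts):", oe.to_inversion_vector(p).tolist())
print("rank permutation:            ", oe.to_permutation(p).tolist())
print("factorial-system index:      ", oe.to_factorial_number(oe.to_inversion_vector(p)))
# The index identifies the pattern among the (d+1)! = 120 classes of order 4.
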