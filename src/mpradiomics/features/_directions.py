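"""Direction offsets and array shifting shared by the texture matrices."""

from __future__ import annotations

from itertools import product

import numpy as np

#: the 13 unique 3D direction offsets at Chebyshev distance 1 (one per
#: antipodal pair of the 26-neighbourhood)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)

assert len(DIRECTIONS_3D) == 13


def shift(arr: np.ndarray, offset, fill=0) -> np.ndarray:
    """out[x] = arr[x + offset], filled with ``fill`` outside the array."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, o in zip(arr.shape, offset):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out
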