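"""Neighbourhood gray-tone difference matrix and its 5 statistics.

For every in-mask voxel with at least one in-mask 26-neighbour, the absolute
difference between its level and the mean level of those neighbours is
accumulated per gray level (Amadasun-Kings style, extended to 3D and to
partial neighbourhoods at the region border).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..standardization import QuantizedRegion

#: documented cap for coarseness when the total difference is zero
#: (perfectly homogeneous region)
COARSENESS_MAX = 1e6

_KERNEL = np.ones((3, 3, 3))
_KERNEL[1, 1, 1] = 0.0


def ngtdm_table(region: QuantizedRegion) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) accumulation and the number of valid voxels.

    Returns (n, s, N): n[i-1] counts valid voxels at level i, s[i-1] is the
    accumulated |i - A| with A the mean level of the in-mask neighbours.
    """
    lv = region.levels
    L = region.n_levels
    mask = region.mask
    bbox = ndimage.find_objects(mask.astype(np.int8))[0]
    lv = lv[bbox]
    m = lv > 0
    nb_sum = ndimage.convolve(lv.astype(float) * m, _KERNEL, mode="constant")
    nb_cnt = ndimage.convolve(m.astype(float), _KERNEL, mode="constant")
    valid = m & (nb_cnt > 0.5)
    if not valid.any():
        raise ValueError("degenerate region: no voxel has an in-mask neighbour")
    A = nb_sum[valid] / nb_cnt[valid]
    levels = lv[valid]
    n = np.bincount(levels - 1, minlength=L).astype(float)
    s = np.bincount(levels - 1, weights=np.abs(levels - A), minlength=L)
    return n, s, int(valid.sum())


def ngtdm_features(n: np.ndarray, s: np.ndarray, N: int) -> dict[str, float]:
    L = n.size
    p = n / N
    i = np.arange(1, L + 1, dtype=float)
    present = p > 0
    ng = int(present.sum())

    ps = float(np.sum(p * s))
    feats: dict[str, float] = {}
    feats["coarseness"] = float(1.0 / ps) if ps > 0 else COARSENESS_MAX

    if ng <= 1:
        feats["contrast"] = 0.0
    else:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        feats["contrast"] = float(
            np.sum(pi * pj * (ii - jj) ** 2) / (ng * (ng - 1)) * (s.sum() / N)
        )

    ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
    pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
    si, sj = np.meshgrid(s[present], s[present], indexing="ij")
    busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
    feats["busyness"] = float(ps / busy_den) if busy_den > 0 else 0.0
    feats["complexity"] = float(
        np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)) / N
    )
    s_tot = float(s.sum())
    feats["strength"] = (
        float(np.sum((pi + pj) * (ii - jj) ** 2) / s_tot) if s_tot > 0 else 0.0
    )
    return feats
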