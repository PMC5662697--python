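"""Gray-level run-length matrix and its 13 statistics.

A run is a maximal set of collinear consecutive in-mask voxels sharing one
quantized level.  Runs are counted along the 13 unique 3D directions and
pooled into a single matrix r(level, length).
"""

from __future__ import annotations

import numpy as np

from ..standardization import QuantizedRegion
from ._directions import DIRECTIONS_3D, shift


def glrlm_matrix(region: QuantizedRegion, directions=DIRECTIONS_3D) -> np.ndarray:
    """Pooled run-length count matrix, shape (L, max run length)."""
    lv = region.levels
    L = region.n_levels
    in_mask = lv > 0
    max_len = int(np.ceil(np.sqrt(sum(n ** 2 for n in lv.shape)))) + 1
    counts = np.zeros((L, max_len), dtype=np.int64)
    neg = lambda d: tuple(-c for c in d)
    for d in directions:
        nxt = shift(lv, d)
        same = in_mask & (nxt == lv) & (nxt > 0)  # continues one step along d
        # run starts: in-mask voxels whose predecessor along d does not continue
        prev_same = shift(same, neg(d), fill=False)
        starts = in_mask & ~prev_same
        # run length at each voxel = 1 + #consecutive continuations
        lengths = in_mask.astype(np.int64)
        chain = same.copy()
        step = same.copy()
        while chain.any():
            lengths += chain
            step = shift(step, d, fill=False)
            chain &= step
        lv_s = lv[starts] - 1
        len_s = lengths[starts] - 1
        counts += np.bincount(lv_s * max_len + len_s,
                              minlength=L * max_len).reshape(L, max_len)
    # trim unused run lengths
    used = np.nonzero(counts.sum(axis=0))[0]
    if used.size == 0:
        raise ValueError("degenerate region: no runs")
    return counts[:, : used[-1] + 1]


def glrlm_features(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    r = np.asarray(r, dtype=float)
    L, m = r.shape
    i = np.arange(1, L + 1)[:, None]
    j = np.arange(1, m + 1)[None, :]
    n_r = r.sum()
    r_i = r.sum(axis=1)  # per gray level
    r_j = r.sum(axis=0)  # per run length

    feats = {
        "SRE": float(np.sum(r / j ** 2) / n_r),
        "LRE": float(np.sum(r * j ** 2) / n_r),
        "GLN": float(np.sum(r_i ** 2) / n_r),
        "RLN": float(np.sum(r_j ** 2) / n_r),
        "RP": float(n_r / n_voxels),
        "LGRE": float(np.sum(r / i ** 2) / n_r),
        "HGRE": float(np.sum(r * i ** 2) / n_r),
        "SRLGE": float(np.sum(r / (i ** 2 * j ** 2)) / n_r),
        "SRHGE": float(np.sum(r * i ** 2 / j ** 2) / n_r),
        "LRLGE": float(np.sum(r * j ** 2 / i ** 2) / n_r),
        "LRHGE": float(np.sum(r * i ** 2 * j ** 2) / n_r),
    }
    mu_i = float(np.sum(i * r) / n_r)
    mu_j = float(np.sum(j * r) / n_r)
    feats["GLV"] = float(np.sum((i - mu_i) ** 2 * r) / n_r)
    feats["RLV"] = float(np.sum((j - mu_j) ** 2 * r) / n_r)
    return feats
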