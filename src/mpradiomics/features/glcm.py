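"""Gray-level co-occurrence matrix and its 22 statistics.

Co-occurrences of quantized levels at distance 1 are pooled over the 13
unique 3D direction offsets into a single symmetric matrix normalized to
sum 1; voxel pairs that leave the region mask are ignored.
"""

from __future__ import annotations

import numpy as np

from ..standardization import QuantizedRegion
from ._directions import DIRECTIONS_3D, shift


def glcm_matrix(region: QuantizedRegion, directions=DIRECTIONS_3D) -> np.ndarray:
    """Symmetric, normalized L x L co-occurrence matrix."""
    lv = region.levels
    L = region.n_levels
    counts = np.zeros((L, L), dtype=np.int64)
    for d in directions:
        nb = shift(lv, d)
        valid = (lv > 0) & (nb > 0)
        if not valid.any():
            continue
        a = lv[valid] - 1
        b = nb[valid] - 1
        counts += np.bincount(a * L + b, minlength=L * L).reshape(L, L)
    counts = counts + counts.T  # symmetrize: count both pair orientations
    total = counts.sum()
    if total == 0:
        raise ValueError("degenerate region: no valid voxel pairs for the GLCM")
    return counts / total


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence statistics of a normalized symmetric GLCM.

    Level indices run 1..L.  The normalized inverse-difference measures
    (IDMN, IDN) divide the level difference by L; IMC2 is clamped to 0 when
    rounding drives the exponent's argument slightly negative.
    """
    p = np.asarray(p, dtype=float)
    L = p.shape[0]
    # operate on the nonzero entries only: at high L the matrix is sparse
    ii, jj = np.nonzero(p)
    pv = p[ii, jj]
    i1 = ii + 1.0
    j1 = jj + 1.0
    lv = np.arange(1, L + 1, dtype=float)
    px = np.bincount(ii, weights=pv, minlength=L)  # == py by symmetry
    py = np.bincount(jj, weights=pv, minlength=L)
    mu_x = float(np.sum(lv * px))
    mu_y = float(np.sum(lv * py))
    sd_x = float(np.sqrt(np.sum((lv - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((lv - mu_y) ** 2 * py)))

    diff = np.abs(i1 - j1)
    # distributions of i+j (2..2L) and |i-j| (0..L-1)
    k_sum = np.arange(2, 2 * L + 1)
    p_sum = np.bincount((ii + jj).astype(int), weights=pv, minlength=2 * L - 1)
    p_diff = np.bincount(diff.astype(int), weights=pv, minlength=L)[:L]

    hxy = _entropy2(pv)
    hx = _entropy2(px)
    hy = _entropy2(py)
    def _log_safe(m):
        out = np.full(L, -np.inf)
        pos = m > 0
        out[pos] = np.log2(m[pos])
        return out

    # cross entropy of p against the product of marginals, and the entropy of
    # that product itself
    hxy1 = float(-np.sum(pv * (_log_safe(px)[ii] + _log_safe(py)[jj])))
    outer = np.outer(px[px > 0], py[py > 0])
    hxy2 = float(-np.sum(outer * np.log2(outer)))

    feats: dict[str, float] = {}
    feats["autocorrelation"] = float(np.sum(i1 * j1 * pv))
    dev = i1 + j1 - mu_x - mu_y
    feats["cluster_prominence"] = float(np.sum(dev ** 4 * pv))
    feats["cluster_shade"] = float(np.sum(dev ** 3 * pv))
    feats["cluster_tendency"] = float(np.sum(dev ** 2 * pv))
    feats["contrast"] = float(np.sum((i1 - j1) ** 2 * pv))
    if sd_x * sd_y > 0:
        feats["correlation"] = float((feats["autocorrelation"] - mu_x * mu_y) / (sd_x * sd_y))
    else:
        feats["correlation"] = 1.0  # single occupied level: perfectly correlated
    feats["difference_entropy"] = _entropy2(p_diff)
    feats["dissimilarity"] = float(np.sum(diff * pv))
    feats["energy"] = float(np.sum(pv ** 2))
    feats["entropy"] = hxy
    feats["homogeneity1"] = float(np.sum(pv / (1.0 + diff)))
    feats["homogeneity2"] = float(np.sum(pv / (1.0 + diff ** 2)))
    denom = max(hx, hy)
    feats["IMC1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    feats["IMC2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    feats["IDMN"] = float(np.sum(pv / (1.0 + (diff / L) ** 2)))
    feats["IDN"] = float(np.sum(pv / (1.0 + diff / L)))
    off = diff > 0
    feats["inverse_variance"] = float(np.sum(pv[off] / diff[off] ** 2))
    feats["max_probability"] = float(pv.max())
    sum_avg = float(np.sum(k_sum * p_sum))
    feats["sum_average"] = sum_avg
    feats["sum_entropy"] = _entropy2(p_sum)
    feats["sum_variance"] = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    feats["variance"] = float(np.sum((i1 - mu_x) ** 2 * pv))
    return feats
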