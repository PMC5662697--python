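"""Gray-level size-zone matrix and its 12 statistics.

A zone is a 26-connected component of voxels sharing one quantized level;
the matrix z(level, size) counts zones.  Unlike run-length matrices, the
GLSZM has no direction dependence.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from ..standardization import QuantizedRegion


def glszm_matrix(region: QuantizedRegion) -> np.ndarray:
    """Zone count matrix, shape (L, max zone size)."""
    lv = region.levels
    L = region.n_levels
    if not (lv > 0).any():
        raise ValueError("degenerate region: empty mask")
    # restrict to the bounding box; label() connects equal-valued neighbours
    bbox = ndimage.find_objects(region.mask.astype(np.int8))[0]
    sub = lv[bbox]
    lab = measure.label(sub, background=0, connectivity=3)
    n_zones = lab.max()
    sizes = np.bincount(lab.ravel())[1:]
    zone_level = ndimage.maximum(sub, labels=lab, index=np.arange(1, n_zones + 1))
    zone_level = np.asarray(zone_level, dtype=np.int64)
    max_size = int(sizes.max())
    counts = np.bincount((zone_level - 1) * max_size + (sizes - 1),
                         minlength=L * max_size).reshape(L, max_size)
    return counts


def glszm_features(z: np.ndarray, n_voxels: int) -> dict[str, float]:
    z = np.asarray(z, dtype=float)
    L, m = z.shape
    i = np.arange(1, L + 1)[:, None]
    s = np.arange(1, m + 1)[None, :]
    n_z = z.sum()
    z_i = z.sum(axis=1)
    z_s = z.sum(axis=0)

    feats = {
        "SAE": float(np.sum(z / s ** 2) / n_z),
        "LAE": float(np.sum(z * s ** 2) / n_z),
        "GLN": float(np.sum(z_i ** 2) / n_z),
        "SZN": float(np.sum(z_s ** 2) / n_z),
        "ZP": float(n_z / n_voxels),
        "LGZE": float(np.sum(z / i ** 2) / n_z),
        "HGZE": float(np.sum(z * i ** 2) / n_z),
        "SALGE": float(np.sum(z / (i ** 2 * s ** 2)) / n_z),
        "SAHGE": float(np.sum(z * i ** 2 / s ** 2) / n_z),
        "LALGE": float(np.sum(z * s ** 2 / i ** 2) / n_z),
        "LAHGE": float(np.sum(z * i ** 2 * s ** 2) / n_z),
    }
    mu_i = float(np.sum(i * z) / n_z)
    feats["GLV"] = float(np.sum((i - mu_i) ** 2 * z) / n_z)
    return feats
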