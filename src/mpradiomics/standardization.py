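"""Image standardization: isotropic resampling and gray-level quantization.

Texture features are only comparable across scanners once voxel size and
intensity scale are standardized.  This module implements the 36-setting
standardization grid: isotropic voxel sizes of 1, 2 and 3 mm crossed with
three scalar quantizers (uniform, equal-probability, Lloyd-Max) at 32, 64,
128 and 256 gray levels.

Quantization is computed per extraction subregion from that subregion's own
intensity sample, which maximizes gray-level utilization in the texture
matrices.  All three quantizers are monotone, so voxel ordering is preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .study import MODALITIES, MultimodalStudy

log = logging.getLogger(__name__)

VOXEL_SIZES = (1.0, 2.0, 3.0)
QUANTIZATION_METHODS = ("uniform", "equal_probability", "lloyd_max")
GRAY_LEVELS = (32, 64, 128, 256)

#: short codes used in feature-column names (match the conventional figure
#: abbreviations Uf / Eq / Ld for the three quantizers)
QM_CODE = {"uniform": "Uf", "equal_probability": "Eq", "lloyd_max": "Ld"}
QM_FROM_CODE = {v: k for k, v in QM_CODE.items()}


@dataclass(frozen=True, order=True)
class ParameterSetting:
    """One (voxel size, quantization method, gray level) standardization triple."""

    voxel_size: float
    quantization: str
    gray_levels: int

    def __post_init__(self) -> None:
        if self.quantization not in QUANTIZATION_METHODS:
            raise ValueError(f"unknown quantization method {self.quantization!r}")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def tag(self) -> str:
        """Column-name suffix, e.g. ``VS1|Uf|GL32``."""
        return f"VS{self.voxel_size:g}|{QM_CODE[self.quantization]}|GL{self.gray_levels}"

    @classmethod
    def from_tag(cls, tag: str) -> "ParameterSetting":
        vs, qm, gl = tag.split("|")
        return cls(float(vs[2:]), QM_FROM_CODE[qm], int(gl[2:]))


def enumerate_grid(
    voxel_sizes=VOXEL_SIZES,
    methods=QUANTIZATION_METHODS,
    gray_levels=GRAY_LEVELS,
) -> list[ParameterSetting]:
    """The full standardization grid in deterministic lexicographic order.

    Ordering is (voxel size, quantization method, gray level) with methods in
    their canonical order uniform < equal_probability < lloyd_max; the default
    grid has 3 x 3 x 4 = 36 settings, first (1 mm, uniform, 32), last
    (3 mm, lloyd_max, 256).
    """
    return [
        ParameterSetting(v, m, g)
        for v, m, g in product(voxel_sizes, methods, gray_levels)
    ]


# --------------------------------------------------------------- resampling


def _resample_array(arr: np.ndarray, spacing, voxel_size: float, order: int) -> np.ndarray:
    in_shape = np.asarray(arr.shape)
    spacing = np.asarray(spacing, dtype=float)
    out_shape = np.floor(in_shape * spacing / voxel_size).astype(int)
    if np.any(out_shape < 2):
        raise ValueError(
            f"resampling to {voxel_size} mm yields grid {tuple(out_shape)}; "
            "need at least 2 voxels per axis"
        )
    # voxel-center coordinates: output index i sits at physical i*voxel_size,
    # mapped back to fractional input indices (origin preserved)
    coords = np.meshgrid(
        *[np.arange(n) * voxel_size / sp for n, sp in zip(out_shape, spacing)],
        indexing="ij",
    )
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def resample_isotropic(study: MultimodalStudy, voxel_size: float) -> MultimodalStudy:
    """Resample all volumes of a study onto an isotropic ``voxel_size`` mm grid.

    Intensities are interpolated linearly; the label map uses nearest-neighbour
    so no new labels are invented.  Output size is floor(extent / voxel_size)
    per axis, hence physical extent is preserved to within one voxel.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    volumes = {
        mod: _resample_array(study.volumes[mod], study.spacing, voxel_size, order=1)
        for mod in MODALITIES
    }
    labels = _resample_array(
        study.label_map.astype(np.int16), study.spacing, voxel_size, order=0
    )
    return MultimodalStudy(
        patient_id=study.patient_id,
        volumes=volumes,
        label_map=labels,
        spacing=(voxel_size,) * 3,
        meta=dict(study.meta),
    )


# -------------------------------------------------------------- quantization


@dataclass
class QuantizedRegion:
    """Integer levels 1..L over a mask, plus the level -> intensity mapping."""

    levels: np.ndarray  # 3D int array, 0 outside the mask
    mask: np.ndarray  # boolean 3D array
    n_levels: int
    representatives: np.ndarray  # length L, representative intensity per level

    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def _assign_levels(values: np.ndarray, inner_edges: np.ndarray) -> np.ndarray:
    # right-closed bins: level k covers (edge_{k-1}, edge_k]
    return np.searchsorted(inner_edges, values, side="left") + 1


def _representatives(values: np.ndarray, levels: np.ndarray, L: int) -> np.ndarray:
    reps = np.zeros(L)
    sums = np.bincount(levels, weights=values, minlength=L + 1)[1:]
    counts = np.bincount(levels, minlength=L + 1)[1:]
    nz = counts > 0
    reps[nz] = sums[nz] / counts[nz]
    return reps


def _uniform_edges(vmin: float, vmax: float, L: int) -> np.ndarray:
    return np.linspace(vmin, vmax, L + 1)[1:-1]


def _lloyd_max_edges(values: np.ndarray, L: int, tol: float = 1e-7,
                     max_iter: int = 500) -> np.ndarray:
    """Iterate the Lloyd conditions from the uniform quantizer's boundaries.

    Alternates (a) representatives = conditional mean per cell and
    (b) boundaries = midpoints of adjacent representatives, until the relative
    decrease of mean-squared quantization error falls below ``tol``.
    Deterministic given the input sample.
    """
    vmin, vmax = float(values.min()), float(values.max())
    edges = _uniform_edges(vmin, vmax, L)
    prev_mse = np.inf
    for _ in range(max_iter):
        levels = _assign_levels(values, edges)
        reps = _representatives(values, levels, L)
        # empty cells inherit the midpoint of their boundaries so ordering holds
        full_edges = np.concatenate([[vmin], edges, [vmax]])
        mids = 0.5 * (full_edges[:-1] + full_edges[1:])
        counts = np.bincount(levels, minlength=L + 1)[1:]
        reps[counts == 0] = mids[counts == 0]
        mse = float(np.mean((values - reps[levels - 1]) ** 2))
        edges = 0.5 * (reps[:-1] + reps[1:])
        if prev_mse - mse <= tol * max(prev_mse, np.finfo(float).tiny):
            break
        prev_mse = mse
    return edges


def quantize(values: np.ndarray, mask: np.ndarray, method: str, L: int) -> QuantizedRegion:
    """Quantize the in-mask intensities of a volume to L gray levels.

    methods
        ``uniform``            L equal-width bins on [min, max], right-closed.
        ``equal_probability``  bin edges at empirical quantiles k/L.
        ``lloyd_max``          MSE-optimal scalar quantizer (Lloyd iteration).

    A constant in-mask sample (zero range) maps every voxel to level 1 and
    logs a warning.  All three quantizers are monotone in the input value.
    """
    if method not in QUANTIZATION_METHODS:
        raise ValueError(f"unknown quantization method {method!r}")
    if L < 2:
        raise ValueError("L must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    sample = np.asarray(values, dtype=float)[mask]
    vmin, vmax = float(sample.min()), float(sample.max())

    levels3d = np.zeros(mask.shape, dtype=np.int32)
    if vmax == vmin:
        warnings.warn("constant intensity sample: all voxels assigned level 1")
        levels3d[mask] = 1
        reps = np.full(L, vmin)
        return QuantizedRegion(levels3d, mask, L, reps)

    if method == "uniform":
        edges = _uniform_edges(vmin, vmax, L)
    elif method == "equal_probability":
        edges = np.quantile(sample, np.arange(1, L) / L)
    else:  # lloyd_max
        edges = _lloyd_max_edges(sample, L)

    lv = _assign_levels(sample, edges)
    reps = _representatives(sample, lv, L)
    levels3d[mask] = lv
    return QuantizedRegion(levels3d, mask, L, reps)


def quantization_mse(values: np.ndarray, mask: np.ndarray, region: QuantizedRegion) -> float:
    """Mean-squared error of a quantizer's representative mapping on its sample."""
    sample = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    lv = region.masked_levels()
    return float(np.mean((sample - region.representatives[lv - 1]) ** 2))
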