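"""High-throughput feature extraction over the standardization grid.

Feature columns are fully qualified as ``modality_region_family_title@tag``:
first-order measures carry only the voxel size (``@VS1``) since quantization
does not apply to them, high-order measures carry the full setting tag
(``@VS1|Uf|GL32``).  With the default 36-setting grid one patient yields
12 x 6 x 4 x 3 = 864 first-order plus 52 x 6 x 4 x 36 = 44 928 high-order
measures, 45 792 in total.

Measures from empty or degenerate subregions are missing values, never
errors; only an empty whole tumor aborts extraction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from ..standardization import ParameterSetting, quantize, resample_isotropic
from ..study import MODALITIES, MultimodalStudy
from .firstorder import first_order_features
from .glcm import glcm_features, glcm_matrix
from .glrlm import glrlm_features, glrlm_matrix
from .glszm import glszm_features, glszm_matrix
from .ngtdm import ngtdm_features, ngtdm_table
from .subregions import REGIONS, derive_subregions

log = logging.getLogger(__name__)

HIGH_ORDER_FAMILIES = ("GLCM", "GLRLM", "GLSZM", "NGTDM")


@lru_cache(maxsize=1)
def catalog() -> dict:
    """The versioned feature catalog (12 first-order + 52 high-order titles)."""
    with resources.files("mpradiomics").joinpath("catalog.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class FeatureKey:
    """Parsed form of a fully qualified feature column name."""

    modality: str
    region: str
    family: str
    title: str
    voxel_size: float
    setting: ParameterSetting | None  # None for first-order measures

    @property
    def base(self) -> str:
        """Setting-free feature identity, e.g. ``T1_necrosis_GLCM_IDMN``."""
        return f"{self.modality}_{self.region}_{self.family}_{self.title}"

    @property
    def column(self) -> str:
        if self.setting is None:
            return f"{self.base}@VS{self.voxel_size:g}"
        return f"{self.base}@{self.setting.tag}"

    @classmethod
    def parse(cls, column: str) -> "FeatureKey":
        base, tag = column.split("@")
        # region names may contain underscores; the family token is the anchor
        parts = base.split("_")
        for k, part in enumerate(parts):
            if part in ("firstorder",) + HIGH_ORDER_FAMILIES:
                modality = parts[0]
                region = "_".join(parts[1:k])
                family = part
                title = "_".join(parts[k + 1:])
                break
        else:
            raise ValueError(f"cannot parse feature column {column!r}")
        if family == "firstorder":
            return cls(modality, region, family, title, float(tag[2:]), None)
        setting = ParameterSetting.from_tag(tag)
        return cls(modality, region, family, title, setting.voxel_size, setting)


def expected_columns(grid: list[ParameterSetting]) -> list[str]:
    """Deterministic full column order for a grid (identical for all patients)."""
    cat = catalog()
    voxel_sizes = sorted({s.voxel_size for s in grid})
    cols: list[str] = []
    for vs in voxel_sizes:
        for mod in MODALITIES:
            for region in REGIONS:
                for title in cat["firstorder"]:
                    cols.append(f"{mod}_{region}_firstorder_{title}@VS{vs:g}")
    for setting in grid:
        for mod in MODALITIES:
            for region in REGIONS:
                for family in HIGH_ORDER_FAMILIES:
                    for title in cat[family]:
                        cols.append(f"{mod}_{region}_{family}_{title}@{setting.tag}")
    return cols


def expected_feature_count(grid: list[ParameterSetting]) -> int:
    return len(expected_columns(grid))


def _high_order_features(values: np.ndarray, mask: np.ndarray,
                         setting: ParameterSetting) -> dict[str, float]:
    """All 52 high-order statistics for one (region, modality, setting)."""
    cat = catalog()
    n_voxels = int(mask.sum())
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-region quantization warning
        region = quantize(values, mask, setting.quantization, setting.gray_levels)
    try:
        p = glcm_matrix(region)
        g = glcm_features(p)
    except ValueError:
        g = {}
    for t in cat["GLCM"]:
        out[f"GLCM_{t}"] = g.get(t, np.nan)
    try:
        r = glrlm_features(glrlm_matrix(region), n_voxels)
    except ValueError:
        r = {}
    for t in cat["GLRLM"]:
        out[f"GLRLM_{t}"] = r.get(t, np.nan)
    try:
        z = glszm_features(glszm_matrix(region), n_voxels)
    except ValueError:
        z = {}
    for t in cat["GLSZM"]:
        out[f"GLSZM_{t}"] = z.get(t, np.nan)
    try:
        n, s, N = ngtdm_table(region)
        d = ngtdm_features(n, s, N)
    except ValueError:
        d = {}
    for t in cat["NGTDM"]:
        out[f"NGTDM_{t}"] = d.get(t, np.nan)
    return out


def extract_study(study: MultimodalStudy,
                  grid: list[ParameterSetting]) -> pd.Series:
    """One patient's full feature row over a standardization grid."""
    cat = catalog()
    values: dict[str, float] = {}
    voxel_sizes = sorted({s.voxel_size for s in grid})
    by_vs = {vs: [s for s in grid if s.voxel_size == vs] for vs in voxel_sizes}

    for vs in voxel_sizes:
        res = resample_isotropic(study, vs)
        masks = derive_subregions(res.label_map)
        for mod in MODALITIES:
            vol = res.volumes[mod]
            for region in REGIONS:
                mask = masks[region]
                n_vox = int(mask.sum())
                prefix = f"{mod}_{region}"
                if n_vox == 0:
                    for title in cat["firstorder"]:
                        values[f"{prefix}_firstorder_{title}@VS{vs:g}"] = np.nan
                    for setting in by_vs[vs]:
                        for fam in HIGH_ORDER_FAMILIES:
                            for title in cat[fam]:
                                values[f"{prefix}_{fam}_{title}@{setting.tag}"] = np.nan
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fo = first_order_features(vol[mask])
                for title, v in fo.items():
                    values[f"{prefix}_firstorder_{title}@VS{vs:g}"] = v
                for setting in by_vs[vs]:
                    if n_vox < 2:
                        ho = {f"{fam}_{t}": np.nan
                              for fam in HIGH_ORDER_FAMILIES for t in cat[fam]}
                    else:
                        ho = _high_order_features(vol, mask, setting)
                    for name, v in ho.items():
                        values[f"{prefix}_{name}@{setting.tag}"] = v

    row = pd.Series(values, name=study.patient_id)
    return row.reindex(expected_columns(grid))


def extract_cohort(studies: list[MultimodalStudy],
                   grid: list[ParameterSetting]) -> pd.DataFrame:
    """Feature table (patients x measures) for a cohort; columns deterministic."""
    rows = []
    for study in studies:
        log.info("extracting %s", study.patient_id)
        rows.append(extract_study(study, grid))
    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    return table
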