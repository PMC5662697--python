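"""Tumor subregion masks from a BRATS-style label map.

Six extraction subregions: the four primitive compartments (necrosis,
enhancing, non-enhancing, edema) plus two composites — the solid core
(whole tumor minus edema) and the whole tumor (union of all four).
"""

from __future__ import annotations

import logging

import numpy as np

from ..study import (
    LABEL_EDEMA,
    LABEL_ENHANCING,
    LABEL_NECROSIS,
    LABEL_NON_ENHANCING,
)

log = logging.getLogger(__name__)

REGIONS = ("necrosis", "enhancing", "non_enhancing", "edema", "solid_core", "whole_tumor")


def derive_subregions(label_map: np.ndarray) -> dict[str, np.ndarray]:
    """Boolean masks for the six extraction subregions.

    Empty primitive subregions are permitted (logged); an empty whole tumor is
    an error since nothing can be extracted.
    """
    lm = np.asarray(label_map)
    masks = {
        "necrosis": lm == LABEL_NECROSIS,
        "enhancing": lm == LABEL_ENHANCING,
        "non_enhancing": lm == LABEL_NON_ENHANCING,
        "edema": lm == LABEL_EDEMA,
    }
    masks["solid_core"] = masks["necrosis"] | masks["enhancing"] | masks["non_enhancing"]
    masks["whole_tumor"] = masks["solid_core"] | masks["edema"]
    if not masks["whole_tumor"].any():
        raise ValueError("whole tumor is empty: no voxel carries a tumor label")
    for name in ("necrosis", "enhancing", "non_enhancing", "edema"):
        if not masks[name].any():
            log.warning("subregion %s is empty; its features will be missing", name)
    return masks
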