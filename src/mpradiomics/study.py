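"""Per-patient container for co-registered multimodal MR data.

A study bundles the four conventional glioma MR modalities (T1, post-contrast
T1, T2 and FLAIR), a BRATS-style integer label map and the voxel spacing.
All arrays share one grid; the label map uses 0 = non-tumor, 1 = necrosis,
2 = edema, 3 = non-enhancing tumor, 4 = enhancing tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("T1", "T1C", "T2", "FLAIR")

#: BRATS-style label codes.
LABEL_NECROSIS = 1
LABEL_EDEMA = 2
LABEL_NON_ENHANCING = 3
LABEL_ENHANCING = 4
VALID_LABELS = frozenset({0, 1, 2, 3, 4})

_MODALITY_SUFFIX = {"T1": "_t1", "T1C": "_t1c", "T2": "_t2", "FLAIR": "_flair"}


@dataclass
class MultimodalStudy:
    """One patient's registered volumes, label map and spacing."""

    patient_id: str
    volumes: dict[str, np.ndarray]
    label_map: np.ndarray
    spacing: tuple[float, float, float]
    #: optional per-patient metadata (e.g. generative ground truth for phantoms)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.volumes) != set(MODALITIES):
            raise ValueError(f"expected modalities {MODALITIES}, got {sorted(self.volumes)}")
        shape = self.label_map.shape
        for name, vol in self.volumes.items():
            if vol.shape != shape:
                raise ValueError(f"modality {name} shape {vol.shape} != label map shape {shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        labels = set(np.unique(self.label_map).tolist())
        if not labels <= VALID_LABELS:
            raise ValueError(f"label map contains invalid values {sorted(labels - VALID_LABELS)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_map.shape

    # ------------------------------------------------------------------ I/O

    def save(self, directory: str | Path) -> list[Path]:
        """Write the study as NIfTI files ``<pid>_<mod>.nii`` + ``<pid>_seg.nii``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*self.spacing, 1.0])
        written = []
        for mod in MODALITIES:
            p = directory / f"{self.patient_id}{_MODALITY_SUFFIX[mod]}.nii"
            nib.save(nib.Nifti1Image(self.volumes[mod].astype(np.float32), affine), p)
            written.append(p)
        p = directory / f"{self.patient_id}_seg.nii"
        nib.save(nib.Nifti1Image(self.label_map.astype(np.uint8), affine), p)
        written.append(p)
        return written

    @classmethod
    def load(cls, directory: str | Path, patient_id: str) -> "MultimodalStudy":
        directory = Path(directory)
        volumes = {}
        spacing = None
        for mod in MODALITIES:
            img = nib.load(directory / f"{patient_id}{_MODALITY_SUFFIX[mod]}.nii")
            volumes[mod] = np.asarray(img.dataobj, dtype=np.float64)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        seg = nib.load(directory / f"{patient_id}_seg.nii")
        label_map = np.asarray(seg.dataobj).astype(np.int16)
        return cls(patient_id=patient_id, volumes=volumes, label_map=label_map, spacing=spacing)
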