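"""Synthetic multimodal tumor phantoms with texture-linked survival.

Real multi-hospital GBM cohorts cannot ship with the package, so every
downstream stage is exercised on phantoms: nested-ellipsoid tumors (necrosis
inside enhancing rim inside non-enhancing tumor inside an edema envelope)
painted into four MR-like modalities as smoothed Gaussian random fields, plus
overall-survival times drawn from an exponential proportional-hazards model
whose log-hazard is linked to a known per-patient texture parameter.

The per-patient generative parameter ``z`` (standard normal) multiplies the
within-tumor noise standard deviation by ``exp(texture_link_strength * z)``,
so dispersion-sensitive features carry the survival signal; ``z`` is recorded
per patient for oracle use in tests.

Defaults emulate the study conditions this pipeline is meant for: cohorts of
a few dozen patients, median overall survival around 427 days, and a modest
independent censoring fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .study import (
    LABEL_EDEMA,
    LABEL_ENHANCING,
    LABEL_NECROSIS,
    LABEL_NON_ENHANCING,
    MODALITIES,
    MultimodalStudy,
)

_REGION_LABEL = {
    "necrosis": LABEL_NECROSIS,
    "enhancing": LABEL_ENHANCING,
    "non_enhancing": LABEL_NON_ENHANCING,
    "edema": LABEL_EDEMA,
}

#: (mean intensity, noise sd, spatial correlation length in mm) per
#: modality and compartment, in arbitrary normalized MR units.  Chosen for
#: qualitative MR realism: necrosis dark on T1/T1C, enhancing rim bright on
#: T1C, edema bright on FLAIR/T2.
DEFAULT_TEXTURE_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "T1": {
        "background": (100.0, 8.0, 1.5),
        "necrosis": (60.0, 10.0, 2.0),
        "enhancing": (90.0, 12.0, 2.0),
        "non_enhancing": (80.0, 12.0, 2.5),
        "edema": (85.0, 10.0, 3.0),
    },
    "T1C": {
        "background": (100.0, 8.0, 1.5),
        "necrosis": (60.0, 10.0, 2.0),
        "enhancing": (180.0, 15.0, 2.0),
        "non_enhancing": (95.0, 12.0, 2.5),
        "edema": (90.0, 10.0, 3.0),
    },
    "T2": {
        "background": (100.0, 8.0, 1.5),
        "necrosis": (160.0, 12.0, 2.0),
        "enhancing": (120.0, 12.0, 2.0),
        "non_enhancing": (140.0, 12.0, 2.5),
        "edema": (160.0, 10.0, 3.0),
    },
    "FLAIR": {
        "background": (100.0, 8.0, 1.5),
        "necrosis": (90.0, 12.0, 2.0),
        "enhancing": (120.0, 12.0, 2.0),
        "non_enhancing": (140.0, 12.0, 2.5),
        "edema": (170.0, 10.0, 3.0),
    },
}

#: nested ellipsoid radii in mm, innermost to outermost
DEFAULT_RADII_MM = {
    "necrosis": 5.0,
    "enhancing": 9.0,
    "non_enhancing": 12.0,
    "edema": 16.0,
}

_RADIUS_ORDER = ("necrosis", "enhancing", "non_enhancing", "edema")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative conditions for a phantom cohort."""

    n_patients: int = 20
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    base_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subregion_radii_mm: dict = field(default_factory=lambda: dict(DEFAULT_RADII_MM))
    texture_params: dict = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_TEXTURE_PARAMS.items()}
    )
    #: log-hazard coefficient on the standardized generative texture parameter
    hazard_beta: float = 1.0
    #: multiplicative link: tumor noise sd scales by exp(strength * z)
    texture_link_strength: float = 0.35
    censoring_rate: float = 0.2
    #: baseline exponential hazard set so median survival at z=0 is this value
    median_survival_days: float = 427.0
    #: per-patient jitter of the tumor radii (fractional, preserves nesting)
    radius_jitter: float = 0.08
    #: patient-id prefix; give train/validation cohorts distinct prefixes
    patient_prefix: str = "P"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        radii = [self.subregion_radii_mm[k] for k in _RADIUS_ORDER]
        if any(r <= 0 for r in radii):
            raise ValueError("all subregion radii must be positive")
        if any(a >= b for a, b in zip(radii, radii[1:])):
            raise ValueError(f"radii must be strictly nested in order {_RADIUS_ORDER}")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if not np.isfinite(self.hazard_beta):
            raise ValueError("hazard_beta must be finite")


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time_days: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("time_days must be positive")


def patient_id(index: int, prefix: str = "P") -> str:
    return f"{prefix}{index:03d}"


# ------------------------------------------------------------------ fields


def _correlated_field(rng: np.random.Generator, shape, corr_len_mm: float,
                      spacing) -> np.ndarray:
    """Unit-variance Gaussian random field with the requested correlation length.

    Gaussian-filtered white noise with filter sigma = correlation length /
    spacing per axis; corr_len_mm = 0 degenerates to i.i.d. voxel noise.
    """
    white = rng.standard_normal(shape)
    if corr_len_mm <= 0:
        return white
    sigma = [corr_len_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generative_parameters(spec: PhantomSpec) -> np.ndarray:
    """The per-patient texture parameter z (first draw of each patient stream)."""
    return np.array(
        [np.random.default_rng([spec.seed, i]).standard_normal()
         for i in range(spec.n_patients)]
    )


def generate_phantom(spec: PhantomSpec, patient_index: int) -> MultimodalStudy:
    """Generate one phantom patient; bit-identical under an identical spec."""
    if patient_index >= spec.n_patients:
        raise ValueError("patient_index out of range")
    rng = np.random.default_rng([spec.seed, patient_index])
    z = rng.standard_normal()  # hazard-linked generative texture parameter
    jitter = 1.0 + spec.radius_jitter * rng.uniform(-1.0, 1.0)

    shape = tuple(spec.volume_shape)
    spacing = spec.base_spacing
    center = [(n - 1) / 2.0 for n in shape]
    coords = np.meshgrid(*[(np.arange(n) - c) * s
                           for n, c, s in zip(shape, center, spacing)], indexing="ij")
    r = np.sqrt(sum(c ** 2 for c in coords))  # radial distance in mm

    label_map = np.zeros(shape, dtype=np.int16)
    prev = 0.0
    shells: dict[str, np.ndarray] = {}
    for name in _RADIUS_ORDER:
        radius = spec.subregion_radii_mm[name] * jitter
        shell = (r >= prev) & (r < radius)
        if not shell.any():
            raise ValueError(f"degenerate geometry: subregion {name!r} is empty")
        shells[name] = shell
        label_map[shell] = _REGION_LABEL[name]
        prev = radius

    sd_mult = float(np.exp(spec.texture_link_strength * z))
    volumes: dict[str, np.ndarray] = {}
    for mod in MODALITIES:
        params = spec.texture_params[mod]
        mean_bg, sd_bg, cl_bg = params["background"]
        vol = mean_bg + sd_bg * _correlated_field(rng, shape, cl_bg, spacing)
        for name in _RADIUS_ORDER:
            mean, sd, cl = params[name]
            field_ = _correlated_field(rng, shape, cl, spacing)
            m = shells[name]
            vol[m] = mean + sd * sd_mult * field_[m]
        volumes[mod] = vol

    return MultimodalStudy(
        patient_id=patient_id(patient_index, spec.patient_prefix),
        volumes=volumes,
        label_map=label_map,
        spacing=tuple(float(s) for s in spacing),
        meta={"z": z, "radius_jitter": jitter},
    )


# ---------------------------------------------------------------- survival


def generate_survival(spec: PhantomSpec,
                      texture_params_per_patient: np.ndarray) -> list[SurvivalRecord]:
    """Exponential proportional-hazards survival linked to the texture parameter.

    Event times follow h(t | z) = h0 * exp(beta * z~) with z~ the standardized
    generative parameter and h0 = ln 2 / median_survival_days.  Censoring is
    independent, uniform on (0, T_max) with T_max calibrated so the realized
    censoring fraction approximates ``censoring_rate``.
    """
    z = np.asarray(texture_params_per_patient, dtype=float)
    n = z.size
    sd = z.std()
    z_std = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
    rng = np.random.default_rng([spec.seed, 999_983])
    h0 = np.log(2.0) / spec.median_survival_days
    hazard = h0 * np.exp(spec.hazard_beta * z_std)
    t_event = rng.exponential(1.0 / hazard)

    if spec.censoring_rate <= 0:
        times, events = t_event, np.ones(n, dtype=bool)
    else:
        # P(censored | T) = min(T / T_max, 1) under C ~ U(0, T_max)
        def expected_censoring(t_max):
            return float(np.mean(np.minimum(t_event / t_max, 1.0))) - spec.censoring_rate

        t_max = optimize.brentq(expected_censoring, t_event.min() * 1e-6,
                                t_event.max() * 1e6)
        c = rng.uniform(0.0, t_max, size=n)
        times = np.minimum(t_event, c)
        events = t_event <= c

    return [
        SurvivalRecord(patient_id(i, spec.patient_prefix),
                       max(float(times[i]), 1e-9), bool(events[i]))
        for i in range(n)
    ]


def survival_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_days": [r.time_days for r in records],
            "event": [int(r.event) for r in records],
        }
    ).set_index("patient_id")


# ------------------------------------------------------------ cohort output


def generate_cohort(spec: PhantomSpec) -> tuple[list[MultimodalStudy], pd.DataFrame]:
    studies = [generate_phantom(spec, i) for i in range(spec.n_patients)]
    z = np.array([s.meta["z"] for s in studies])
    surv = survival_frame(generate_survival(spec, z))
    return studies, surv


def write_cohort(spec: PhantomSpec, directory: str | Path) -> dict:
    """Write NIfTI volumes, survival.csv and a ground-truth JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = {"spec_seed": spec.seed, "hazard_beta": spec.hazard_beta, "patients": {}}
    z_all = []
    ids = []
    for i in range(spec.n_patients):
        study = generate_phantom(spec, i)
        study.save(directory)
        truth["patients"][study.patient_id] = {
            "z": study.meta["z"],
            "radius_jitter": study.meta["radius_jitter"],
        }
        z_all.append(study.meta["z"])
        ids.append(study.patient_id)
    surv = survival_frame(generate_survival(spec, np.array(z_all)))
    surv.to_csv(directory / "survival.csv")
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {"patients": ids, "directory": str(directory)}


# ------------------------------------------------- post-extraction phantoms


def synthetic_feature_table(
    n_patients: int,
    hazard_beta: float = 1.5,
    n_linked: int = 3,
    n_noise: int = 40,
    measurement_sd: float = 0.3,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """A ready-made feature table whose hazard-linked family derives from z.

    Emulates the post-extraction stage of the pipeline at arbitrary cohort
    size without simulating images: ``n_linked`` columns are noisy copies of
    the per-patient texture parameter z (the family a working screening +
    LASSO stage should recover) and ``n_noise`` columns are independent
    standard-normal distractors.  Survival is generated by the same
    proportional-hazards model as the image phantoms.

    Returns (feature table, survival frame, z).
    """
    spec = PhantomSpec(
        n_patients=n_patients,
        hazard_beta=hazard_beta,
        censoring_rate=censoring_rate,
        seed=seed,
    )
    z = generative_parameters(spec)
    surv = survival_frame(generate_survival(spec, z))
    rng = np.random.default_rng([seed, 424_243])
    cols = {}
    for j in range(n_linked):
        cols[f"hazard_linked_f{j + 1}"] = z + measurement_sd * rng.standard_normal(n_patients)
    for j in range(n_noise):
        cols[f"noise_f{j + 1}"] = rng.standard_normal(n_patients)
    X = pd.DataFrame(cols, index=[patient_id(i) for i in range(n_patients)])
    X.index.name = "patient_id"
    return X, surv, z
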