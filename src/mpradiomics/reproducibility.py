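"""Reproducibility screening via the overall concordance correlation coefficient.

The OCCC generalizes Lin's concordance correlation coefficient to J > 2
observers; here the "observers" are repeated measurements of one feature
under different image-standardization settings.  For J columns with sample
means m_j, variances s_j^2 and covariances s_jk (1/n convention),

    OCCC = 2 sum_{j<k} s_jk
           / [ (J-1) sum_j s_j^2 + sum_{j<k} (m_j - m_k)^2 ],

which reduces exactly to Lin's two-rater CCC at J = 2.

Each first-order feature gets one 3-column test (voxel sizes 1/2/3 mm with
nothing else to vary).  Each high-order feature gets a 33-test battery,
varying one standardization parameter while fixing the other two:
12 voxel-size tests (3 measures each), 12 quantization tests (3 each) and
9 gray-level tests (4 each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .features.extract import FeatureKey
from .standardization import GRAY_LEVELS, QM_CODE, QUANTIZATION_METHODS, VOXEL_SIZES


def occc(measures: np.ndarray) -> float:
    """Overall concordance correlation coefficient of an n-subject x J matrix.

    Returns NaN (with a warning) when every column is constant, in which case
    agreement is undefined.
    """
    X = np.asarray(measures, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x J matrix with J >= 2")
    n, J = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(X).any():
        raise ValueError("missing cells are not allowed")
    m = X.mean(axis=0)
    Xc = X - m
    cov = (Xc.T @ Xc) / n  # 1/n convention, matching Lin's estimator
    s2 = np.diag(cov)
    iu = np.triu_indices(J, k=1)
    num = 2.0 * cov[iu].sum()
    den = (J - 1) * s2.sum() + ((m[:, None] - m[None, :]) ** 2)[iu].sum()
    if den == 0:
        warnings.warn("all columns constant: OCCC undefined")
        return float("nan")
    return float(num / den)


@dataclass
class OCCCTest:
    varied: str                 # "voxel_size" | "quantization" | "gray_levels"
    fixed: str                  # description of the fixed parameters
    columns: list[str]
    occc: float = float("nan")


@dataclass
class OCCCBattery:
    base: str                   # setting-free feature identity
    family: str
    tests: list[OCCCTest] = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return len(self.tests)

    def n_passing(self, threshold: float = 0.85) -> int:
        return sum(1 for t in self.tests if np.isfinite(t.occc) and t.occc > threshold)


def _high_order_tests(base: str) -> list[OCCCTest]:
    from .standardization import ParameterSetting

    def col(vs, qm, gl):
        return f"{base}@{ParameterSetting(vs, qm, gl).tag}"

    tests = []
    for qm, gl in product(QUANTIZATION_METHODS, GRAY_LEVELS):
        tests.append(OCCCTest("voxel_size", f"QM={QM_CODE[qm]},GL={gl}",
                              [col(v, qm, gl) for v in VOXEL_SIZES]))
    for vs, gl in product(VOXEL_SIZES, GRAY_LEVELS):
        tests.append(OCCCTest("quantization", f"VS={vs:g},GL={gl}",
                              [col(vs, q, gl) for q in QUANTIZATION_METHODS]))
    for vs, qm in product(VOXEL_SIZES, QUANTIZATION_METHODS):
        tests.append(OCCCTest("gray_levels", f"VS={vs:g},QM={QM_CODE[qm]}",
                              [col(vs, qm, g) for g in GRAY_LEVELS]))
    return tests


def build_batteries(table: pd.DataFrame,
                    on_missing: str = "error") -> list[OCCCBattery]:
    """One OCCC battery per feature, computed over the table's patients.

    The table must contain the complete 36-setting grid for every high-order
    feature and all three voxel sizes for every first-order feature; missing
    settings raise with the offending columns listed.  With
    ``on_missing="skip"`` such features are silently excluded instead — the
    behaviour used after missing-value cleaning, where a feature that lost
    part of its grid cannot be assessed for reproducibility.
    """
    if on_missing not in ("error", "skip"):
        raise ValueError("on_missing must be 'error' or 'skip'")
    bases: dict[str, FeatureKey] = {}
    for colname in table.columns:
        key = FeatureKey.parse(colname)
        bases.setdefault(key.base, key)

    batteries = []
    for base, key in bases.items():
        if key.family == "firstorder":
            cols = [f"{base}@VS{v:g}" for v in VOXEL_SIZES]
            tests = [OCCCTest("voxel_size", "(first-order)", cols)]
        else:
            tests = _high_order_tests(base)
        missing = sorted({c for t in tests for c in t.columns} - set(table.columns))
        if missing:
            if on_missing == "skip":
                continue
            raise ValueError(
                f"incomplete standardization grid for {base}: missing {missing}"
            )
        batteries.append(OCCCBattery(base=base, family=key.family, tests=tests))

    # evaluate all tests on one numpy view (pandas indexing per test is slow)
    arr = table.to_numpy(dtype=float)
    colmap = {c: j for j, c in enumerate(table.columns)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for bat in batteries:
            for t in bat.tests:
                t.occc = occc(arr[:, [colmap[c] for c in t.columns]])
    return batteries


def select_reproducible(batteries: list[OCCCBattery],
                        occc_min: float = 0.85,
                        min_passing_tests: int = 10) -> list[str]:
    """Reproducible feature bases under the selection rules.

    First-order features are kept iff their single OCCC >= occc_min;
    high-order features iff at least ``min_passing_tests`` of their 33 OCCCs
    are strictly greater than occc_min (the asymmetric boundary conventions
    are intentional and literal).  Undefined (NaN) OCCCs never count.
    """
    kept = []
    for bat in batteries:
        if bat.family == "firstorder":
            v = bat.tests[0].occc
            if np.isfinite(v) and v >= occc_min:
                kept.append(bat.base)
        else:
            if bat.n_passing(occc_min) >= min_passing_tests:
                kept.append(bat.base)
    return kept


def battery_report(batteries: list[OCCCBattery]) -> pd.DataFrame:
    """Long-format OCCC report (feature, varied_parameter, fixed_setting, occc)."""
    rows = [
        {"feature": b.base, "family": b.family, "varied_parameter": t.varied,
         "fixed_setting": t.fixed, "occc": t.occc}
        for b in batteries for t in b.tests
    ]
    return pd.DataFrame(rows)
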