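"""Univariate prognostic screening by Harrell's C-index and redundancy pruning.

For censored survival data the concordance index is the fraction of usable
patient pairs (the earlier time carries an event) in which the patient with
the higher predictor value fails first; ties in the predictor count 1/2.
C > 0.5 marks a positive risk association, C < 0.5 a protective one.

The selection chain keeps measures with C >= c_high or C <= c_low, then
greedily removes the less prognostic member of every feature pair whose
Spearman |rho| exceeds corr_max ("more prognostic" = larger |C - 0.5|, so
positively and negatively associated features compete on equal footing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv


@dataclass(frozen=True)
class ScreeningThresholds:
    occc_min: float = 0.85
    min_passing_tests: int = 10
    c_high: float = 0.60
    c_low: float = 0.40
    corr_max: float = 0.90
    max_missing: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.c_low < 0.5 < self.c_high < 1:
            raise ValueError("need 0 < c_low < 0.5 < c_high < 1")


def to_structured(survival: pd.DataFrame) -> np.ndarray:
    """Survival frame (columns time_days, event) -> scikit-survival format."""
    return Surv.from_arrays(
        event=survival["event"].astype(bool).to_numpy(),
        time=survival["time_days"].to_numpy(),
    )


def cindex(values: np.ndarray, survival: pd.DataFrame) -> float:
    """Harrell's concordance index of a predictor against censored survival."""
    values = np.asarray(values, dtype=float)
    if values.size != len(survival) or values.size < 2:
        raise ValueError("predictor and survival must align, n >= 2")
    event = survival["event"].astype(bool).to_numpy()
    if not event.any():
        raise ValueError("need at least one event")
    c, *_ = concordance_index_censored(event, survival["time_days"].to_numpy(), values)
    return float(c)


def clean_feature_table(table: pd.DataFrame,
                        max_missing: float = 0.20) -> pd.DataFrame:
    """Drop columns missing in more than ``max_missing`` of patients,
    median-impute the remainder, and drop all-constant columns' NaNs safely."""
    arr = table.to_numpy(dtype=float)
    frac = np.isnan(arr).mean(axis=0)
    keep = frac <= max_missing
    arr = arr[:, keep]
    nan_r, nan_c = np.nonzero(np.isnan(arr))
    if nan_r.size:
        med = np.nanmedian(arr, axis=0)
        arr[nan_r, nan_c] = med[nan_c]
    return pd.DataFrame(arr, index=table.index, columns=table.columns[keep])


def cindex_table(table: pd.DataFrame, survival: pd.DataFrame) -> pd.Series:
    """Per-column C-index; constant columns are NaN (no usable ordering)."""
    survival = survival.loc[table.index]
    out = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        if np.nanstd(v) == 0 or np.isnan(v).any():
            out[col] = np.nan
            continue
        out[col] = cindex(v, survival)
    return pd.Series(out, name="cindex")


def select_prognostic(cindices: pd.Series,
                      c_high: float = 0.60, c_low: float = 0.40) -> list[str]:
    keep = cindices[(cindices >= c_high) | (cindices <= c_low)]
    return list(keep.index)


def prune_correlated(table: pd.DataFrame, cindices: pd.Series,
                     corr_max: float = 0.90) -> list[str]:
    """Greedy redundancy pruning on Spearman correlation.

    Pairs with |rho| >= corr_max are visited in descending |rho| (ties broken
    by column order); in each still-alive pair the feature with the larger
    |C - 0.5| survives, the other is removed.  Deterministic.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    rho, _ = stats.spearmanr(table.to_numpy(), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    prog = np.abs(cindices.loc[cols].to_numpy() - 0.5)

    pairs = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = abs(rho[a, b])
            if r >= corr_max:
                pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    alive = np.ones(len(cols), dtype=bool)
    for _, a, b in pairs:
        if alive[a] and alive[b]:
            if prog[a] > prog[b]:
                alive[b] = False
            elif prog[b] > prog[a]:
                alive[a] = False
            else:
                alive[b] = False  # tie: keep the earlier column
    return [c for c, keep in zip(cols, alive) if keep]


@dataclass
class ScreeningReport:
    """Results of the full screening chain on a training cohort."""

    occc_report: pd.DataFrame
    reproducible_bases: list[str]
    cindices: pd.Series
    prognostic: list[str]
    selected: list[str]


def screen(table: pd.DataFrame, survival: pd.DataFrame,
           thresholds: ScreeningThresholds = ScreeningThresholds()) -> ScreeningReport:
    """Reproducibility -> prognosis -> redundancy screening of a feature table.

    Expects the full-grid table of a training cohort; returns the surviving
    measure columns plus the intermediate per-feature diagnostics.
    """
    from .features.extract import FeatureKey
    from .reproducibility import battery_report, build_batteries, select_reproducible

    clean = clean_feature_table(table, thresholds.max_missing)
    batteries = build_batteries(clean, on_missing="skip")
    bases = select_reproducible(batteries, thresholds.occc_min,
                                thresholds.min_passing_tests)
    base_set = set(bases)
    measure_cols = [c for c in clean.columns if FeatureKey.parse(c).base in base_set]
    cindices = cindex_table(clean[measure_cols], survival).dropna()
    prognostic = select_prognostic(cindices, thresholds.c_high, thresholds.c_low)
    selected = prune_correlated(clean[prognostic], cindices, thresholds.corr_max)
    return ScreeningReport(
        occc_report=battery_report(batteries),
        reproducible_bases=bases,
        cindices=cindices,
        prognostic=prognostic,
        selected=selected,
    )
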