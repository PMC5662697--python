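"""First-order intensity statistics (12 titles).

Computed on the raw, unquantized intensity sample of a subregion; only the
histogram-based entropy and uniformity discretize, using a fixed 64-bin
histogram over the sample range.  Kurtosis is reported non-excess (a normal
sample gives ~3).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

FIRSTORDER_TITLES = (
    "mean", "median", "minimum", "maximum", "range", "std", "variance",
    "skewness", "kurtosis", "energy", "entropy", "uniformity",
)

_HIST_BINS = 64


def first_order_features(values: np.ndarray) -> dict[str, float]:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty intensity sample")

    out: dict[str, float] = {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "energy": float(np.sum(x ** 2)),
    }

    var = float(x.var()) if x.size >= 2 else 0.0
    if x.size < 2:
        warnings.warn("sample size < 2: dispersion features reported as 0")
    if var > 0:
        out["std"] = float(x.std())
        out["variance"] = var
        out["skewness"] = float(stats.skew(x))
        out["kurtosis"] = float(stats.kurtosis(x, fisher=False))
    else:
        # zero-variance sample: dispersion and shape moments degenerate
        out["std"] = out["variance"] = 0.0
        out["skewness"] = out["kurtosis"] = 0.0

    counts, _ = np.histogram(x, bins=_HIST_BINS)
    p = counts[counts > 0] / x.size
    out["entropy"] = float(-np.sum(p * np.log2(p)))
    out["uniformity"] = float(np.sum(p ** 2))
    return out
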