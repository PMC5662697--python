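"""Multiparametric radiomics signature: LASSO-Cox fit, risk score and validation.

The signature is a sparse linear predictor on screened feature measures.
Features are z-standardized on training statistics; an L1-penalized Cox
partial-likelihood path (glmnet-style) is fitted and the penalty weight
lambda is chosen by 10-fold cross-validated partial-likelihood deviance
(Verweij & van Houwelingen), minimum criterion.  The risk score of a patient
is the weighted sum of the standardized selected features; a training-derived
optimal cutpoint (maximally selected log-rank statistic with a 10% minimum
group size) stratifies patients into low-/high-risk groups, validated by
C-index, Kaplan-Meier curves, the G-rho weighted log-rank test (rho = 1) and
the hazard ratio of the group indicator.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored

from .screening import (
    ScreeningThresholds,
    cindex_table,
    clean_feature_table,
    select_prognostic,
    to_structured,
)
from .standardization import ParameterSetting

log = logging.getLogger(__name__)


# ------------------------------------------------------------------- model


@dataclass
class SignatureModel:
    """A fitted radiomics signature (selected measures, Cox weights, cutoff).

    ``weights`` apply to features standardized with the stored training
    ``center``/``scale``; the risk score is sum_k w_k (x_k - c_k)/s_k.
    """

    features: list[str]
    weights: np.ndarray
    lam: float
    center: np.ndarray
    scale: np.ndarray
    cutoff: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return len(self.features) == 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": self.features,
            "weights": np.asarray(self.weights).tolist(),
            "lambda": self.lam,
            "center": np.asarray(self.center).tolist(),
            "scale": np.asarray(self.scale).tolist(),
            "cutoff": self.cutoff,
            "standardization": "z-score on training statistics",
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=d["features"],
            weights=np.asarray(d["weights"]),
            lam=d["lambda"],
            center=np.asarray(d["center"]),
            scale=np.asarray(d["scale"]),
            cutoff=d["cutoff"],
            meta=d.get("meta", {}),
        )


def rad_score(model: SignatureModel, features: pd.DataFrame) -> np.ndarray:
    """Risk score per patient: weighted sum of training-standardized features."""
    for f in model.features:
        if f not in features.columns:
            raise KeyError(f"feature {f!r} required by the signature is missing")
    if model.degenerate:
        return np.zeros(len(features))
    X = features[model.features].to_numpy(dtype=float)
    Z = (X - model.center) / model.scale
    return Z @ np.asarray(model.weights)


# -------------------------------------------------- Cox partial likelihood


def cox_partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                       beta: np.ndarray) -> float:
    """Breslow-ties Cox log partial likelihood at coefficient vector beta."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = X @ np.asarray(beta, dtype=float)
    order = np.argsort(time, kind="stable")
    t, e, eta = np.asarray(time)[order], np.asarray(event, bool)[order], eta[order]
    # risk-set denominators: reverse cumulative sum, shared across tied times
    rev = np.cumsum(np.exp(eta)[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    return float(np.sum(eta[e] - np.log(rev[first][e])))


def _event_stratified_folds(event: np.ndarray, n_folds: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Fold labels such that events and censorings spread evenly over folds."""
    n = event.size
    folds = np.empty(n, dtype=int)
    for group in (np.flatnonzero(event), np.flatnonzero(~event)):
        perm = rng.permutation(group)
        folds[perm] = np.arange(perm.size) % n_folds
    return folds


def fit_lasso_cox(
    X: pd.DataFrame,
    survival: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    alphas: np.ndarray | None = None,
) -> SignatureModel:
    """L1-penalized Cox model with lambda chosen by cross-validated deviance.

    Features are z-standardized on the training sample.  The cross-validation
    error of a penalty value is the Verweij-van Houwelingen partial-likelihood
    deviance  -2 * [ pl_full(beta_-k) - pl_without_fold_k(beta_-k) ] summed
    over folds; the minimum-criterion lambda is kept and the model refitted on
    the full training set.  Fold assignment is seeded and stratified by event
    status so every fold holds events.
    """
    survival = survival.loc[X.index]
    time = survival["time_days"].to_numpy(float)
    event = survival["event"].astype(bool).to_numpy()
    n, p = X.shape
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} patients for {n_folds}-fold CV")

    center = X.mean(axis=0).to_numpy()
    scale = X.std(axis=0, ddof=0).to_numpy()
    scale[scale == 0] = 1.0
    Z = (X.to_numpy(float) - center) / scale
    y = to_structured(survival)

    def coxnet(alpha_path=None):
        kw = dict(l1_ratio=1.0, normalize=False, fit_baseline_model=False,
                  tol=1e-9, max_iter=10 ** 6)
        if alpha_path is not None:
            kw["alphas"] = np.asarray(alpha_path, dtype=float)
        else:
            kw["n_alphas"] = 100
            kw["alpha_min_ratio"] = 0.01
        return CoxnetSurvivalAnalysis(**kw)

    path_model = coxnet(alphas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # an all-zero path is a valid outcome
        path_model.fit(Z, y)
    alpha_path = np.asarray(path_model.alphas_)

    if alpha_path.size == 1:
        best_idx = 0
        cv_dev = np.zeros(1)
    else:
        rng = np.random.default_rng(seed)
        folds = _event_stratified_folds(event, n_folds, rng)
        cv_dev = np.zeros(alpha_path.size)
        for k in range(n_folds):
            keep = folds != k
            mk = coxnet(alpha_path)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mk.fit(Z[keep], y[keep])
            coefs = mk.coef_  # p x n_alphas (may be truncated by early stop)
            for a in range(alpha_path.size):
                beta = coefs[:, min(a, coefs.shape[1] - 1)]
                pl_full = cox_partial_loglik(Z, time, event, beta)
                pl_sub = cox_partial_loglik(Z[keep], time[keep], event[keep], beta)
                cv_dev[a] += -2.0 * (pl_full - pl_sub)
        best_idx = int(np.argmin(cv_dev))

    beta = path_model.coef_[:, best_idx]
    active = np.flatnonzero(beta)
    if active.size >= n / 10:
        log.warning(
            "signature keeps %d features for %d patients (> n/10 guideline)",
            active.size, n,
        )
    return SignatureModel(
        features=[X.columns[j] for j in active],
        weights=beta[active],
        lam=float(alpha_path[best_idx]),
        center=center[active],
        scale=scale[active],
        meta={
            "n_training": n,
            "n_candidates": p,
            "cv_deviance": cv_dev.tolist(),
            "alphas": alpha_path.tolist(),
        },
    )


# -------------------------------------------------------- weighted log-rank


def weighted_logrank(groups: np.ndarray, survival: pd.DataFrame,
                     rho: float = 1.0) -> tuple[float, float]:
    """G-rho family two-group test; weights are pooled KM survival S(t-)^rho.

    rho = 0 reduces to the standard log-rank test; rho = 1 (Peto-Peto style)
    upweights early survival differences.  Returns (chi-square, p) on 1 df.
    """
    g = np.asarray(groups, dtype=bool)
    if g.all() or (~g).all():
        raise ValueError("need two non-empty groups")
    time = survival["time_days"].to_numpy(float)
    event = survival["event"].astype(bool).to_numpy()
    if not event.any():
        warnings.warn("no events: weighted log-rank undefined, returning p = 1")
        return 0.0, 1.0

    event_times = np.unique(time[event])
    # pooled left-continuous Kaplan-Meier for the weights
    km_t = np.ones_like(event_times)
    surv_prev = 1.0
    U = 0.0
    V = 0.0
    for j, tj in enumerate(event_times):
        at_risk = time >= tj
        nj = at_risk.sum()
        n1j = (at_risk & g).sum()
        dj = (event & (time == tj)).sum()
        d1j = (event & (time == tj) & g).sum()
        w = surv_prev ** rho
        U += w * (d1j - n1j * dj / nj)
        if nj > 1:
            V += w ** 2 * dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
        surv_prev *= 1.0 - dj / nj
    if V == 0:
        return 0.0, 1.0
    chi2 = U ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ----------------------------------------------------------- cutpoint scan


def optimal_cutpoint(scores: np.ndarray, survival: pd.DataFrame,
                     min_group_frac: float = 0.10) -> float:
    """Maximally selected log-rank cutpoint on the training risk scores.

    Candidates are the unique score values; a candidate c assigns high risk to
    score >= c and is admissible when both groups hold at least
    ``min_group_frac`` of patients.  Among admissible candidates the one
    maximizing the standard (rho = 0) log-rank chi-square is returned, ties
    broken toward the smallest cutpoint.  Deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    n_events = int(survival["event"].sum())
    if n < 10 or n_events < 5:
        raise ValueError("cutpoint analysis needs >= 10 patients and >= 5 events")
    min_size = min_group_frac * n
    best = None
    for c in np.unique(scores):
        high = scores >= c
        if high.sum() < min_size or (~high).sum() < min_size:
            continue
        chi2, _ = weighted_logrank(high, survival, rho=0.0)
        if best is None or chi2 > best[0] + 1e-12:
            best = (chi2, float(c))
    if best is None:
        raise ValueError("no admissible cutpoint under the minimum group size")
    return best[1]


# --------------------------------------------------------------- validation


def cindex_with_ci(values: np.ndarray, survival: pd.DataFrame,
                   alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """C-index with an asymptotic (Noether-style) normal-approximation CI."""
    event = survival["event"].astype(bool).to_numpy()
    c, concordant, discordant, tied_risk, _ = concordance_index_censored(
        event, survival["time_days"].to_numpy(), np.asarray(values, float)
    )
    n_pairs = concordant + discordant + tied_risk
    se = np.sqrt(c * (1 - c) / n_pairs) if n_pairs > 0 else np.nan
    zq = stats.norm.ppf(1 - alpha / 2)
    return float(c), (float(c - zq * se), float(c + zq * se))


@dataclass
class StratificationResult:
    """Risk stratification of one cohort under a fitted signature."""

    scores: pd.Series
    groups: pd.Series                  # "low" / "high"
    cindex: float
    cindex_ci: tuple[float, float]
    logrank_stat: float
    logrank_p: float
    hazard_ratio: float
    hazard_ratio_ci: tuple[float, float]
    km_curves: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "cindex": self.cindex,
            "cindex_ci": self.cindex_ci,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
            "hazard_ratio_ci": self.hazard_ratio_ci,
            "n_low": int((self.groups == "low").sum()),
            "n_high": int((self.groups == "high").sum()),
        }


def _group_hazard_ratio(high: np.ndarray, survival: pd.DataFrame):
    df = pd.DataFrame(
        {
            "time": survival["time_days"].to_numpy(float),
            "event": survival["event"].astype(int).to_numpy(),
            "high": high.astype(int),
        }
    )
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        with np.errstate(over="ignore"):  # near-separation: honest infinite bound
            lo, hi = np.exp(cph.confidence_intervals_.loc["high"].to_numpy())
        return hr, (float(lo), float(hi))
    except Exception:  # no events in a group, separation, ...
        return float("nan"), (float("nan"), float("nan"))


def validate_signature(model: SignatureModel, table: pd.DataFrame,
                       survival: pd.DataFrame,
                       training_ids: set[str] | None = None) -> StratificationResult:
    """Score, stratify and evaluate a cohort with a training-fitted signature.

    Scores use the training-time standardization constants; the cutoff is the
    training-derived one.  Refuses cohorts that overlap the training patients
    when ``training_ids`` is provided.
    """
    if training_ids is not None:
        overlap = set(training_ids) & set(table.index)
        if overlap:
            raise ValueError(f"validation cohort overlaps training: {sorted(overlap)[:5]}")
    survival = survival.loc[table.index]
    scores = pd.Series(rad_score(model, table), index=table.index, name="rad_score")
    c, ci = cindex_with_ci(scores.to_numpy(), survival)

    if model.cutoff is None or model.degenerate:
        high = np.zeros(len(table), dtype=bool)
    else:
        high = scores.to_numpy() >= model.cutoff
    groups = pd.Series(np.where(high, "high", "low"), index=table.index, name="risk_group")

    if high.any() and (~high).any():
        chi2, p = weighted_logrank(high, survival, rho=1.0)
        hr, hr_ci = _group_hazard_ratio(high, survival)
    else:
        chi2, p = 0.0, 1.0
        hr, hr_ci = float("nan"), (float("nan"), float("nan"))

    km_curves = {}
    for name, sel in (("low", ~high), ("high", high)):
        if sel.any():
            km = KaplanMeierFitter()
            km.fit(survival["time_days"][sel], survival["event"][sel], label=name)
            sf = km.survival_function_
            km_curves[name] = (sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float))

    return StratificationResult(
        scores=scores, groups=groups, cindex=c, cindex_ci=ci,
        logrank_stat=chi2, logrank_p=p, hazard_ratio=hr, hazard_ratio_ci=hr_ci,
        km_curves=km_curves,
    )


# ------------------------------------------------- fixed-parameter variants


def setting_columns(columns, setting: ParameterSetting) -> list[str]:
    """The 1536-column subset of one fixed setting: the 288 first-order
    measures at its voxel size plus the 1248 high-order measures at its tag."""
    fo_tag = f"@VS{setting.voxel_size:g}"
    ho_tag = f"@{setting.tag}"
    return [c for c in columns
            if c.endswith(ho_tag) or ("firstorder" in c and c.endswith(fo_tag))]


def fit_setting_signature(train_table: pd.DataFrame, train_surv: pd.DataFrame,
                          thresholds: ScreeningThresholds = ScreeningThresholds(),
                          n_folds: int = 10, seed: int = 0) -> SignatureModel:
    """Prognostic screen (C-index thresholds only) + LASSO Cox + cutpoint.

    Used for the fixed-parameter comparators, which skip the reproducibility
    screen: within one setting there is nothing to vary.
    """
    clean = clean_feature_table(train_table, thresholds.max_missing)
    cindices = cindex_table(clean, train_surv).dropna()
    prognostic = select_prognostic(cindices, thresholds.c_high, thresholds.c_low)
    if not prognostic:
        return SignatureModel([], np.zeros(0), np.nan, np.zeros(0), np.zeros(0),
                              meta={"degenerate_reason": "no prognostic features"})
    model = fit_lasso_cox(clean[prognostic], train_surv, n_folds=n_folds, seed=seed)
    if not model.degenerate:
        scores = rad_score(model, clean)
        try:
            model.cutoff = optimal_cutpoint(scores, train_surv.loc[clean.index])
        except ValueError as exc:
            log.warning("no admissible cutpoint: %s", exc)
    return model


def build_fixed_parameter_signatures(
    train_table: pd.DataFrame, train_surv: pd.DataFrame,
    val_table: pd.DataFrame, val_surv: pd.DataFrame,
    grid: list[ParameterSetting],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    n_folds: int = 10, seed: int = 0,
) -> tuple[dict[str, SignatureModel], pd.DataFrame]:
    """One comparator signature per standardization setting, all validated on
    the same cohort.  Settings where nothing survives screening or the LASSO
    are marked degenerate and excluded from stratification."""
    models: dict[str, SignatureModel] = {}
    rows = []
    for setting in grid:
        cols = setting_columns(train_table.columns, setting)
        model = fit_setting_signature(train_table[cols], train_surv,
                                      thresholds, n_folds, seed)
        models[setting.tag] = model
        row = {"setting": setting.tag, "n_active": len(model.features),
               "lambda": model.lam}
        if model.degenerate:
            row.update(cindex=np.nan, logrank_p=np.nan, hazard_ratio=np.nan,
                       degenerate=True)
            log.warning("setting %s: degenerate signature", setting.tag)
        else:
            res = validate_signature(model, val_table[cols], val_surv)
            row.update(cindex=res.cindex, logrank_p=res.logrank_p,
                       hazard_ratio=res.hazard_ratio, degenerate=False)
        rows.append(row)
    return models, pd.DataFrame(rows).set_index("setting")
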