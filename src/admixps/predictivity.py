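"""Trait-prediction evaluation of PS/aspPS/casPS configurations.

The evaluation design mirrors standard PS benchmarking: a *base* model of
non-genetic covariates (e.g. sex, age polynomials, batch, ancestry
fraction) is compared with an *extended* model that adds one PS
configuration.  Predictivity is the realized R^2 on a prediction set
(Nagelkerke pseudo-R^2 for binary traits, computed from transported model
log-likelihoods); *added* R^2 is realized minus base R^2, with its
standard deviation obtained by bootstrap resampling of the prediction set
(the fitted coefficients are held fixed; a refit mode exists for
sensitivity checks).  Nested models are compared by likelihood-ratio test
and non-nested ones by the classical Vuong closeness test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import HaplotypeMatrix, WeightTable
from .scores import shared_mask_pps

__all__ = [
    "FittedModel",
    "ModelPair",
    "fit_models",
    "realized_r2",
    "added_r2",
    "nagelkerke_r2",
    "added_r2_bootstrap",
    "likelihood_ratio_test",
    "vuong_test",
    "mask_resampling_experiment",
    "balanced_fit_set",
]


def _design(data: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in columns])
    return X


def _check_full_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate offending columns via QR: near-zero diagonal of R
        _, Rm = np.linalg.qr(X)
        diag = np.abs(np.diag(Rm))
        scale = diag.max() if diag.max() > 0 else 1.0
        names = ["(intercept)"] + list(columns)
        bad = [names[i] for i in np.where(diag < 1e-8 * scale)[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


@dataclass
class FittedModel:
    """A fitted GLM: intercept + named covariate columns."""

    columns: list[str]
    family: str  # "gaussian" | "binomial"
    params: np.ndarray
    llf: float
    nobs: int
    scale_mle: float | None = None  # gaussian residual sd (MLE), for loglik
    outcome: np.ndarray = field(default=None, repr=False)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        eta = _design(data, self.columns) @ self.params
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def pointwise_loglik(self, data: pd.DataFrame, y: np.ndarray) -> np.ndarray:
        mu = self.predict(data)
        if self.family == "binomial":
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            return y * np.log(mu) + (1 - y) * np.log(1 - mu)
        return stats.norm.logpdf(y, loc=mu, scale=self.scale_mle)


@dataclass
class ModelPair:
    base: FittedModel
    extended: FittedModel
    label: str = ""


def _fit_one(data: pd.DataFrame, outcome: str, columns: list[str], family: str) -> FittedModel:
    y = data[outcome].to_numpy(float)
    X = _design(data, columns)
    _check_full_rank(X, columns)
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        scale_mle = float(np.sqrt(np.mean(res.resid**2)))
        llf = float(res.llf)
    elif family == "binomial":
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binomial outcome must be coded 0/1")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        scale_mle = None
        llf = float(res.llf)
    else:
        raise ValueError(f"unknown family {family!r}")
    return FittedModel(
        columns=list(columns),
        family=family,
        params=np.asarray(res.params, float),
        llf=llf,
        nobs=len(y),
        scale_mle=scale_mle,
        outcome=y,
    )


def fit_models(
    data: pd.DataFrame,
    outcome: str,
    base_covariates: list[str],
    ps_columns: list[str],
    family: str = "gaussian",
    label: str = "",
) -> ModelPair:
    """Fit the base (covariates-only) and extended (base + PS) models.

    ``ps_columns`` is the PS configuration under test: a single total PS,
    the set of aspPS columns, a casPS column, or total PS plus ancestry
    fraction.  Rows with missing values in any used column are dropped
    (complete-case, identical rows for both models).
    """
    used = [outcome] + list(base_covariates) + list(ps_columns)
    sub = data[used].dropna()
    base = _fit_one(sub, outcome, list(base_covariates), family)
    ext = _fit_one(sub, outcome, list(base_covariates) + list(ps_columns), family)
    return ModelPair(base=base, extended=ext, label=label)


def nagelkerke_r2(null_loglik: float, full_loglik: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from null and full model log-likelihoods."""
    if n <= 0:
        raise ValueError("n must be positive")
    num = 1.0 - np.exp(2.0 * (null_loglik - full_loglik) / n)
    den = 1.0 - np.exp(2.0 * null_loglik / n)
    if den == 0:
        raise ValueError("degenerate null likelihood")
    return float(num / den)


def realized_r2(model: FittedModel, data: pd.DataFrame, outcome: str) -> float:
    """R^2 of a fitted model's predictions on a (possibly new) sample set.

    Gaussian: 1 - SS_res/SS_tot.  Binomial: Nagelkerke R^2 with the null
    log-likelihood from the evaluation set's own prevalence.
    """
    sub = data[[outcome] + model.columns].dropna()
    y = sub[outcome].to_numpy(float)
    if model.family == "gaussian":
        pred = model.predict(sub)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError("constant outcome on evaluation set")
        return 1.0 - ss_res / ss_tot
    p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    l0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
    l1 = float(model.pointwise_loglik(sub, y).sum())
    return nagelkerke_r2(l0, l1, len(y))


def added_r2(pair: ModelPair, data: pd.DataFrame, outcome: str) -> float:
    """Realized R^2 of the extended model minus the base model's."""
    return realized_r2(pair.extended, data, outcome) - realized_r2(
        pair.base, data, outcome
    )


def added_r2_bootstrap(
    pair: ModelPair,
    data: pd.DataFrame,
    outcome: str,
    n_boot: int = 5000,
    seed=None,
    refit: bool = False,
) -> tuple[float, float]:
    """Added R^2 on a prediction set and its bootstrap standard deviation.

    Bootstrap replicates resample prediction-set individuals with
    replacement; coefficients stay fixed unless ``refit`` is set.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    used = [outcome] + pair.extended.columns
    sub = data[used].dropna().reset_index(drop=True)
    point = added_r2(pair, sub, outcome)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    n = len(sub)
    for k in range(n_boot):
        boot = sub.iloc[rng.integers(0, n, n)]
        if refit:
            rp = fit_models(
                boot, outcome, pair.base.columns,
                [c for c in pair.extended.columns if c not in pair.base.columns],
                family=pair.base.family,
            )
            vals[k] = added_r2(rp, boot, outcome)
        else:
            vals[k] = added_r2(pair, boot, outcome)
    return point, float(vals.std(ddof=1))


def likelihood_ratio_test(base: FittedModel, extended: FittedModel) -> float:
    """Chi-squared LRT p-value of nested fitted models."""
    if not set(base.columns) <= set(extended.columns):
        raise ValueError("models are not nested")
    if base.nobs != extended.nobs:
        raise ValueError("models fitted on different samples")
    df = len(extended.columns) - len(base.columns)
    if df == 0:
        return 1.0
    stat = max(2.0 * (extended.llf - base.llf), 0.0)
    return float(stats.chi2.sf(stat, df))


def vuong_test(
    model1: FittedModel, model2: FittedModel, data: pd.DataFrame, outcome: str
) -> tuple[float, float, int]:
    """Classical Vuong closeness test for non-nested models.

    Returns ``(z, two-sided p, preferred)`` with preferred 1 when model1
    fits the data better (z > 0), 2 otherwise.  No AIC/BIC correction and
    no preliminary variance test are applied.
    """
    sub = data[
        sorted(set([outcome] + model1.columns + model2.columns))
    ].dropna()
    y = sub[outcome].to_numpy(float)
    m = model1.pointwise_loglik(sub, y) - model2.pointwise_loglik(sub, y)
    n = len(m)
    omega = float(m.std(ddof=0))
    if omega == 0:
        raise ValueError("indistinguishable models (identical pointwise likelihoods)")
    z = float(np.sqrt(n) * m.mean() / omega)
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p, (1 if z > 0 else 2)


def mask_resampling_experiment(
    genos: HaplotypeMatrix,
    mask_library: list[np.ndarray],
    weights: WeightTable | np.ndarray,
    reference: HaplotypeMatrix,
    data: pd.DataFrame,
    outcome: str,
    base_covariates: list[str],
    family: str = "gaussian",
) -> pd.DataFrame:
    """Predictivity of pPS built from a library of genomic subsets.

    Each mask (a boolean site-selection shared by all individuals of the
    uniform cohort) yields a pPS distribution, which is plugged into the
    base model; one output row per mask reports the genomic fraction, the
    added R^2 over the base model and the LRT p-value.  Empty masks are
    excluded.
    """
    rows = []
    for k, sel in enumerate(mask_library):
        sel = np.asarray(sel, dtype=bool)
        if sel.sum() == 0:
            continue
        tab = shared_mask_pps(genos, weights, sel, reference)
        merged = data.merge(
            tab[["sample", "pps"]].rename(columns={"pps": "_pps"}), on="sample"
        )
        pair = fit_models(merged, outcome, base_covariates, ["_pps"], family=family)
        rows.append(
            {
                "mask": k,
                "fraction": float(sel.mean()),
                "added_r2": added_r2(pair, merged, outcome),
                "lrt_p": likelihood_ratio_test(pair.base, pair.extended),
            }
        )
    return pd.DataFrame(rows)


def balanced_fit_set(
    data: pd.DataFrame, group_column: str, seed=None
) -> pd.DataFrame:
    """Downsample every group to the smallest group's size (seeded)."""
    rng = np.random.default_rng(seed)
    sizes = data[group_column].value_counts()
    target = int(sizes.min())
    parts = []
    for g, sub in data.groupby(group_column, sort=False):
        idx = rng.choice(len(sub), size=target, replace=False)
        parts.append(sub.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)
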