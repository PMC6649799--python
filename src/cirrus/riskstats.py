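"""Risk-gradient statistics: OPERA adjustment, OR per adjusted SD,
interquartile risk ratio, and AUC conversions.

A continuous risk measure is made comparable across measures and studies
by the OPERA convention: regress it on age and log BMI *among controls*,
take every woman's residual from that control-fitted model, and scale by
the control-residual SD.  Risk gradients are then odds ratios per one SD
of the adjusted measure, from logistic regression with age and log BMI
as covariates, with Wald inference.

For a normally distributed risk factor and a relatively rare disease the
OR per SD converts in closed form to the interquartile risk ratio

    IQRR = Phi(log OR - b) / Phi(a - log OR),

with a = Phi^-1(0.25) = -b, and to the ROC area under the equal-variance
normal model, AUC = Phi(log OR / sqrt 2).  The standardized case-control
mean difference of such a factor equals log OR, giving OR = exp(delta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: quartile points of the standard normal: a = Phi^-1(0.25) = -b
IQRR_A = float(stats.norm.ppf(0.25))
IQRR_B = float(stats.norm.ppf(0.75))

_Z95 = 1.959964  # 95% Wald multiplier


class SeparationError(RuntimeError):
    """Perfect separation: use the Bayesian-lasso model instead."""


@dataclass
class ORResult:
    """Odds ratio per adjusted SD with 95% Wald interval."""

    or_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    log_or: float
    se_log_or: float
    n_cases: int
    n_controls: int

    def __post_init__(self):
        assert self.ci_low < self.or_per_sd < self.ci_high

    def __str__(self):
        return (
            f"OR {self.or_per_sd:.2f} (95% CI {self.ci_low:.2f} to "
            f"{self.ci_high:.2f}), P = {self.p_value:.2g}"
        )


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


def opera_adjust(measure, age, bmi, status, use_log_bmi: bool = True) -> np.ndarray:
    """Age/BMI-adjusted measure in control-residual SD units.

    OLS of the measure on age and log BMI is fitted on controls only;
    residuals from that model are computed for all women and divided by
    the control-residual SD (so controls have mean 0, SD 1 exactly).
    Rows with missing measure/age/BMI are propagated as NaN.
    """
    measure = np.asarray(measure, dtype=np.float64)
    age = np.asarray(age, dtype=np.float64)
    bmi = np.asarray(bmi, dtype=np.float64)
    status = np.asarray(status).astype(int)
    bmi_term = np.log(bmi) if use_log_bmi else bmi
    design = sm.add_constant(np.column_stack([age, bmi_term]))

    ok = ~(np.isnan(measure) | np.isnan(age) | np.isnan(bmi))
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} rows with missing values set to NaN")
    controls = ok & (status == 0)
    if controls.sum() < 10:
        raise ValueError("need at least 10 controls for the OPERA adjustment")
    Xc = design[controls]
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("singular adjustment design (constant age/BMI)")
    fit = sm.OLS(measure[controls], Xc).fit()
    resid_sd = float(np.std(fit.resid, ddof=1))
    if resid_sd < 1e-12:
        raise ValueError("zero control residual SD: measure is a perfect "
                         "function of age/BMI among controls")
    adjusted = np.full(measure.shape, np.nan)
    adjusted[ok] = (measure[ok] - design[ok] @ fit.params) / resid_sd
    return adjusted


def adjusted_or(adjusted, status, age, bmi, extra_measures=None,
                use_log_bmi: bool = True) -> ORResult:
    """OR per adjusted SD from logistic regression with age and log BMI.

    ``extra_measures`` (array n x k or DataFrame) enter the model as
    additional covariates — the joint-model semantics used to ask how
    much one measure's gradient attenuates given another.  The returned
    ORResult describes the first (primary) measure; use
    :func:`joint_adjusted_or` for a full table.
    """
    adjusted = np.asarray(adjusted, dtype=np.float64)
    status = np.asarray(status).astype(int)
    age = np.asarray(age, dtype=np.float64)
    bmi = np.asarray(bmi, dtype=np.float64)
    cols = [adjusted]
    if extra_measures is not None:
        extra = np.asarray(extra_measures, dtype=np.float64)
        if extra.ndim == 1:
            extra = extra[:, None]
        cols.extend(extra.T)
    bmi_term = np.log(bmi) if use_log_bmi else bmi
    X = sm.add_constant(np.column_stack(cols + [age, bmi_term]))
    ok = ~np.isnan(X).any(axis=1)
    X, y = X[ok], status[ok]
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both cases and controls are required")
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=False)
    except Exception as exc:
        raise SeparationError(
            "logistic fit failed (possible separation); consider the "
            "Bayesian-lasso model, which handles separation via its prior"
        ) from exc
    b = float(fit.params[1])
    se = float(fit.bse[1])
    return ORResult(
        or_per_sd=float(np.exp(b)),
        ci_low=float(np.exp(b - _Z95 * se)),
        ci_high=float(np.exp(b + _Z95 * se)),
        p_value=float(fit.pvalues[1]),
        log_or=b,
        se_log_or=se,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
    )


def joint_adjusted_or(measures: pd.DataFrame, status, age, bmi,
                      use_log_bmi: bool = True) -> pd.DataFrame:
    """One joint logistic model; an OR row per measure (plus log BMI).

    Reproduces the layout of a combined-model risk table: every column of
    ``measures`` enters simultaneously, each summarized by its OR per SD
    with 95% CI and Wald p.
    """
    status = np.asarray(status).astype(int)
    age = np.asarray(age, dtype=np.float64)
    bmi = np.asarray(bmi, dtype=np.float64)
    bmi_term = np.log(bmi) if use_log_bmi else bmi
    M = measures.to_numpy(dtype=np.float64)
    X = sm.add_constant(np.column_stack([M, age, bmi_term]))
    ok = ~np.isnan(X).any(axis=1)
    fit = sm.Logit(status[ok], X[ok]).fit(disp=False)
    rows = []
    names = list(measures.columns) + ["age", "log_bmi" if use_log_bmi else "bmi"]
    for j, name in enumerate(names, start=1):
        b, se = float(fit.params[j]), float(fit.bse[j])
        rows.append({
            "measure": name,
            "or": np.exp(b),
            "ci_low": np.exp(b - _Z95 * se),
            "ci_high": np.exp(b + _Z95 * se),
            "p": float(fit.pvalues[j]),
            "log_or": b,
        })
    return pd.DataFrame(rows).set_index("measure")


def iqrr(or_per_sd: float) -> float:
    """Interquartile risk ratio implied by an OR per SD.

    Closed form for a normal risk factor and a relatively rare disease:
    the ratio of mean risk in the top versus bottom quartile of the
    factor's distribution.
    """
    if or_per_sd <= 0:
        raise ValueError("or_per_sd must be positive")
    log_or = np.log(or_per_sd)
    return float(
        stats.norm.cdf(log_or - IQRR_B) / stats.norm.cdf(IQRR_A - log_or)
    )


def auc_from_log_or(log_or: float) -> float:
    """ROC area implied by a log OR per SD under the equal-variance
    normal model; approximately linear in log OR over AUC 0.5 to 0.7."""
    return float(stats.norm.cdf(log_or / np.sqrt(2.0)))


def or_from_mean_difference(delta: float) -> float:
    """OR per SD implied by a standardized case-control mean difference."""
    return float(np.exp(delta))


def empirical_auc(scores, status) -> AUCResult:
    """Mann-Whitney AUC (ties count 1/2) with the Hanley-McNeil 95% CI."""
    scores = np.asarray(scores, dtype=np.float64)
    status = np.asarray(status).astype(int)
    cases = scores[status == 1]
    controls = scores[status == 0]
    n1, n0 = cases.size, controls.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both cases and controls are required")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    half = _Z95 * np.sqrt(max(var, 0.0))
    return AUCResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_cases=n1, n_controls=n0,
    )


def roc_curve(scores, status) -> pd.DataFrame:
    """ROC coordinates (1 - specificity, sensitivity) at every threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    status = np.asarray(status).astype(int)
    order = np.argsort(-scores, kind="mergesort")
    y = status[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    sens = np.concatenate([[0.0], tps / max(y.sum(), 1)])
    fpr = np.concatenate([[0.0], fps / max((1 - y).sum(), 1)])
    return pd.DataFrame({"fpr": fpr, "sensitivity": sens})


def plot_roc(scores, status, ax=None, label=None):
    """ROC curve of a score; returns the matplotlib axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords = roc_curve(scores, status)
    res = empirical_auc(scores, status)
    ax.plot(coords["fpr"], coords["sensitivity"],
            label=(label or "score") + f" (AUC = {res.auc:.3f})")
    ax.plot([0, 1], [0, 1], color="gray", lw=0.8, ls="--")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax


def transform_density(absolute_density, percent_density):
    """Variance-stabilizing transforms of the conventional density pair.

    Fourth root of absolute dense area (cm^2), cube root of percent
    density; both are then OPERA-adjusted like any other measure.
    """
    absolute_density = np.asarray(absolute_density, dtype=np.float64)
    percent_density = np.asarray(percent_density, dtype=np.float64)
    if np.nanmin(absolute_density) < 0:
        raise ValueError("absolute density must be nonnegative")
    if np.nanmin(percent_density) < 0 or np.nanmax(percent_density) > 100:
        raise ValueError("percent density must be in [0, 100]")
    return absolute_density ** 0.25, np.cbrt(percent_density)
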