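"""Bayesian-lasso logistic regression and the Cirrus risk score.

The texture features are heavily collinear (many pairwise correlations
above 0.9), so ordinary maximum likelihood produces unstable weights and
stepwise selection picks features essentially at random.  The model here
is logistic regression with independent Laplace (double-exponential)
shrinkage priors on the standardized coefficients and a global penalty
that is itself sampled — the Bayesian lasso.  The risk score for a woman
is the linear combination of posterior-mean coefficients and her
standardized features.

Model
-----
    y_i ~ Bernoulli(logit^{-1}(alpha + x_i' beta))      x standardized
    beta_j | tau_j^2 ~ N(0, tau_j^2)
    tau_j^2 | lambda^2 ~ Exp(lambda^2 / 2)              (Laplace mixture)
    lambda^2 ~ Gamma(r, delta)                          r = 1, delta = 0.1
    alpha ~ flat

Posterior exploration is a Gibbs sampler: Pólya-Gamma augmentation makes
the logistic likelihood conditionally Gaussian, the scale-mixture
representation of the Laplace prior gives inverse-Gaussian updates for
1/tau_j^2, and the conjugate Gamma update handles lambda^2.

API follows the statsmodels convention: ``CirrusModel(y, X).fit()``
returns a :class:`CirrusResults` carrying posterior summaries,
diagnostics, ``summary()`` and ``score()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._polya_gamma import polya_gamma

_LAMBDA2_PRIOR = (1.0, 0.1)  # Gamma(shape, rate) hyperprior on lambda^2


@dataclass
class StandardizationParams:
    """Training-set feature means and SDs; scoring always reuses these."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: list[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


class CirrusModel:
    """Bayesian-lasso logistic model of case status on texture features.

    Parameters
    ----------
    endog : array-like of 0/1
        Case (1) / control (0) status, one entry per woman.
    exog : array-like or DataFrame, n x p
        Per-woman aggregated feature values (raw scale; standardization
        happens inside `fit` and is stored with the results).
    feature_names : optional list of column names when exog is an array.
    """

    def __init__(self, endog, exog, feature_names: list[str] | None = None):
        if isinstance(exog, pd.DataFrame):
            feature_names = list(exog.columns)
            exog = exog.to_numpy(dtype=np.float64)
        exog = np.asarray(exog, dtype=np.float64)
        endog = np.asarray(endog, dtype=np.float64).ravel()
        if exog.ndim != 2 or exog.shape[0] != endog.size:
            raise ValueError("endog and exog shapes are inconsistent")
        if not np.isin(endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        keep = ~np.isnan(exog).any(axis=1)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} rows with missing feature values"
            )
        self.endog = endog[keep]
        self.exog = exog[keep]
        if self.endog.sum() < 2 or (1 - self.endog).sum() < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(exog.shape[1])]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, status_col: str = "status",
                       feature_cols: list[str] | None = None) -> "CirrusModel":
        if feature_cols is None:
            from .texture import FEATURE_NAMES
            feature_cols = [c for c in FEATURE_NAMES if c in df.columns]
        return cls(df[status_col].to_numpy(), df[feature_cols])

    def fit(self, n_draws: int = 10000, n_burnin: int = 1000,
            seed: int = 0, store_every: int = 1) -> "CirrusResults":
        """Run the Gibbs sampler and return posterior summaries.

        ``n_draws`` is the total number of posterior draws, the first
        ``n_burnin`` of which are discarded.  Given identical inputs and
        seed the results are bit-identical.
        """
        if n_draws <= n_burnin:
            raise ValueError("n_draws must exceed n_burnin")
        y = self.endog
        n, p = self.exog.shape
        mean = self.exog.mean(axis=0)
        sd = self.exog.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = [self.feature_names[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant feature columns: {bad}")
        std = StandardizationParams(mean, sd, list(self.feature_names))
        X = std.transform(self.exog)
        Z = np.column_stack([np.ones(n), X])

        rng = np.random.default_rng(seed)
        kappa = y - 0.5
        beta = np.zeros(p)
        alpha = 0.0
        inv_tau2 = np.ones(p)
        lam2 = 1.0
        omega = np.empty(n)
        r0, d0 = _LAMBDA2_PRIOR

        n_keep = (n_draws - n_burnin + store_every - 1) // store_every
        coef_samples = np.empty((n_keep, p))
        intercept_samples = np.empty(n_keep)
        lam2_samples = np.empty(n_keep)
        kept = 0
        Zt_kappa = Z.T @ kappa

        for it in range(n_draws):
            eta = alpha + X @ beta
            polya_gamma(rng, eta, omega)
            # (alpha, beta) | omega  ~  N(m, V),  V^-1 = Z' Omega Z + D
            prec = (Z * omega[:, None]).T @ Z
            prec[np.arange(1, p + 1), np.arange(1, p + 1)] += inv_tau2
            chol = np.linalg.cholesky(prec)
            m = np.linalg.solve(chol.T, np.linalg.solve(chol, Zt_kappa))
            draw = m + np.linalg.solve(chol.T, rng.standard_normal(p + 1))
            alpha, beta = draw[0], draw[1:]
            # 1/tau_j^2 | beta, lambda ~ InvGauss(sqrt(lambda^2/beta_j^2), lambda^2)
            babs = np.maximum(np.abs(beta), 1e-10)
            inv_tau2 = rng.wald(np.sqrt(lam2) / babs, lam2)
            # lambda^2 | tau ~ Gamma(r + p, delta + sum(tau_j^2)/2)
            lam2 = rng.gamma(r0 + p, 1.0 / (d0 + 0.5 * np.sum(1.0 / inv_tau2)))
            if it >= n_burnin and (it - n_burnin) % store_every == 0:
                coef_samples[kept] = beta
                intercept_samples[kept] = alpha
                lam2_samples[kept] = lam2
                kept += 1

        return CirrusResults(
            model=self,
            coefficient_samples=coef_samples[:kept],
            intercept_samples=intercept_samples[:kept],
            regularization_samples=lam2_samples[:kept],
            n_draws=n_draws,
            n_burnin=n_burnin,
            seed=seed,
            standardization=std,
        )


class CirrusResults:
    """Posterior summaries of a fitted Bayesian-lasso logistic model.

    ``params`` are posterior-mean coefficients on the standardized scale —
    the standardized weights of the risk score.  ``score`` produces the
    Cirrus linear predictor for new women using the training
    standardization.
    """

    def __init__(self, model, coefficient_samples, intercept_samples,
                 regularization_samples, n_draws, n_burnin, seed,
                 standardization):
        self.model = model
        self.coefficient_samples = coefficient_samples
        self.intercept_samples = intercept_samples
        self.regularization_samples = regularization_samples
        self.n_draws = n_draws
        self.n_burnin = n_burnin
        self.seed = seed
        self.standardization = standardization
        self.feature_names = standardization.feature_names
        self._check_convergence()

    # -- posterior summaries -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(
            self.coefficient_samples.mean(axis=0), index=self.feature_names,
            name="standardized_weight",
        )

    @property
    def intercept(self) -> float:
        return float(self.intercept_samples.mean())

    @property
    def posterior_sd(self) -> pd.Series:
        return pd.Series(
            self.coefficient_samples.std(axis=0, ddof=1),
            index=self.feature_names, name="posterior_sd",
        )

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        lo = (1 - level) / 2
        q = np.quantile(self.coefficient_samples, [lo, 1 - lo], axis=0)
        return pd.DataFrame(
            {"lower": q[0], "upper": q[1]}, index=self.feature_names
        )

    @property
    def rhat(self) -> pd.Series:
        """Split-chain potential scale reduction for each coefficient."""
        s = self.coefficient_samples
        half = s.shape[0] // 2
        chains = np.stack([s[:half], s[half:2 * half]])  # 2 x m x p
        m = chains.shape[1]
        cmeans = chains.mean(axis=1)
        W = chains.var(axis=1, ddof=1).mean(axis=0)
        B = m * cmeans.var(axis=0, ddof=1)
        var_hat = (m - 1) / m * W + B / m
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.sqrt(var_hat / W)
        return pd.Series(r, index=self.feature_names, name="rhat")

    def _check_convergence(self):
        r = self.rhat
        bad = r[r > 1.1]
        if len(bad):
            warnings.warn(
                "possible non-convergence (split-chain Rhat > 1.1) for: "
                + ", ".join(bad.index)
            )

    # -- scoring -------------------------------------------------------------
    def score(self, X, woman_ids=None) -> pd.Series:
        """Cirrus linear risk score for new women.

        The score is Σ_j w_j (x_j - m_j)/s_j with the training
        standardization (m, s); the intercept is omitted — the score is a
        relative measure.  Missing values are imputed at the training mean
        (standardized 0) with a warning; missing columns are an error.
        """
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            if woman_ids is None and X.index.name == "woman_id":
                woman_ids = X.index
            X = X[self.feature_names].to_numpy(dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature dimension mismatch")
        Xs = self.standardization.transform(X)
        if np.isnan(Xs).any():
            warnings.warn("missing feature values imputed at the training mean")
            Xs = np.nan_to_num(Xs, nan=0.0)
        scores = Xs @ self.params.to_numpy()
        return pd.Series(scores, index=woman_ids, name="cirrus")

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        ci = self.credible_interval()
        tab = pd.DataFrame(
            {
                "weight": self.params,
                "post_sd": self.posterior_sd,
                "ci_2.5%": ci["lower"],
                "ci_97.5%": ci["upper"],
                "rhat": self.rhat,
            }
        )
        lam = self.regularization_samples
        lines = [
            "Bayesian lasso logistic regression (Cirrus)",
            "=" * 60,
            f"n obs: {self.model.endog.size}   "
            f"cases: {int(self.model.endog.sum())}   "
            f"draws: {self.n_draws} (burn-in {self.n_burnin}, seed {self.seed})",
            f"intercept (posterior mean): {self.intercept:+.4f}",
            f"lambda^2 posterior mean: {lam.mean():.4f} "
            f"(95% CI {np.quantile(lam, 0.025):.4f} to {np.quantile(lam, 0.975):.4f})",
            "-" * 60,
            tab.round(4).to_string(),
        ]
        return "\n".join(lines)

    def plot_coefficients(self, ax=None):
        """Posterior means with 95% credible intervals, one row per feature."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        ci = self.credible_interval()
        ypos = np.arange(len(self.feature_names))[::-1]
        ax.errorbar(
            self.params.to_numpy(), ypos,
            xerr=np.vstack([
                self.params.to_numpy() - ci["lower"].to_numpy(),
                ci["upper"].to_numpy() - self.params.to_numpy(),
            ]),
            fmt="o", capsize=2,
        )
        ax.axvline(0.0, color="gray", lw=0.8)
        ax.set_yticks(ypos)
        ax.set_yticklabels(self.feature_names)
        ax.set_xlabel("standardized weight (posterior mean, 95% CrI)")
        return ax

    # -- persistence ---------------------------------------------------------
    def to_json(self, path=None) -> str | None:
        """Flat JSON artifact: weights, standardization and sampler meta."""
        payload = {
            "feature_names": self.feature_names,
            "weights": self.params.to_numpy().tolist(),
            "posterior_sd": self.posterior_sd.to_numpy().tolist(),
            "intercept": self.intercept,
            "standardization_mean": self.standardization.mean.tolist(),
            "standardization_sd": self.standardization.sd.tolist(),
            "n_draws": self.n_draws,
            "n_burnin": self.n_burnin,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @staticmethod
    def load_weights(path) -> "FrozenScore":
        with open(path) as fh:
            payload = json.load(fh)
        return FrozenScore(payload)


class FrozenScore:
    """A serialized Cirrus score: weights + training standardization only."""

    def __init__(self, payload: dict):
        self.feature_names = payload["feature_names"]
        self.weights = np.asarray(payload["weights"], dtype=np.float64)
        self.standardization = StandardizationParams(
            np.asarray(payload["standardization_mean"]),
            np.asarray(payload["standardization_sd"]),
            list(self.feature_names),
        )

    def score(self, X) -> pd.Series:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            X = X[self.feature_names].to_numpy(dtype=np.float64)
        Xs = self.standardization.transform(np.asarray(X, dtype=np.float64))
        Xs = np.nan_to_num(Xs, nan=0.0)
        return pd.Series(Xs @ self.weights, name="cirrus")


def cross_study_evaluate(datasets: dict[str, pd.DataFrame],
                         feature_cols: list[str] | None = None,
                         n_draws: int = 10000, n_burnin: int = 1000,
                         seed: int = 0) -> pd.DataFrame:
    """Train-on-one, test-on-each risk-gradient grid across studies.

    For every (train, test) pair of named per-woman tables (columns:
    status, age, bmi + features) the score is trained on ``train``,
    applied to ``test``, OPERA-adjusted within ``test``, and summarized
    as the OR per adjusted SD.  Returns a DataFrame of
    :class:`cirrus.riskstats.ORResult`, rows = training study, columns =
    testing study.
    """
    from .riskstats import adjusted_or, opera_adjust

    if feature_cols is None:
        from .texture import FEATURE_NAMES
        first = next(iter(datasets.values()))
        feature_cols = [c for c in FEATURE_NAMES if c in first.columns]
    names = list(datasets)
    grid = pd.DataFrame(index=names, columns=names, dtype=object)
    for i, train_name in enumerate(names):
        train = datasets[train_name]
        fit = CirrusModel.from_dataframe(train, feature_cols=feature_cols).fit(
            n_draws=n_draws, n_burnin=n_burnin, seed=seed + i,
        )
        for test_name in names:
            test = datasets[test_name]
            scores = fit.score(test[feature_cols]).to_numpy()
            adjusted = opera_adjust(
                scores, test["age"].to_numpy(), test["bmi"].to_numpy(),
                test["status"].to_numpy(),
            )
            grid.loc[train_name, test_name] = adjusted_or(
                adjusted, test["status"].to_numpy(),
                test["age"].to_numpy(), test["bmi"].to_numpy(),
            )
    return grid
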