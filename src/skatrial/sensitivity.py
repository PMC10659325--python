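"""Multivariable regression sensitivity analysis over a model population.

Linear analysis: z-scored log features regressed on z-scored log scaling
factors by ordinary least squares; the standardized coefficients are
directly comparable across parameters (the bar heights of a sensitivity
chart). Logistic analysis: maximum-likelihood fit of a binary outcome
(e.g. DAD development at 2-Hz pacing) on the same standardized predictors;
the intercept b0 sets the outcome probability of the unperturbed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class SensitivityResult:
    """Regression coefficients with labels and fit diagnostics."""

    kind: str                       # "linear" or "logistic"
    parameters: list                # predictor names (perturbed parameters)
    features: list                  # response names (1 for logistic)
    coefficients: np.ndarray        # (n_parameters, n_features)
    intercept: np.ndarray           # (n_features,)
    stderr: np.ndarray              # (n_parameters, n_features)
    n_used: int
    diagnostics: dict = field(default_factory=dict)   # R2 / deviance etc.

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coefficients, index=self.parameters,
                            columns=self.features)

    def summary(self) -> str:
        lines = [f"{self.kind} sensitivity ({self.n_used} variants)"]
        for j, feat in enumerate(self.features):
            lines.append(f"\n  {feat}  (intercept b0 = {self.intercept[j]:+.3g})")
            for key, val in self.diagnostics.items():
                if key.endswith(feat):
                    lines.append(f"    {key} = {val:.4g}")
            order = np.argsort(-np.abs(self.coefficients[:, j]))
            for i in order:
                lines.append(f"    {self.parameters[i]:<14s} "
                             f"{self.coefficients[i, j]:+.4f} "
                             f"(SE {self.stderr[i, j]:.4f})")
        return "\n".join(lines)


def _zscore_log(x: np.ndarray, name: str) -> np.ndarray:
    if np.any(x <= 0):
        raise ValueError(f"{name} must be strictly positive for the log transform")
    lx = np.log(x)
    sd = lx.std(ddof=0, axis=0)
    if np.any(sd == 0):
        raise ValueError(f"{name} has a zero-variance column")
    return (lx - lx.mean(axis=0)) / sd


def linear_sensitivity(factors: pd.DataFrame, features: pd.DataFrame
                       ) -> SensitivityResult:
    """OLS of z-scored log features on z-scored log factors.

    Rows must be aligned (same variants, exclusions already applied).
    Raises on rank deficiency, naming the collinear columns.
    """
    if len(factors) != len(features):
        raise ValueError("factor and feature tables must have aligned rows")
    X = _zscore_log(factors.to_numpy(dtype=float), "scaling factors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify (nearly) collinear columns via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [factors.columns[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = _zscore_log(features.to_numpy(dtype=float), "features")
    Xc = sm.add_constant(X)
    npar, nfeat = X.shape[1], Y.shape[1]
    coefs = np.empty((npar, nfeat))
    ses = np.empty((npar, nfeat))
    intercept = np.empty(nfeat)
    diagnostics = {}
    for j in range(nfeat):
        fit = sm.OLS(Y[:, j], Xc).fit()
        intercept[j] = fit.params[0]
        coefs[:, j] = fit.params[1:]
        ses[:, j] = fit.bse[1:]
        diagnostics[f"r2_{features.columns[j]}"] = float(fit.rsquared)
    return SensitivityResult("linear", list(factors.columns),
                             list(features.columns), coefs, intercept, ses,
                             len(factors), diagnostics)


#: ridge penalty (standardized scale) used only on detected separation
SEPARATION_RIDGE = 1e-4


def logistic_sensitivity(factors: pd.DataFrame, outcome: np.ndarray,
                         outcome_name: str = "outcome") -> SensitivityResult:
    """Maximum-likelihood logistic fit of a binary outcome on z-scored
    log factors. On complete separation the fit falls back to a small ridge
    penalty and records that in the diagnostics."""
    y = np.asarray(outcome, dtype=float)
    if len(factors) != len(y):
        raise ValueError("factor table and outcome must have aligned rows")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("outcome must contain both classes (0 and 1)")
    X = _zscore_log(factors.to_numpy(dtype=float), "scaling factors")
    Xc = sm.add_constant(X)
    model = sm.Logit(y, Xc)
    diagnostics = {}
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=False, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        separated = (not converged) or (not np.all(np.isfinite(fit.bse)))
    except Exception:
        separated = True
        fit = None
    if separated:
        fit = model.fit_regularized(alpha=SEPARATION_RIDGE, disp=False,
                                    maxiter=500)
        diagnostics["separation_fallback_ridge"] = SEPARATION_RIDGE
        bse = np.full(Xc.shape[1], np.nan)
    else:
        bse = np.asarray(fit.bse)
        diagnostics[f"deviance_{outcome_name}"] = float(-2.0 * fit.llf)
    params = np.asarray(fit.params)
    return SensitivityResult(
        "logistic", list(factors.columns), [outcome_name],
        params[1:][:, None], np.array([params[0]]), bse[1:][:, None],
        len(y), diagnostics)


def make_synthetic_linear(n: int, coefficients: dict, noise_sd: float = 0.0,
                          sigma: float = 0.1, seed: int = 0
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic fixture with planted coefficients, for recovery tests.

    Factors are log-normal (sigma); the feature is
    ``exp(sum_k B_k * log(f_k) + noise)`` so the standardized fit recovers
    ``B_k * sd(log f_k) / sd(log feature)``.
    """
    rng = np.random.default_rng(seed)
    names = list(coefficients)
    logf = rng.normal(0.0, sigma, size=(n, len(names)))
    b = np.array([coefficients[k] for k in names])
    logy = logf @ b + rng.normal(0.0, noise_sd, size=n)
    factors = pd.DataFrame(np.exp(logf), columns=names)
    features = pd.DataFrame({"feature": np.exp(logy)})
    return factors, features


def make_synthetic_logistic(n: int, coefficients: dict, intercept: float = 0.0,
                            sigma: float = 0.1, seed: int = 0
                            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic binary fixture from a known logistic model on z-scored
    log factors."""
    rng = np.random.default_rng(seed)
    names = list(coefficients)
    logf = rng.normal(0.0, sigma, size=(n, len(names)))
    z = (logf - logf.mean(0)) / logf.std(0)
    b = np.array([coefficients[k] for k in names])
    eta = intercept + z @ b
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=n) < prob).astype(float)
    return pd.DataFrame(np.exp(logf), columns=names), y
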