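"""Logistic ASD-risk classifier with forward-stepwise AIC selection.

The probability ``q`` that an infant belongs to the high-risk group is
modelled as

    log(q / (1 - q)) = b0 + b1 * x1 + ... + bk * xk,

where the candidate regressors are the 26 movement indices (z-scored
column-wise before entering the model) plus a binary sex dummy.
Coefficients are maximum-likelihood estimates (Newton iterations on the
binomial log-likelihood, via statsmodels); inference is Wald: standard
errors from the observed information, ``z = b / SE`` and two-sided
normal p-values.

Feature selection is pure forward stepwise on the Akaike information
criterion: starting from the intercept-only model, at each step the
single candidate whose addition lowers the AIC the most is added; the
search stops when no addition lowers it.  AIC ties break toward the
lowest candidate column index, making the procedure deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "DesignMatrix",
    "FittedModel",
    "standardize",
    "fit_logistic",
    "forward_stepwise_aic",
    "predict",
    "wald_stats",
    "model_report",
]

#: |beta| beyond this (on z-scored regressors) signals quasi-separation;
#: the candidate set is rejected during selection.
SEPARATION_BETA = 15.0
MAX_ITER = 100
LL_TOL = 1e-8


@dataclass
class DesignMatrix:
    """Standardized regressors plus labels, ready for fitting."""

    X: pd.DataFrame          # z-scored features (+ raw 0/1 sex dummy)
    y: np.ndarray            # 1 = high risk
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def candidates(self) -> list[str]:
        return list(self.X.columns)


def standardize(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    passthrough: tuple[str, ...] = ("sex",),
) -> DesignMatrix:
    """Z-score feature columns and assemble the design matrix.

    Missing cells are imputed with the column median before z-scoring
    (median imputation is neutral under the subsequent centring).
    Columns listed in ``passthrough`` (the sex dummy) are left on their
    0/1 coding.  Constant columns carry no information and are dropped
    with a record in ``dropped``.
    """
    y = np.asarray(labels, dtype=int)
    if len(features) != len(y):
        raise ValueError("features and labels differ in length")
    if len(features) < 2:
        raise ValueError("need at least 2 infants to standardize")
    X = pd.DataFrame(index=features.index)
    dropped: list[str] = []
    for col in features.columns:
        v = features[col].astype(float)
        if v.isna().any():
            v = v.fillna(v.median())
        if col in passthrough:
            X[col] = v
            continue
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            dropped.append(col)
            continue
        X[col] = (v - v.mean()) / sd
    return DesignMatrix(X=X, y=y, dropped=dropped)


@dataclass
class FittedModel:
    """A fitted logistic model with Wald inference and its AIC."""

    terms: list[str]                 # selected regressors, excl. intercept
    beta: dict[str, float]           # includes "intercept"
    se: dict[str, float]
    zvalues: dict[str, float]
    pvalues: dict[str, float]
    aic: float
    loglik: float
    n: int
    converged: bool
    separation: bool = False

    @property
    def k(self) -> int:
        """Number of estimated parameters, intercept included."""
        return len(self.terms) + 1

    def linear_predictor(self, row: pd.Series | dict) -> float:
        eta = self.beta["intercept"]
        for t in self.terms:
            if t not in row:
                raise KeyError(f"design row lacks selected term {t!r}")
            eta += self.beta[t] * float(row[t])
        return eta


def wald_stats(beta: float, se: float) -> tuple[float, float]:
    """Wald z and two-sided normal p from a coefficient and its SE."""
    z = beta / se
    return z, 2.0 * stats.norm.sf(abs(z))


def fit_logistic(design: DesignMatrix, terms: list[str] | None = None) -> FittedModel:
    """ML fit of the logit model on a subset of candidate terms.

    Newton iterations on the log-likelihood (tolerance 1e-8, at most 100
    iterations); quasi-separation is flagged when any standardized
    coefficient exceeds 15 in magnitude or the fit fails to converge.
    """
    terms = list(design.candidates if terms is None else terms)
    if design.n <= len(terms) + 1:
        raise ValueError("need n > number of terms + 1")
    X = sm.add_constant(design.X[terms], has_constant="add") if terms else \
        pd.DataFrame({"const": np.ones(design.n)}, index=design.X.index)
    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(design.y, X).fit(
                method="newton", maxiter=MAX_ITER, tol=LL_TOL, disp=0,
                warn_convergence=False,
            )
        except (np.linalg.LinAlgError, PerfectSeparationError):
            return FittedModel(terms, {}, {}, {}, {}, np.inf, -np.inf,
                               design.n, converged=False, separation=True)

    names = ["intercept" if c == "const" else c for c in X.columns]
    beta = dict(zip(names, np.asarray(res.params, dtype=float)))
    se = dict(zip(names, np.asarray(res.bse, dtype=float)))
    zv, pv = {}, {}
    for name in names:
        zv[name], pv[name] = wald_stats(beta[name], se[name])
    converged = bool(res.mle_retvals.get("converged", True))
    separation = (not converged) or any(
        abs(beta[t]) > SEPARATION_BETA for t in names if t != "intercept"
    )
    return FittedModel(
        terms=terms, beta=beta, se=se, zvalues=zv, pvalues=pv,
        aic=float(res.aic), loglik=float(res.llf), n=design.n,
        converged=converged, separation=separation,
    )


def forward_stepwise_aic(design: DesignMatrix, verbose: bool = False) -> FittedModel:
    """Pure forward-stepwise selection minimizing AIC.

    Starts from the intercept-only model; at each step fits every
    remaining candidate added to the current set and keeps the addition
    with the smallest AIC if it improves on the current one (ties break
    toward the earliest candidate column).  Candidates whose fit shows
    separation or non-convergence are rejected at that step.
    """
    current = fit_logistic(design, [])
    remaining = list(design.candidates)
    while remaining:
        best: FittedModel | None = None
        best_term: str | None = None
        for term in remaining:  # column order == tie-break order
            cand = fit_logistic(design, current.terms + [term])
            if cand.separation or not np.isfinite(cand.aic):
                continue
            if best is None or cand.aic < best.aic - 1e-12:
                best, best_term = cand, term
        if best is None or best.aic >= current.aic:
            break
        if verbose:
            print(f"  + {best_term}: AIC {current.aic:.3f} -> {best.aic:.3f}")
        current = best
        remaining.remove(best_term)
    return current


def predict(model: FittedModel, row: pd.Series | dict) -> float:
    """High-risk probability ``q = 1 / (1 + exp(-eta))`` for one design row."""
    eta = model.linear_predictor(row)
    return float(1.0 / (1.0 + np.exp(-eta)))


def predict_many(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    return np.array([predict(model, X.iloc[i]) for i in range(len(X))])


def model_report(models: dict[str, FittedModel]) -> str:
    """JSON report per arousal state: term table (beta/SE/z/p), AIC, n."""
    out = {}
    for state, m in models.items():
        rows = []
        for name in ["intercept"] + m.terms:
            rows.append({
                "term": name,
                "beta": m.beta[name], "se": m.se[name],
                "z": m.zvalues[name], "p": m.pvalues[name],
            })
        out[state] = {"terms": rows, "aic": m.aic,
                      "loglik": m.loglik, "n": m.n}
    return json.dumps(out, indent=2)
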