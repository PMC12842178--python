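"""Bias-reduced (Firth) logistic regression.

Maximizes the Jeffreys-penalized log-likelihood

    l*(beta) = l(beta) + 1/2 * log det I(beta),

where I(beta) = X' W X is the Fisher information of the logistic model and
W = diag(p_i (1 - p_i)).  The penalty keeps estimates finite under complete
separation — exactly the regime produced by genes whose qualifying-variant
carriers are all cases and no controls, where the ordinary MLE diverges.

The score of the penalized likelihood has the closed form

    U*(beta) = X' (y - p + h * (1/2 - p)),

with h the leverages of the weighted hat matrix
H = W^{1/2} X (X'WX)^{-1} X' W^{1/2}.  Newton iterations on U* with
step-halving on the penalized log-likelihood give the standard
bias-reduction algorithm; the covariance reported is the inverse penalized
information at the optimum, from which Wald odds ratios, confidence
intervals and p-values follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

__all__ = [
    "FirthFit",
    "fit_firth",
    "wald_inference",
    "penalized_lrt",
    "build_design",
    "clean_design",
]


class RankDeficientDesignError(ValueError):
    """Design matrix not full column rank after degenerate-column removal."""


@dataclass
class FirthFit:
    """Result of a penalized logistic fit.

    beta/cov are on the log-odds scale; ``names`` aligns with columns of the
    (possibly cleaned) design; ``dropped`` lists columns removed as
    zero-variance or collinear before fitting.
    """

    beta: np.ndarray
    cov: np.ndarray
    names: list[str]
    converged: bool
    n_iter: int
    max_score: float
    loglik_pen: float
    dropped: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def build_design(
    carrier: np.ndarray,
    sex_male: np.ndarray,
    age_months: np.ndarray,
    family_history: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    """Standard burden-model design: intercept, CAST carrier indicator,
    sex (male=1), standardized age, family history (yes=1).

    Age is centered and scaled to unit SD (constant ages left at 0), so the
    intercept refers to an average-aged, female, no-family-history
    non-carrier.
    """
    age = np.asarray(age_months, dtype=float)
    sd = age.std()
    age_std = (age - age.mean()) / sd if sd > 0 else np.zeros_like(age)
    X = np.column_stack(
        [
            np.ones_like(age),
            np.asarray(carrier, dtype=float),
            np.asarray(sex_male, dtype=float),
            age_std,
            np.asarray(family_history, dtype=float),
        ]
    )
    return X, ["intercept", "carrier", "sex_male", "age_std", "family_history"]


def clean_design(X: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop zero-variance (non-intercept) and collinear columns.

    Controls may, e.g., all share family_history = 0 in a small simulation;
    keeping such a column would make the information singular.  Returns
    (X_clean, kept_names, dropped_names).
    """
    X = np.asarray(X, dtype=float)
    names = list(names)
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        is_intercept = np.all(col == col[0]) and col[0] != 0
        if j > 0 and np.ptp(col) == 0:
            dropped.append(names[j])
            continue
        if keep:
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) <= len(keep):
                dropped.append(names[j])
                continue
        elif is_intercept and j > 0:  # pragma: no cover - defensive
            pass
        keep.append(j)
    if dropped:
        warnings.warn(f"dropped degenerate design columns: {dropped}", stacklevel=3)
    return X[:, keep], [names[j] for j in keep], dropped


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood written stably: sum y*eta - log(1 + e^eta)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = expit(eta)
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    max_halvings: int = 5,
    clean: bool = True,
) -> FirthFit:
    """Fit a Firth-penalized logistic regression.

    Newton iterations on the modified score, initialized at beta = 0, with
    up to ``max_halvings`` step-halvings per iteration whenever the
    penalized log-likelihood fails to increase.  Convergence requires
    max|U*| < tol within ``max_iter`` iterations; a non-converged fit is
    returned with ``converged=False`` and a warning rather than raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be binary 0/1")
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome lengths differ")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    dropped: list[str] = []
    if clean:
        X, names, dropped = clean_design(X, names)
    else:
        names = list(names)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError("design matrix is rank deficient")

    k = X.shape[1]
    beta = np.zeros(k)
    ll = _penalized_loglik(X, y, beta)
    max_score = np.inf
    converged = False
    it = 0
    damping = 1.0
    last_max_score = np.inf
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        Xw = X * w[:, None]
        info = X.T @ Xw
        info_inv = np.linalg.inv(info)
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        max_score = float(np.max(np.abs(score)))
        if max_score < tol:
            converged = True
            break
        # the expected-information step can overshoot the true penalized
        # Hessian near the optimum (oscillating score); damp it when the
        # score magnitude stalls, reset once progress resumes
        if max_score >= last_max_score:
            damping = max(damping * 0.5, 2.0**-8)
        else:
            damping = 1.0
        last_max_score = max_score
        step = damping * (info_inv @ score)
        new_beta = beta + step
        new_ll = _penalized_loglik(X, y, new_beta)
        n_half = 0
        # halve while the penalized log-likelihood fails to increase; a step
        # onto a numerically singular information (-inf) is never accepted,
        # however many halvings it takes
        while (new_ll < ll and n_half < max_halvings) or not np.isfinite(new_ll):
            step *= 0.5
            new_beta = beta + step
            new_ll = _penalized_loglik(X, y, new_beta)
            n_half += 1
            if n_half > 60:  # pragma: no cover - float underflow guard
                new_beta, new_ll = beta, ll
                break
        beta, ll = new_beta, new_ll
    if not converged:
        warnings.warn(
            f"Firth fit did not converge in {max_iter} iterations (max|U*|={max_score:.2e})",
            stacklevel=2,
        )
    p = expit(X @ beta)
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return FirthFit(
        beta=beta,
        cov=cov,
        names=list(names),
        converged=converged,
        n_iter=it,
        max_score=max_score,
        loglik_pen=ll,
        dropped=dropped,
    )


def wald_inference(fit: FirthFit, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient Wald summaries: estimate, OR = exp(beta), CI bounds
    on the OR scale, and the two-sided normal p-value.
    """
    if not fit.converged:
        raise ValueError("Wald inference requires a converged fit")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    se = fit.se
    zstat = np.divide(fit.beta, se, out=np.zeros_like(se), where=se > 0)
    return pd.DataFrame(
        {
            "estimate": fit.beta,
            "se": se,
            "OR": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z * se),
            "ci_high": np.exp(fit.beta + z * se),
            "p": 2.0 * norm.sf(np.abs(zstat)),
        },
        index=pd.Index(fit.names, name="term"),
    )


def penalized_lrt(fit_full: FirthFit, fit_null: FirthFit) -> float:
    """Penalized likelihood-ratio p-value for nested Firth fits.

    More robust than Wald near separation, where the Wald statistic is
    deflated by the inflated standard error; offered alongside Wald, not
    instead of it.
    """
    if not set(fit_null.names) <= set(fit_full.names):
        raise ValueError("null design is not nested in the full design")
    df = len(fit_full.names) - len(fit_null.names)
    if df < 0:
        raise ValueError("null design has more terms than the full design")
    stat = max(0.0, 2.0 * (fit_full.loglik_pen - fit_null.loglik_pen))
    if df == 0:
        return 1.0
    return float(chi2.sf(stat, df)) if stat > 0 else 1.0
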