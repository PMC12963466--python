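"""Logistic prediction of spontaneous stone passage from measured size.

A plain binomial logistic model, P(passage) = expit(b0 + b1 * size),
fitted by maximum likelihood with Fisher scoring (IRLS).  No penalization
is applied: complete separation is detected and surfaced as an
unconverged fit rather than silently corrected, because a penalized
slope would change the interpretation of the prediction curves.

The inverse read-off ``size_at_prob`` answers the clinical question "up
to what measured size is passage at least p likely?", e.g. the size at
90% expected passage probability; when different window settings shift
measured sizes systematically smaller, the whole curve — and that
read-off — shifts left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import SeparationError

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "predict_prob",
    "size_at_prob",
    "curve_family",
]

_MAX_ITER = 50
_SCORE_TOL = 1e-8


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit of outcome on size."""

    intercept: float
    slope: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    n_obs: int
    converged: bool
    status: str = "converged"


def fit_logistic(sizes, outcomes) -> LogisticFit:
    """Fit P(outcome=1) = expit(b0 + b1*size) by Fisher scoring.

    Requires at least one event and one non-event.  Convergence is
    declared when the maximum absolute score drops below 1e-8 (at most 50
    iterations).  Diverging coefficients (complete separation) yield
    ``converged=False`` with status ``"separation"`` — the last iterate
    is reported for inspection but must not be used for prediction.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sizes and outcomes must be matching 1D sequences")
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    status = "max_iterations"
    cov = np.full((2, 2), np.nan)
    for _ in range(_MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        # all fitted probabilities numerically 0/1: the likelihood is climbing
        # an unbounded ridge (complete separation), even if the score underflows
        if np.abs(beta).max() > 1e3 or w.max() < 1e-6:
            status = "separation"
            break
        score = X.T @ (y - mu)
        if np.abs(score).max() < _SCORE_TOL:
            converged = True
            status = "converged"
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            status = "separation"
            break
        # dampen absurd steps to keep the iteration stable near separation
        nrm = np.abs(step).max()
        if nrm > 20.0:
            step *= 20.0 / nrm
        beta = beta + step
    else:
        # loop exhausted without break: check whether it diverged
        if np.abs(beta).max() > 1e3:
            status = "separation"
    if converged:
        eta = X @ beta
        w = expit(eta) * (1.0 - expit(eta))
        info = (X * w[:, None]).T @ X
        cov = np.linalg.inv(info)
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        cov=cov,
        n_obs=len(y),
        converged=converged,
        status=status,
    )


def _require_converged(fit: LogisticFit) -> None:
    if not fit.converged:
        raise SeparationError(
            f"logistic fit did not converge (status={fit.status!r}); "
            "predictions are undefined"
        )


def predict_prob(fit: LogisticFit, size) -> np.ndarray | float:
    """Predicted passage probability at the given size(s)."""
    _require_converged(fit)
    p = expit(fit.intercept + fit.slope * np.asarray(size, dtype=float))
    return float(p) if np.isscalar(size) else p


def size_at_prob(fit: LogisticFit, p: float) -> float:
    """Size at which the predicted probability equals p (exact inverse)."""
    _require_converged(fit)
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if fit.slope == 0.0:
        raise ZeroDivisionError("slope is 0; the probability curve is flat")
    return float((logit(p) - fit.intercept) / fit.slope)


def curve_family(
    df: pd.DataFrame,
    group_cols: tuple[str, ...] = ("observer_id", "window"),
    size_col: str = "d_largest_mm",
    outcome_col: str = "passed",
    grid: np.ndarray | None = None,
) -> tuple[dict[tuple, LogisticFit], pd.DataFrame, dict[tuple, str]]:
    """Fit one logistic curve per group and evaluate all on a common grid.

    Returns ``(fits, curves, failures)``: the per-group fits, a long
    DataFrame of predicted probabilities over the size grid (converged
    groups only), and a dict of groups whose fit failed its
    preconditions or did not converge, with the reason — failures are
    reported, never silently dropped.
    """
    if grid is None:
        grid = np.arange(2.0, 12.0 + 1e-9, 0.1)
    fits: dict[tuple, LogisticFit] = {}
    failures: dict[tuple, str] = {}
    rows = []
    for key, g in df.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        try:
            fit = fit_logistic(g[size_col].to_numpy(), g[outcome_col].to_numpy())
        except ValueError as exc:
            failures[key] = str(exc)
            continue
        if not fit.converged:
            failures[key] = f"not converged: {fit.status}"
            continue
        fits[key] = fit
        probs = predict_prob(fit, grid)
        for s, p in zip(grid, probs):
            rows.append(dict(zip(group_cols, key)) | {"size_mm": s, "prob": p})
    return fits, pd.DataFrame(rows), failures
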