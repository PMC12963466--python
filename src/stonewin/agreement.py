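"""Multi-observer agreement: limits of agreement with the mean (LOAM).

Measurements y_ij of subject i by observer j are modeled with the
additive two-way random-effects decomposition

    y_ij = mu + a_i + b_j + e_ij,
    a_i ~ N(0, sigma_A^2)   (subjects),
    b_j ~ N(0, sigma_B^2)   (observers),
    e_ij ~ N(0, sigma_E^2)  (residual),  all independent.

The deviation of one observer from the per-subject mean of all m
observers is y_ij - ybar_i. = (b_j - bbar) + (e_ij - ebar_i.), whose
variance is (1 - 1/m)(sigma_B^2 + sigma_E^2).  LOAM is the half-width of
the central ``level`` interval of that deviation:

    LOAM = z_{(1+level)/2} * sqrt((1 - 1/m)(sigma_B^2 + sigma_E^2)).

Variance components come from the balanced two-way ANOVA moment
estimators when every (subject, observer) cell is present, and from REML
on the full Gaussian likelihood otherwise (e.g. when one observer's
readings in one window were excluded).  Negative moment estimates are
truncated at zero with a warning.

The default confidence interval is a modified-large-sample (MLS,
Graybill–Wang-type) interval on the non-negative mean-square combination
sigma_B^2 + sigma_E^2, mapped through the LOAM formula; a parametric
bootstrap is available as an alternative and is the only path for
unbalanced tables.  The interval construction is validated by coverage
simulation rather than by formula identity with any one reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MeasurementTable",
    "LoamResult",
    "as_table",
    "fit_two_way",
    "loam",
    "bland_altman_points",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasurementTable:
    """Long-format subject x observer measurements, validated.

    ``n`` subjects, ``m`` observers; ``balanced`` is True when every
    (subject, observer) cell is present exactly once.
    """

    subject: np.ndarray  # integer codes, 0..n-1
    observer: np.ndarray  # integer codes, 0..m-1
    value: np.ndarray
    n: int
    m: int
    balanced: bool


@dataclass(frozen=True)
class TwoWayFit:
    var_subject: float
    var_observer: float
    var_residual: float
    grand_mean: float
    # balanced-ANOVA extras used by the MLS interval (NaN for REML path)
    ms_observer: float
    ms_residual: float
    df_observer: float
    df_residual: float


@dataclass(frozen=True)
class LoamResult:
    """LOAM half-width (report as +/- loam) with CI and variance components."""

    loam: float
    ci_low: float
    ci_high: float
    var_subject: float
    var_observer: float
    var_residual: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.loam + 1e-12:
            raise ValueError("require 0 <= ci_low <= loam")
        if self.ci_high < self.loam - 1e-12:
            raise ValueError("require loam <= ci_high")


def as_table(
    df: pd.DataFrame,
    subject_col: str = "stone_id",
    observer_col: str = "observer_id",
    value_col: str = "d_largest_mm",
) -> MeasurementTable:
    """Validate a long-format DataFrame into a MeasurementTable."""
    sub, sub_levels = pd.factorize(df[subject_col], sort=True)
    obs, obs_levels = pd.factorize(df[observer_col], sort=True)
    if df.duplicated([subject_col, observer_col]).any():
        raise ValueError("each (subject, observer) pair may appear at most once")
    n, m = len(sub_levels), len(obs_levels)
    if n < 2 or m < 2:
        raise ValueError("need >= 2 subjects and >= 2 observers")
    balanced = len(df) == n * m
    return MeasurementTable(
        subject=np.asarray(sub),
        observer=np.asarray(obs),
        value=np.asarray(df[value_col], dtype=float),
        n=n,
        m=m,
        balanced=balanced,
    )


def _anova_balanced(t: MeasurementTable) -> TwoWayFit:
    y = np.empty((t.n, t.m))
    y[t.subject, t.observer] = t.value
    gm = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_a = t.m * ((row_means - gm) ** 2).sum()
    ss_b = t.n * ((col_means - gm) ** 2).sum()
    resid = y - row_means[:, None] - col_means[None, :] + gm
    ss_e = (resid**2).sum()
    df_a, df_b = t.n - 1, t.m - 1
    df_e = (t.n - 1) * (t.m - 1)
    ms_a, ms_b, ms_e = ss_a / df_a, ss_b / df_b, ss_e / df_e
    var_e = ms_e
    var_a = (ms_a - ms_e) / t.m
    var_b = (ms_b - ms_e) / t.n
    for name, v in (("subject", var_a), ("observer", var_b)):
        if v < 0:
            logger.warning("negative %s variance moment estimate %.3g truncated to 0", name, v)
    return TwoWayFit(
        var_subject=max(var_a, 0.0),
        var_observer=max(var_b, 0.0),
        var_residual=var_e,
        grand_mean=float(gm),
        ms_observer=ms_b,
        ms_residual=ms_e,
        df_observer=df_b,
        df_residual=df_e,
    )


def _reml_neg_loglik(
    log_var: np.ndarray, y: np.ndarray, za: np.ndarray, zb: np.ndarray
) -> float:
    va, vb, ve = np.exp(log_var)
    nobs = len(y)
    V = va * (za @ za.T) + vb * (zb @ zb.T) + ve * np.eye(nobs)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.log(np.diag(L)).sum()
    x = np.ones((nobs, 1))
    vinv_x = np.linalg.solve(V, x)
    vinv_y = np.linalg.solve(V, y)
    xtvx = (x.T @ vinv_x).item()
    beta = (x.T @ vinv_y).item() / xtvx
    r = y - beta
    vinv_r = np.linalg.solve(V, r)
    return 0.5 * (logdet + np.log(xtvx) + float(r @ vinv_r))


def _reml_unbalanced(t: MeasurementTable) -> TwoWayFit:
    y = t.value
    za = np.zeros((len(y), t.n))
    za[np.arange(len(y)), t.subject] = 1.0
    zb = np.zeros((len(y), t.m))
    zb[np.arange(len(y)), t.observer] = 1.0
    v0 = max(y.var(ddof=1), 1e-8)
    x0 = np.log([v0, v0 / 10.0, v0 / 10.0])
    res = optimize.minimize(
        _reml_neg_loglik,
        x0,
        args=(y, za, zb),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    va, vb, ve = np.exp(res.x)
    # components optimized on the log scale cannot go negative; values that
    # collapse to numerical zero are reported as 0
    tiny = 1e-10 * v0
    va, vb, ve = (0.0 if v < tiny else float(v) for v in (va, vb, ve))
    gm = float(np.mean(y))
    return TwoWayFit(va, vb, ve, gm, np.nan, np.nan, np.nan, np.nan)


def fit_two_way(table: MeasurementTable | pd.DataFrame) -> TwoWayFit:
    """Estimate the two-way random-effects variance components.

    Balanced tables use the closed-form ANOVA moment estimators (negative
    estimates truncated at 0); unbalanced tables use REML.  A table whose
    values are all identical yields all-zero components.
    """
    t = as_table(table) if isinstance(table, pd.DataFrame) else table
    if np.allclose(t.value, t.value[0]):
        return TwoWayFit(0.0, 0.0, 0.0, float(t.value[0]), 0.0, 0.0, t.m - 1, (t.n - 1) * (t.m - 1))
    if t.balanced:
        return _anova_balanced(t)
    return _reml_unbalanced(t)


def _mls_interval_theta(fit: TwoWayFit, n: int, level: float) -> tuple[float, float]:
    """MLS two-sided interval for theta = sigma_B^2 + sigma_E^2 (balanced).

    theta-hat = MS_B/n + (1 - 1/n) MS_E, a positive combination of two
    independent mean squares; Graybill–Wang limits apply.
    """
    alpha = (1.0 - level) / 2.0
    cs = np.array([1.0 / n, 1.0 - 1.0 / n])
    mss = np.array([fit.ms_observer, fit.ms_residual])
    dfs = np.array([fit.df_observer, fit.df_residual])
    theta = float(cs @ mss)
    g = 1.0 - dfs / stats.chi2.ppf(1.0 - alpha, dfs)
    h = dfs / stats.chi2.ppf(alpha, dfs) - 1.0
    lo = theta - np.sqrt(((g * cs * mss) ** 2).sum())
    hi = theta + np.sqrt(((h * cs * mss) ** 2).sum())
    return max(float(lo), 0.0), float(hi)


def _bootstrap_interval_theta(
    fit: TwoWayFit,
    t: MeasurementTable,
    level: float,
    n_boot: int,
    seed: int,
) -> tuple[float, float]:
    """Percentile parametric bootstrap for theta = sigma_B^2 + sigma_E^2."""
    rng = np.random.default_rng(seed)
    sa, sb, se = np.sqrt([fit.var_subject, fit.var_observer, fit.var_residual])
    thetas = np.empty(n_boot)
    for b in range(n_boot):
        a_i = rng.normal(0.0, sa, t.n)
        b_j = rng.normal(0.0, sb, t.m)
        e = rng.normal(0.0, se, len(t.value))
        yb = fit.grand_mean + a_i[t.subject] + b_j[t.observer] + e
        tb = MeasurementTable(t.subject, t.observer, yb, t.n, t.m, t.balanced)
        fb = fit_two_way(tb)
        thetas[b] = fb.var_observer + fb.var_residual
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(thetas, [alpha, 1.0 - alpha])
    theta_hat = fit.var_observer + fit.var_residual
    # percentile limits are clamped to bracket the point estimate so the
    # reported interval is always interpretable as a CI around it
    return min(float(lo), theta_hat), max(float(hi), theta_hat)


def loam(
    table: MeasurementTable | pd.DataFrame,
    level: float = 0.95,
    ci_method: str = "mls",
    n_boot: int = 500,
    seed: int = 0,
) -> LoamResult:
    """Limits of agreement with the mean, with confidence interval.

    ``ci_method`` is ``"mls"`` (balanced tables; modified-large-sample
    interval) or ``"bootstrap"`` (parametric bootstrap; required for
    unbalanced tables and used automatically for them).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    t = as_table(table) if isinstance(table, pd.DataFrame) else table
    fit = fit_two_way(t)
    z = stats.norm.ppf((1.0 + level) / 2.0)
    k = 1.0 - 1.0 / t.m
    theta = fit.var_observer + fit.var_residual
    half = z * np.sqrt(k * theta)
    if theta == 0.0:
        lo = hi = 0.0
    elif ci_method == "mls" and t.balanced:
        lo, hi = _mls_interval_theta(fit, t.n, level)
    elif ci_method in ("mls", "bootstrap"):
        lo, hi = _bootstrap_interval_theta(fit, t, level, n_boot, seed)
    else:
        raise ValueError("ci_method must be 'mls' or 'bootstrap'")
    return LoamResult(
        loam=float(half),
        ci_low=float(z * np.sqrt(k * lo)),
        ci_high=float(z * np.sqrt(k * hi)),
        var_subject=fit.var_subject,
        var_observer=fit.var_observer,
        var_residual=fit.var_residual,
        level=level,
    )


def bland_altman_points(
    df: pd.DataFrame,
    subject_col: str = "stone_id",
    observer_col: str = "observer_id",
    value_col: str = "d_largest_mm",
) -> pd.DataFrame:
    """Multi-observer Bland–Altman plot data.

    One row per measurement: the per-subject all-observer mean on the
    x-axis and the observer's deviation from it on the y-axis.  Subjects
    with a single observer are excluded with a warning; per-subject
    deviations sum to zero by construction.
    """
    counts = df.groupby(subject_col)[value_col].transform("size")
    dropped = df.loc[counts < 2, subject_col].unique()
    if len(dropped):
        logger.warning(
            "excluding %d subject(s) with a single observer from Bland–Altman data",
            len(dropped),
        )
    d = df[counts >= 2].copy()
    means = d.groupby(subject_col)[value_col].transform("mean")
    return pd.DataFrame(
        {
            "subject_mean": means.to_numpy(),
            "deviation": (d[value_col] - means).to_numpy(),
            "observer_id": d[observer_col].to_numpy(),
        }
    )
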