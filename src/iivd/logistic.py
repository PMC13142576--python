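"""Binomial logistic regression for one-year conversion prediction.

The fit is an in-package maximum-likelihood implementation via iteratively
reweighted least squares (Newton–Raphson on the log-likelihood), with
standard errors from the inverse observed information, Wald tests, odds
ratios with 95% CIs, the likelihood-ratio test against an intercept-only
null, Nagelkerke's R², and the Hosmer–Lemeshow decile-of-risk calibration
test.  After every successful fit the score equations Xᵀ(y - p̂) = 0 are
checked to 1e-6 — a violated score equation is a bug, not a warning.

Complete or quasi-separation (an unbounded likelihood) is detected from
divergence of the linear predictor and reported as
:class:`~iivd.errors.SeparationError` rather than silently returning huge
coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist

from iivd.errors import SeparationError

logger = logging.getLogger(__name__)

_Z95 = 1.959964
_MAX_ETA = 500.0  # |linear predictor| beyond this is numerically separated


@dataclass
class LogisticFit:
    """Fitted logistic model with the full reporting suite."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    ll1: float
    ll0: float
    lr_chi2: float
    lr_df: int
    lr_p: float
    nagelkerke_r2: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    n: int
    converged: bool
    n_iter: int
    fitted: np.ndarray = field(repr=False)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.coef,
                "se": self.se,
                "wald_z": self.wald_z,
                "p": self.wald_p,
                "odds_ratio": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def fit_logistic(
    y,
    X,
    names: list[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    hl_groups: int = 10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS with intercept.

    ``X`` is an (n, k) predictor table (DataFrame or array); ``y`` a binary
    outcome vector containing both classes.  Convergence is declared when
    the largest coefficient update falls below ``tol`` (default 1e-8)
    within ``max_iter`` (default 100) iterations.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")

    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept", *names]

    beta = np.zeros(X.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        if np.abs(eta).max() > _MAX_ETA:
            raise SeparationError(
                "linear predictor diverged: complete or quasi-separation"
            )
        p = expit(eta)
        w = p * (1.0 - p)
        # Newton step: (X' W X) delta = X'(y - p)
        xtwx = X.T @ (X * w[:, None])
        score = X.T @ (y - p)
        try:
            delta = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:  # singular information
            raise SeparationError(
                "singular information matrix (separation or collinearity)"
            ) from exc
        beta = beta + delta
        if np.abs(delta).max() < tol:
            converged = True
            break

    eta = X @ beta
    if np.abs(eta).max() > _MAX_ETA or (not converged and np.abs(beta).max() > 1e3):
        raise SeparationError(
            "coefficients diverged without convergence: separation suspected"
        )
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", n_iter)

    p_hat = expit(eta)
    ll1 = _bernoulli_ll(y, p_hat)
    ll0 = _bernoulli_ll(y, np.full(n, y.mean()))

    score_resid = np.abs(X.T @ (y - p_hat)).max()
    if converged and score_resid > 1e-6 * max(1.0, np.abs(X).max() * n):
        raise AssertionError(
            f"score equations violated at optimum (max |X'(y-p)| = {score_resid:.2e})"
        )

    w = p_hat * (1.0 - p_hat)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    wald_z = beta / se
    wald_p = 2 * norm_dist.sf(np.abs(wald_z))
    ors, lo, hi = or_from_coef(beta, se)

    lr_df = X.shape[1] - 1
    lr_chi2 = max(0.0, 2.0 * (ll1 - ll0))
    lr_p = float(chi2_dist.sf(lr_chi2, lr_df)) if lr_df else 1.0
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(y, p_hat, g=hl_groups)

    return LogisticFit(
        names=names,
        coef=beta,
        se=se,
        wald_z=wald_z,
        wald_p=wald_p,
        odds_ratio=ors,
        ci_low=lo,
        ci_high=hi,
        ll1=ll1,
        ll0=ll0,
        lr_chi2=lr_chi2,
        lr_df=lr_df,
        lr_p=lr_p,
        nagelkerke_r2=nagelkerke_r2(ll0, ll1, n),
        hl_chi2=hl_chi2,
        hl_df=hl_df,
        hl_p=hl_p,
        n=n,
        converged=converged,
        n_iter=n_iter,
        fitted=p_hat,
    )


def or_from_coef(coef, se):
    """Odds ratio exp(B) with 95% CI exp(B ± 1.959964·SE)."""
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se < 0).any():
        raise ValueError("standard errors must be non-negative")
    return np.exp(coef), np.exp(coef - _Z95 * se), np.exp(coef + _Z95 * se)


def nagelkerke_r2(ll0: float, ll1: float, n: int) -> float:
    """Nagelkerke's rescaled Cox–Snell pseudo-R².

    R²_CS = 1 - exp(2(LL0 - LL1)/n), divided by its maximum
    1 - exp(2·LL0/n) so a saturated fit of a balanced outcome reaches 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if ll1 < ll0 - 1e-10:
        raise ValueError("LL1 must be >= LL0")
    r2_cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    if denom <= 0:
        return 0.0
    return float(min(1.0, max(0.0, r2_cs / denom)))


def hosmer_lemeshow(y, p, g: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow decile-of-risk goodness-of-fit chi-square.

    Subjects are sorted by fitted probability and split into ``g``
    near-equal groups; tied fitted values stay in one group.  The statistic
    sums (O - E)²/E over groups and both outcomes, with E from the summed
    fitted probabilities; df = g_effective - 2.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    n = y.size
    if n < g:
        raise ValueError("need at least g observations")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("fitted probabilities must lie strictly in (0, 1)")

    order = np.argsort(p, kind="stable")
    ys, ps = y[order], p[order]
    # nominal equal-size boundaries, then push each forward past ties
    bounds = [round(n * i / g) for i in range(1, g)]
    cut: list[int] = []
    for b in bounds:
        while b < n and ps[b] == ps[b - 1]:
            b += 1
        if b < n and (not cut or b > cut[-1]):
            cut.append(b)
    groups_y = np.split(ys, cut)
    groups_p = np.split(ps, cut)
    g_eff = len(groups_y)
    if g_eff < g:
        logger.info("Hosmer-Lemeshow groups reduced from %d to %d by ties", g, g_eff)

    stat = 0.0
    for gy, gp in zip(groups_y, groups_p):
        e1 = gp.sum()
        e0 = len(gp) - e1
        o1 = gy.sum()
        o0 = len(gy) - o1
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = max(1, g_eff - 2)
    return float(stat), df, float(chi2_dist.sf(stat, df))


def run_conversion_models(
    analysis: pd.DataFrame,
    cov_scale: float = 0.1,
    standardize: bool = False,
    outcome_col: str = "converted",
    updrs_col: str = "updrs3",
) -> dict[str, LogisticFit]:
    """Fit the two conversion models on followed Stage-2 subjects.

    Model ``"total"`` uses the total CoV, model ``"ae"`` the
    attention/executive CoV, each controlling for baseline motor severity
    (MDS-UPDRS III).  CoV enters per ``cov_scale`` units (default 0.1, so
    coefficients are log-odds per 0.1 CoV); ``standardize=True`` enters
    z-scored CoV instead.
    """
    fits: dict[str, LogisticFit] = {}
    for key, cov_col in (("total", "cov_total"), ("ae", "cov_ae")):
        sub = analysis[[outcome_col, cov_col, updrs_col]].dropna()
        y = sub[outcome_col].astype(float).to_numpy()
        cov = sub[cov_col].to_numpy(dtype=float)
        if standardize:
            cov = (cov - cov.mean()) / cov.std(ddof=1)
            cov_name = f"{cov_col} (z)"
        else:
            cov = cov / cov_scale
            cov_name = f"{cov_col} (per {cov_scale:g})"
        X = pd.DataFrame({cov_name: cov, "updrs3": sub[updrs_col].to_numpy(float)})
        fits[key] = fit_logistic(y, X)
    return fits


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
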