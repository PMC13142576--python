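"""Regression-based internal norms and T-score conversion.

For each battery test a linear model in age, sex and education is fit on a
reference sample by least squares; demographic corrections are applied
*selectively* — only covariates whose Wald test reaches p < alpha are
retained, with one refit on the retained set.  The residual scale of the
final fit (root mean square residual with the unbiased n - k - 1
denominator) converts observed deviations to the T metric:

    T = 50 + 10 * (observed - predicted) / residual_scale,

with the sign flipped first for timed tests where higher raw scores mean
worse performance.  Applied back to its own reference sample a fitted norm
reproduces mean 50 and (up to the n - k - 1 vs n - 1 denominator and the
selection refit) SD 10 per test, and T scores are invariant to affine
rescaling of a test's raw units.

By default the analysis pipeline fits norms on the healthy-control group;
the reference sample used by the study's internal norms is not published,
so this choice is an explicit assumption (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from iivd.errors import ValidationError
from iivd.registry import TestRegistry, default_registry

logger = logging.getLogger(__name__)

COVARIATES = ("age", "sex", "education")


@dataclass
class NormModel:
    """Per-test regression norm: coefficients, residual scale, orientation."""

    test: str
    intercept: float
    coefficients: dict[str, float]  # retained covariates only
    residual_scale: float
    higher_is_worse: bool
    n_reference: int = 0

    def __post_init__(self) -> None:
        if self.residual_scale <= 0:
            raise ValidationError(
                f"norm for {self.test!r} has non-positive residual scale"
            )
        extra = set(self.coefficients) - set(COVARIATES)
        if extra:
            raise ValidationError(f"unknown covariates in norm: {sorted(extra)}")

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        pred = np.full(len(df), self.intercept)
        for cov, beta in self.coefficients.items():
            pred = pred + beta * _covariate_column(df, cov)
        return pred


def _covariate_column(df: pd.DataFrame, cov: str) -> np.ndarray:
    if cov == "sex":
        return (df["sex"] == "M").to_numpy(dtype=float)
    return df[cov].to_numpy(dtype=float)


def fit_norms(
    reference: pd.DataFrame,
    registry: TestRegistry | None = None,
    alpha: float = 0.05,
) -> dict[str, NormModel]:
    """Fit selective demographic norms on a reference sample.

    Per test: a full three-covariate least-squares fit, then a single refit
    keeping only covariates with Wald p < ``alpha``.  Constant (degenerate)
    covariates are dropped up front with a logged warning.
    """
    registry = registry or default_registry()
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must lie in (0, 1]")

    complete = reference[registry.names].notna().all(axis=1)
    ref = reference.loc[complete]
    if len(ref) < 30:
        raise ValidationError(
            f"reference sample has only {len(ref)} complete records (need >= 30)"
        )

    usable = []
    for cov in COVARIATES:
        col = _covariate_column(ref, cov)
        if np.ptp(col) == 0:
            logger.warning("covariate %r is constant in reference; dropped", cov)
        else:
            usable.append(cov)

    norms: dict[str, NormModel] = {}
    for spec in registry:
        y = ref[spec.name].to_numpy(dtype=float)
        selected = usable
        if usable:
            full = _ols(y, ref, usable)
            # first column of params/pvalues is the intercept
            selected = [
                cov for cov, p in zip(usable, full.pvalues[1:]) if p < alpha
            ]
        final = _ols(y, ref, selected)
        k = len(selected)
        resid_scale = float(np.sqrt(final.ssr / (len(ref) - k - 1)))
        coefs = dict(zip(selected, (float(b) for b in final.params[1:])))
        norms[spec.name] = NormModel(
            test=spec.name,
            intercept=float(final.params[0]),
            coefficients=coefs,
            residual_scale=resid_scale,
            higher_is_worse=spec.higher_is_worse,
            n_reference=len(ref),
        )
    return norms


def _ols(y: np.ndarray, df: pd.DataFrame, covariates: list[str]):
    X = np.column_stack(
        [np.ones(len(df))] + [_covariate_column(df, c) for c in covariates]
    )
    return sm.OLS(y, X).fit()


def apply_norms(
    records: pd.DataFrame,
    norms: dict[str, NormModel],
    registry: TestRegistry | None = None,
) -> pd.DataFrame:
    """Convert raw scores to T scores (higher = better for every test).

    Returns a panel table with ``participant_id``, ``visit_index`` and one
    T-score column per test.  Visits missing any raw score keep NaN in the
    affected columns; downstream dispersion excludes those panels.
    """
    registry = registry or default_registry()
    missing = [t.name for t in registry if t.name not in norms]
    if missing:
        raise ValidationError(f"no norm fitted for tests: {missing}")

    out = records[["participant_id", "visit_index"]].copy()
    for spec in registry:
        norm = norms[spec.name]
        raw = records[spec.name].to_numpy(dtype=float)
        z = (raw - norm.predict(records)) / norm.residual_scale
        if norm.higher_is_worse:
            z = -z
        out[spec.name] = 50.0 + 10.0 * z
    return out


def save_norms(norms: dict[str, NormModel], path: str | Path) -> None:
    """Serialize norms to a structured text (YAML) file, one block per test."""
    payload = {
        name: {
            "intercept": m.intercept,
            "coefficients": m.coefficients,
            "residual_scale": m.residual_scale,
            "higher_is_worse": m.higher_is_worse,
            "n_reference": m.n_reference,
        }
        for name, m in norms.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def load_norms(path: str | Path) -> dict[str, NormModel]:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return {
        name: NormModel(
            test=name,
            intercept=float(block["intercept"]),
            coefficients={k: float(v) for k, v in block["coefficients"].items()},
            residual_scale=float(block["residual_scale"]),
            higher_is_worse=bool(block["higher_is_worse"]),
            n_reference=int(block.get("n_reference", 0)),
        )
        for name, block in payload.items()
    }
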