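"""Per-subject composite scores and coefficient-of-variation dispersion.

The dispersion metric is the coefficient of variation (CoV) of a subject's
11 normed T scores at one visit: the population standard deviation (the
square root of the *average* squared deviation from the mean, i.e. the
n-divisor form) divided by the mean of those scores.  The
attention/executive CoV restricts the same calculation to the registry's
five attention/executive scores.  Higher CoV means greater within-person
dispersion of performance across tests.

CoV is meaningless when the mean composite is not positive; such panels
are excluded with a logged count rather than silently emitted as NaN (in
the calibrated T-score range they do not occur).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from iivd.errors import UndefinedDispersionError
from iivd.registry import TestRegistry, default_registry

logger = logging.getLogger(__name__)


def coefficient_of_variation(scores, ddof: int = 0) -> float:
    """CoV of a list of scores: n-divisor SD over mean.

    ``ddof=0`` (the default) is the definitional form; ``ddof=1`` is
    provided only for sensitivity analysis with the sample SD.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("CoV requires at least 2 scores")
    if not np.all(np.isfinite(x)):
        raise ValueError("CoV requires finite scores")
    mean = x.mean()
    if mean <= 0:
        raise UndefinedDispersionError(
            f"CoV undefined for non-positive mean score ({mean:.3f})"
        )
    return float(x.std(ddof=ddof) / mean)


def compute_dispersion(
    panels: pd.DataFrame,
    registry: TestRegistry | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Dispersion results for a table of T-score panels.

    ``panels`` must hold ``participant_id``, ``visit_index`` and the 11
    T-score columns named after the registry tests.  Rows with any missing
    score (incomplete panels) or a non-positive mean composite are excluded
    with a logged reason.

    Returns one row per retained panel with ``mean_composite`` (mean of all
    11 T scores), ``ae_composite`` (mean of the 5 attention/executive
    scores), ``cov_total`` and ``cov_ae``.
    """
    registry = registry or default_registry()
    names = registry.names
    ae_names = registry.attention_executive

    complete = panels[names].notna().all(axis=1)
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        logger.info("excluding %d incomplete panels from dispersion", n_incomplete)
    kept = panels.loc[complete]

    total = kept[names].to_numpy(dtype=float)
    ae = kept[ae_names].to_numpy(dtype=float)
    mean_total = total.mean(axis=1)
    mean_ae = ae.mean(axis=1)

    positive = (mean_total > 0) & (mean_ae > 0)
    n_nonpos = int((~positive).sum())
    if n_nonpos:
        logger.warning(
            "excluding %d panels with non-positive mean composite "
            "(CoV undefined)", n_nonpos,
        )
    total, ae = total[positive], ae[positive]
    mean_total, mean_ae = mean_total[positive], mean_ae[positive]

    out = pd.DataFrame(
        {
            "participant_id": kept.loc[positive, "participant_id"].to_numpy(),
            "visit_index": kept.loc[positive, "visit_index"].to_numpy(),
            "mean_composite": mean_total,
            "ae_composite": mean_ae,
            "cov_total": total.std(axis=1, ddof=ddof) / mean_total,
            "cov_ae": ae.std(axis=1, ddof=ddof) / mean_ae,
        }
    )
    out.attrs["n_incomplete"] = n_incomplete
    out.attrs["n_nonpositive_mean"] = n_nonpos
    return out
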