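#!/usr/bin/env python
"""Logistic conversion-prediction models.

Fits the two binomial logistic models on followed Stage-2 subjects —
(1) total CoV + MDS-UPDRS III, (2) attention/executive CoV + MDS-UPDRS
III — reporting coefficients, odds ratios with 95% CIs, the LR test
against the null, Nagelkerke R², and Hosmer–Lemeshow calibration.  CoV
enters per 0.1 unit.
"""

from pathlib import Path

import pandas as pd

from iivd.logistic import run_conversion_models
from iivd.pipeline import _fit_report, emit_table
from iivd.schema import read_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    disp = pd.read_csv(OUT / "dispersion.csv")
    outcomes = pd.read_csv(OUT / "conversion_outcomes.csv")
    base = cohort[cohort["visit_index"] == 0][["participant_id", "updrs3"]]
    conv = (
        outcomes[outcomes["followed"]]
        .merge(disp[disp["visit_index"] == 0], on="participant_id")
        .merge(base, on="participant_id")
    )
    fits = run_conversion_models(conv, cov_scale=0.1)
    for key, fit in fits.items():
        emit_table(_fit_report(fit), OUT / f"logistic_{key}")
        cov_term = fit.names[1]
        print(
            f"model {key}: n={fit.n}, LR chi2({fit.lr_df})={fit.lr_chi2:.2f} "
            f"(p={fit.lr_p:.2g}), Nagelkerke R2={fit.nagelkerke_r2:.3f}, "
            f"HL chi2={fit.hl_chi2:.2f} (p={fit.hl_p:.3f})"
        )
        print(
            f"  {cov_term}: B={fit.coef[1]:.3f} (p={fit.wald_p[1]:.3g}), "
            f"OR={fit.odds_ratio[1]:.2f} "
            f"[{fit.ci_low[1]:.2f}, {fit.ci_high[1]:.2f}]"
        )
        print(
            f"  updrs3: B={fit.coef[2]:.3f} (p={fit.wald_p[2]:.3g}), "
            f"OR={fit.odds_ratio[2]:.3f} "
            f"[{fit.ci_low[2]:.3f}, {fit.ci_high[2]:.3f}]"
        )


if __name__ == "__main__":
    main()
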