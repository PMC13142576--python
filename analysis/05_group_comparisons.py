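#!/usr/bin/env python
"""Group comparisons and CoV correlates.

Builds the Table-1-style HC vs Stage-2 comparison (variance-gated t tests,
chi-square for sex, pooled Cohen's d, BH-FDR at 0.05 across the family),
the Table-2-style converter vs non-converter comparison, and Pearson
correlations of CoV with age, education, motor severity, mood and smell.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from iivd.pipeline import (
    CORRELATION_VARIABLES,
    TABLE1_CONTINUOUS,
    TABLE2_VARIABLES,
    analysis_sets,
    emit_table,
)
from iivd.schema import read_cohort
from iivd.stats import compare_groups, correlation_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    stages = pd.read_csv(OUT / "stages.csv")
    disp = pd.read_csv(OUT / "dispersion.csv")
    outcomes = pd.read_csv(OUT / "conversion_outcomes.csv")
    hc_ids, stage2_ids, _ = analysis_sets(cohort, stages)

    base = cohort[cohort["visit_index"] == 0].merge(
        disp, on=["participant_id", "visit_index"], how="left"
    )
    base["group"] = np.select(
        [base["participant_id"].isin(hc_ids), base["participant_id"].isin(stage2_ids)],
        ["hc", "stage2"], default="",
    )
    analysis = base[base["group"] != ""]

    variables = {"sex": "categorical", **{v: "continuous" for v in TABLE1_CONTINUOUS}}
    table1 = compare_groups(analysis, "group", variables, q=0.05,
                            group_order=("hc", "stage2"))
    emit_table(table1, OUT / "table1_group_comparison")
    sig = table1[table1["significant"]]["variable"].tolist()
    print(f"Table 1: {len(sig)}/{len(table1)} variables significant after BH: {sig}")
    cov_row = table1.set_index("variable").loc["cov_total"]
    print(f"  total CoV: HC {cov_row['mean1']:.3f} vs Stage 2 {cov_row['mean2']:.3f} "
          f"(d = {cov_row['cohens_d']:.2f}, p = {cov_row['p_raw']:.4g})")

    followed = outcomes[outcomes["followed"]].merge(analysis, on="participant_id")
    followed["converted_label"] = np.where(
        followed["converted"].astype(bool), "converter", "non-converter"
    )
    table2 = compare_groups(
        followed, "converted_label", {v: "continuous" for v in TABLE2_VARIABLES},
        q=0.05, group_order=("non-converter", "converter"),
    )
    emit_table(table2, OUT / "table2_converter_comparison")
    row = table2.set_index("variable").loc["cov_total"]
    print(f"Table 2: baseline CoV {row['mean1']:.3f} (non-conv) vs "
          f"{row['mean2']:.3f} (conv), d = {row['cohens_d']:.2f}")

    frames = []
    for label, frame in (("full", analysis),
                         ("stage2", analysis[analysis["group"] == "stage2"])):
        tab = correlation_table(frame, ["cov_total", "cov_ae"], CORRELATION_VARIABLES)
        tab.insert(0, "sample", label)
        frames.append(tab)
    corr = pd.concat(frames, ignore_index=True)
    emit_table(corr, OUT / "correlations")
    s2 = corr[(corr["sample"] == "stage2") & (corr["var1"] == "cov_total")]
    print("Stage-2 CoV correlations:",
          {r["var2"]: round(r["r"], 3) for _, r in s2.iterrows()})


if __name__ == "__main__":
    main()
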