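#!/usr/bin/env python
"""Fit internal regression norms and convert raw scores to T scores.

Stages every visit, derives the HC analysis set (SAA-negative, no
hyposmia, MoCA-stable across one year), fits selective age/sex/education
norms per test on those baseline records, and writes the norms plus the
T-score panels for the whole cohort.
"""

from pathlib import Path

from iivd.norms import apply_norms, fit_norms, save_norms
from iivd.pipeline import analysis_sets
from iivd.schema import read_cohort
from iivd.staging import assign_stages

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    stages = assign_stages(cohort)
    stages.to_csv(OUT / "stages.csv", index=False)
    hc_ids, stage2_ids, accounting = analysis_sets(cohort, stages)
    print(f"analysis sets: HC n={len(hc_ids)}, Stage 2 n={len(stage2_ids)}; "
          f"excluded {accounting['excluded']}")

    reference = cohort[
        cohort["participant_id"].isin(hc_ids) & (cohort["visit_index"] == 0)
    ]
    norms = fit_norms(reference, alpha=0.05)
    save_norms(norms, OUT / "norms.yaml")
    selected = {t: sorted(m.coefficients) for t, m in norms.items()}
    print("covariates retained per test:")
    for t, cov in selected.items():
        print(f"  {t}: {cov or 'none'}")

    panels = apply_norms(cohort, norms)
    panels.to_csv(OUT / "tscores.csv", index=False)
    print(f"wrote {OUT / 'tscores.csv'} ({len(panels)} panels)")


if __name__ == "__main__":
    main()
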