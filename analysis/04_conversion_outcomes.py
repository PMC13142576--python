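#!/usr/bin/env python
"""Label one-year conversion outcomes and count stage transitions.

A Stage-2 participant is followed when a complete-battery visit falls
0.75-1.25 years after baseline; conversion means that visit is staged 3+
(slight or greater functional impairment with positive SAA).
"""

from pathlib import Path

import pandas as pd

from iivd.pipeline import analysis_sets
from iivd.schema import read_cohort
from iivd.staging import label_conversion, transition_counts

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    stages = pd.read_csv(OUT / "stages.csv")
    _, stage2_ids, _ = analysis_sets(cohort, stages)
    outcomes = label_conversion(stages, cohort)
    outcomes = outcomes[outcomes["participant_id"].isin(stage2_ids)]
    outcomes.to_csv(OUT / "conversion_outcomes.csv", index=False)
    followed = outcomes[outcomes["followed"]]
    print(f"Stage 2 analyzed: {len(outcomes)}; followed at one year: "
          f"{len(followed)}; converted to Stage 3+: "
          f"{int(followed['converted'].sum())}")
    table = transition_counts(outcomes)
    table.reset_index().to_csv(OUT / "stage_transitions.csv", index=False)
    print("baseline x Year-1 stage transitions:")
    print(table.to_string())


if __name__ == "__main__":
    main()
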