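#!/usr/bin/env python
"""Compute composite scores and CoV dispersion per participant-visit.

The total CoV is the population SD of the 11 T scores divided by their
mean; the attention/executive CoV restricts to SDMT, TMT-A, LNS, lexical
fluency and TMT-B.
"""

from pathlib import Path

import pandas as pd

from iivd.dispersion import compute_dispersion

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panels = pd.read_csv(OUT / "tscores.csv")
    disp = compute_dispersion(panels)
    disp.to_csv(OUT / "dispersion.csv", index=False)
    baseline = disp[disp["visit_index"] == 0]
    print(f"wrote {OUT / 'dispersion.csv'} ({len(disp)} rows)")
    print("baseline summary:")
    print(baseline[["mean_composite", "ae_composite", "cov_total", "cov_ae"]]
          .describe().loc[["mean", "std"]].round(3).to_string())


if __name__ == "__main__":
    main()
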