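"""NSD-ISS stage assignment, HC eligibility, and conversion labeling.

Stage labels follow the integrated staging system's biological anchors:
a positive CSF α-synuclein seed amplification assay (SAA) anchors NSD;
dopaminergic neuronal dysfunction (DAT deficit) splits Stage 2 into 2A
(without) and 2B (with).  Stage 2 requires subtle signs or symptoms with
*no* functional impairment; any (even slight) functional impairment moves
a participant to Stage 3 or higher ("3plus" here — higher severity anchors
are out of scope).  SAA-positive participants without subtle signs are
Stage 1; SAA-negative participants are healthy-control candidates.

"Subtle signs or symptoms" are operationalized for synthetic data as any
of: the hyposmia flag, RBDSQ >= 5, or MDS-UPDRS III > 0.  The staging
system's own sign thresholds live in its defining criteria, not here;
real-data users should supply their own sign flag via ``sign_rule``.

Stage assignment is a pure function of one visit record; only conversion
labeling looks across visits.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from iivd.errors import UnstageableError
from iivd.registry import TestRegistry, default_registry
from iivd.schema import complete_battery_mask

logger = logging.getLogger(__name__)

STAGES = ("HC-eligible", "1", "2A", "2B", "3plus")
CONVERSION_WINDOW = (0.75, 1.25)  # years; earliest qualifying visit wins


def default_sign_rule(record: Mapping) -> tuple[bool, list[str]]:
    """Subtle-sign rule for synthetic data: hyposmia, RBDSQ>=5 or UPDRS-III>0."""
    reasons = []
    if bool(record.get("hyposmia")):
        reasons.append("sign:hyposmia")
    rbdsq = record.get("rbdsq")
    if rbdsq is not None and not pd.isna(rbdsq) and rbdsq >= 5:
        reasons.append("sign:rbdsq>=5")
    updrs = record.get("updrs3")
    if updrs is not None and not pd.isna(updrs) and updrs > 0:
        reasons.append("sign:updrs3>0")
    return bool(reasons), reasons


def assign_stage(
    record: Mapping,
    sign_rule: Callable[[Mapping], tuple[bool, list[str]]] = default_sign_rule,
) -> tuple[str, list[str]]:
    """Stage label and fired reason codes for one visit record.

    Raises :class:`UnstageableError` when the SAA result (or, for an
    SAA-positive prodromal candidate, the DAT result) is missing.
    """
    saa = record.get("saa_positive")
    if saa is None or pd.isna(saa):
        raise UnstageableError(
            f"missing SAA result for participant {record.get('participant_id')!r}"
        )
    if not saa:
        return "HC-eligible", ["saa:negative"]

    reasons = ["saa:positive"]
    impairment = record.get("functional_impairment")
    if impairment in ("slight", "greater"):
        reasons.append(f"impairment:{impairment}")
        return "3plus", reasons

    has_signs, sign_reasons = sign_rule(record)
    if not has_signs:
        reasons.append("signs:none")
        return "1", reasons
    reasons.extend(sign_reasons)

    dat = record.get("dat_deficit")
    if dat is None or pd.isna(dat):
        raise UnstageableError(
            "missing DAT result for SAA-positive participant "
            f"{record.get('participant_id')!r}"
        )
    if dat:
        reasons.append("dat:deficit")
        return "2B", reasons
    reasons.append("dat:normal")
    return "2A", reasons


def assign_stages(
    cohort: pd.DataFrame,
    sign_rule: Callable[[Mapping], tuple[bool, list[str]]] | None = None,
) -> pd.DataFrame:
    """Stage every visit row; unstageable rows get a null stage, logged.

    Returns ``participant_id``, ``visit_index``, ``stage`` and semicolon-
    joined ``reason_codes``.  With the default sign rule this runs as
    vectorized column arithmetic (equivalent to mapping
    :func:`assign_stage` row by row, which is what a custom ``sign_rule``
    falls back to).
    """
    if sign_rule is not None:
        return _assign_stages_rowwise(cohort, sign_rule)

    saa = cohort["saa_positive"].astype("boolean")
    saa_known = saa.notna().to_numpy()
    saa_pos = saa.fillna(False).to_numpy(dtype=bool)
    impaired = cohort["functional_impairment"].isin(["slight", "greater"]).to_numpy()
    hyposmia = cohort["hyposmia"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    rbdsq = cohort["rbdsq"].to_numpy(dtype=float)
    updrs = cohort["updrs3"].to_numpy(dtype=float)
    sign_rbd = np.nan_to_num(rbdsq, nan=-np.inf) >= 5
    sign_updrs = np.nan_to_num(updrs, nan=0.0) > 0
    signs = hyposmia | sign_rbd | sign_updrs
    dat = cohort["dat_deficit"].astype("boolean")
    dat_known = dat.notna().to_numpy()
    dat_def = dat.fillna(False).to_numpy(dtype=bool)

    needs_dat = saa_known & saa_pos & ~impaired & signs
    stage = np.select(
        [
            ~saa_known,
            ~saa_pos,
            impaired,
            ~signs,
            needs_dat & ~dat_known,
            dat_def,
        ],
        [None, "HC-eligible", "3plus", "1", None, "2B"],
        default="2A",
    )

    imp_level = cohort["functional_impairment"].to_numpy()
    codes = []
    for i in range(len(cohort)):
        if not saa_known[i]:
            codes.append("unstageable:missing SAA result")
            continue
        if not saa_pos[i]:
            codes.append("saa:negative")
            continue
        parts = ["saa:positive"]
        if impaired[i]:
            parts.append(f"impairment:{imp_level[i]}")
        elif not signs[i]:
            parts.append("signs:none")
        else:
            if hyposmia[i]:
                parts.append("sign:hyposmia")
            if sign_rbd[i]:
                parts.append("sign:rbdsq>=5")
            if sign_updrs[i]:
                parts.append("sign:updrs3>0")
            if not dat_known[i]:
                parts.append("unstageable:missing DAT result")
            else:
                parts.append("dat:deficit" if dat_def[i] else "dat:normal")
        codes.append(";".join(parts))

    n_unstageable = int(pd.isna(stage).sum())
    if n_unstageable:
        logger.warning("%d visit records could not be staged", n_unstageable)
    out = cohort[["participant_id", "visit_index"]].copy()
    out["stage"] = stage
    out["reason_codes"] = codes
    out.attrs["n_unstageable"] = n_unstageable
    return out


def _assign_stages_rowwise(cohort: pd.DataFrame, sign_rule) -> pd.DataFrame:
    stages, codes = [], []
    n_unstageable = 0
    for rec in cohort.to_dict("records"):
        try:
            stage, reasons = assign_stage(rec, sign_rule)
        except UnstageableError as exc:
            stage, reasons = None, [f"unstageable:{exc}"]
            n_unstageable += 1
        stages.append(stage)
        codes.append(";".join(reasons))
    if n_unstageable:
        logger.warning("%d visit records could not be staged", n_unstageable)
    out = cohort[["participant_id", "visit_index"]].copy()
    out["stage"] = stages
    out["reason_codes"] = codes
    out.attrs["n_unstageable"] = n_unstageable
    return out


def hc_eligibility(baseline: Mapping, year1: Mapping | None) -> tuple[bool, list[str]]:
    """Healthy-control analysis-set eligibility across baseline and Year 1.

    Requires baseline MoCA >= 27, no hyposmia, a negative SAA, a Year-1
    MoCA >= 26, and no more than a 2-point MoCA decline.
    """
    reasons = []
    moca0 = baseline.get("moca")
    if moca0 is None or pd.isna(moca0) or moca0 < 27:
        reasons.append("hc:baseline-moca<27")
    if bool(baseline.get("hyposmia")):
        reasons.append("hc:hyposmia")
    saa = baseline.get("saa_positive")
    if saa is None or pd.isna(saa):
        reasons.append("hc:saa-missing")
    elif saa:
        reasons.append("hc:saa-positive")
    moca1 = None if year1 is None else year1.get("moca")
    if moca1 is None or pd.isna(moca1):
        reasons.append("hc:year1-moca-missing")
    else:
        if moca1 < 26:
            reasons.append("hc:year1-moca<26")
        if moca0 is not None and not pd.isna(moca0) and (moca0 - moca1) > 2:
            reasons.append("hc:moca-decline>2")
    return (not reasons), reasons


@dataclass
class ConversionOutcome:
    participant_id: str
    baseline_stage: str  # 2A or 2B
    followed: bool
    converted: bool | None  # defined only when followed
    year1_stage: str | None = None


def label_conversion(
    staged: pd.DataFrame,
    cohort: pd.DataFrame,
    registry: TestRegistry | None = None,
    window: tuple[float, float] = CONVERSION_WINDOW,
) -> pd.DataFrame:
    """One-year conversion outcomes for baseline Stage-2 participants.

    A participant is *followed* when a later visit with a complete battery
    falls inside the follow-up ``window`` (years since baseline); the
    earliest such visit determines ``converted`` (its stage is "3plus").
    Missing follow-up yields followed=False with converted undefined.
    """
    registry = registry or default_registry()
    lo, hi = window
    if not lo < hi:
        raise ValueError("conversion window must satisfy low < high")

    merged = cohort.merge(staged, on=["participant_id", "visit_index"])
    merged["complete"] = complete_battery_mask(merged, registry)

    base = merged[merged["visit_index"] == 0]
    base = base[base["stage"].isin(["2A", "2B"])][["participant_id", "stage"]]
    base = base.rename(columns={"stage": "baseline_stage"})

    later = merged[
        (merged["visit_index"] > 0)
        & merged["complete"]
        & merged["visit_offset_years"].between(lo, hi)
        & merged["stage"].notna()
    ]
    first = (
        later[["participant_id", "visit_offset_years", "stage"]]
        .sort_values(["participant_id", "visit_offset_years"], kind="stable")
        .groupby("participant_id", sort=True)
        .first()[["stage"]]
        .rename(columns={"stage": "year1_stage"})
    )

    out = base.merge(first, on="participant_id", how="left")
    out["followed"] = out["year1_stage"].notna()
    out["converted"] = pd.array(
        np.where(out["followed"], out["year1_stage"] == "3plus", None),
        dtype="boolean",
    )
    out = out[
        ["participant_id", "baseline_stage", "followed", "converted", "year1_stage"]
    ]
    return out.sort_values("participant_id", kind="stable").reset_index(drop=True)


def transition_counts(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Baseline-stage x Year-1-stage counts over followed participants."""
    followed = outcomes[outcomes["followed"]]
    if followed.empty:
        return pd.DataFrame()
    table = pd.crosstab(followed["baseline_stage"], followed["year1_stage"])
    table.index.name = "baseline"
    table.columns.name = "year1"
    return table
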