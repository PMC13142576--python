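"""End-to-end pipeline: simulate/read -> norm -> dispersion -> staging ->
group comparisons -> correlations -> conversion models -> transitions.

Every artifact is a plain-text table (CSV plus an aligned text mirror);
the run configuration and seed are echoed into ``run_info.json`` so a
bundle regenerates byte-identically from the same config and seed.
Participants excluded at any gate are counted per rule, and the counts
satisfy enrolled = analyzed + excluded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from iivd.dispersion import compute_dispersion
from iivd.errors import ValidationError
from iivd.logistic import LogisticFit, run_conversion_models
from iivd.norms import apply_norms, fit_norms, save_norms
from iivd.registry import TestRegistry, default_registry
from iivd.schema import complete_battery_mask, read_cohort, write_cohort
from iivd.simulate import SimulationConfig, simulate_cohort
from iivd.staging import (
    CONVERSION_WINDOW,
    assign_stages,
    hc_eligibility,
    label_conversion,
    transition_counts,
)
from iivd.stats import compare_groups, correlation_table

logger = logging.getLogger(__name__)

TABLE1_CONTINUOUS = [
    "age", "education", "updrs3", "hoehn_yahr", "scopa_aut", "gds15", "quip",
    "stai_state", "upsit", "ess", "rbdsq", "moca",
    "mean_composite", "cov_total", "ae_composite", "cov_ae",
]
TABLE2_VARIABLES = [
    "mean_composite", "cov_total", "ae_composite", "cov_ae",
    "age", "education", "updrs3", "hoehn_yahr", "scopa_aut", "gds15", "quip",
    "stai_state", "upsit", "ess", "rbdsq",
]
CORRELATION_VARIABLES = ["age", "education", "updrs3", "gds15", "stai_state", "upsit"]


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    seed: int = 0
    input_path: str | None = None  # read a cohort CSV instead of simulating
    sim: SimulationConfig | None = None
    norm_alpha: float = 0.05  # covariate-selection significance level
    fdr_q: float = 0.05
    conversion_window: tuple[float, float] = CONVERSION_WINDOW
    cov_scale: float = 0.1
    standardize_cov: bool = False
    out_dir: str | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValidationError("fdr_q must lie in (0, 1)")
        if not 0 < self.norm_alpha <= 1:
            raise ValidationError("norm_alpha must lie in (0, 1]")
        lo, hi = self.conversion_window
        if not lo < hi:
            raise ValidationError("conversion window must satisfy low < high")

    def resolve_sim(self) -> SimulationConfig:
        if self.sim is not None:
            return dataclasses.replace(self.sim, seed=self.seed)
        return SimulationConfig(seed=self.seed)


def run_full_pipeline(
    config: RunConfig, registry: TestRegistry | None = None
) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    Bundle keys: ``cohort``, ``stages``, ``norms``, ``panels``,
    ``dispersion``, ``hc_ids``, ``stage2_ids``, ``table1``,
    ``correlations``, ``outcomes``, ``table2``, ``fits``, ``transitions``,
    ``accounting``, ``notices``.  If ``config.out_dir`` is set every table
    is also written as CSV + aligned text.
    """
    registry = registry or default_registry()
    notices: list[str] = []

    if config.input_path:
        cohort = read_cohort(config.input_path, registry)
    else:
        cohort = simulate_cohort(config.resolve_sim(), registry)

    stages = assign_stages(cohort)
    hc_ids, stage2_ids, accounting = analysis_sets(cohort, stages, registry)

    # --- norming and dispersion ----------------------------------------
    reference = cohort[
        (cohort["participant_id"].isin(hc_ids)) & (cohort["visit_index"] == 0)
    ]
    if len(reference) < 30:
        raise ValidationError(
            f"norming reference has only {len(reference)} records (need >= 30)"
        )
    norms = fit_norms(reference, registry, alpha=config.norm_alpha)
    panels = apply_norms(cohort, norms, registry)
    disp = compute_dispersion(panels, registry)

    analysis = _analysis_table(cohort, disp, hc_ids, stage2_ids)

    # --- Table-1 family -------------------------------------------------
    bundle: dict = {
        "cohort": cohort,
        "stages": stages,
        "norms": norms,
        "panels": panels,
        "dispersion": disp,
        "hc_ids": hc_ids,
        "stage2_ids": stage2_ids,
        "accounting": accounting,
        "notices": notices,
    }

    if hc_ids and stage2_ids:
        variables: dict[str, str] = {"sex": "categorical"}
        variables.update({v: "continuous" for v in TABLE1_CONTINUOUS})
        bundle["table1"] = compare_groups(
            analysis, "group", variables, q=config.fdr_q,
            group_order=("hc", "stage2"),
        )
    else:
        notices.append("table1 skipped: need both an HC and a Stage-2 analysis set")
        bundle["table1"] = None

    corr_frames = []
    for label, frame in (("full", analysis), ("stage2", analysis[analysis["group"] == "stage2"])):
        if len(frame) >= 3:
            tab = correlation_table(frame, ["cov_total", "cov_ae"], CORRELATION_VARIABLES)
            tab.insert(0, "sample", label)
            corr_frames.append(tab)
    bundle["correlations"] = pd.concat(corr_frames, ignore_index=True) if corr_frames else None

    # --- conversion -----------------------------------------------------
    outcomes = label_conversion(stages, cohort, registry, window=config.conversion_window)
    outcomes = outcomes[outcomes["participant_id"].isin(stage2_ids)].reset_index(drop=True)
    bundle["outcomes"] = outcomes
    followed = outcomes[outcomes["followed"]]

    if len(followed) >= 20 and followed["converted"].nunique() == 2:
        conv = _conversion_table(followed, analysis)
        bundle["table2"] = compare_groups(
            conv, "converted_label", {v: "continuous" for v in TABLE2_VARIABLES},
            q=config.fdr_q, group_order=("non-converter", "converter"),
        )
        bundle["fits"] = run_conversion_models(
            conv, cov_scale=config.cov_scale, standardize=config.standardize_cov
        )
        bundle["transitions"] = transition_counts(outcomes)
    else:
        notices.append(
            "table2/logistic stage skipped: no followed Stage-2 subjects with "
            "both outcomes (HC-only cohort or insufficient follow-up)"
        )
        bundle["table2"] = None
        bundle["fits"] = None
        bundle["transitions"] = transition_counts(outcomes) if len(followed) else None

    if config.out_dir:
        _write_bundle(bundle, config, registry)
    for notice in notices:
        logger.warning(notice)
    return bundle


def analysis_sets(
    cohort: pd.DataFrame,
    stages: pd.DataFrame,
    registry: TestRegistry | None = None,
) -> tuple[list[str], list[str], dict]:
    """Derive the HC and Stage-2 analysis sets with exclusion accounting.

    HC: SAA-negative candidates passing the two-visit MoCA eligibility
    rule.  Stage 2: baseline stage 2A/2B with a complete battery.  Returns
    (hc_ids, stage2_ids, accounting) with
    enrolled = analyzed + excluded guaranteed.
    """
    registry = registry or default_registry()
    merged = cohort.merge(stages, on=["participant_id", "visit_index"])
    merged["complete"] = complete_battery_mask(merged, registry)
    baseline = merged[merged["visit_index"] == 0].set_index("participant_id")

    accounting: dict = {"enrolled": baseline.shape[0]}
    excluded: dict[str, int] = {}
    hc_ids, hc_excl = _hc_analysis_set(merged, baseline)
    excluded.update(hc_excl)

    stage2_mask = baseline["stage"].isin(["2A", "2B"]) & baseline["complete"]
    stage2_ids = baseline.index[stage2_mask].tolist()
    n_other = int(
        (~baseline.index.isin(hc_ids) & ~baseline.index.isin(stage2_ids)).sum()
        - sum(hc_excl.values())
    )
    if n_other:
        excluded["not-stage2-at-baseline"] = n_other
    accounting["hc_analyzed"] = len(hc_ids)
    accounting["stage2_analyzed"] = len(stage2_ids)
    accounting["excluded"] = dict(excluded)
    _check_accounting(accounting)
    return hc_ids, stage2_ids, accounting


def _hc_analysis_set(merged: pd.DataFrame, baseline: pd.DataFrame):
    """HC analysis ids plus per-rule exclusion counts."""
    hc_ids: list[str] = []
    excluded: dict[str, int] = {}
    candidates = baseline[(baseline["stage"] == "HC-eligible") & baseline["complete"]]
    year1 = merged[merged["visit_index"] > 0].sort_values("visit_index")
    year1_first = year1.groupby("participant_id").first()
    for pid, base_rec in candidates.iterrows():
        y1 = year1_first.loc[pid].to_dict() if pid in year1_first.index else None
        ok, reasons = hc_eligibility(base_rec.to_dict(), y1)
        if ok:
            hc_ids.append(pid)
        else:
            key = reasons[0]
            excluded[key] = excluded.get(key, 0) + 1
    return hc_ids, excluded


def _check_accounting(accounting: dict) -> None:
    total = (
        accounting["hc_analyzed"]
        + accounting["stage2_analyzed"]
        + sum(accounting["excluded"].values())
    )
    if total != accounting["enrolled"]:
        raise AssertionError(
            f"exclusion accounting mismatch: {total} != {accounting['enrolled']}"
        )


def _analysis_table(cohort, disp, hc_ids, stage2_ids) -> pd.DataFrame:
    base = cohort[cohort["visit_index"] == 0].copy()
    base = base.merge(disp, on=["participant_id", "visit_index"], how="left")
    base["group"] = np.select(
        [base["participant_id"].isin(hc_ids), base["participant_id"].isin(stage2_ids)],
        ["hc", "stage2"],
        default="",
    )
    return base[base["group"] != ""].reset_index(drop=True)


def _conversion_table(followed: pd.DataFrame, analysis: pd.DataFrame) -> pd.DataFrame:
    conv = followed.merge(
        analysis, left_on="participant_id", right_on="participant_id"
    )
    conv["converted_label"] = np.where(
        conv["converted"].astype(bool), "converter", "non-converter"
    )
    conv["converted"] = conv["converted"].astype(bool)
    return conv


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def emit_table(df: pd.DataFrame, base_path: str | Path | None = None) -> str:
    """Render a report table as aligned text; optionally write CSV + text.

    Numbers are formatted to 2 decimals, p-value columns to 3; the column
    order of the input is preserved.  Returns the text rendering.
    """
    if df is None or len(df) == 0:
        text = "" if df is None else ", ".join(df.columns)
    else:
        shown = df.copy()
        for col in shown.columns:
            if pd.api.types.is_float_dtype(shown[col]):
                digits = 3 if col.startswith("p") or col in ("p_raw", "p_adj") else 2
                shown[col] = shown[col].map(
                    lambda v, d=digits: "" if pd.isna(v) else f"{v:.{d}f}"
                )
        text = shown.to_string(index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
    if base_path is not None:
        base_path = Path(base_path)
        base_path.parent.mkdir(parents=True, exist_ok=True)
        if df is not None:
            df.to_csv(base_path.with_suffix(".csv"), index=df.index.name is not None)
        base_path.with_suffix(".txt").write_text(text + "\n", encoding="utf-8")
    return text


def _fit_report(fit: LogisticFit) -> pd.DataFrame:
    summary = fit.coef_table()
    summary["n"] = fit.n
    summary["ll1"] = fit.ll1
    summary["ll0"] = fit.ll0
    summary["lr_chi2"] = fit.lr_chi2
    summary["lr_df"] = fit.lr_df
    summary["lr_p"] = fit.lr_p
    summary["nagelkerke_r2"] = fit.nagelkerke_r2
    summary["hl_chi2"] = fit.hl_chi2
    summary["hl_df"] = fit.hl_df
    summary["hl_p"] = fit.hl_p
    return summary


def _write_bundle(bundle: dict, config: RunConfig, registry: TestRegistry) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(bundle["cohort"], out / "cohort.csv", registry)
    save_norms(bundle["norms"], out / "norms.yaml")
    emit_table(bundle["stages"], out / "stages")
    emit_table(bundle["dispersion"], out / "dispersion")
    if bundle["table1"] is not None:
        emit_table(bundle["table1"], out / "table1_group_comparison")
    if bundle["correlations"] is not None:
        emit_table(bundle["correlations"], out / "correlations")
    if bundle["outcomes"] is not None and len(bundle["outcomes"]):
        emit_table(bundle["outcomes"], out / "conversion_outcomes")
    if bundle["table2"] is not None:
        emit_table(bundle["table2"], out / "table2_converter_comparison")
    if bundle["fits"] is not None:
        for key, fit in bundle["fits"].items():
            emit_table(_fit_report(fit), out / f"logistic_{key}")
    if bundle.get("transitions") is not None and len(bundle["transitions"]):
        trans = bundle["transitions"].reset_index()
        emit_table(trans, out / "stage_transitions")
    info = {
        "seed": config.seed,
        "config": _config_dict(config),
        "accounting": bundle["accounting"],
        "notices": bundle["notices"],
    }
    (out / "run_info.json").write_text(
        json.dumps(info, indent=2, default=str) + "\n", encoding="utf-8"
    )


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # location of the bundle, not part of its content
    return d
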