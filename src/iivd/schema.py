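"""Cohort table schema and delimited-text input/output.

A cohort is a pandas ``DataFrame`` with one row per participant-visit.
``COLUMNS`` is the machine-readable column dictionary; ``write_cohort``
ships it as a JSON sidecar next to every CSV it writes.  Unknown columns
are preserved verbatim on read and write.

Missing values are encoded as empty cells.  The three biomarker/flag
columns use pandas' nullable ``boolean`` dtype so that "unknown" is a
first-class state (e.g. healthy controls without a DaTscan).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from iivd.errors import SchemaError
from iivd.registry import TestRegistry, default_registry

IMPAIRMENT_LEVELS = ("none", "slight", "greater")

ID_COLUMNS = {
    "participant_id": "opaque participant identifier (string)",
    "visit_index": "integer visit counter; 0 = first visit with a complete battery",
    "visit_offset_years": "years since the participant's baseline visit (>= 0)",
}
DEMO_COLUMNS = {
    "age": "age in years at visit",
    "sex": "binary category, 'M' or 'F'",
    "education": "years of education (>= 0)",
}
SCALE_COLUMNS = {
    "updrs3": "MDS-UPDRS Part III motor examination total (higher = worse)",
    "hoehn_yahr": "Hoehn & Yahr stage",
    "scopa_aut": "SCOPA-AUT autonomic dysfunction total",
    "gds15": "Geriatric Depression Scale, 15-item total",
    "quip": "QUIP impulsive-compulsive disorder screen total",
    "stai_state": "State-Trait Anxiety Inventory, state subscale total",
    "upsit": "University of Pennsylvania Smell Identification Test total",
    "ess": "Epworth Sleepiness Scale total",
    "rbdsq": "REM Sleep Behavior Disorder Questionnaire total",
    "moca": "Montreal Cognitive Assessment total (0-30)",
}
FLAG_COLUMNS = {
    "saa_positive": "CSF alpha-synuclein seed amplification assay result (boolean; blank = not assayed)",
    "dat_deficit": "putamen DAT specific binding ratio < 75% of age/sex-adjusted reference (boolean; blank = no scan)",
    "hyposmia": "hyposmia present (boolean)",
    "functional_impairment": "ordered category: none < slight < greater",
}

BOOLEAN_COLUMNS = ("saa_positive", "dat_deficit", "hyposmia")


def test_columns(registry: TestRegistry | None = None) -> dict[str, str]:
    registry = registry or default_registry()
    suffix = " raw score (seconds; higher = worse)"
    return {
        t.name: t.label + (suffix if t.higher_is_worse else " raw score")
        for t in registry
    }


def column_dictionary(registry: TestRegistry | None = None) -> dict[str, str]:
    """Full machine-readable column dictionary for a cohort file."""
    return {
        **ID_COLUMNS,
        **DEMO_COLUMNS,
        **test_columns(registry),
        **SCALE_COLUMNS,
        **FLAG_COLUMNS,
    }


def required_columns(registry: TestRegistry | None = None) -> list[str]:
    return list(column_dictionary(registry))


def validate_cohort(
    df: pd.DataFrame, registry: TestRegistry | None = None
) -> pd.DataFrame:
    """Check a cohort table against the schema; returns the table unchanged.

    Raises :class:`SchemaError` naming the offending column or rows.
    Columns outside the schema are allowed and untouched.
    """
    for col in required_columns(registry):
        if col not in df.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    dup = df.duplicated(subset=["participant_id", "visit_index"])
    if dup.any():
        first = df.loc[dup, ["participant_id", "visit_index"]].iloc[0]
        raise SchemaError(
            "duplicate (participant_id, visit_index) pair: "
            f"({first['participant_id']!r}, {first['visit_index']!r})"
        )
    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        raise SchemaError(
            f"column 'sex' contains values outside {{'M','F'}}: "
            f"{sorted(df.loc[bad_sex, 'sex'].astype(str).unique())[:5]}"
        )
    imp = df["functional_impairment"]
    bad_imp = ~(imp.isin(IMPAIRMENT_LEVELS) | imp.isna())
    if bad_imp.any():
        raise SchemaError(
            "column 'functional_impairment' contains values outside "
            f"{IMPAIRMENT_LEVELS}"
        )
    if (df["education"].dropna() < 0).any():
        raise SchemaError("column 'education' contains negative values")
    moca = df["moca"].dropna()
    if ((moca < 0) | (moca > 30)).any():
        raise SchemaError("column 'moca' contains values outside [0, 30]")
    return df


def write_cohort(
    df: pd.DataFrame,
    path: str | Path,
    registry: TestRegistry | None = None,
    sidecar: bool = True,
) -> None:
    """Write a cohort table as UTF-8 CSV plus a JSON column-dictionary sidecar."""
    path = Path(path)
    validate_cohort(df, registry)
    df.to_csv(path, index=False, encoding="utf-8")
    if sidecar:
        extra = {
            c: "extra column (carried through, not part of the schema)"
            for c in df.columns
            if c not in column_dictionary(registry)
        }
        sidecar_path = path.with_suffix(path.suffix + ".dict.json")
        sidecar_path.write_text(
            json.dumps({**column_dictionary(registry), **extra}, indent=2) + "\n",
            encoding="utf-8",
        )


def read_cohort(path: str | Path, registry: TestRegistry | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Unknown columns are parsed with pandas' default inference and carried
    through untouched.
    """
    registry = registry or default_registry()
    df = pd.read_csv(path, encoding="utf-8")
    df = coerce_dtypes(df, registry)
    return validate_cohort(df, registry)


def coerce_dtypes(df: pd.DataFrame, registry: TestRegistry | None = None) -> pd.DataFrame:
    """Apply schema dtypes (nullable booleans, string ids) in place-ish."""
    df = df.copy()
    if "participant_id" in df.columns:
        df["participant_id"] = df["participant_id"].astype(str)
    for col in BOOLEAN_COLUMNS:
        if col in df.columns:
            df[col] = _to_nullable_bool(df[col], col)
    return df


def _to_nullable_bool(s: pd.Series, name: str) -> pd.Series:
    if s.dtype == bool or str(s.dtype) == "boolean":
        return s.astype("boolean")
    mapping = {
        "True": True, "False": False, "true": True, "false": False,
        True: True, False: False, 1.0: True, 0.0: False, 1: True, 0: False,
    }
    out = s.map(lambda v: mapping.get(v, pd.NA) if pd.notna(v) else pd.NA)
    unmapped = s.notna() & out.isna()
    if unmapped.any():
        raise SchemaError(
            f"column {name!r} contains non-boolean values: "
            f"{sorted(s[unmapped].astype(str).unique())[:5]}"
        )
    return out.astype("boolean")


def complete_battery_mask(
    df: pd.DataFrame, registry: TestRegistry | None = None
) -> pd.Series:
    """True where all 11 raw test scores are present at the visit."""
    registry = registry or default_registry()
    return df[registry.names].notna().all(axis=1)
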