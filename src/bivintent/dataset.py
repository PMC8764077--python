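"""Respondent-level survey table: schema, validation, reading and writing.

The analysis operates on one row per respondent with two 0-100 intention
scores (COVID-19 vaccine, contact-tracing app), four 0-4 motivation items,
three 0-100 risk-perception items, three 0-100 trust items, and a set of
demographic and attitude covariates.  Validation is complete-case: rows
missing any modelled field are dropped and counted, never imputed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """A value is outside its documented range."""


#: canonical field -> (kind, constraint)
#: kind is one of "score" (numeric range), "ordinal" (integer range),
#: "binary", "category", "id", "positive"
SCHEMA: dict[str, tuple[str, object]] = {
    "respondent_id": ("id", None),
    "vaccine_intent": ("score", (0, 100)),
    "cta_intent": ("score", (0, 100)),
    "motivation_vaccine_self": ("ordinal", (0, 4)),
    "motivation_vaccine_others": ("ordinal", (0, 4)),
    "motivation_cta_self": ("ordinal", (0, 4)),
    "motivation_cta_others": ("ordinal", (0, 4)),
    "risk_likelihood": ("score", (0, 100)),
    "risk_severity": ("score", (0, 100)),
    "risk_scare": ("score", (0, 100)),
    "trust_international": ("score", (0, 100)),
    "trust_national": ("score", (0, 100)),
    "trust_scientific": ("score", (0, 100)),
    "trust_local": ("score", (0, 100)),
    "self_efficacy": ("score", (0, 100)),
    "vaccine_doubts": ("score", (0, 100)),
    "flu_vaccine_2019": ("binary", None),
    "conspiracy": ("ordinal", (1, 7)),
    "gender": ("category", ("female", "male")),
    "age": ("positive", None),
    "education": (
        "category",
        ("middle school", "high school", "university degree or higher"),
    ),
    "family_status": ("category", None),
    "job": ("category", ("employee", "business-owner", "retired-unemployed", "student")),
    "salary": ("category", None),
    "covid_contact": ("binary", None),
}

RISK_ITEMS = ["risk_likelihood", "risk_severity", "risk_scare"]
TRUST_ITEMS = ["trust_international", "trust_national", "trust_scientific"]
MOTIVATION_ITEMS = [
    "motivation_vaccine_self",
    "motivation_vaccine_others",
    "motivation_cta_self",
    "motivation_cta_others",
]

#: motivation items are collected on 0-4 but modelled on 1-4; the bottom two
#: raw levels collapse into level 1.  Overridable by passing a different map.
DEFAULT_MOTIVATION_RECODE: dict[int, int] = {0: 1, 1: 1, 2: 2, 3: 3, 4: 4}


@dataclasses.dataclass
class SurveyDataset:
    """Validated respondent-level table (complete cases only).

    Attributes
    ----------
    table : pandas.DataFrame
        One row per respondent, canonical column names, validated ranges.
    drop_report : dict
        Counts of rows removed during validation, keyed by reason.
    """

    table: pd.DataFrame
    drop_report: dict[str, int] = dataclasses.field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.table)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.table)


def _check_ranges(df: pd.DataFrame, strict: bool) -> None:
    """Raise ValidationError naming the first offending row, if any."""
    for field, (kind, constraint) in SCHEMA.items():
        if field not in df.columns:
            continue
        col = df[field]
        if kind in ("score", "ordinal", "positive"):
            vals = pd.to_numeric(col, errors="coerce")
            if kind == "positive":
                bad = vals.notna() & (vals <= 0)
            else:
                lo, hi = constraint
                bad = vals.notna() & ((vals < lo) | (vals > hi))
            if kind == "ordinal":
                bad |= vals.notna() & (vals != vals.round())
            if bad.any():
                rid = df.loc[bad, "respondent_id"].iloc[0]
                raise ValidationError(
                    f"out-of-range value in column {field!r} "
                    f"(respondent_id={rid!r})"
                )
        elif kind == "binary":
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.notna() & ~vals.isin([0, 1])
            if bad.any():
                rid = df.loc[bad, "respondent_id"].iloc[0]
                raise ValidationError(
                    f"non-binary value in column {field!r} (respondent_id={rid!r})"
                )
        elif kind == "category" and constraint is not None and strict:
            bad = col.notna() & ~col.isin(constraint)
            if bad.any():
                rid = df.loc[bad, "respondent_id"].iloc[0]
                raise ValidationError(
                    f"unknown level {col[bad].iloc[0]!r} in column {field!r} "
                    f"(respondent_id={rid!r})"
                )


def validate(df: pd.DataFrame, strict_categories: bool = True) -> SurveyDataset:
    """Validate a raw table into a :class:`SurveyDataset`.

    Complete-case by construction: rows with any missing modelled field are
    dropped (counted in ``drop_report['incomplete']``).  Out-of-range values
    raise :class:`ValidationError`; missing columns raise :class:`SchemaError`.
    Validating an already-validated table is a no-op.
    """
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df["respondent_id"].duplicated().any():
        dup = df.loc[df["respondent_id"].duplicated(), "respondent_id"].iloc[0]
        raise ValidationError(f"duplicate respondent_id {dup!r}")

    df = df.copy()
    _check_ranges(df, strict_categories)

    modelled = [c for c in SCHEMA if c != "respondent_id"]
    complete = df[modelled].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    out = df.loc[complete].reset_index(drop=True)

    for field, (kind, _) in SCHEMA.items():
        if kind in ("score", "positive"):
            out[field] = out[field].astype(float)
        elif kind in ("ordinal", "binary"):
            out[field] = out[field].astype(int)
        elif kind == "category":
            out[field] = out[field].astype(str)

    report = {"incomplete": n_dropped} if n_dropped else {}
    return SurveyDataset(table=out, drop_report=report)


def read_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    strict_categories: bool = True,
) -> SurveyDataset:
    """Read a delimited survey file (comma or tab, auto-detected) and validate.

    Parameters
    ----------
    schema : mapping, optional
        Maps canonical field names to the file's column headers, so an
        arbitrarily-headed deposit file can be bound without code changes.
        Fields absent from the mapping are assumed to use canonical names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    raw = pd.read_csv(path, sep=sep)
    if schema:
        missing_src = [src for src in schema.values() if src not in raw.columns]
        if missing_src:
            raise SchemaError(
                f"schema maps to column(s) absent from file: {', '.join(missing_src)}"
            )
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    return validate(raw, strict_categories=strict_categories)


def write_table(
    table: pd.DataFrame, path: str | Path, format: str = "delimited"
) -> None:
    """Write a rectangular report table as delimited text or markdown.

    Delimited output round-trips losslessly through :func:`pandas.read_csv`
    up to dtype coercion.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        table.to_csv(path, index=False)
    elif format == "markdown":
        path.write_text(table.to_markdown(index=False) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_survey(ds: SurveyDataset, path: str | Path) -> None:
    """Write a survey dataset in the same delimited format ``read_survey`` reads."""
    write_table(ds.table, path, format="delimited")


def recode_motivation(
    values: pd.Series | np.ndarray,
    mapping: Mapping[int, int] = DEFAULT_MOTIVATION_RECODE,
) -> np.ndarray:
    """Recode raw 0-4 motivation responses onto the 1-4 modelling scale."""
    arr = np.asarray(values, dtype=int)
    out = np.array([mapping[v] for v in arr.ravel()], dtype=int)
    return out.reshape(arr.shape)
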