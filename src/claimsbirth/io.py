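"""Reading, validating and writing the three tabular inputs.

The pipeline consumes plain CSV extracts:

* population: ``woman_id,birth_year,birth_month,husband_identified``
* links:      ``mother_id,child_birth_year,child_birth_month``
* claims:     ``woman_id,year,month,domain,code,suspected`` with
  ``domain`` in {diagnosis, procedure, medication} and ``suspected`` in {0,1}

Internally year/month pairs are collapsed into a single integer ``month``
column (see :mod:`claimsbirth.months`); the ``month_idx`` convention is used
for that derived column throughout the package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "DOMAINS",
    "read_population",
    "read_links",
    "read_claims",
    "write_population",
    "write_links",
    "write_claims",
]

DOMAINS = ("diagnosis", "procedure", "medication")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns {missing}")


def _month_col(df: pd.DataFrame, ycol: str, mcol: str, what: str) -> pd.Series:
    y = pd.to_numeric(df[ycol], errors="coerce")
    m = pd.to_numeric(df[mcol], errors="coerce")
    bad = y.isna() | m.isna() | (m < 1) | (m > 12) | (m % 1 != 0) | (y % 1 != 0)
    if bad.any():
        rows = df.index[bad][:5].tolist()
        raise SchemaError(
            f"{what} table has invalid {ycol}/{mcol} values at rows {rows}"
        )
    return (y.astype(np.int64) * 12 + m.astype(np.int64) - 1).rename("month_idx")


def read_population(path: str | Path) -> pd.DataFrame:
    """Population table -> DataFrame indexed by ``woman_id`` with columns
    ``birth_month_idx`` (int) and ``husband_identified`` (bool)."""
    df = pd.read_csv(path, dtype={"woman_id": str})
    _require_columns(df, ("woman_id", "birth_year", "birth_month", "husband_identified"), "population")
    if df["woman_id"].duplicated().any():
        dup = df.loc[df["woman_id"].duplicated(), "woman_id"].iloc[:5].tolist()
        raise SchemaError(f"population table has duplicate woman_id values: {dup}")
    hid = pd.to_numeric(df["husband_identified"], errors="coerce")
    if hid.isna().any() or not hid.isin((0, 1)).all():
        raise SchemaError("population husband_identified must be 0 or 1")
    out = pd.DataFrame(
        {
            "birth_month_idx": _month_col(df, "birth_year", "birth_month", "population").values,
            "husband_identified": hid.astype(bool).values,
        },
        index=pd.Index(df["woman_id"], name="woman_id"),
    )
    return out


def read_links(path: str | Path) -> pd.DataFrame:
    """Parent-child link table -> DataFrame with ``mother_id`` (str) and
    ``child_birth_month_idx`` (int) columns."""
    df = pd.read_csv(path, dtype={"mother_id": str})
    _require_columns(df, ("mother_id", "child_birth_year", "child_birth_month"), "links")
    return pd.DataFrame(
        {
            "mother_id": df["mother_id"].values,
            "child_birth_month_idx": _month_col(
                df, "child_birth_year", "child_birth_month", "links"
            ).values,
        }
    )


def read_claims(path: str | Path) -> pd.DataFrame:
    """Claims table -> DataFrame with ``woman_id``, ``month_idx``, ``domain``,
    ``code``, ``suspected`` (bool) columns.

    The suspected flag is meaningful only for diagnosis lines; it is forced
    to False elsewhere (a set flag on a procedure/medication line is a
    schema violation).
    """
    df = pd.read_csv(path, dtype={"woman_id": str, "code": str})
    _require_columns(df, ("woman_id", "year", "month", "domain", "code", "suspected"), "claims")
    if not df["domain"].isin(DOMAINS).all():
        bad = sorted(set(df["domain"]) - set(DOMAINS))
        raise SchemaError(f"claims table has unknown domains {bad}")
    susp = pd.to_numeric(df["suspected"], errors="coerce")
    if susp.isna().any() or not susp.isin((0, 1)).all():
        raise SchemaError("claims suspected must be 0 or 1")
    susp = susp.astype(bool)
    if (susp & (df["domain"] != "diagnosis")).any():
        raise SchemaError("suspected flag set on a non-diagnosis claim line")
    return pd.DataFrame(
        {
            "woman_id": df["woman_id"].values,
            "month_idx": _month_col(df, "year", "month", "claims").values,
            "domain": df["domain"].values,
            "code": df["code"].values,
            "suspected": susp.values,
        }
    )


def _split_month(idx: pd.Series) -> tuple[pd.Series, pd.Series]:
    return idx // 12, idx % 12 + 1


def write_population(df: pd.DataFrame, path: str | Path) -> None:
    y, m = _split_month(df["birth_month_idx"])
    out = pd.DataFrame(
        {
            "woman_id": df.index,
            "birth_year": y.values,
            "birth_month": m.values,
            "husband_identified": df["husband_identified"].astype(int).values,
        }
    )
    out.to_csv(path, index=False)


def write_links(df: pd.DataFrame, path: str | Path) -> None:
    y, m = _split_month(df["child_birth_month_idx"])
    pd.DataFrame(
        {"mother_id": df["mother_id"].values, "child_birth_year": y.values, "child_birth_month": m.values}
    ).to_csv(path, index=False)


def write_claims(df: pd.DataFrame, path: str | Path) -> None:
    y, m = _split_month(df["month_idx"])
    pd.DataFrame(
        {
            "woman_id": df["woman_id"].values,
            "year": y.values,
            "month": m.values,
            "domain": df["domain"].values,
            "code": df["code"].values,
            "suspected": df["suspected"].astype(int).values,
        }
    ).to_csv(path, index=False)
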