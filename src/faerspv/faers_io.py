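"""Reading and writing FAERS-dialect quarterly ASCII extracts.

The quarterly extracts of a spontaneous-reporting database arrive as
``$``-delimited text tables.  Four of them carry everything this pipeline
needs: patient demographics (DEMO), drug records (DRUG), coded reactions
(REAC) and report outcomes (OUTC), linked by ``primaryid``.  This module
parses those tables into typed :class:`pandas.DataFrame` objects, bundles
the four tables of one quarter together, and can write a bundle back out in
the same dialect (the synthetic generator relies on the round trip).

Dialect notes
-------------
* The delimiter is a literal ``$`` with no quoting.  On write, any ``$``
  embedded in a free-text field is replaced by a space; on read, lines are
  split naively.  This mirrors the real extracts and is a documented
  limitation.
* Dates are ``YYYYMMDD``; partial dates (``YYYYMM``, ``YYYY``) are accepted,
  the missing parts are imputed to 01 for ordering only and the row is
  flagged partial.
* Ages are normalised to years (months/12, weeks/52.18, days/365.25,
  decades*10, hours/8766); an unknown unit leaves the age missing.
* Column names drifted across database eras; a header alias map (e.g. the
  old ``gndr_cod`` for ``sex``) is applied before schema validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

logger = logging.getLogger(__name__)

TABLE_KINDS = ("demo", "drug", "reac", "outc")

#: Raw file columns per table kind, in on-disk order.
RAW_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "primaryid",
        "caseid",
        "caseversion",
        "fda_dt",
        "sex",
        "age",
        "age_cod",
        "occp_cod",
        "reporter_country",
    ],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
}

#: Historic column-name synonyms, applied to headers before validation.
DEFAULT_HEADER_ALIASES: dict[str, str] = {
    "gndr_cod": "sex",
    "case_version": "caseversion",
}

AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

SEX_CODES = frozenset({"F", "M"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OCCUPATION_CODES = frozenset({"MD", "PH", "OT", "CN", "LW"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

UNK = "UNK"


def normalize_pt(pt: str) -> str:
    """Normalise a preferred term: upper-case, collapse internal whitespace,
    strip trailing punctuation."""
    return " ".join(str(pt).upper().split()).rstrip(".,;:")


def _normalize_pt_series(s: pd.Series) -> pd.Series:
    out = s.astype(str).str.upper().str.split().str.join(" ")
    return out.str.rstrip(".,;:")


# ---------------------------------------------------------------------------
# raw file <-> raw frame


def _read_raw(path: str | Path, kind: str,
              aliases: Mapping[str, str] | None = None) -> tuple[pd.DataFrame, int]:
    """Split a ``$``-delimited file into a raw string DataFrame.

    Returns the frame and the number of malformed (wrong field count) data
    lines that were skipped.
    """
    path = Path(path)
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    if not path.exists():
        raise InputError(f"table file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file, no header line")
    header = [c.strip().lower() for c in lines[0].split("$")]
    alias_map = dict(DEFAULT_HEADER_ALIASES)
    if aliases:
        alias_map.update({k.lower(): v.lower() for k, v in aliases.items()})
    header = [alias_map.get(c, c) for c in header]
    required = RAW_COLUMNS[kind]
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: header is missing required column {col!r}")
    ncol = len(header)
    rows: list[list[str]] = []
    skipped = 0
    for line in lines[1:]:
        fields = line.split("$")
        if len(fields) != ncol:
            skipped += 1
            continue
        rows.append(fields)
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    if frame.empty:
        frame = pd.DataFrame({c: pd.Series(dtype=str) for c in header})
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, skipped)
    return frame, skipped


# ---------------------------------------------------------------------------
# raw frame -> typed frame

def _parse_dates(raw: pd.Series) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Parse YYYYMMDD / YYYYMM / YYYY strings.

    Returns (datetime64 series, partial flag, canonical raw string).
    Missing parts are imputed to 01 for ordering only.
    """
    s = raw.fillna("").astype(str).str.strip()
    digits = s.str.fullmatch(r"\d{4}|\d{6}|\d{8}")
    s = s.where(digits.fillna(False), "")
    partial = (s.str.len() > 0) & (s.str.len() < 8)
    padded = s.copy()
    padded = padded.where(~(s.str.len() == 4), s + "0101")
    padded = padded.where(~(s.str.len() == 6), s + "01")
    dates = pd.to_datetime(padded.replace("", pd.NA), format="%Y%m%d", errors="coerce")
    return dates, partial, s


def parse_demo(raw: pd.DataFrame) -> pd.DataFrame:
    """Type the raw DEMO table.

    Adds derived columns (``case_version``, ``fda_date``, ``age_years``,
    ``event_year`` ...) while keeping the canonical raw strings needed for a
    faithful round trip.
    """
    out = pd.DataFrame(index=raw.index)
    out["primaryid"] = raw["primaryid"].astype(str).str.strip()
    out["caseid"] = raw["caseid"].astype(str).str.strip()
    ver = pd.to_numeric(raw["caseversion"], errors="coerce")
    out["case_version"] = ver.fillna(1).astype(np.int64).clip(lower=1)
    dates, partial, canon = _parse_dates(raw["fda_dt"])
    out["fda_dt"] = canon
    out["fda_date"] = dates
    out["date_partial"] = partial
    out["event_year"] = dates.dt.year.astype("Int64")
    sex = raw["sex"].fillna("").astype(str).str.strip().str.upper()
    out["sex"] = sex.where(sex.isin(SEX_CODES), UNK)
    age = pd.to_numeric(raw["age"], errors="coerce")
    unit = raw["age_cod"].fillna("").astype(str).str.strip().str.upper()
    unit = unit.where(unit.isin(AGE_UNIT_TO_YEARS), UNK)
    unit = unit.where(age.notna(), UNK)
    out["age_value"] = age
    out["age_unit"] = unit
    factor = unit.map(AGE_UNIT_TO_YEARS)
    out["age_years"] = age * factor
    occ = raw["occp_cod"].fillna("").astype(str).str.strip().str.upper()
    out["reporter_occupation"] = occ.where(occ.isin(OCCUPATION_CODES), UNK)
    country = raw["reporter_country"].fillna("").astype(str).str.strip().str.upper()
    out["country"] = country.where(country != "", UNK)
    _attach_extras(out, raw, "demo")
    return out


def parse_drug(raw: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=raw.index)
    out["primaryid"] = raw["primaryid"].astype(str).str.strip()
    out["drug_seq"] = pd.to_numeric(raw["drug_seq"], errors="coerce").fillna(0).astype(np.int64)
    out["role_code"] = raw["role_cod"].fillna("").astype(str).str.strip().str.upper()
    out["verbatim_name"] = raw["drugname"].fillna("").astype(str).str.strip()
    out = out[out["verbatim_name"] != ""].reset_index(drop=True)
    _attach_extras(out, raw, "drug")
    return out


def parse_reac(raw: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=raw.index)
    out["primaryid"] = raw["primaryid"].astype(str).str.strip()
    out["pt"] = _normalize_pt_series(raw["pt"].fillna(""))
    out = out[out["pt"] != ""]
    out = out.drop_duplicates(["primaryid", "pt"]).reset_index(drop=True)
    _attach_extras(out, raw, "reac")
    return out


def parse_outc(raw: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=raw.index)
    out["primaryid"] = raw["primaryid"].astype(str).str.strip()
    code = raw["outc_cod"].fillna("").astype(str).str.strip().str.upper()
    out["outcome_code"] = code.where(code.isin(OUTCOME_CODES), "OT")
    out = out.drop_duplicates(["primaryid", "outcome_code"]).reset_index(drop=True)
    _attach_extras(out, raw, "outc")
    return out


def _attach_extras(out: pd.DataFrame, raw: pd.DataFrame, kind: str) -> None:
    """Pass unknown columns through untouched."""
    for col in raw.columns:
        if col not in RAW_COLUMNS[kind] and col not in out.columns:
            out[col] = raw[col].astype(str)


PARSERS = {"demo": parse_demo, "drug": parse_drug, "reac": parse_reac, "outc": parse_outc}


def read_table(path: str | Path, kind: str,
               aliases: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read one FAERS-dialect table into a typed DataFrame.

    Malformed data lines (wrong field count) are skipped; their number is
    available as ``frame.attrs["n_skipped"]``.
    """
    raw, skipped = _read_raw(path, kind, aliases)
    parsed = PARSERS[kind](raw)
    parsed.attrs["n_skipped"] = skipped
    return parsed


# ---------------------------------------------------------------------------
# quarter bundles


@dataclass(eq=False)
class QuarterBundle:
    """The four parsed tables of one quarter, orphan-free.

    Any DRUG/REAC/OUTC row whose ``primaryid`` is absent from DEMO is an
    orphan: it is dropped at assembly time and counted in
    :attr:`orphans_removed`.
    """

    quarter_label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    orphans_removed: dict[str, int] = field(default_factory=dict)

    def table(self, kind: str) -> pd.DataFrame:
        return getattr(self, kind)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def equals(self, other: "QuarterBundle") -> bool:
        if self.quarter_label != other.quarter_label:
            return False
        for kind in TABLE_KINDS:
            a = self.table(kind).reset_index(drop=True)
            b = other.table(kind).reset_index(drop=True)
            if list(a.columns) != list(b.columns) or not a.equals(b):
                return False
        return True


def drop_orphans(demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame,
                 outc: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Remove DRUG/REAC/OUTC rows whose primaryid is not in DEMO. Idempotent."""
    known = set(demo["primaryid"])
    counts: dict[str, int] = {}
    out = []
    for kind, frame in (("drug", drug), ("reac", reac), ("outc", outc)):
        keep = frame["primaryid"].isin(known)
        counts[kind] = int((~keep).sum())
        if counts[kind]:
            logger.warning("dropping %d orphan %s row(s)", counts[kind], kind.upper())
        out.append(frame[keep].reset_index(drop=True))
    return out[0], out[1], out[2], counts


def make_bundle(quarter_label: str, demo: pd.DataFrame, drug: pd.DataFrame,
                reac: pd.DataFrame, outc: pd.DataFrame) -> QuarterBundle:
    drug, reac, outc, orphans = drop_orphans(demo, drug, reac, outc)
    return QuarterBundle(quarter_label, demo.reset_index(drop=True), drug, reac, outc,
                         orphans_removed=orphans)


def table_filename(kind: str, quarter_label: str) -> str:
    return f"{kind.upper()}_{quarter_label}.txt"


def load_quarter(directory: str | Path, quarter_label: str,
                 aliases: Mapping[str, str] | None = None) -> QuarterBundle:
    """Load the four tables of one quarter from ``directory``."""
    directory = Path(directory)
    tables = {}
    for kind in TABLE_KINDS:
        path = directory / table_filename(kind, quarter_label)
        if not path.exists():
            raise InputError(f"missing {kind.upper()} table for {quarter_label}: {path}")
        tables[kind] = read_table(path, kind, aliases)
    return make_bundle(quarter_label, tables["demo"], tables["drug"], tables["reac"],
                       tables["outc"])


# ---------------------------------------------------------------------------
# writing


def _fmt_number(x: float) -> str:
    if pd.isna(x):
        return ""
    f = float(x)
    return str(int(f)) if f == int(f) else repr(f)


def _unparse_demo(demo: pd.DataFrame) -> pd.DataFrame:
    raw = pd.DataFrame(index=demo.index)
    raw["primaryid"] = demo["primaryid"]
    raw["caseid"] = demo["caseid"]
    raw["caseversion"] = demo["case_version"].astype(str)
    raw["fda_dt"] = demo["fda_dt"]
    raw["sex"] = demo["sex"].replace(UNK, "")
    raw["age"] = demo["age_value"].map(_fmt_number)
    raw["age_cod"] = demo["age_unit"].replace(UNK, "")
    raw["occp_cod"] = demo["reporter_occupation"].replace(UNK, "")
    raw["reporter_country"] = demo["country"].replace(UNK, "")
    return raw


def _unparse_drug(drug: pd.DataFrame) -> pd.DataFrame:
    raw = pd.DataFrame(index=drug.index)
    raw["primaryid"] = drug["primaryid"]
    raw["drug_seq"] = drug["drug_seq"].astype(str)
    raw["role_cod"] = drug["role_code"]
    raw["drugname"] = drug["verbatim_name"]
    return raw


def _unparse_reac(reac: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"primaryid": reac["primaryid"], "pt": reac["pt"]})


def _unparse_outc(outc: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"primaryid": outc["primaryid"],
                         "outc_cod": outc["outcome_code"]})


UNPARSERS = {"demo": _unparse_demo, "drug": _unparse_drug,
             "reac": _unparse_reac, "outc": _unparse_outc}


def write_table(frame: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a parsed table back to the ``$``-delimited dialect.

    Embedded ``$`` characters in free text are replaced by a space (the
    dialect has no quoting).
    """
    raw = UNPARSERS[kind](frame)
    for extra in frame.columns:
        if extra not in RAW_COLUMNS[kind] and extra not in raw.columns and extra not in (
                "case_version", "fda_date", "date_partial", "event_year", "age_value",
                "age_unit", "age_years", "reporter_occupation", "country", "sex",
                "role_code", "verbatim_name", "outcome_code"):
            raw[extra] = frame[extra].astype(str)
    sanitized = raw.astype(str).apply(lambda s: s.str.replace("$", " ", regex=False))
    lines = ["$".join(sanitized.columns)]
    lines.extend("$".join(row) for row in sanitized.itertuples(index=False, name=None))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_quarter(bundle: QuarterBundle, directory: str | Path) -> list[Path]:
    """Write a bundle's four tables; returns the written paths."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable parent
        raise InputError(f"cannot create output directory {directory}: {exc}") from exc
    paths = []
    for kind in TABLE_KINDS:
        path = directory / table_filename(kind, bundle.quarter_label)
        write_table(bundle.table(kind), path, kind)
        paths.append(path)
    return paths


def concat_bundles(bundles: Iterable[QuarterBundle]) -> dict[str, pd.DataFrame]:
    """Concatenate the tables of several quarters into one frame per kind."""
    bundles = list(bundles)
    if not bundles:
        raise InputError("no quarter bundles supplied")
    return {kind: pd.concat([b.table(kind) for b in bundles], ignore_index=True)
            for kind in TABLE_KINDS}
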