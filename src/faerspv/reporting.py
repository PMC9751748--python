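"""Descriptive output tables: demographics, outcomes, death causes, trends.

All percentages follow the ``N (%)`` convention of pharmacovigilance
descriptive tables: count / denominator x 100, rounded half-up to two
decimals.  Every emitted percent is recomputable from the counts in the
same table, which the test suite checks on every output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import AnalysisDataset

#: Fine age strata (years) used in the per-drug demographic table.
AGE_BUCKETS_FINE = ((0, 18, "<18"), (18, 45, "18-44"), (45, 65, "45-64"),
                    (65, 75, "65-74"), (75, np.inf, ">=75"))
#: Coarse strata used in the death-demographics table.
AGE_BUCKETS_COARSE = ((0, 18, "<18"), (18, 45, "18-44"), (45, 65, "45-64"),
                      (65, np.inf, ">=65"))

OCCUPATION_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "OT": "Other health-professional",
    "PH": "Pharmacist",
    "LW": "others",
    "UNK": "Unknown",
}

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization (initial or prolonged)",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious outcome",
}


def percent(count: int, denominator: int) -> float:
    """``count / denominator * 100`` rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ParameterError("percent denominator must be positive")
    value = Decimal(int(count)) * 100 / Decimal(int(denominator))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _bucket_age(age_years: pd.Series, buckets) -> pd.Series:
    out = pd.Series("Unknown", index=age_years.index, dtype=object)
    for lo, hi, label in buckets:
        mask = age_years.notna() & (age_years >= lo) & (age_years < hi)
        out[mask] = label
    return out


def _stratum_frame(labels: pd.Series, order: list[str], denominator: int,
                   category: str) -> pd.DataFrame:
    counts = labels.value_counts()
    rows = [{"category": category, "stratum": lab,
             "count": int(counts.get(lab, 0)),
             "percent": percent(int(counts.get(lab, 0)), denominator) if denominator else 0.0}
            for lab in order]
    return pd.DataFrame(rows)


def demographics_table(dataset: AnalysisDataset, drug: str,
                       top_countries: int = 3) -> pd.DataFrame:
    """Sex / age / reporter / country strata for one drug's reports.

    The denominator of every percent is the drug's deduplicated report
    count; countries list the ``top_countries`` most frequent by name plus
    an ``Others`` bucket.
    """
    ids = dataset.report_ids(drug)
    demo = dataset.demo[dataset.demo["primaryid"].isin(set(ids))]
    n = len(demo)
    parts = []

    sex = demo["sex"].map({"F": "Female", "M": "Male"}).fillna("Unknown")
    parts.append(_stratum_frame(sex, ["Female", "Male", "Unknown"], n, "Sex"))

    age = _bucket_age(demo["age_years"], AGE_BUCKETS_FINE)
    order = [b[2] for b in AGE_BUCKETS_FINE] + ["Unknown"]
    parts.append(_stratum_frame(age, order, n, "Age (year)"))

    occ = demo["reporter_occupation"].map(OCCUPATION_LABELS).fillna("Unknown")
    parts.append(_stratum_frame(occ, [OCCUPATION_LABELS[k] for k in
                                      ("CN", "MD", "OT", "PH", "LW", "UNK")],
                                n, "Reporters"))

    country = demo["country"].replace("UNK", "Unknown")
    top = [c for c in country.value_counts().index if c != "Unknown"][:top_countries]
    country = country.where(country.isin(top), "Others")
    parts.append(_stratum_frame(country, top + ["Others"], n, "Reporter country"))

    table = pd.concat(parts, ignore_index=True)
    table.insert(0, "drug", drug)
    return table


def outcome_distribution(dataset: AnalysisDataset, drug: str,
                         denominator: str = "mentions") -> pd.DataFrame:
    """Outcome-code counts for one drug.

    A report with several distinct codes counts once per code.  The percent
    denominator is the total number of outcome mentions by default, or the
    drug's report count with ``denominator="reports"`` (both views are
    legitimate; pick one and say so).
    """
    if denominator not in ("mentions", "reports"):
        raise ParameterError("denominator must be 'mentions' or 'reports'")
    ids = set(dataset.report_ids(drug))
    outc = dataset.outcomes[dataset.outcomes["primaryid"].isin(ids)]
    if outc.empty:
        return pd.DataFrame(columns=["drug", "outcome_code", "outcome", "count", "percent"])
    counts = outc["outcome_code"].value_counts()
    denom = int(counts.sum()) if denominator == "mentions" else len(ids)
    rows = [{"drug": drug, "outcome_code": code, "outcome": OUTCOME_LABELS.get(code, code),
             "count": int(cnt), "percent": percent(int(cnt), denom)}
            for code, cnt in counts.sort_index().items()]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeathCauseRank:
    pt: str
    death_report_count: int
    rank: int


def death_cause_ranking(dataset: AnalysisDataset, drug: str,
                        top_n: int = 10) -> list[DeathCauseRank]:
    """Top PTs among the drug's reports with a death (DE) outcome.

    Counts deduplicated reports per retained PT; ranking is by count
    descending with ties broken alphabetically.
    """
    if top_n <= 0:
        raise ParameterError("top_n must be positive")
    ids = set(dataset.report_ids(drug))
    dead = set(dataset.outcomes.loc[dataset.outcomes["outcome_code"] == "DE",
                                    "primaryid"]) & ids
    pts = dataset.reactions[dataset.reactions["primaryid"].isin(dead)]
    counts = pts["pt"].value_counts()
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return [DeathCauseRank(pt, int(cnt), i + 1) for i, (pt, cnt) in enumerate(ordered)]


def death_demographics(dataset: AnalysisDataset, pts: list[str],
                       per_drug: bool = False) -> pd.DataFrame:
    """Sex and coarse-age strata of death reports mentioning each PT.

    By default the study drugs are pooled into one table per PT (set
    ``per_drug=True`` for a per-drug breakdown); the percent denominator is
    that PT's death-report total.
    """
    dead = set(dataset.outcomes.loc[dataset.outcomes["outcome_code"] == "DE",
                                    "primaryid"])
    study = set()
    for drug in dataset.drugs:
        study |= set(dataset.report_ids(drug))
    groups = dataset.drugs if per_drug else (None,)
    parts = []
    for pt in pts:
        with_pt = set(dataset.reactions.loc[dataset.reactions["pt"] == pt, "primaryid"])
        for drug in groups:
            pool = study if drug is None else set(dataset.report_ids(drug))
            ids = dead & with_pt & pool
            demo = dataset.demo[dataset.demo["primaryid"].isin(ids)]
            n = len(demo)
            if n == 0:
                continue
            sex = demo["sex"].map({"F": "Female", "M": "Male"}).fillna("Unknown")
            sexes = _stratum_frame(sex, ["Female", "Male", "Unknown"], n, "Sex")
            age = _bucket_age(demo["age_years"], AGE_BUCKETS_COARSE)
            order = [b[2] for b in AGE_BUCKETS_COARSE] + ["Unknown"]
            ages = _stratum_frame(age, order, n, "Age (year)")
            block = pd.concat([sexes, ages], ignore_index=True)
            block.insert(0, "pt", pt)
            block.insert(0, "drug", drug if drug else "ALL")
            parts.append(block)
    if not parts:
        return pd.DataFrame(columns=["drug", "pt", "category", "stratum", "count", "percent"])
    return pd.concat(parts, ignore_index=True)


def yearly_trend(dataset: AnalysisDataset, drug: str) -> pd.DataFrame:
    """Per-calendar-year report counts and shares of the drug's total.

    Years between the first and last observed year are always present, with
    zero counts where nothing was reported.
    """
    ids = dataset.report_ids(drug)
    demo = dataset.demo[dataset.demo["primaryid"].isin(set(ids))]
    years = demo["event_year"].dropna().astype(int)
    total = len(demo)
    if years.empty:
        return pd.DataFrame(columns=["drug", "year", "count", "percent"])
    counts = years.value_counts()
    span = range(int(years.min()), int(years.max()) + 1)
    rows = [{"drug": drug, "year": y, "count": int(counts.get(y, 0)),
             "percent": percent(int(counts.get(y, 0)), total)}
            for y in span]
    return pd.DataFrame(rows)


def format_table(frame: pd.DataFrame) -> str:
    """Aligned plain-text rendering used by the CLI."""
    return frame.to_string(index=False)
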