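"""Deduplication, drug-name matching and filtering into the analysis dataset.

Spontaneous-reporting extracts carry the same case many times: literal
duplicate rows, and successive versions of one case sharing a ``CASEID``.
The cleaning procedure is the standard two-step recommendation: drop exact
duplicate rows, then keep only the latest version of each case.  The study
population is then restricted to reports in which a study drug was coded as
the *primary suspect* (role ``PS``); reports whose only study-drug record is
secondary suspect, concomitant or interacting are excluded.  Finally,
preferred terms naming the treated disease or its complications (indication
bias) are removed before any counting.

Every stage logs its in/out record counts in a :class:`FilterLedger`, so a
run is auditable end to end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DictionaryError
from .faers_io import QuarterBundle, concat_bundles, normalize_pt
from .meddra import UNMAPPED, PtSocMap, map_pt

# ---------------------------------------------------------------------------
# drug dictionary


def _normalize_term(term: str) -> str:
    return " ".join(str(term).split()).casefold()


@dataclass(frozen=True)
class DrugDictionary:
    """Verbatim-name -> canonical-drug dictionary.

    ``matching_mode`` is either ``"exact_normalized"`` (full-string equality
    after case-folding and whitespace trimming) or ``"substring"`` (the term
    must occur as a word-bounded substring of the verbatim name, catching
    strings like ``"THALOMID 50MG CAPSULE"``).
    """

    entries: Mapping[str, frozenset[str]]
    matching_mode: str = "substring"

    def __post_init__(self) -> None:
        if self.matching_mode not in ("exact_normalized", "substring"):
            raise ConfigurationError(f"unknown matching mode {self.matching_mode!r}")
        seen: dict[str, str] = {}
        norm: dict[str, frozenset[str]] = {}
        for drug, terms in self.entries.items():
            terms = frozenset(_normalize_term(t) for t in terms)
            norm[drug] = terms
            for t in terms:
                if t in seen and seen[t] != drug:
                    raise DictionaryError(
                        f"term {t!r} maps to both {seen[t]} and {drug}")
                seen[t] = drug
        object.__setattr__(self, "entries", norm)
        object.__setattr__(self, "_term_to_drug", seen)
        patterns = {t: re.compile(r"(?<!\w)" + re.escape(t) + r"(?!\w)")
                    for t in seen}
        object.__setattr__(self, "_patterns", patterns)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def match(self, verbatim: str) -> str | None:
        """Canonical drug for a verbatim name, or ``None``."""
        name = _normalize_term(verbatim)
        if self.matching_mode == "exact_normalized":
            return self._term_to_drug.get(name)
        hits = {self._term_to_drug[t] for t, pat in self._patterns.items()
                if pat.search(name)}
        if len(hits) > 1:
            raise ConfigurationError(
                f"verbatim name {verbatim!r} matches several drugs: {sorted(hits)}")
        return next(iter(hits)) if hits else None


#: The study drugs and the verbatim trade/generic names that identify them.
IMID_DICTIONARY_TERMS: dict[str, tuple[str, ...]] = {
    "THALIDOMIDE": ("Thalomid", "Thalidomide", "Distaval", "Contergan"),
    "LENALIDOMIDE": ("Revlimid", "Lenalidomide"),
    "POMALIDOMIDE": ("Pomalidomide", "Pomalyst"),
}


def default_drug_dictionary(matching_mode: str = "substring") -> DrugDictionary:
    return DrugDictionary({d: frozenset(t) for d, t in IMID_DICTIONARY_TERMS.items()},
                          matching_mode=matching_mode)


def match_drug(verbatim: str, dictionary: DrugDictionary) -> str | None:
    return dictionary.match(verbatim)


def load_drug_dictionary(path: str | Path,
                         matching_mode: str = "substring") -> DrugDictionary:
    """Load a 2-column (canonical TAB verbatim-term) dictionary file."""
    path = Path(path)
    if not path.exists():
        raise DictionaryError(f"drug dictionary not found: {path}")
    entries: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DictionaryError(f"{path}:{lineno}: expected 'CANONICAL<TAB>term'")
        entries.setdefault(parts[0].strip().upper(), set()).add(parts[1])
    return DrugDictionary({d: frozenset(t) for d, t in entries.items()},
                          matching_mode=matching_mode)


def write_drug_dictionary(dictionary: DrugDictionary, path: str | Path) -> None:
    lines = ["# canonical drug\tverbatim term"]
    for drug in dictionary.drugs:
        for term in sorted(dictionary.entries[drug]):
            lines.append(f"{drug}\t{term}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# exclusion list

#: Illustrative default indication/complication terms for multiple myeloma.
#: The list is an editable input, not an assertion about any licensed
#: terminology.
DEFAULT_EXCLUSION_PTS: tuple[str, ...] = (
    "MULTIPLE MYELOMA",
    "PLASMA CELL MYELOMA",
    "PLASMACYTOMA",
    "MULTIPLE MYELOMA PROGRESSION",
    "BONE PAIN",
    "PATHOLOGICAL FRACTURE",
    "HYPERCALCAEMIA OF MALIGNANCY",
    "MYELOMA CAST NEPHROPATHY",
)


def load_exclusion_list(path: str | Path) -> frozenset[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(normalize_pt(l) for l in lines
                     if l.strip() and not l.strip().startswith("#"))


def write_exclusion_list(pts: Iterable[str], path: str | Path) -> None:
    body = "\n".join(sorted(normalize_pt(p) for p in pts))
    Path(path).write_text("# excluded indication/complication PTs\n" + body + "\n",
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# ledger


@dataclass
class LedgerStage:
    name: str
    unit: str           # "demo_rows", "reports" or "report_pt_pairs"
    records_in: int
    records_out: int


@dataclass
class FilterLedger:
    """Per-stage (in, out) record counts of the cleaning pipeline."""

    stages: list[LedgerStage] = field(default_factory=list)

    def add(self, name: str, unit: str, records_in: int, records_out: int) -> None:
        if records_out > records_in:
            raise ValueError(f"stage {name}: out {records_out} > in {records_in}")
        self.stages.append(LedgerStage(name, unit, int(records_in), int(records_out)))

    def __getitem__(self, name: str) -> LedgerStage:
        for stage in self.stages:
            if stage.name == name:
                return stage
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stages])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stage operations


def drop_duplicate_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact-duplicate rows, keeping first occurrence order."""
    return frame.drop_duplicates(keep="first").reset_index(drop=True)


def _version_sort_key(demo: pd.DataFrame) -> pd.DataFrame:
    key = demo[["caseid", "case_version", "fda_date", "primaryid"]].copy()
    # a missing date loses against any present date
    key["fda_date"] = key["fda_date"].fillna(pd.Timestamp.min)
    # numeric primaryid comparison when possible, else lexicographic
    pid_num = pd.to_numeric(key["primaryid"], errors="coerce")
    key["pid_key"] = pid_num if pid_num.notna().all() else key["primaryid"]
    return key


def keep_latest_case_version(demo: pd.DataFrame) -> pd.DataFrame:
    """One record per case: maximal (case_version, fda_date, primaryid).

    The tuple comparison makes the survivor deterministic even when a case
    carries duplicate version numbers.
    """
    if demo.empty:
        return demo.reset_index(drop=True)
    key = _version_sort_key(demo)
    order = key.sort_values(["caseid", "case_version", "fda_date", "pid_key"],
                            kind="mergesort")
    keep_idx = order.drop_duplicates("caseid", keep="last").index
    return demo.loc[demo.index.isin(keep_idx)].reset_index(drop=True)


def match_drug_table(drug: pd.DataFrame, dictionary: DrugDictionary) -> pd.DataFrame:
    """Annotate a DRUG table with canonical matches (distinct verbatim names
    are matched once and broadcast)."""
    uniq = drug["verbatim_name"].drop_duplicates()
    lookup = {name: dictionary.match(name) for name in uniq}
    out = drug.copy()
    out["canonical_drug"] = drug["verbatim_name"].map(lookup)
    return out


# ---------------------------------------------------------------------------
# the analysis dataset


@dataclass
class AnalysisDataset:
    """The cleaned study dataset plus its full-database background.

    ``demo`` holds one row per deduplicated report across *all* drugs — the
    background against which disproportionality is computed.  ``ps_drugs``
    links reports to the canonical study drugs they name as primary suspect;
    reports without such a link are background only.  ``reactions`` holds
    distinct (report, PT) pairs after indication-PT exclusion, annotated
    with the PT's primary SOC.
    """

    demo: pd.DataFrame           # primaryid, caseid, sex, age_years, ..., event_year
    ps_drugs: pd.DataFrame       # primaryid, canonical_drug (distinct pairs)
    reactions: pd.DataFrame      # primaryid, pt, soc (distinct (primaryid, pt))
    outcomes: pd.DataFrame       # primaryid, outcome_code (distinct pairs)
    exclusion: frozenset[str]
    ledger: FilterLedger
    n_unmapped_pts: int = 0

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self.ps_drugs["canonical_drug"].unique()))

    def report_ids(self, drug: str | None = None) -> pd.Index:
        """Deduplicated report ids, optionally restricted to one study drug."""
        if drug is None:
            return pd.Index(self.demo["primaryid"])
        sel = self.ps_drugs.loc[self.ps_drugs["canonical_drug"] == drug, "primaryid"]
        return pd.Index(sel.unique())

    def n_reports(self, drug: str | None = None) -> int:
        return len(self.report_ids(drug))

    def pairs(self, level: str = "PT") -> pd.DataFrame:
        """Distinct (report, event) pairs at PT or SOC level.

        At SOC level a report with several PTs in one organ class counts
        once for that class, and unmapped PTs contribute nothing.
        """
        if level == "PT":
            return self.reactions[["primaryid", "pt"]].rename(columns={"pt": "event"})
        if level == "SOC":
            soc = self.reactions.loc[self.reactions["soc"] != UNMAPPED,
                                     ["primaryid", "soc"]]
            return soc.drop_duplicates().rename(columns={"soc": "event"}).reset_index(drop=True)
        raise ValueError(f"unknown level {level!r}")


def build_dataset(bundles: Sequence[QuarterBundle],
                  dictionary: DrugDictionary,
                  exclusion: Iterable[str],
                  pt_soc: PtSocMap) -> tuple[AnalysisDataset, FilterLedger]:
    """Run the fixed cleaning pipeline over loaded quarters.

    Stage order: exact-duplicate-row removal -> latest case version ->
    primary-suspect drug matching -> PT exclusion -> SOC annotation.
    Background reports (no PS study drug) stay in the dataset so 2x2
    tables can use the whole database as comparator; reports with zero
    retained PTs also stay, for demographic and outcome counting.
    """
    if not dictionary.entries:
        raise ConfigurationError("drug dictionary is empty")
    exclusion = frozenset(normalize_pt(p) for p in exclusion)
    tables = concat_bundles(bundles)
    ledger = FilterLedger()

    # 1. exact duplicate rows (each table)
    raw_demo = tables["demo"]
    demo = drop_duplicate_rows(raw_demo)
    ledger.add("raw_rows", "demo_rows", len(raw_demo), len(raw_demo))
    ledger.add("unique_rows", "demo_rows", len(raw_demo), len(demo))
    drug = drop_duplicate_rows(tables["drug"])
    reac = drop_duplicate_rows(tables["reac"])
    outc = drop_duplicate_rows(tables["outc"])

    # 2. latest case version; drop companion rows of discarded versions
    demo = keep_latest_case_version(demo)
    kept = set(demo["primaryid"])
    ledger.add("latest_case_version", "reports", ledger["unique_rows"].records_out,
               len(demo))
    drug = drug[drug["primaryid"].isin(kept)].reset_index(drop=True)
    reac = reac[reac["primaryid"].isin(kept)].reset_index(drop=True)
    outc = outc[outc["primaryid"].isin(kept)].reset_index(drop=True)

    # 3. primary-suspect matching
    matched = match_drug_table(drug, dictionary)
    ps = matched[(matched["role_code"] == "PS") & matched["canonical_drug"].notna()]
    ps_drugs = (ps[["primaryid", "canonical_drug"]]
                .drop_duplicates()
                .reset_index(drop=True))
    ledger.add("ps_drug_match", "reports", len(demo),
               ps_drugs["primaryid"].nunique())

    # 4. PT exclusion (applied uniformly, background included)
    pairs_in = len(reac)
    reac = reac[~reac["pt"].isin(exclusion)].reset_index(drop=True)
    ledger.add("pt_exclusion", "report_pt_pairs", pairs_in, len(reac))

    # 5. SOC annotation
    soc_lookup = {pt: map_pt(pt, pt_soc) for pt in reac["pt"].unique()}
    reactions = reac[["primaryid", "pt"]].copy()
    reactions["soc"] = reac["pt"].map(soc_lookup)
    n_unmapped = int((reactions["soc"] == UNMAPPED).sum())

    dataset = AnalysisDataset(
        demo=demo,
        ps_drugs=ps_drugs,
        reactions=reactions,
        outcomes=outc[["primaryid", "outcome_code"]].reset_index(drop=True),
        exclusion=exclusion,
        ledger=ledger,
        n_unmapped_pts=n_unmapped,
    )
    return dataset, ledger
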