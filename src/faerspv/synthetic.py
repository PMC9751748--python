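"""Ground-truth synthetic generator for FAERS-dialect report data.

The generator emulates the statistical structure of a spontaneous-reporting
extract — duplicate case versions sharing a CASEID, literal duplicate rows,
multi-PT reports, primary-suspect vs. concomitant drug roles, demographic
strata, serious-outcome codes with PT-conditional death excess, report
dates spanning years — and, crucially, *injected drug-event associations*
with a configurable relative reporting rate ``r``.  Alongside the data it
writes a :class:`TruthManifest` of the counts every pipeline stage should
recover, so cleaning, mapping and signal detection are all testable with no
external download.

Sampling model
--------------
Each case draws one suspect drug (a study drug or a background drug), then
a preferred-term set: the number of draws is truncated-geometric and each
draw picks a term with probability proportional to its weight
``base_rate(p) * r(D, p)`` (``r = 1`` unless injected), duplicates within a
report collapsing to one mention.  Because the 2x2 statistics are ratios of within-margin odds,
this construction makes the population reporting odds ratio of an injected
pair equal ``r`` whenever it is the drug's only injected association, which
is what the recovery and CI-coverage tests exploit.  Indication terms
(the treated disease reported as an event) receive extra weight under study
drugs only; they are listed in the emitted exclusion file and vanish before
any counting, which is exactly the bias the exclusion step exists to remove.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .faers_io import QuarterBundle, make_bundle, write_quarter
from .meddra import PtSocMap, build_pt_soc_map, write_pt_soc_map
from .preprocess import (DrugDictionary, IMID_DICTIONARY_TERMS,
                         write_drug_dictionary, write_exclusion_list)

# ---------------------------------------------------------------------------
# configuration defaults

#: Marginal probability that a case's suspect drug is each study drug.
DEFAULT_DRUG_PROBS = {"THALIDOMIDE": 0.010, "LENALIDOMIDE": 0.080,
                      "POMALIDOMIDE": 0.030}

DEFAULT_BACKGROUND_DRUGS = ("METFORMIN", "ASPIRIN", "ATORVASTATIN",
                            "LISINOPRIL", "OMEPRAZOLE", "AMLODIPINE")

_COMMON_PTS = {
    "PNEUMONIA": 0.020, "DIARRHOEA": 0.020, "FATIGUE": 0.020, "NAUSEA": 0.015,
    "DYSPNOEA": 0.012, "SEPSIS": 0.010, "PYREXIA": 0.010, "ANAEMIA": 0.010,
    "RASH": 0.010, "DIZZINESS": 0.010, "CONSTIPATION": 0.010, "VOMITING": 0.010,
    "ASTHENIA": 0.010, "RENAL FAILURE": 0.008, "NEUTROPENIA": 0.008,
    "THROMBOCYTOPENIA": 0.008, "OEDEMA PERIPHERAL": 0.008,
    "PERIPHERAL NEUROPATHY": 0.006, "DEEP VEIN THROMBOSIS": 0.006,
    "PULMONARY EMBOLISM": 0.005,
}


def default_background_pts(n_rare: int = 230, rare_rate: float = 0.002) -> dict[str, float]:
    """The default PT vocabulary: 20 named common terms plus generic rare ones."""
    pts = dict(_COMMON_PTS)
    for i in range(1, n_rare + 1):
        pts[f"PT_{i:04d}"] = rare_rate
    return pts


#: Indication/complication terms (excluded downstream) and their base weight.
DEFAULT_INDICATION_PTS = {"MULTIPLE MYELOMA": 0.010, "BONE PAIN": 0.006,
                          "PLASMA CELL MYELOMA": 0.003}

#: Default injected associations: (drug, pt, relative reporting rate r).
DEFAULT_ASSOCIATIONS = (
    ("THALIDOMIDE", "PERIPHERAL NEUROPATHY", 8.0),
    ("THALIDOMIDE", "DEEP VEIN THROMBOSIS", 5.0),
    ("LENALIDOMIDE", "DIARRHOEA", 3.0),
    ("POMALIDOMIDE", "PNEUMONIA", 2.0),
)

DEFAULT_SEX_PROBS = {"F": 0.47, "M": 0.50, "UNK": 0.03}
DEFAULT_AGE_BUCKET_PROBS = {"<18": 0.01, "18-44": 0.02, "45-64": 0.15,
                            "65-74": 0.18, ">=75": 0.17, "UNK": 0.47}
_AGE_RANGES = {"<18": (1, 17), "18-44": (18, 44), "45-64": (45, 64),
               "65-74": (65, 74), ">=75": (75, 95)}
DEFAULT_REPORTER_PROBS = {"CN": 0.06, "MD": 0.21, "OT": 0.25, "PH": 0.38,
                          "LW": 0.08, "UNK": 0.02}
DEFAULT_COUNTRY_PROBS = {"US": 0.90, "JP": 0.02, "CA": 0.01, "GB": 0.02,
                         "FR": 0.02, "DE": 0.03}
DEFAULT_OUTCOME_PROBS = {"DE": 0.13, "LT": 0.03, "HO": 0.27, "DS": 0.02,
                         "CA": 0.005, "RI": 0.01, "OT": 0.40}
#: Death probability when the report carries one of these PTs.
DEFAULT_DEATH_PT_BOOST = {"PNEUMONIA": 0.45, "SEPSIS": 0.50}

DEFAULT_YEAR_WEIGHTS = {2013: 0.06, 2014: 0.07, 2015: 0.08, 2016: 0.10,
                        2017: 0.11, 2018: 0.12, 2019: 0.13, 2020: 0.15,
                        2021: 0.18}

#: Synthetic organ classes used by :func:`make_pt_soc_map`.
_SOC_NAMES = (
    "Infections and infestations",
    "Cardiac disorders",
    "Gastrointestinal disorders",
    "Vascular disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Blood and lymphatic system disorders",
    "Nervous system disorders",
    "Renal and urinary disorders",
    "Skin and subcutaneous tissue disorders",
    "General disorders and administration site conditions",
    "Investigations",
    "Musculoskeletal and connective tissue disorders",
    "Metabolism and nutrition disorders",
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Psychiatric disorders",
)

_NAMED_PT_SOC = {
    "PNEUMONIA": "Infections and infestations",
    "SEPSIS": "Infections and infestations",
    "DIARRHOEA": "Gastrointestinal disorders",
    "NAUSEA": "Gastrointestinal disorders",
    "VOMITING": "Gastrointestinal disorders",
    "CONSTIPATION": "Gastrointestinal disorders",
    "FATIGUE": "General disorders and administration site conditions",
    "ASTHENIA": "General disorders and administration site conditions",
    "PYREXIA": "General disorders and administration site conditions",
    "OEDEMA PERIPHERAL": "General disorders and administration site conditions",
    "DYSPNOEA": "Respiratory, thoracic and mediastinal disorders",
    "ANAEMIA": "Blood and lymphatic system disorders",
    "NEUTROPENIA": "Blood and lymphatic system disorders",
    "THROMBOCYTOPENIA": "Blood and lymphatic system disorders",
    "RASH": "Skin and subcutaneous tissue disorders",
    "DIZZINESS": "Nervous system disorders",
    "PERIPHERAL NEUROPATHY": "Nervous system disorders",
    "RENAL FAILURE": "Renal and urinary disorders",
    "DEEP VEIN THROMBOSIS": "Vascular disorders",
    "PULMONARY EMBOLISM": "Vascular disorders",
    "MULTIPLE MYELOMA":
        "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "PLASMA CELL MYELOMA":
        "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "BONE PAIN": "Musculoskeletal and connective tissue disorders",
}

_NAME_SUFFIXES = (" 25MG", " 50MG CAPSULE", " 100 MG", " TABLETS")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic report generator.

    The defaults are the package's reference study conditions; tests and the
    acceptance experiments derive narrower configs from them (e.g. a single
    injected association for CI-coverage runs).
    """

    n_cases: int = 5000
    seed: int = 0
    drug_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUG_PROBS))
    drug_variants: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(IMID_DICTIONARY_TERMS))
    background_drugs: tuple[str, ...] = DEFAULT_BACKGROUND_DRUGS
    name_suffix_prob: float = 0.30
    ps_concomitant_prob: float = 0.10    # study drug coded C instead of PS
    extra_concomitant_prob: float = 0.30  # add an unrelated concomitant row
    background_pts: dict[str, float] = field(default_factory=default_background_pts)
    indication_pts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDICATION_PTS))
    indication_bias: float = 5.0          # indication-PT weight multiplier, study drugs
    associations: tuple[tuple[str, str, float], ...] = DEFAULT_ASSOCIATIONS
    pts_per_report_mean: float = 2.1
    max_pts_per_report: int = 8
    sex_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    age_bucket_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BUCKET_PROBS))
    month_age_unit_prob: float = 0.02
    reporter_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPORTER_PROBS))
    country_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_PROBS))
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    death_pt_boost: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEATH_PT_BOOST))
    year_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_YEAR_WEIGHTS))
    partial_date_prob: float = 0.005
    duplicate_version_prob: float = 0.08
    max_versions: int = 3
    duplicate_row_prob: float = 0.01

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        probs = [self.name_suffix_prob, self.ps_concomitant_prob,
                 self.extra_concomitant_prob, self.partial_date_prob,
                 self.duplicate_version_prob, self.duplicate_row_prob,
                 self.month_age_unit_prob,
                 *self.outcome_probs.values(), *self.death_pt_boost.values()]
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if sum(self.drug_probs.values()) > 1.0 + 1e-9:
            raise ConfigurationError("study-drug marginal probabilities exceed 1")
        for dist_name in ("sex_probs", "age_bucket_probs", "reporter_probs",
                          "country_probs", "year_weights"):
            dist = getattr(self, dist_name)
            total = sum(dist.values())
            if total <= 0 or any(v < 0 for v in dist.values()):
                raise ConfigurationError(f"{dist_name} must be non-negative with positive sum")
        for drug, pt, r in self.associations:
            if r < 1:
                raise ConfigurationError(f"association ({drug}, {pt}): r must be >= 1")
            if drug not in self.drug_probs:
                raise ConfigurationError(f"association names unknown drug {drug!r}")
            if pt not in self.background_pts:
                raise ConfigurationError(f"association names unknown PT {pt!r}")
        if self.pts_per_report_mean < 1:
            raise ConfigurationError("pts_per_report_mean must be >= 1")
        if not (1 <= self.max_pts_per_report <= len(self.background_pts)):
            raise ConfigurationError("max_pts_per_report out of range")
        if self.max_versions < 2:
            raise ConfigurationError("max_versions must be >= 2")


# ---------------------------------------------------------------------------
# truth manifest


@dataclass
class TruthManifest:
    """What the generator actually injected, for stage-by-stage recovery tests."""

    seed: int
    n_cases: int
    raw_rows: dict[str, int]
    unique_rows: dict[str, int]
    kept_primaryids: list[str]
    n_ps_reports: int
    ps_reports_per_drug: dict[str, int]
    pairs_before_exclusion: int
    pairs_after_exclusion: int
    pair_counts: dict[str, dict[str, int]]       # drug -> pt -> a
    death_pt_counts: dict[str, dict[str, int]]   # drug -> pt -> death reports
    year_counts: dict[str, dict[str, int]]       # drug -> year -> reports
    outcome_counts: dict[str, dict[str, int]]    # drug -> code -> mentions
    sex_counts: dict[str, dict[str, int]]        # drug -> sex -> reports
    associations: list[list]                     # [drug, pt, r]
    exclusion_pts: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class GeneratedData:
    """Everything one generator run produces."""

    bundles: list[QuarterBundle]
    manifest: TruthManifest
    drug_dictionary: DrugDictionary
    pt_soc_map: PtSocMap
    exclusion_pts: frozenset[str]

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Emit quarter files, dictionaries, exclusion list and manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for bundle in self.bundles:
            write_quarter(bundle, directory)
        paths = {
            "drug_dictionary": directory / "drug_dictionary.tsv",
            "pt_soc_map": directory / "pt_soc_map.txt",
            "exclusion": directory / "pt_exclusions.txt",
            "manifest": directory / "truth_manifest.json",
        }
        write_drug_dictionary(self.drug_dictionary, paths["drug_dictionary"])
        write_pt_soc_map(self.pt_soc_map, paths["pt_soc_map"])
        write_exclusion_list(self.exclusion_pts, paths["exclusion"])
        self.manifest.to_json(paths["manifest"])
        return paths


def make_pt_soc_map(pts: list[str]) -> PtSocMap:
    """Complete synthetic PT->SOC dictionary over the generated vocabulary.

    Named clinical terms get their natural organ class; generic rare terms
    are assigned round-robin.  A couple of terms carry secondary SOCs so the
    multiaxiality path is exercised.
    """
    rows = []
    for i, pt in enumerate(sorted(pts)):
        primary = _NAMED_PT_SOC.get(pt, _SOC_NAMES[i % len(_SOC_NAMES)])
        secondary = []
        if pt == "PNEUMONIA":
            secondary = ["Respiratory, thoracic and mediastinal disorders"]
        elif pt == "DEEP VEIN THROMBOSIS":
            secondary = ["Cardiac disorders"]
        rows.append((pt, primary, secondary))
    return build_pt_soc_map(rows, version_label="synthetic")


def _truncated_geometric(rng: np.random.Generator, mean: float, max_k: int,
                         size: int) -> np.ndarray:
    """Geometric on {1, 2, ...} with nominal mean, truncated at ``max_k``."""
    p = min(1.0, 1.0 / mean)
    u = rng.random(size)
    k = np.floor(np.log1p(-u) / np.log1p(-p)).astype(np.int64) + 1
    return np.clip(k, 1, max_k)


def _choice(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    keys = np.array(list(dist.keys()), dtype=object)
    w = np.array(list(dist.values()), dtype=float)
    return keys[rng.choice(len(keys), size=size, p=w / w.sum())]


# ---------------------------------------------------------------------------
# the generator


def _demo_frame(primaryid, caseid, case_version, fda_dt, fda_date, partial,
                sex, age_value, age_unit, age_years, reporter, country):
    """Assemble a typed DEMO frame with the same schema parse_demo emits."""
    out = pd.DataFrame({
        "primaryid": pd.Series(primaryid, dtype=object),
        "caseid": pd.Series(caseid, dtype=object),
        "case_version": pd.Series(case_version, dtype=np.int64),
        "fda_dt": pd.Series(fda_dt, dtype=object),
        "fda_date": pd.Series(fda_date, dtype="datetime64[ns]"),
        "date_partial": pd.Series(partial, dtype=bool),
    })
    out["event_year"] = pd.Series(out["fda_date"].dt.year, dtype="Int64")
    out["sex"] = pd.Series(sex, dtype=object)
    out["age_value"] = pd.Series(age_value, dtype=float)
    out["age_unit"] = pd.Series(age_unit, dtype=object)
    out["age_years"] = pd.Series(age_years, dtype=float)
    out["reporter_occupation"] = pd.Series(reporter, dtype=object)
    out["country"] = pd.Series(country, dtype=object)
    return out


def generate(config: GeneratorConfig | None = None) -> GeneratedData:
    """Draw one synthetic study and its ground-truth manifest.

    Deterministic given ``config.seed``: two runs with the same config emit
    byte-identical files.  The generator assembles the typed per-quarter
    tables directly (all per-case draws vectorised); the round-trip tests
    pin their equivalence to what reading the written files produces, so a
    replicated experiment can skip the file layer without changing results.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases

    # --- drug assignment -------------------------------------------------
    study = list(cfg.drug_probs)
    p_study = np.array([cfg.drug_probs[d] for d in study])
    p_bg = (1.0 - p_study.sum()) / len(cfg.background_drugs)
    drug_pool = study + list(cfg.background_drugs)
    p_drug = np.concatenate([p_study, np.full(len(cfg.background_drugs), p_bg)])
    drug_idx = rng.choice(len(drug_pool), size=n, p=p_drug / p_drug.sum())
    is_study = drug_idx < len(study)

    verbatim = np.empty(n, dtype=object)
    for j, drug in enumerate(drug_pool):
        mask = drug_idx == j
        m = int(mask.sum())
        if not m:
            continue
        if j < len(study):
            variants = np.array(cfg.drug_variants[drug], dtype=object)
            verbatim[mask] = variants[rng.integers(0, len(variants), size=m)]
        else:
            verbatim[mask] = drug
    suffix_mask = rng.random(n) < cfg.name_suffix_prob
    suffixes = np.array(_NAME_SUFFIXES, dtype=object)[
        rng.integers(0, len(_NAME_SUFFIXES), size=n)]
    verbatim = np.where(suffix_mask, verbatim + suffixes, verbatim)
    role = np.where(is_study & (rng.random(n) < cfg.ps_concomitant_prob),
                    "C", "PS").astype(object)
    extra_conc = rng.random(n) < cfg.extra_concomitant_prob
    conc_names = _choice(rng, {d: 1.0 for d in cfg.background_drugs}, n)

    # --- demographics, dates ---------------------------------------------
    sex = _choice(rng, cfg.sex_probs, n)
    bucket = _choice(rng, cfg.age_bucket_probs, n)
    age_years = np.full(n, np.nan)
    for lab, (lo, hi) in _AGE_RANGES.items():
        mask = bucket == lab
        if mask.any():
            age_years[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    mon_unit = (rng.random(n) < cfg.month_age_unit_prob) & ~np.isnan(age_years)
    age_value = age_years.copy()
    age_unit = np.where(np.isnan(age_years), "UNK", "YR").astype(object)
    age_value[mon_unit] = np.round(age_years[mon_unit] * 12.0)
    age_unit[mon_unit] = "MON"
    age_years = age_value * np.where(age_unit == "MON", 1.0 / 12.0, 1.0)
    reporter = _choice(rng, cfg.reporter_probs, n)
    country = _choice(rng, cfg.country_probs, n)

    year = _choice(rng, {str(y): w for y, w in cfg.year_weights.items()}, n).astype(int)
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 29, size=n)
    partial = rng.random(n) < cfg.partial_date_prob
    day_eff = np.where(partial, 1, day)  # partial dates impute day 01
    date_str = np.where(partial,
                        (year * 100 + month).astype(str),
                        (year * 10000 + month * 100 + day).astype(str)).astype(object)
    fda_date = pd.to_datetime(
        pd.DataFrame({"year": year, "month": month, "day": day_eff}))
    quarter = np.char.add(np.char.add(year.astype(str), "Q"),
                          ((month - 1) // 3 + 1).astype(str)).astype(object)

    # --- preferred terms ---------------------------------------------------
    pool = list(cfg.background_pts) + list(cfg.indication_pts)
    base_w = np.array([cfg.background_pts.get(p) or cfg.indication_pts[p]
                       for p in pool])
    pt_index = {p: i for i, p in enumerate(pool)}
    assoc_by_drug: dict[str, dict[str, float]] = {}
    for drug, pt, r in cfg.associations:
        assoc_by_drug.setdefault(drug, {})[pt] = r

    k_pts = _truncated_geometric(rng, cfg.pts_per_report_mean,
                                 cfg.max_pts_per_report, n)
    max_k = cfg.max_pts_per_report
    flat_case_parts, flat_pt_parts = [], []
    # weight groups: one per study drug, one shared background group
    groups = [(drug, drug_idx == j) for j, drug in enumerate(study)]
    groups.append(("__background__", ~is_study))
    for gdrug, mask in groups:
        m = int(mask.sum())
        if not m:
            continue
        w = base_w.copy()
        if gdrug != "__background__":
            for pt, r in assoc_by_drug.get(gdrug, {}).items():
                w[pt_index[pt]] *= r
            for pt in cfg.indication_pts:
                w[pt_index[pt]] *= cfg.indication_bias
        # k_i weighted draws with replacement, duplicates collapsed: at the
        # small per-term rates used here this is the same multi-PT model as
        # sequential sampling without replacement, and far cheaper
        ks = k_pts[mask]
        draws = rng.choice(len(pool), size=(m, max_k), p=w / w.sum())
        draws = np.where(np.arange(max_k)[None, :] < ks[:, None], draws, -1)
        draws.sort(axis=1)
        first = np.ones_like(draws, dtype=bool)
        first[:, 1:] = draws[:, 1:] != draws[:, :-1]
        keep = first & (draws >= 0)
        rows = np.nonzero(mask)[0]
        flat_case_parts.append(rows[np.nonzero(keep)[0]])
        flat_pt_parts.append(draws[keep])
    flat_case = np.concatenate(flat_case_parts)
    flat_pt = np.concatenate(flat_pt_parts)
    order = np.argsort(flat_case, kind="stable")
    flat_case, flat_pt = flat_case[order], flat_pt[order]
    case_starts = np.searchsorted(flat_case, np.arange(n))
    case_ends = np.searchsorted(flat_case, np.arange(n), side="right")
    pool_arr = np.array(pool, dtype=object)

    # --- outcomes ----------------------------------------------------------
    de_prob = np.full(n, cfg.outcome_probs.get("DE", 0.0))
    for pt, boost in cfg.death_pt_boost.items():
        if pt not in pt_index:
            continue
        has = np.zeros(n, dtype=bool)
        has[flat_case[flat_pt == pt_index[pt]]] = True
        de_prob = np.where(has, np.maximum(de_prob, boost), de_prob)
    codes = list(cfg.outcome_probs)
    u_out = rng.random((n, len(codes)))
    p_out = np.array([cfg.outcome_probs[c] for c in codes])[None, :]
    hit = u_out < p_out
    if "DE" in codes:
        de_col = codes.index("DE")
        hit[:, de_col] = u_out[:, de_col] < de_prob

    # --- duplicate case versions ------------------------------------------
    caseid_num = 10_000_000 + np.arange(n, dtype=np.int64)
    dup_mask = rng.random(n) < cfg.duplicate_version_prob
    n_versions = np.where(dup_mask,
                          rng.integers(2, cfg.max_versions + 1, size=n), 1)
    caseid_str = caseid_num.astype(str).astype(object)
    final_pid = (caseid_num * 10 + n_versions).astype(str).astype(object)

    # final-version rows, fully vectorised
    demo_f = _demo_frame(final_pid, caseid_str, n_versions, date_str, fda_date,
                         partial, sex, age_value, age_unit, age_years,
                         reporter, country)
    drug_f = pd.DataFrame({"primaryid": pd.Series(final_pid, dtype=object),
                           "drug_seq": np.ones(n, dtype=np.int64),
                           "role_code": pd.Series(role, dtype=object),
                           "verbatim_name": pd.Series(verbatim, dtype=object)})
    conc_sel = np.nonzero(extra_conc)[0]
    drug_c = pd.DataFrame({"primaryid": pd.Series(final_pid[conc_sel], dtype=object),
                           "drug_seq": np.full(len(conc_sel), 2, dtype=np.int64),
                           "role_code": pd.Series(np.full(len(conc_sel), "C",
                                                          dtype=object)),
                           "verbatim_name": pd.Series(conc_names[conc_sel],
                                                      dtype=object)})
    reac_f = pd.DataFrame({"primaryid": pd.Series(final_pid[flat_case], dtype=object),
                           "pt": pd.Series(pool_arr[flat_pt], dtype=object)})
    out_case, out_code = np.nonzero(hit)
    outc_f = pd.DataFrame({"primaryid": pd.Series(final_pid[out_case], dtype=object),
                           "outcome_code": pd.Series(
                               np.array(codes, dtype=object)[out_code], dtype=object)})
    q_tab = {"demo": [quarter], "drug": [quarter, quarter[conc_sel]],
             "reac": [quarter[flat_case]], "outc": [quarter[out_case]]}

    # earlier versions of duplicated cases (small fraction; plain loop)
    min_year = min(cfg.year_weights)
    demo_e, drug_e, reac_e, outc_e = [], [], [], []
    q_e = {"demo": [], "drug": [], "reac": [], "outc": []}
    for i in np.nonzero(dup_mask)[0]:
        pts_i = list(pool_arr[flat_pt[case_starts[i]:case_ends[i]]])
        for v in range(1, int(n_versions[i])):
            pid = str(caseid_num[i] * 10 + v)
            back = int(rng.integers(10, 200))
            ts = pd.Timestamp(int(year[i]), int(month[i]), int(day[i])) \
                - pd.Timedelta(days=back)
            if ts.year < min_year:
                ts = pd.Timestamp(min_year, 1, 1)
            d_str = f"{ts.year:04d}{ts.month:02d}{ts.day:02d}"
            q = f"{ts.year}Q{(ts.month - 1) // 3 + 1}"
            # an update may have added the newest reaction
            pts_v = pts_i[:-1] if (len(pts_i) > 1 and rng.random() < 0.5) else pts_i
            demo_e.append((pid, caseid_str[i], v, d_str, ts, False, sex[i],
                           age_value[i], age_unit[i], age_years[i], reporter[i],
                           country[i]))
            q_e["demo"].append(q)
            drug_e.append((pid, 1, role[i], verbatim[i]))
            q_e["drug"].append(q)
            if extra_conc[i]:
                drug_e.append((pid, 2, "C", conc_names[i]))
                q_e["drug"].append(q)
            reac_e.extend((pid, p) for p in pts_v)
            q_e["reac"].extend([q] * len(pts_v))
            for j in np.nonzero(hit[i])[0]:
                outc_e.append((pid, codes[j]))
                q_e["outc"].append(q)
    tables = {"demo": demo_f, "drug": pd.concat([drug_f, drug_c],
                                                ignore_index=True),
              "reac": reac_f, "outc": outc_f}
    if demo_e:
        cols = list(zip(*demo_e))
        extra_demo = _demo_frame(cols[0], cols[1], cols[2], cols[3],
                                 list(cols[4]), cols[5], cols[6], cols[7],
                                 cols[8], cols[9], cols[10], cols[11])
        tables["demo"] = pd.concat([tables["demo"], extra_demo],
                                   ignore_index=True)
        extra_drug = pd.DataFrame(drug_e, columns=list(drug_f.columns))
        extra_drug["drug_seq"] = extra_drug["drug_seq"].astype(np.int64)
        tables["drug"] = pd.concat([tables["drug"], extra_drug],
                                   ignore_index=True)
        if reac_e:
            tables["reac"] = pd.concat(
                [tables["reac"], pd.DataFrame(reac_e, columns=["primaryid", "pt"])],
                ignore_index=True)
        if outc_e:
            tables["outc"] = pd.concat(
                [tables["outc"], pd.DataFrame(outc_e,
                                              columns=["primaryid", "outcome_code"])],
                ignore_index=True)
    q_arrays = {}
    for kind in tables:
        parts = [np.asarray(a, dtype=object) for a in q_tab[kind] + [q_e[kind]]
                 if len(a)]
        q_arrays[kind] = (np.concatenate(parts) if parts
                          else np.empty(0, dtype=object))

    # REAC/OUTC are unique by construction and stay unique through parsing,
    # so literal duplicate rows (the first dedup stage's workload) are
    # injected into DEMO and DRUG only.
    unique_rows = {k: len(v) for k, v in tables.items()}
    if cfg.duplicate_row_prob > 0:
        for kind in ("demo", "drug"):
            nrow = len(tables[kind])
            n_dup = int(rng.binomial(nrow, cfg.duplicate_row_prob))
            if n_dup:
                picks = rng.choice(nrow, size=n_dup, replace=False)
                tables[kind] = pd.concat([tables[kind], tables[kind].iloc[picks]],
                                         ignore_index=True)
                q_arrays[kind] = np.concatenate([q_arrays[kind],
                                                 q_arrays[kind][picks]])
    raw_rows = {k: len(v) for k, v in tables.items()}

    # --- manifest ----------------------------------------------------------
    exclusion = frozenset(cfg.indication_pts)
    excluded_idx = np.array([pt_index[p] for p in exclusion], dtype=np.int64)
    flat_excluded = np.isin(flat_pt, excluded_idx)
    kept_pids = [str(pid) for pid in (caseid_num * 10 + n_versions)]
    ps_study = is_study & (role == "PS")
    drug_names = np.array(drug_pool, dtype=object)[drug_idx]
    de_case = hit[:, codes.index("DE")] if "DE" in codes else np.zeros(n, bool)

    pair_counts: dict[str, dict[str, int]] = {}
    death_pt_counts: dict[str, dict[str, int]] = {}
    year_counts: dict[str, dict[str, int]] = {}
    outcome_counts: dict[str, dict[str, int]] = {}
    sex_counts: dict[str, dict[str, int]] = {}
    for j, d in enumerate(study):
        sel = ps_study & (drug_idx == j)
        in_sel = sel[flat_case] & ~flat_excluded
        cnt = np.bincount(flat_pt[in_sel], minlength=len(pool))
        pair_counts[d] = {pool[k]: int(c) for k, c in enumerate(cnt) if c}
        in_de = in_sel & de_case[flat_case]
        cnt_de = np.bincount(flat_pt[in_de], minlength=len(pool))
        death_pt_counts[d] = {pool[k]: int(c) for k, c in enumerate(cnt_de) if c}
        ys, yc = np.unique(year[sel], return_counts=True)
        year_counts[d] = {str(int(y)): int(c) for y, c in zip(ys, yc)}
        oc = hit[sel].sum(axis=0)
        outcome_counts[d] = {codes[k]: int(c) for k, c in enumerate(oc) if c}
        sx, sc = np.unique(sex[sel].astype(str), return_counts=True)
        sex_counts[d] = {str(s): int(c) for s, c in zip(sx, sc)}

    manifest = TruthManifest(
        seed=cfg.seed,
        n_cases=n,
        raw_rows=raw_rows,
        unique_rows=unique_rows,
        kept_primaryids=sorted(kept_pids),
        n_ps_reports=int(ps_study.sum()),
        ps_reports_per_drug={d: int((ps_study & (drug_names == d)).sum())
                             for d in study},
        pairs_before_exclusion=int(len(flat_case)),
        pairs_after_exclusion=int((~flat_excluded).sum()),
        pair_counts=pair_counts,
        death_pt_counts=death_pt_counts,
        year_counts=year_counts,
        outcome_counts=outcome_counts,
        sex_counts=sex_counts,
        associations=[[d, p, r] for d, p, r in cfg.associations],
        exclusion_pts=sorted(exclusion),
    )

    # --- split into quarter bundles ----------------------------------------
    labels = sorted(set(q_arrays["demo"]))
    bundles = []
    for q in labels:
        parts = {}
        for kind, frame in tables.items():
            sel = q_arrays[kind] == q
            parts[kind] = frame[sel].reset_index(drop=True)
        bundles.append(make_bundle(q, parts["demo"], parts["drug"],
                                   parts["reac"], parts["outc"]))

    dictionary = DrugDictionary({d: frozenset(cfg.drug_variants[d]) for d in study})
    pt_soc = make_pt_soc_map(pool)
    return GeneratedData(bundles, manifest, dictionary, pt_soc, exclusion)


def make_independence_dataset(n: int, seed: int = 0) -> GeneratedData:
    """Null-calibration draw: no injected associations, no duplication."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    cfg = GeneratorConfig(n_cases=n, seed=seed, associations=(),
                          indication_bias=1.0, duplicate_version_prob=0.0,
                          duplicate_row_prob=0.0)
    return generate(cfg)
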