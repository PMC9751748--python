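"""Deduplication, drug matching and the filtering pipeline."""

import numpy as np
import pandas as pd
import pytest

from faerspv import (ConfigurationError, DrugDictionary, build_dataset,
                     default_drug_dictionary, drop_duplicate_rows,
                     keep_latest_case_version, load_quarter, match_drug)
from faerspv.errors import DictionaryError
from faerspv.meddra import build_pt_soc_map


class TestDropDuplicateRows:
    def test_identical_rows_collapse(self):
        frame = pd.DataFrame({"a": [1, 1, 1], "b": ["x", "x", "x"]})
        assert len(drop_duplicate_rows(frame)) == 1

    def test_near_duplicates_kept(self):
        frame = pd.DataFrame({"a": [1, 1], "b": ["x", "y"]})
        assert len(drop_duplicate_rows(frame)) == 2

    def test_injected_duplicate_count(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"a": np.arange(200), "b": rng.integers(0, 9, 200)})
        k = 17
        picks = rng.choice(200, size=k, replace=False)
        noisy = pd.concat([frame, frame.iloc[picks]], ignore_index=True)
        deduped = drop_duplicate_rows(noisy.sample(frac=1, random_state=1))
        assert len(deduped) == len(noisy) - k


def _demo(rows):
    frame = pd.DataFrame(rows, columns=["primaryid", "caseid", "case_version",
                                        "fda_dt"])
    frame["fda_date"] = pd.to_datetime(frame["fda_dt"], format="%Y%m%d")
    return frame


class TestKeepLatestCaseVersion:
    def test_higher_version_wins(self):
        demo = _demo([("5001", "500", 1, "20150101"), ("5002", "500", 2, "20150301")])
        kept = keep_latest_case_version(demo)
        assert list(kept["primaryid"]) == ["5002"]

    def test_single_version_untouched(self):
        demo = _demo([("1", "10", 1, "20150101")])
        assert keep_latest_case_version(demo).equals(demo)

    def test_ties_broken_by_date_then_primaryid(self):
        demo = _demo([("7", "70", 2, "20150101"), ("8", "70", 2, "20150601"),
                      ("9", "71", 1, "20160101"), ("12", "71", 1, "20160101")])
        kept = keep_latest_case_version(demo)
        assert sorted(kept["primaryid"]) == ["12", "8"]

    def test_brute_force_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        rows = []
        pid = 0
        for case in range(100):
            for v in range(1, rng.integers(1, 5) + 1):
                pid += 1
                date = f"20{15 + rng.integers(0, 5):02d}0{rng.integers(1, 10)}01"
                rows.append((str(pid), str(case), int(v), date))
        demo = _demo(rows).sample(frac=1, random_state=7)
        kept = keep_latest_case_version(demo)
        assert len(kept) == 100
        # brute force: max of the comparison tuple per case
        best = {}
        for _, row in demo.iterrows():
            key = (row["case_version"], row["fda_date"], int(row["primaryid"]))
            if row["caseid"] not in best or key > best[row["caseid"]][0]:
                best[row["caseid"]] = (key, row["primaryid"])
        assert set(kept["primaryid"]) == {pid for _, pid in best.values()}

    def test_idempotent(self):
        demo = _demo([("1", "10", 1, "20150101"), ("2", "10", 2, "20150201"),
                      ("3", "11", 1, "20150301")])
        once = keep_latest_case_version(demo)
        assert keep_latest_case_version(once).equals(once)


class TestMatchDrug:
    def test_paper_terms_resolve(self):
        d = default_drug_dictionary()
        assert match_drug("  REVLIMID ", d) == "LENALIDOMIDE"
        assert match_drug("Contergan", d) == "THALIDOMIDE"
        assert match_drug("Pomalyst", d) == "POMALIDOMIDE"

    def test_unrelated_drug_is_none(self):
        assert match_drug("aspirin", default_drug_dictionary()) is None

    def test_substring_vs_exact_mode(self):
        sub = default_drug_dictionary("substring")
        exact = default_drug_dictionary("exact_normalized")
        assert match_drug("THALOMID 50MG CAPSULE", sub) == "THALIDOMIDE"
        assert match_drug("THALOMID 50MG CAPSULE", exact) is None
        # word boundary: no match inside a longer word
        assert match_drug("METHALOMIDE", sub) is None

    def test_term_in_two_drugs_rejected(self):
        with pytest.raises(DictionaryError):
            DrugDictionary({"A": frozenset({"revlimid"}),
                            "B": frozenset({"Revlimid"})})

    def test_ambiguous_substring_match_is_config_error(self):
        d = DrugDictionary({"A": frozenset({"alpha"}), "B": frozenset({"beta"})})
        with pytest.raises(ConfigurationError):
            d.match("alpha beta 10mg")


class TestBuildDataset:
    def _toy_bundle(self, toy_quarter_dir):
        return load_quarter(toy_quarter_dir, "2015Q1")

    def _pt_soc(self):
        return build_pt_soc_map([("PNEUMONIA", "Infections and infestations", []),
                                 ("DIARRHOEA", "Gastrointestinal disorders", []),
                                 ("FATIGUE", "General disorders", []),
                                 ("MULTIPLE MYELOMA", "Neoplasms", [])])

    def test_exclusion_removes_indication_pt(self, toy_quarter_dir):
        bundle = self._toy_bundle(toy_quarter_dir)
        dataset, _ = build_dataset([bundle], default_drug_dictionary(),
                                   {"MULTIPLE MYELOMA"}, self._pt_soc())
        pts_1001 = set(dataset.reactions.loc[dataset.reactions["primaryid"] == "1001",
                                             "pt"])
        assert pts_1001 == {"PNEUMONIA"}

    def test_concomitant_only_report_not_in_study(self, toy_quarter_dir):
        # report 1003's only study drug (Pomalyst) has role C
        bundle = self._toy_bundle(toy_quarter_dir)
        dataset, _ = build_dataset([bundle], default_drug_dictionary(),
                                   {"MULTIPLE MYELOMA"}, self._pt_soc())
        assert "1003" not in set(dataset.ps_drugs["primaryid"])
        assert "1003" in set(dataset.demo["primaryid"])  # stays as background

    def test_empty_dictionary_rejected(self, toy_quarter_dir):
        bundle = self._toy_bundle(toy_quarter_dir)
        with pytest.raises(ConfigurationError):
            build_dataset([bundle], DrugDictionary({}), set(), self._pt_soc())

    def test_ledger_matches_truth_manifest(self, small_study):
        dataset, ledger = build_dataset(small_study.bundles,
                                        small_study.drug_dictionary,
                                        small_study.exclusion_pts,
                                        small_study.pt_soc_map)
        m = small_study.manifest
        assert ledger["raw_rows"].records_in == m.raw_rows["demo"]
        assert ledger["unique_rows"].records_out == m.unique_rows["demo"]
        assert ledger["latest_case_version"].records_out == m.n_cases
        assert ledger["ps_drug_match"].records_out == m.n_ps_reports
        assert ledger["pt_exclusion"].records_in == m.pairs_before_exclusion
        assert ledger["pt_exclusion"].records_out == m.pairs_after_exclusion
        for drug, n in m.ps_reports_per_drug.items():
            assert dataset.n_reports(drug) == n

    def test_monotone_filtering_and_composition(self, small_dataset):
        stages = small_dataset.ledger.stages
        for stage in stages:
            assert stage.records_out <= stage.records_in
        # report-unit stages compose
        report_stages = [s for s in stages if s.unit in ("demo_rows", "reports")]
        for prev, nxt in zip(report_stages, report_stages[1:]):
            assert nxt.records_in == prev.records_out

    def test_no_excluded_pt_survives(self, small_dataset):
        assert not set(small_dataset.reactions["pt"]) & small_dataset.exclusion

    def test_two_step_dedup_idempotent(self, small_study, small_dataset):
        # feeding the cleaned demo back through both steps changes nothing
        demo = small_dataset.demo
        again = keep_latest_case_version(drop_duplicate_rows(demo))
        assert again.sort_values("primaryid").reset_index(drop=True).equals(
            demo.sort_values("primaryid").reset_index(drop=True))
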