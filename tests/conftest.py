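"""Shared fixtures: small generated studies and hand-written table files."""

from __future__ import annotations

import pytest

from faerspv import (GeneratorConfig, build_dataset, generate)


@pytest.fixture(scope="session")
def small_study():
    """A 4000-case synthetic study with duplication and role mixtures."""
    return generate(GeneratorConfig(n_cases=4000, seed=101))


@pytest.fixture(scope="session")
def small_dataset(small_study):
    dataset, ledger = build_dataset(small_study.bundles,
                                    small_study.drug_dictionary,
                                    small_study.exclusion_pts,
                                    small_study.pt_soc_map)
    return dataset


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


DEMO_HEADER = "primaryid$caseid$caseversion$fda_dt$sex$age$age_cod$occp_cod$reporter_country"
DRUG_HEADER = "primaryid$drug_seq$role_cod$drugname"
REAC_HEADER = "primaryid$pt"
OUTC_HEADER = "primaryid$outc_cod"


@pytest.fixture()
def toy_quarter_dir(tmp_path):
    """Three hand-written reports in one quarter (one orphan REAC row)."""
    write_lines(tmp_path / "DEMO_2015Q1.txt", [
        DEMO_HEADER,
        "1001$500$1$20150301$F$63$YR$MD$US",
        "1002$501$1$20150315$M$70$YR$PH$US",
        "1003$502$2$20150320$$$$$JP",
    ])
    write_lines(tmp_path / "DRUG_2015Q1.txt", [
        DRUG_HEADER,
        "1001$1$PS$THALOMID 50MG CAPSULE",
        "1002$1$PS$REVLIMID",
        "1002$2$C$ASPIRIN",
        "1003$1$C$Pomalyst",
    ])
    write_lines(tmp_path / "REAC_2015Q1.txt", [
        REAC_HEADER,
        "1001$Pneumonia",
        "1001$MULTIPLE MYELOMA",
        "1002$Diarrhoea",
        "1003$Fatigue",
        "9999$Rash",          # orphan: no DEMO row
    ])
    write_lines(tmp_path / "OUTC_2015Q1.txt", [
        OUTC_HEADER,
        "1001$DE",
        "1001$HO",
        "1002$HO",
    ])
    return tmp_path
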