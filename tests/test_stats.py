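"""ROR / PRR / BCPNN-IC estimators, signal rules, and dataset scans."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faerspv import (BcpnnPriors, ContingencyTable, GeneratorConfig,
                     Thresholds, bcpnn_ic, build_dataset, contingency_table,
                     evaluate_signal, generate, prr, ror, scan, signal_frame)
from faerspv.preprocess import AnalysisDataset, FilterLedger
from faerspv.stats import raw_ic

from _oracles import chi2_oracle, ic_oracle, prr_oracle, ror_oracle

cells = st.integers(min_value=0, max_value=100_000)


def tbl(a, b, c, d):
    return ContingencyTable(a, b, c, d)


class TestRor:
    def test_independence_table(self):
        res = ror(tbl(10, 90, 90, 810))
        assert res.ror == 1.0
        assert res.ci_low < 1.0 < res.ci_high

    def test_strong_association_point_value(self):
        res = ror(tbl(20, 80, 100, 9800))
        assert res.ror == pytest.approx(24.5, rel=1e-12)
        oracle = ror_oracle(20, 80, 100, 9800)
        assert res.ci_low == pytest.approx(oracle[1], rel=1e-12)
        assert res.ci_high == pytest.approx(oracle[2], rel=1e-12)

    def test_zero_cell_policies(self):
        assert not ror(tbl(0, 10, 10, 100)).defined
        corrected = ror(tbl(0, 10, 10, 100), zero_cell_policy="haldane")
        oracle = ror_oracle(0, 10, 10, 100, haldane=True)
        assert corrected.defined
        assert corrected.ror == pytest.approx(oracle[0], rel=1e-12)
        assert corrected.ci_low == pytest.approx(oracle[1], rel=1e-12)

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for a, b, c, d in [(20, 80, 100, 9800), (3, 7, 11, 500), (50, 50, 50, 50)]:
            t2 = sm.Table2x2(np.array([[a, b], [c, d]]))
            res = ror(tbl(a, b, c, d))
            assert res.ror == pytest.approx(t2.oddsratio, rel=1e-10)
            lo, hi = t2.oddsratio_confint(0.05)
            assert res.ci_low == pytest.approx(lo, rel=1e-8)
            assert res.ci_high == pytest.approx(hi, rel=1e-8)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=250, derandomize=True, deadline=None)
    def test_matches_oracle(self, a, b, c, d):
        res = ror(tbl(a, b, c, d))
        oracle = ror_oracle(a, b, c, d)
        if oracle is None:
            assert not res.defined
        else:
            assert res.ror == pytest.approx(oracle[0], rel=1e-10)
            assert res.ci_low == pytest.approx(oracle[1], rel=1e-10)
            assert res.ci_low <= res.ror <= res.ci_high


class TestPrr:
    def test_independence_table(self):
        res = prr(tbl(10, 90, 90, 810), yates=False)
        assert res.prr == 1.0 and res.chi2 == 0.0

    def test_point_value_and_chi2_variants(self):
        res_y = prr(tbl(20, 80, 100, 9800), yates=True)
        res_u = prr(tbl(20, 80, 100, 9800), yates=False)
        assert res_y.prr == pytest.approx(19.8, rel=1e-12)
        assert res_y.chi2 == pytest.approx(chi2_oracle(20, 80, 100, 9800, True),
                                           rel=1e-10)
        assert res_u.chi2 == pytest.approx(chi2_oracle(20, 80, 100, 9800, False),
                                           rel=1e-10)

    def test_all_drug_reports_share_event(self):
        res = prr(tbl(5, 0, 100, 900))
        assert res.defined
        assert res.prr == pytest.approx(1.0 / (100 / 1000), rel=1e-12)

    def test_undefined_cases(self):
        assert not prr(tbl(0, 0, 5, 5)).defined   # empty drug margin
        assert not prr(tbl(5, 5, 0, 5)).defined   # event absent in comparator

    def test_against_scipy(self):
        from scipy.stats import chi2_contingency
        for a, b, c, d in [(20, 80, 100, 9800), (12, 34, 56, 78)]:
            for yates in (True, False):
                expected = chi2_contingency(np.array([[a, b], [c, d]]),
                                            correction=yates).statistic
                assert prr(tbl(a, b, c, d), yates=yates).chi2 == pytest.approx(
                    expected, rel=1e-10)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=250, derandomize=True, deadline=None)
    def test_matches_oracle(self, a, b, c, d):
        res = prr(tbl(a, b, c, d))
        oracle = prr_oracle(a, b, c, d)
        if oracle is None:
            assert not res.defined
        else:
            assert res.prr == pytest.approx(oracle, rel=1e-10)
            chi = chi2_oracle(a, b, c, d, True)
            if chi is not None and res.defined:
                assert res.chi2 == pytest.approx(chi, rel=1e-10, abs=1e-10)


class TestBcpnnIc:
    def test_independence_table_shrinks_below_zero(self):
        res = bcpnn_ic(tbl(10, 90, 90, 810))
        assert raw_ic(tbl(10, 90, 90, 810)) == 0.0
        assert -0.1 < res.ic < 0.0
        e, v = ic_oracle(10, 90, 90, 810)
        assert res.ic == pytest.approx(e, abs=1e-12)
        assert res.var_ic == pytest.approx(v, rel=1e-12)

    def test_empty_table_finite_priors_only_limit(self):
        res = bcpnn_ic(tbl(0, 0, 0, 0))
        assert math.isfinite(res.ic) and math.isfinite(res.var_ic)
        assert res.ic_minus_2sd <= res.ic

    def test_monotone_in_a_at_fixed_bcd(self):
        values = [bcpnn_ic(tbl(a, 50, 50, 5000)).ic for a in range(1, 51)]
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_monte_carlo_posterior_moments(self):
        """The closed form equals log2 of the ratio of posterior means of
        (p11, p1, p2); a sampling estimate of that ratio must agree."""
        rng = np.random.default_rng(2024)
        p = BcpnnPriors()
        for a, b, c, d in [(10, 90, 90, 810), (34, 200, 300, 50_000)]:
            n = a + b + c + d
            g = p.gamma(a, b, c, n)
            p11 = rng.beta(a + p.gamma11, n - a + g - p.gamma11, size=200_000)
            p1 = rng.beta(a + b + p.alpha1, n - (a + b) + p.alpha - p.alpha1,
                          size=200_000)
            p2 = rng.beta(a + c + p.beta1, n - (a + c) + p.beta - p.beta1,
                          size=200_000)
            mc = math.log2(p11.mean() / (p1.mean() * p2.mean()))
            assert bcpnn_ic(tbl(a, b, c, d)).ic == pytest.approx(mc, abs=5e-3)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=250, derandomize=True, deadline=None)
    def test_matches_oracle(self, a, b, c, d):
        res = bcpnn_ic(tbl(a, b, c, d))
        e, v = ic_oracle(a, b, c, d)
        assert res.ic == pytest.approx(e, rel=1e-10, abs=1e-10)
        assert res.var_ic == pytest.approx(v, rel=1e-10)
        assert res.var_ic >= 0
        assert res.ic_minus_2sd <= res.ic


class TestEvaluateSignal:
    STRONG = (34, 200, 300, 50_000)

    def test_independence_is_negative(self):
        s = evaluate_signal(tbl(10, 90, 90, 810))
        assert not (s.ror_positive or s.prr_positive or s.ic_positive)
        assert not s.consensus_positive

    def test_min_a_gate(self):
        s = evaluate_signal(tbl(2, 1, 1, 10_000))
        assert ror(tbl(2, 1, 1, 10_000)).ror > 1000
        assert not s.consensus_positive

    def test_strong_table_is_consensus_positive(self):
        s = evaluate_signal(tbl(*self.STRONG))
        assert s.ror_result.ci_low > 1
        assert s.prr_result.prr >= 2 and s.prr_result.chi2 >= 4
        assert s.bcpnn_result.ic_minus_2sd > 0
        assert s.consensus_positive

    @pytest.mark.parametrize("flip_ror", [False, True])
    @pytest.mark.parametrize("flip_prr", [False, True])
    @pytest.mark.parametrize("flip_ic", [False, True])
    def test_consensus_is_strict_conjunction(self, flip_ror, flip_prr, flip_ic):
        """All 8 combinations: forcing any single criterion negative via its
        threshold makes consensus negative."""
        big = 1e9
        th = Thresholds(ror_ci_low=big if flip_ror else 1.0,
                        prr_min=big if flip_prr else 2.0,
                        ic_minus_2sd_min=big if flip_ic else 0.0)
        s = evaluate_signal(tbl(*self.STRONG), thresholds=th)
        assert s.ror_positive == (not flip_ror)
        assert s.prr_positive == (not flip_prr)
        assert s.ic_positive == (not flip_ic)
        assert s.consensus_positive == (s.ror_positive and s.prr_positive
                                        and s.ic_positive)


def _hand_dataset():
    """2 X-reports with PT P, 1 X-report with only Q, 3 Y-reports with P,
    4 Y-reports with Q; X is the study drug, Y reports are background."""
    pids = [f"r{i}" for i in range(10)]
    demo = pd.DataFrame({"primaryid": pids})
    ps = pd.DataFrame({"primaryid": pids[:3], "canonical_drug": "X"})
    reac = pd.DataFrame({
        "primaryid": pids[:2] + [pids[2]] + pids[3:6] + pids[6:10],
        "pt": ["P", "P", "Q", "P", "P", "P", "Q", "Q", "Q", "Q"],
    })
    reac["soc"] = "SOC1"
    outc = pd.DataFrame({"primaryid": [], "outcome_code": []})
    return AnalysisDataset(demo=demo, ps_drugs=ps, reactions=reac,
                           outcomes=outc, exclusion=frozenset(),
                           ledger=FilterLedger())


class TestContingencyAndScan:
    def test_hand_counted_table(self):
        t = contingency_table(_hand_dataset(), "X", "P")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 3, 4)

    def test_absent_event_gives_zero_cells(self):
        t = contingency_table(_hand_dataset(), "X", "NOT SEEN")
        assert t.a == 0 and t.c == 0

    def test_manifest_pair_count_is_a(self, small_study, small_dataset):
        m = small_study.manifest
        for drug, pt, _ in m.associations:
            t = contingency_table(small_dataset, drug, pt)
            assert t.a == m.pair_counts[drug].get(pt, 0)

    def test_injected_association_ranks_first(self):
        cfg = GeneratorConfig(n_cases=20_000, seed=11,
                              associations=(("LENALIDOMIDE", "PT_0001", 10.0),),
                              duplicate_version_prob=0.0, duplicate_row_prob=0.0)
        data = generate(cfg)
        ds, _ = build_dataset(data.bundles, data.drug_dictionary,
                              data.exclusion_pts, data.pt_soc_map)
        results = scan(ds, "LENALIDOMIDE")
        assert results[0].table.event == "PT_0001"
        assert results[0].consensus_positive

    def test_scan_covers_all_observed_events(self, small_dataset):
        results = scan(small_dataset, "LENALIDOMIDE")
        pairs = small_dataset.pairs("PT")
        ids = set(small_dataset.report_ids("LENALIDOMIDE"))
        observed = set(pairs.loc[pairs["primaryid"].isin(ids), "event"])
        assert {s.table.event for s in results} == observed
        assert all(s.table.a >= 1 for s in results)

    def test_tied_tables_break_by_event_name(self):
        ds = _hand_dataset()
        # P and Q have different tables; craft a tie via two single-report PTs
        reac = pd.concat([ds.reactions,
                          pd.DataFrame({"primaryid": ["r0", "r1"],
                                        "pt": ["ZZ", "AA"], "soc": "SOC1"})],
                         ignore_index=True)
        ds2 = AnalysisDataset(ds.demo, ds.ps_drugs, reac, ds.outcomes,
                              ds.exclusion, ds.ledger)
        results = scan(ds2, "X")
        aa = [s.table.event for s in results if s.table.event in ("AA", "ZZ")]
        assert aa == ["AA", "ZZ"]

    def test_report_order_permutation_invariance(self, small_dataset):
        ds = small_dataset
        shuffled = AnalysisDataset(
            demo=ds.demo.sample(frac=1, random_state=1).reset_index(drop=True),
            ps_drugs=ds.ps_drugs.sample(frac=1, random_state=2).reset_index(drop=True),
            reactions=ds.reactions.sample(frac=1, random_state=3).reset_index(drop=True),
            outcomes=ds.outcomes.sample(frac=1, random_state=4).reset_index(drop=True),
            exclusion=ds.exclusion, ledger=ds.ledger)
        f1 = signal_frame(scan(ds, "LENALIDOMIDE"))
        f2 = signal_frame(scan(shuffled, "LENALIDOMIDE"))
        pd.testing.assert_frame_equal(f1, f2)
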