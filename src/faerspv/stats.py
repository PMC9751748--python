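r"""Disproportionality statistics on 2x2 report-count tables.

For a drug :math:`D` and event :math:`E` the database is cross-classified as

=============  =========  ============
               event E    other events
drug D         a          b
other drugs    c          d
=============  =========  ============

where the counting unit is the distinct (report, event) pair at the chosen
level (preferred term or primary system organ class).  Three classical
signal-detection statistics are computed on this table:

* **ROR** — reporting odds ratio :math:`ad/bc`, with the Woolf 95% CI
  :math:`\exp(\ln\mathrm{ROR} \pm z_{0.975}\sqrt{1/a+1/b+1/c+1/d})`.
* **PRR** — proportional reporting ratio
  :math:`[a/(a+b)] / [c/(c+d)]`, paired with a Pearson :math:`\chi^2`
  statistic (Yates-corrected by default).
* **BCPNN IC** — the information component of the Bayesian confidence
  propagation neural network, i.e. the shrunk :math:`\log_2` ratio of the
  observed to expected joint reporting probability, from closed-form
  posterior moments of independent Beta posteriors.

A drug-event pair is a *consensus positive signal* only when all three
algorithms flag it simultaneously (ROR CI lower bound > 1; PRR >= 2 with
chi2 >= 4; IC - 2SD > 0; each additionally requires at least ``min_a``
co-reports).  The conjunction trades sensitivity for a lower false-positive
rate, which is the conventional choice when the three methods are run side
by side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd
from scipy.stats import norm

from .errors import ParameterError
from .preprocess import AnalysisDataset

LN2 = math.log(2.0)

Level = Literal["PT", "SOC"]


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 counts for one (drug, event) pair."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    event: str = ""
    level: str = "PT"

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ParameterError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    defined: bool


@dataclass(frozen=True)
class PrrResult:
    prr: float
    chi2: float
    defined: bool


@dataclass(frozen=True)
class BcpnnPriors:
    """Prior parameters of the BCPNN Beta model.

    Defaults are the classical non-informative choice: marginal priors
    Beta(1, 1) (``alpha = beta = 2`` totals) and joint prior Beta(gamma11,
    gamma - gamma11) with ``gamma`` calibrated so that, at the observed
    margins, the prior expectation of the joint probability equals the
    product of the marginal expectations.
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gamma11", "alpha1", "beta1", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"prior {name} must be strictly positive")

    def gamma(self, a: float, b: float, c: float, n: float) -> float:
        """Data-calibrated total of the joint Beta prior."""
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((a + b + self.alpha1) * (a + c + self.beta1)))


@dataclass(frozen=True)
class BcpnnResult:
    ic: float
    var_ic: float
    ic_minus_2sd: float
    priors: BcpnnPriors


@dataclass(frozen=True)
class Thresholds:
    """Positive-signal criteria for the three algorithms.

    The defaults are the standard published triple: at least ``min_a``
    co-reports; ROR 95% CI lower bound above 1; PRR >= 2 together with
    chi2 >= 4; IC - 2SD above 0.
    """

    min_a: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic_minus_2sd_min: float = 0.0

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ParameterError("min_a must be >= 1")


@dataclass(frozen=True)
class SignalResult:
    table: ContingencyTable
    ror_result: RorResult
    prr_result: PrrResult
    bcpnn_result: BcpnnResult
    ror_positive: bool
    prr_positive: bool
    ic_positive: bool

    @property
    def consensus_positive(self) -> bool:
        return self.ror_positive and self.prr_positive and self.ic_positive


# ---------------------------------------------------------------------------
# estimators


def ror(table: ContingencyTable, ci_level: float = 0.95,
        zero_cell_policy: str = "undefined") -> RorResult:
    """Reporting odds ratio with Woolf confidence interval.

    With a zero in any cell the ratio or its log-variance degenerates; under
    the default policy the result is flagged undefined (and can never be a
    positive signal), under ``"haldane"`` 0.5 is added to every cell.
    """
    a, b, c, d = (float(table.a), float(table.b), float(table.c), float(table.d))
    if min(a, b, c, d) == 0.0:
        if zero_cell_policy == "undefined":
            return RorResult(math.nan, math.nan, math.nan, defined=False)
        if zero_cell_policy != "haldane":
            raise ParameterError(f"unknown zero-cell policy {zero_cell_policy!r}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    z = float(norm.ppf(0.5 + ci_level / 2.0))
    est = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return RorResult(est, est * math.exp(-z * se), est * math.exp(z * se), defined=True)


def prr(table: ContingencyTable, yates: bool = True) -> PrrResult:
    """Proportional reporting ratio and its Pearson chi-square.

    ``yates=True`` applies the continuity correction
    :math:`N(|ad-bc|-N/2)_+^2 / [(a+b)(c+d)(a+c)(b+d)]`.
    The ratio is undefined when the drug margin is empty or no comparator
    report carries the event.
    """
    a, b, c, d = (float(table.a), float(table.b), float(table.c), float(table.d))
    n = a + b + c + d
    if a + b == 0.0 or c == 0.0:
        return PrrResult(math.nan, math.nan, defined=False)
    est = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0.0:
        chi2 = math.nan
        return PrrResult(est, chi2, defined=False)
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2.0, 0.0)
    chi2 = n * dev * dev / denom
    return PrrResult(est, chi2, defined=True)


def bcpnn_ic(table: ContingencyTable, priors: BcpnnPriors | None = None) -> BcpnnResult:
    """BCPNN information component from closed-form posterior moments.

    .. math::

       E(IC) = \\log_2 \\frac{(a+\\gamma_{11})(N+\\alpha)(N+\\beta)}
                             {(N+\\gamma)(a+b+\\alpha_1)(a+c+\\beta_1)}

    with the posterior variance

    .. math::

       V(IC) = \\frac{1}{\\ln^2 2}\\Bigl[
         \\frac{N-a+\\gamma-\\gamma_{11}}{(a+\\gamma_{11})(1+N+\\gamma)} +
         \\frac{N-(a+b)+\\alpha-\\alpha_1}{(a+b+\\alpha_1)(1+N+\\alpha)} +
         \\frac{N-(a+c)+\\beta-\\beta_1}{(a+c+\\beta_1)(1+N+\\beta)} \\Bigr].

    Defined for every non-negative table (priors keep all terms positive).
    """
    p = priors or BcpnnPriors()
    a, b, c = float(table.a), float(table.b), float(table.c)
    n = float(table.n)
    g = p.gamma(a, b, c, n)
    ic = math.log2((a + p.gamma11) * (n + p.alpha) * (n + p.beta)
                   / ((n + g) * (a + b + p.alpha1) * (a + c + p.beta1)))
    var = (
        (n - a + g - p.gamma11) / ((a + p.gamma11) * (1.0 + n + g))
        + (n - (a + b) + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1.0 + n + p.alpha))
        + (n - (a + c) + p.beta - p.beta1) / ((a + c + p.beta1) * (1.0 + n + p.beta))
    ) / (LN2 * LN2)
    return BcpnnResult(ic, var, ic - 2.0 * math.sqrt(var), p)


def raw_ic(table: ContingencyTable) -> float:
    """Unshrunk information component ``log2[aN / ((a+b)(a+c))]``.

    Exactly 0 for tables with independent margins; NaN when a margin or
    ``a`` is empty.  Useful for null-calibration checks.
    """
    a, n = float(table.a), float(table.n)
    m1, m2 = float(table.a + table.b), float(table.a + table.c)
    if a == 0.0 or m1 == 0.0 or m2 == 0.0:
        return math.nan
    return math.log2(a * n / (m1 * m2))


def evaluate_signal(table: ContingencyTable,
                    thresholds: Thresholds | None = None,
                    priors: BcpnnPriors | None = None,
                    zero_cell_policy: str = "undefined",
                    yates: bool = True) -> SignalResult:
    """Apply all three algorithms and the consensus conjunction."""
    th = thresholds or Thresholds()
    r = ror(table, zero_cell_policy=zero_cell_policy)
    q = prr(table, yates=yates)
    ic = bcpnn_ic(table, priors)
    gate = table.a >= th.min_a
    ror_pos = gate and r.defined and r.ci_low > th.ror_ci_low
    prr_pos = gate and q.defined and q.prr >= th.prr_min and q.chi2 >= th.chi2_min
    ic_pos = gate and ic.ic_minus_2sd > th.ic_minus_2sd_min
    return SignalResult(table, r, q, ic, ror_pos, prr_pos, ic_pos)


# ---------------------------------------------------------------------------
# tables from a dataset


def contingency_table(dataset: AnalysisDataset, drug: str, event: str,
                      level: Level = "PT") -> ContingencyTable:
    """2x2 table for one (drug, event) pair.

    ``a + b`` counts the (report, event) pairs of reports primary-suspect
    matched to ``drug``; ``c, d`` come from every other report in the loaded
    background (all drugs, not only study drugs).  An event never observed
    yields ``a = c = 0`` rather than an error.
    """
    pairs = dataset.pairs(level)
    drug_reports = set(dataset.report_ids(drug))
    in_drug = pairs["primaryid"].isin(drug_reports)
    is_event = pairs["event"] == event
    a = int((in_drug & is_event).sum())
    b = int(in_drug.sum()) - a
    c = int(is_event.sum()) - a
    d = len(pairs) - a - b - c
    return ContingencyTable(a, b, c, d, drug=drug, event=event, level=level)


def scan(dataset: AnalysisDataset, drug: str, level: Level = "PT",
         thresholds: Thresholds | None = None,
         priors: BcpnnPriors | None = None,
         zero_cell_policy: str = "undefined",
         yates: bool = True,
         positives_only: bool = False) -> list[SignalResult]:
    """Evaluate every event observed at least once for ``drug``.

    Results are ranked by E(IC) descending, ties broken by ``a`` descending
    then event name, so repeated runs order identically.
    """
    pairs = dataset.pairs(level)
    drug_reports = set(dataset.report_ids(drug))
    in_drug = pairs["primaryid"].isin(drug_reports)
    a_counts = pairs.loc[in_drug, "event"].value_counts()
    event_totals = pairs["event"].value_counts()
    n_pairs = len(pairs)
    n_drug_pairs = int(in_drug.sum())
    results = []
    for event, a in a_counts.items():
        a = int(a)
        c = int(event_totals[event]) - a
        b = n_drug_pairs - a
        d = n_pairs - a - b - c
        table = ContingencyTable(a, b, c, d, drug=drug, event=str(event), level=level)
        results.append(evaluate_signal(table, thresholds, priors,
                                       zero_cell_policy=zero_cell_policy, yates=yates))
    results.sort(key=lambda s: (-s.bcpnn_result.ic, -s.table.a, s.table.event))
    if positives_only:
        results = [s for s in results if s.consensus_positive]
    return results


def signal_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Flatten scan results into the exportable signal table."""
    rows = []
    for s in results:
        t = s.table
        rows.append({
            "drug": t.drug, "level": t.level, "event": t.event, "a": t.a,
            "ROR": s.ror_result.ror, "ROR_CI_low": s.ror_result.ci_low,
            "ROR_CI_high": s.ror_result.ci_high,
            "PRR": s.prr_result.prr, "chi2": s.prr_result.chi2,
            "IC": s.bcpnn_result.ic, "IC_minus_2SD": s.bcpnn_result.ic_minus_2sd,
            "consensus": s.consensus_positive,
        })
    columns = ["drug", "level", "event", "a", "ROR", "ROR_CI_low", "ROR_CI_high",
               "PRR", "chi2", "IC", "IC_minus_2SD", "consensus"]
    return pd.DataFrame(rows, columns=columns)
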