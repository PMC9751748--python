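# Methods

This note records the model, the cleaning procedure, the defaults and the
design decisions behind `faerspv`, in the spirit of a statistical software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Data model and cleaning pipeline

A spontaneous-reporting quarterly extract is four `$`-delimited tables
linked by `primaryid`: DEMO (one row per report version: case id, version
number, receipt date, sex, age with unit, reporter occupation, country),
DRUG (one row per drug record with a role code — primary suspect PS,
secondary suspect SS, concomitant C, interacting I — and a free-text
verbatim name), REAC (one row per coded preferred term) and OUTC (one row
per outcome code: DE, LT, HO, DS, CA, RI, OT). Reports referenced in
DRUG/REAC/OUTC but absent from DEMO are orphans: counted, logged and
dropped at assembly.

Cleaning runs in a fixed order, and every stage records its in/out counts
in a filter ledger:

1. **Exact duplicate rows** are collapsed (first occurrence kept).
2. **Latest case version**: one record per `caseid`, the maximum of the
   tuple (case version, receipt date, primaryid). The two tie-breaks are
   ours — the convention in the field says only "latest version" — and make
   the survivor deterministic; numeric primaryid comparison is used when
   all ids are numeric, else lexicographic. Companion DRUG/REAC/OUTC rows
   of discarded versions are dropped with them.
3. **Primary-suspect matching**: a report enters the study population for
   drug X only if some record with role PS matches X's dictionary terms;
   non-PS matches are ignored entirely. Matching is case-insensitive and
   whitespace-normalised; the default mode accepts a dictionary term as a
   word-bounded substring (catching `"THALOMID 50MG CAPSULE"`), with a
   strict full-string mode available. A verbatim name matching two
   canonical drugs raises a configuration error rather than guessing.
   Reports that match no study drug are *kept* as background (see §3).
4. **Indication-PT exclusion**: preferred terms naming the treated disease
   or its complications are removed from all reports before any counting
   (indication bias). The shipped default list (multiple myeloma terms) is
   illustrative and fully overridable — the authoritative list is a study
   input, not a package constant.
5. **SOC annotation**: each retained PT is mapped to its single *primary*
   system organ class through a user-supplied dictionary (MedDRA itself is
   licensed and never shipped; the synthetic generator emits a complete
   synthetic dictionary). Unmapped PTs stay in PT-level analyses and are
   counted, but contribute to no SOC-level table.

Parsing details: ages are normalised to years (MON/12, WK/52.18, DY/365.25,
DEC×10, HR/8766; unknown unit ⇒ missing) — the source analyses do not state
their conversion, so this is a package choice. Dates are YYYYMMDD; partial
dates (YYYYMM, YYYY) are accepted, imputed to the first day/month for
ordering only, and flagged. The `$` dialect has no quoting: embedded `$` in
free text becomes a space on write and lines are split naively on read, a
documented limitation shared with the upstream format.

## 2. Counting units

PT-level cells count distinct (report, PT) pairs; SOC-level cells count
distinct (report, primary-SOC) pairs, so a report with three PTs in one
organ class counts once there and the SOC totals partition the mapped PT
pairs (no repetitive counting). Whether the original analyses counted SOC
cells as reports or PT records is not stated; the report-pair unit is the
default here because it cannot inflate within-report correlated terms, and
the PT-record unit remains available through the pair tables.

## 3. Disproportionality statistics

For drug D and event E the 2×2 table (a, b, c, d) uses as comparator **all
other loaded reports**, background drugs included, not only the study
drugs. ROR with Woolf CI, PRR with Pearson χ², and the BCPNN information
component are computed as stated in the README; numerical choices:

- **Zero cells**: the default policy flags ROR as undefined when any of
  b, c is zero (an undefined estimate can never be a positive signal); the
  optional Haldane–Anscombe policy adds 0.5 to all four cells. PRR is
  undefined when the drug margin is empty or no comparator report carries
  the event.
- **χ²**: Yates-corrected by default — the standard companion of the
  PRR ≥ 2 criterion — with the uncorrected variant selectable. The negative
  part of `|ad−bc| − N/2` truncates at zero.
- **BCPNN**: closed-form posterior moments of independent Beta posteriors,
  with the classical non-informative priors γ₁₁ = α₁ = β₁ = 1, α = β = 2
  and γ calibrated so the prior joint expectation matches the product of
  the marginal expectations. The formula is defined for every non-negative
  table, including the all-zero priors-only limit. A Monte-Carlo check in
  the tests samples the three Beta posteriors at 10⁶ draws and confirms the
  closed form to three decimals.
- **Thresholds**: a ≥ 3; ROR CI lower bound > 1; PRR ≥ 2 with χ² ≥ 4;
  IC − 2SD > 0. This is the standard triple used when the three algorithms
  are run side by side; the motivating study keeps its exact criteria in
  supplementary material, so the values are configurable and not asserted
  to be the authors'. The consensus flag is the strict conjunction.
- **Ranking**: scans order by E(IC) descending, ties by a descending then
  event name, so repeated runs are bit-identical; permuting report order
  changes nothing.

## 4. Descriptive tables

Percentages follow the `N (%)` convention: count/denominator × 100 rounded
half-up to two decimals (half-up matches every spot-checked cell of the
published tables this package was built against). Demographic strata use
sex {F, M, Unknown}, age in years {<18, 18–44, 45–64, 65–74, ≥75, Unknown},
reporter occupation, and top-k countries plus Others, with the drug's
deduplicated report count as denominator. Outcome distributions count a
report once per distinct code; the percent denominator is total mentions by
default (report count selectable) since the original figure does not state
its denominator. Death-cause rankings count deduplicated DE reports per
retained PT; death demographics pool the study drugs by default (per-drug
breakdown by flag) and use the coarser age strata {<18, 18–44, 45–64, ≥65,
Unknown}. Yearly trends report each calendar year's share of the drug's
total across loaded years, zero-count years included.

## 5. The synthetic generator

The generator emulates the structure the pipeline must survive — duplicate
case versions sharing a CASEID (earlier versions arrive weeks earlier and
may lack the newest reaction), literal duplicate DEMO/DRUG rows, multi-PT
reports, PS vs concomitant role mixtures, demographic strata, outcome codes
with PT-conditional death excess (pneumonia and sepsis by default), report
dates spanning 2013–2021 with increasing yearly weights, verbatim drug-name
variants with dosage suffixes, and indication-biased terms under the study
drugs — and emits, from the same draw, a truth manifest of every count the
pipeline should recover.

Sampling model: each case draws one suspect drug (study-drug marginal
probabilities 1% / 8% / 3%, the rest spread over six background drugs),
then a truncated-geometric number of PT draws (mean 2.1, cap 8 — two PT
records per report is the right order of magnitude for this data class),
each draw proportional to `base_rate(pt) × r(drug, pt)`, duplicates within
a report collapsing. The vocabulary is 20 named common terms (rates
0.005–0.02) plus 230 rare generic terms (0.002) and 3 indication terms.
Because the 2×2 statistics are ratios of within-margin odds, the weight of
non-target terms cancels and the population ROR of an injected pair equals
r exactly whenever it is the drug's only injected association — the
property the CI-coverage and recovery tests exploit. Default injected
associations: thalidomide–peripheral neuropathy (r = 8),
thalidomide–deep vein thrombosis (r = 5), lenalidomide–diarrhoea (r = 3),
pomalidomide–pneumonia (r = 2).

Two implementation choices trade generator purity for speed, both needed to
make replicated experiments (500 × 50,000 cases) practical on one CPU:
draws come from a single vectorised RNG stream per run (so adding cases
re-randomises a run, but a fixed config is byte-identical across runs —
the determinism the pipeline guarantees), and the generator assembles the
typed per-quarter tables directly rather than routing text through the file
parser; the write→read round-trip tests compare field-for-field, pinning
the direct construction to the file dialect.

What the generator does **not** emulate: drug co-prescription structure,
free-text narratives, real MedDRA term lists, reporting-rate secular trends
within a drug, or between-report correlation beyond duplicate versions.
Passing recovery tests therefore show the *pipeline arithmetic* is right
under a known model, not that real extracts satisfy that model.

## 6. Experiment sizes

The CI-coverage experiment runs 500 replicates of 50,000 cases with a
single injected association (lenalidomide, one rare term, r = 5), no
duplication, no indication bias, no concomitant-role study records and one
calendar year — the configuration in which the injected pair's population
ROR equals r, since each of the disabled features moves the estimand:
duplication changes effective counts, and concomitant-role study reports
leak the association into the comparator arm —
and checks that the Woolf 95% interval covers r in 95% ± 3% of replicates.
Consensus-sensitivity monotonicity is checked at r ∈ {1, 2, 5, 10} with 16
replicates of 20,000 cases each. The null calibration scans a 20,000-case
independence draw and bounds the consensus false-positive proportion at 2%;
the three-way conjunction with the a ≥ 3 gate is deliberately conservative,
which is also why the observed rate is far below classical single-statistic
false-positive rates.

## 7. Known limitations

- The headline numbers of the motivating study are not reproducible
  without the full multi-million-report background extract; the package
  validates its arithmetic against oracles and synthetic truth instead.
- Probabilistic record linkage across different CASEIDs, drug-name spelling
  correction, RxNorm normalisation, MGPS/EBGM, multiple-testing adjustment
  across events and time-to-onset analyses are out of scope.
- The `$` dialect's lack of quoting makes embedded delimiters in free text
  unrecoverable; they are sanitised to spaces on write.
- Streaming parsing of full-size real quarters is not implemented; tables
  are loaded whole.
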