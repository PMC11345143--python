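# Methods

## Problem and scope

Spontaneous adverse-event reporting systems such as FAERS collect
unsolicited reports of suspected drug reactions. Because there is no
denominator of exposed patients, safety signals are screened by
*disproportionality analysis*: for a drug class and an adverse-event term,
one asks whether the term is reported more often with the drug than the
reporting background would predict. `faerspv` implements this screen for a
target ingredient class (by default low-molecular-weight heparin, LMWH)
in two strata — the overall database and an SMQ-retrieved pregnancy
cohort — together with the ingestion, deduplication and cohort machinery
around it, and a synthetic report generator that makes every stage
testable against known ground truth.

## Counting model

The unit of analysis is the **distinct (report, PT) event**, not the
report: a report listing k distinct reaction preferred terms contributes
k events. For a term t the 2×2 table within a stratum is

|              | term t | other terms |
|--------------|--------|-------------|
| target drug  | a      | b           |
| other drugs  | c      | d           |

with N = a+b+c+d the stratum's total event count. "Target drug" means
the report names a target ingredient as its **primary suspect (PS)**
drug; reports carrying the ingredient only as concomitant are background.
The comparator is all other drugs *in the same stratum*, so pregnancy
signals are measured against the pregnancy reporting background — the
standard guard against confounding by the very different term mix of
pregnancy reports. SOC-level cells sum the events of member PTs without
per-report collapsing, which conserves N across the SOC partition.

## Estimators

All computed at full precision; the reporting layer rounds to 2 dp.

* **ROR** = ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = [a/(a+b)]/[c/(c+d)],
  95% CI = exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))), with the
  Pearson chi-square N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), no Yates
  correction.
* **IC** = log₂(aN/((a+b)(a+c))), the information component. Its lower
  bound **IC025** is the BCPNN closed-form posterior expectation minus
  two posterior standard deviations (Bate's moments) with priors
  γ₁₁ = α₁ = β₁ = 1, α = β = 2 and γ recomputed per table so the prior
  matches independence. Note the hybrid: the point estimate is the
  *unshrunk* log₂ O/E while the bound is the shrunk posterior bound.
  This pairing is deliberate — it is the convention the benchmark rows
  follow, and both columns reproduce exactly under it.
* **EBGM** here denotes the observed/expected ratio aN/((a+b)(a+c)),
  with **EBGM05** = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d)). No
  DuMouchel gamma-mixture (MGPS) shrinkage is fitted; the label is kept
  because it is how this quantity is reported in the screening
  literature this package targets. Consequently IC = log₂(EBGM) holds
  identically — a property the test suite asserts.

**Signal criterion** (conjunctive, all six): a ≥ 3, ROR lower bound > 1,
PRR ≥ 2, χ² ≥ 4, IC025 > 0, EBGM05 > 2. Any zero cell leaves the
affected statistics undefined (NaN) and the pair can never be a signal;
no Haldane 0.5 correction is applied since the a ≥ 3 gate dominates.
Ranked signal tables sort by ROR descending, ties by a then term name.
No multiple-testing adjustment is made — deliberate, and a known
limitation of conjunctive threshold screens: the criterion's strictness
is its only error control (empirically ≤1% false-signal rate over
eligible pairs under the generator's null).

## Table reconstruction from published statistics

`reconstruct_table(a, drug_total, N, ROR)` inverts a published ROR to
the integer comparator cell c = round((N − drug_total)/(1 + ROR·b/a))
and verifies the round trip at 2 dp. This turns printed summary rows
into exact 2×2 tables, enabling a row-by-row regression suite
(`faerspv.benchmarks`, 15 frozen rows over both strata) in which every
recomputed statistic must match its published value at printed
precision; interval bounds are compared at 3 significant digits because
published rounding occasionally disagrees in the fourth. For one
large-a/low-ROR row the anchor is ambiguous to ±1 in c; that row pins c
explicitly, refined by a brute-force scan over all printed statistics.

## Deduplication and assembly

FAERS re-publishes corrected case versions. Deduplication keeps, per
caseid, the version with the latest receipt date (`fda_dt`), ties broken
by the larger primaryid; a `key="primaryid"` knob disables collapsing
for sensitivity analysis. Dedup precedes all filtering. Ages are
harmonized to years from FAERS unit codes (YR, DEC, MON, WK, DY, HR);
unparseable values become missing. Occurrence country is preferred over
reporter country. Full 8-digit dates are required for onset arithmetic
(event date minus earliest PS target-drug therapy start; negative →
missing); partial dates still feed annual tallies via their year prefix.
Reports with no reaction rows are dropped at assembly.

## Pregnancy cohort

Retrieval uses six pregnancy SMQ codes against the adverse-event fields
and a three-code subset against the indication fields. Retrieved cases
partition into:

* **definitive** — any maternal/foetal exposure PT (the ten published
  codes) in reactions or indications, or any drug with transplacental
  route;
* **excluded** — paternal-exposure PTs (six codes), age below the
  pediatric cutoff (default 12 years; the source analyses never state
  one, so it is a documented config knob), or — off by default — male
  sex (retained and annotated by default, matching how published
  characteristic tables tabulate male rows as presumed misreporting);
* **other** — SMQ-retrieved with neither.

Exclusions are evaluated first; definitive evidence does not override a
paternal or pediatric exclusion. The cohort is definitive ∪ other, each
case once. Classification is a pure function of the case and config.

## Vocabulary fixtures

MedDRA and SMQ content is licensed, so the package operates on
user-supplied dictionary files; the built-in fixture dictionary uses the
publicly printed exposure/paternal PT codes and pregnancy SMQ codes with
*synthetic* member lists and filler terms. It is sufficient for testing
and for the generator, not a substitute for licensed MedDRA in a real
analysis. Drug-name normalization is exact lookup after folding
(lowercase, non-alphanumerics to single spaces) — deterministic and
auditable, no fuzzy matching.

## Synthetic data generator

`synthetic_faers.generate` emits the six quarterly tables plus a
ground-truth manifest. Reaction PTs follow a Zipf(s = 1.2) marginal over
an 800-term vocabulary — heavy-tailed like real term frequencies, so
small-a edge cases arise naturally. Defaults: mean 2.5 distinct
reactions per report (1 + truncated Poisson), 2% of reports on the
target class (one PS drug per case), 8% carrying pregnancy SMQ evidence
(40% of those definitive, with a 30% transplacental-route variant; 3%
paternal and 2% pediatric branches exercising the exclusions), 5%
duplicate case versions, 30% missing age. Planted signals multiply the
planted PT's selection odds by its relative risk for target cases and
renormalize, so the realized O/E is a consistent (mildly attenuated,
because the background also contains target events) estimate of the
planted RR.

What the generator does **not** emulate: drug co-prescription
correlation, temporal reporting trends, free-text name noise beyond
case/punctuation variants, or independent duplicate reports from
different senders (only explicit case versioning). Passing recovery tests therefore
demonstrates correctness of the pipeline's logic, not robustness to
real-world FAERS messiness.

## Validation problem sizes

The end-to-end power study uses 20 datasets of 100,000 cases with
RR = 20 planted on a rank-200 PT (baseline share ≈ 4×10⁻⁴, expected
a ≈ 40): the combined criterion must fire in ≥ 95% of seeds with EBGM
within a factor 2 of truth. Null calibration pools 5 datasets of 50,000
cases with all RR = 1 and requires a ≤ 1% flag rate over pairs with
a ≥ 3. Cohort and duplicate recovery are exact set equalities against
the manifest. These sizes give stable pass/fail behavior at interactive
runtimes; power at these margins is far from the threshold (a is ~5 SD
above the criterion boundary).

## Numerical notes

* z = 1.96 for all 95% log-scale bounds; base-2 logs only for IC.
* Quartiles (onset times) use linear interpolation over the sorted
  sample (type-7); published quartile conventions are rarely stated, and
  differences are below half a day at realistic sample sizes.
* Age bands are left-closed: [18, 45), [45, 65), ≥65.
* Ties in dedup, ranking and top-K tables break deterministically
  (primaryid, then-term-name), so pipeline outputs are byte-identical
  across reruns.
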