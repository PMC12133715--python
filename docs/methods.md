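# Methods

## Scope and model

`bcrecur` estimates the long-term frequency of breast-cancer recurrence at
the population level from a registry extract linked to two claims sources
(hospital discharge data, HDD; outpatient services, OPS). The estimand is
the cause-specific cumulative incidence function (CIF) of recurrence with
second primary cancer and death from any cause as competing events, plus
descriptive outputs: crude rates per 1000 person-years, conditional CIFs,
and a six-state classification of follow-up status at 10 years.

The pipeline runs in five stages — cohort construction, claims-based
ascertainment, competing-risks estimation, status tabulation, reporting —
each usable as a library function or CLI subcommand. Time is measured in
days from the date of diagnosis for all causes.

## Eligibility cascade

Exclusions are applied sequentially, each woman removed at the *first*
criterion she matches: prior cancer (except C44 non-melanoma skin cancer),
synchronous cancer, autopsy/death-certificate-only registration, zero
survival time, death within 6 months, missing stage, stage IV, age > 74.
Per-criterion counts therefore depend on the order (and exactly reproduce a
published cascade when fed the same inputs), while final membership does
not — a property the tests check under random permutations of the criteria.

Conventions where the data definitions leave room:

* "death within 6 months" is `death_date − diagnosis_date < 183` days
  (half of 365.25, rounded up);
* "no survival time" is death on the day of diagnosis;
* age at diagnosis is completed years (floor).

## Surrogate subtype and strata

HER2-positive ⇒ HER2+ regardless of hormone receptors; HER2-negative with
ER or PR positive ⇒ HR+/HER2−; HER2-negative with both negative ⇒ TN;
otherwise unclassifiable. The function is total over
{positive, negative, missing}³ and verified by full enumeration.

Two age groupings are provided: five bands (20–39, 40–49, 50–59, 60–69,
70–74; the default, matching status tables) and a coarser four-band variant
(50–69 merged) used by some stratified incidence analyses. Period of
diagnosis splits at 2007 (2004–2006 vs 2007–2010).

## Claims-based ascertainment

A claim matches indicator class k if any of its ICD-9-CM codes
(dot-stripped) begins with a class-k prefix. The four classes — restart of
chemotherapy, restart of radiotherapy, mastectomy/malignant breast
neoplasm, secondary malignant neoplasm — are configuration, not logic; the
defaults (99.25, V58.1x; 92.2x, V58.0; 85.4x, 174.x; 196.x–198.x) are
standard oncology claim codes consistent with the class definitions and can
be replaced from YAML, e.g. with a jurisdiction's validated lists.

Decisions fixed for determinism:

* surveillance starts 12 months (HER2− and HER2-missing — the longer window
  is phrased as the HER2-positive exception) or 24 months (HER2+) after
  diagnosis; a sensitivity flag forces 12 months for all;
* months → days as `round(m × 30.4375)` (banker's rounding: 365 / 730
  days); the start boundary is inclusive;
* a same-day multi-class claim reports the lowest class number (class
  identity never affects recurrence timing);
* HDD claims are dated by admission, OPS by service date;
* classes 1–2 trigger on a single claim; no persistence requirement is
  imposed (a conservative reading — configurable code sets let users
  tighten this upstream by supplying stricter lists);
* malformed codes skip the claim with a warning rather than aborting.

The first event among {recurrence, second primary, death, emigration,
administrative cut-off} resolves the outcome; same-day ties break by that
priority order (a recurrence claim on the death date implies the event
preceded death within the day's resolution).

## Competing-risks estimation

The Aalen–Johansen estimator is implemented directly (product-limit overall
survival, cause-specific increments `S(t_{j−1}) d_kj / n_j`), with ties
across causes processed simultaneously within a step. Pointwise variance
uses the standard Aalen-type estimator

    Var[F̂_k(t)] = Σ_{j≤t} (F̂_k(t)−F̂_k(t_j))² d_j /(n_j(n_j−d_j))
                 + Σ_{j≤t} S(t_{j−1})² (n_j−d_kj) d_kj / n_j³
                 − 2 Σ_{j≤t} (F̂_k(t)−F̂_k(t_j)) S(t_{j−1}) d_kj / n_j² ,

evaluated in O(J) per cause via cumulative sums, and 95 % CIs use the
log(−log) transform clamped to [0, 1] (degenerate at F̂ ∈ {0, 1} or zero
variance). Correctness is checked three ways: exact agreement with a pure
Fraction-arithmetic brute-force product-limit oracle on all small datasets,
agreement with `lifelines.AalenJohansenFitter` on tie-free data, and the
additivity invariant Σ_k F̂_k(t) + Ŝ(t) = 1 at every step.

**Risk time between diagnosis and the surveillance start.** Because
recurrence cannot be ascertained before the surveillance start, two
readings exist: count risk time from diagnosis (recurrence simply cannot
occur early), or delay entry until the window opens. The default counts
risk time from diagnosis for all causes, matching a follow-up definition
that starts at diagnosis; a `left_truncation` flag instead sets each
woman's entry time to her surveillance start (risk sets
`{i : entry_i < t ≤ time_i}`), exercising the delayed-entry reading.
Neither is asserted as the only correct one.

Other conventions: years → days via 365.25; right-continuous step lookup;
lookups beyond the last follow-up return the last value with a flag;
percentages round half-up to one decimal. Conditional CIFs
`(F(t2)−F(t1))/S(t1)` are flagged undefined (NaN) when no one is event-free
at t1.

## Ten-year status

Each woman's pathway is her first event strictly before the 10-year horizon
(3652.5 days): recurrence, second primary, or none; vital status at the
horizon splits each pathway into alive/dead. Events and deaths on/after the
horizon are ignored (strict-`<` boundary, fixed because the horizon
convention is otherwise ambiguous). Deaths whose first event was death —
including early progression without a disease-free interval — fall under
"dead without recurrence". Women censored by emigration before the horizon
count as alive, consistent with registries that retain vital-status
follow-up. The six states partition every stratum by construction, and on
emigration-free synthetic data the recurrence-pathway count equals the
number of ascertained recurrences before the horizon.

## Synthetic-data generator

The generator emulates the linked-data structure the analysis assumes, not
any particular published cohort:

* one latent time per cause (recurrence, second primary, death, emigration)
  drawn as independent exponentials from a (subtype, stage)-specific hazard
  table; the minimum wins; administrative censoring at the cut-off. The
  independence construction is the simplest one matching the estimator's
  assumptions, since the cause-specific CIF is identified without modelling
  dependence;
* a post-event death hazard (default 0.09/yr) applied after recurrence
  *and* after second primary, so that all six 10-year states are populated;
* claims generated from the truth: every woman receives primary-treatment
  codes strictly before her surveillance start (12/24 months by HER2),
  creating the false-positive pressure the window must absorb; a true
  recurrence emits its first indicator claim after a constant delay
  (default 30 days; the delay distribution is degenerate because no
  empirical delay data are modelled), with class mix defaulting to the
  observed breakdown of ascertained recurrences (≈ 20/16/52/13 % for
  classes 1–4), optional missed-claim probability, and occasional follow-up
  treatment claims;
* no claim postdates death, emigration or the cut-off.

Defaults mirror a 2004–2010 diagnosis window with follow-up to end-2021,
n = 5825, and the age/stage/subtype mix of a screening-era Italian cohort.
The default hazard table (recurrence 0.015/0.032/0.065 per year for stages
I/II/III, subtype multipliers 1.0/1.2/1.8 for HR+/HER2+/TN; death
0.010/0.015/0.035; second primary 0.006; emigration 0.003) is calibrated
only so that stage and subtype *orderings* of the 10-year CIF are
realistic; exact published values are deliberately not a generator target.

What the generator does **not** emulate — hence what passing tests do not
show about real data: non-constant (e.g. delayed or era-dependent) hazards,
screening-driven stage migration, claim miscoding beyond whole-claim
omission, misclassification of second breast primaries as recurrence, and
dependence between causes. Recovery results on synthetic data validate the
*algorithmic* chain, not the clinical accuracy of the code lists.

## Problem sizes and numerical checks

The test suite uses cohorts of 120–2000 women for pipeline properties,
n ≤ 8 exhaustive-oracle datasets (200 seeds) for estimator equivalence at
1e−10 tolerance, and one n = 20,000 constant-hazard cohort for closed-form
recovery of the 10-year CIF within ±0.01 — sizes chosen so the entire suite
runs in seconds while keeping Monte-Carlo error well inside each tolerance.
The acceptance script runs the full default-scale study (n = 5825) plus the
same recovery checks.

## Known limitations

Local/regional/distant recurrences are not distinguished (administrative
codes cannot separate them); cause of death is not modelled; no
subdistribution (Fine–Gray) regression or k-sample tests — the package is
descriptive by design; the default code prefixes are plausible but not a
validated jurisdiction-specific list and should be replaced for real
analyses.
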