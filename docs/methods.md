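# Methods

## Diet model

Each food item contributes `fat_g × correction_factor` grams of glycerol,
on the assumption that dietary fat is essentially triglyceride. The
correction factor is the glycerol mass fraction of the triglyceride and
depends on fatty-acid chain length; food-specific factors are rarely
published, so the package documents a single default of **0.1040**, the
molar-mass ratio of glycerol to triolein (92.09 / 885.45). It is a
chemically motivated stand-in, not a food-database value: users with
measured factors supply them per item in the `correction_factor` column.

Days are assigned to dinner-glycerol exposure classes either by explicit
day sets (default: high {3, 4, 7, 8}, low {1, 2, 5, 6, 9}, excluded
{10, 11} — the days whose urine was pooled over 24 h and cannot resolve an
overnight window) or, for unseen menus, by a dinner-glycerol threshold of
1.5 g, chosen midway between the observed low-dinner maximum (1.26 g) and
high-dinner minimum (2.1 g).

## Urinary excretion

Interval amounts are `conc (ng/mL) × volume (mL) / MW / 1000` µmol, with
volume from urine weight at an assumed density of 1 kg/L. The molar
masses are computed from the molecular formulas (3-HPMA C8H15NO4S →
221.27 g/mol; CEMA C8H13NO5S → 235.25 g/mol, IUPAC 2021 atomic weights).

The study day runs 08:00→08:00 (interventions of this design start at
8 a.m.), the overnight window 20:00→08:00; both are half-open. An
interval straddling a boundary is **pro-rated by the fraction of its
duration inside the window**, which assumes uniform excretion within the
interval. This rule conserves total excreted amount under any partition
of the timeline and is invariant to splitting an interval into abutting
sub-intervals — both properties are tested to 1e-9 µmol. Whole-interval
assignment (by interval midpoint) is available as a config option
(`WindowSpec(prorate=False)`) since collection protocols differ in how
they book boundary intervals; pro-rating is the default because it is the
only conservation-preserving choice.

Days with no overlapping interval are emitted with `coverage_h = 0` and a
`missing` flag rather than dropped, so downstream stages can decide.
Daily CEMA/3-HPMA ratios are undefined (NaN, excluded from medians) when
the 3-HPMA amount is zero.

## Mass balance

The chain has three steps, each a one-line formula with an explicit
physiological constant:

1. **Colonic delivery**: small-intestinal lipid hydrolysis is ~95%
   efficient, so `(1 − 0.95)` of dietary glycerol reaches the colon;
   in mmol, `(1 − η) · m_g / 92.09 × 1000`. At the defaults this maps a
   0.44 g (minimum low) dinner to 0.24 mmol and a 1.26 g (maximum low)
   dinner to 0.68 mmol.
2. **Intestinal acrolein**: oral dosing studies in rats recover ~20% of
   an acrolein dose as urinary 3-HPMA; assuming the same fraction in
   humans, intestinal acrolein is overnight 3-HPMA / 0.20.
3. **mol% conversion**: `100 × acrolein (µmol) / pool (nmol)`. The
   denominator defaults to the colonic pool (`denominator_mode =
   "colonic"`), the pool microbes actually see; total intake is available
   as `"intake"`. The choice changes the result by exactly the factor
   `1/(1 − η)` (20× at the default), so it is logged with every run.

Both constants are assumptions imported from other model systems, not
measurements in the cohort at hand; the module exposes them as parameters
precisely because the back-calculated acrolein scales linearly in `1/φ`
and the mol% in `1/(1 − η)`. Reported tables round half-even to 2
decimals; all internal computation is full precision. CEMA is *not*
added to the acrolein back-calculation: the 20% recovery figure is
specific to 3-HPMA, so using the sum would require a recovery fraction
for which no measurement exists.

## Phenotype classification

The rule is a disjunction of two strict-inequality clauses evaluated on a
participant's valid days (both analytes positive, ≥3 days):

- **day majority**: fraction of days with CEMA > 3-HPMA exceeds 0.5;
- **median override**: median daily CEMA > median daily 3-HPMA.

Either clause labels the participant CEMA; ties and all other cases fall
to 3-HPMA, the usual dominant mercapturic acid in humans. Participants
whose clauses disagree (e.g. an HPMA majority of days but a higher CEMA
median) are labelled CEMA by the disjunction and flagged `conflicting`
for review. The rule is permutation-invariant over days and invariant to
rescaling both analytes, and matches exhaustive clause evaluation on
small inputs (property-tested).

Group contrasts use two-sided Mann–Whitney U with participant-nights as
units for the overnight high-vs-low comparison (matching per-sample
boxplot practice), and Kruskal–Wallis with Bonferroni-corrected pairwise
Mann–Whitney follow-ups for between-day effects. Tukey-style rank
post-hoc procedures are out of scope.

## Community tables

A genome is *pdu*-positive when it carries at least one of pduC/pduD/pduE
(`mode="any"`; `mode="all"` for the strict operon definition — always a
subset, property-tested). Percentages are reported at full precision.
Quantities below an assay's limit of detection are censored, not zero:
LOD/2 substitution for share computation (a standard censoring
convention), absence for occurrence counting, and NaN — never log(0) —
for log10 reporting. SCFA proportions normalize acetate, propionate and
butyrate to their sum; note that medians of per-sample ratios are not
ratios of medians, so cohort summaries are computed per sample first.

## Synthetic cohort

The generator emulates the design the analysis targets: 20 participants
(10 male, 10 female), 11 days, four menus cycling as {1,5,9}, {2,6,10},
{3,7,11}, {4,8}, high-glycerol dinners (2.1–3.4 g) on days 3/4/7/8 and
low (0.44–1.26 g) otherwise, lunch carrying ~50% of daily glycerol on
low-dinner days, and female menus scaled by 0.92. Urine follows the
timed-collection pattern: four intervals per day (08–12, 12–16, 16–20,
20:00–08:00) with the overnight interval always present, and a single
24 h interval on days 10–11 — which is why those days are excluded from
the overnight contrast.

Daily excretion model: participant-day totals are log-normal with median
1.05 µmol, participant-level log-sd 0.25 and day-level log-sd 0.20 —
positive and right-skewed, landing pooled daily CEMA in 0.11–1.82 and
3-HPMA in 0.20–1.90 µmol/day. The CEMA/(CEMA+3-HPMA) split follows a
phenotype-specific median ratio (0.67 for HPMA-phenotype, 1.45 for
CEMA-phenotype) with participant log-sd 0.06 and day log-sd 0.13. These
four numbers were calibrated analytically so the pooled median of daily
ratios over a 14:6 cohort sits at 0.73 with a median-sampling sd of
~0.02. Phenotype labels are assigned deterministically — the first
⌈0.7·20⌉ = 14 participants of a seeded permutation — so the 14:6 split is
exact in every cohort and label-recovery tests are sharp. Distribution
forms are modeling choices; the targets they are calibrated to are
summary ranges, not distributional claims.

High-glycerol dinners multiply the overnight interval's excretion of both
analytes by 1.5 (the `overnight_effect`); measurement adds ~5%
multiplicative noise per interval and analyte. The latent truth table
records phenotypes and post-uplift, pre-noise daily amounts.

Community tables: the nine *pdu*-positive taxa are the species recurrently
reported as gut glycerol/1,2-propanediol transformers (two
*Anaerobutyricum*, three *Blautia*, two *Mediterraneibacter*,
*Flavonifractor plautii*, and the transient cheese culture
*Propionibacterium freudenreichii*), seven with the full pduCDE and two
partial, in a background of 31 *pdu*-negative genomes. Detection per
donor is Bernoulli with per-taxon probabilities (1.0 for the dominant
*A. hallii* down to 0.75), topped up deterministically to a minimum of 5
detected species per donor — the cohort-level minimum the tables should
exhibit. *A. hallii* receives ~200× the pduC copies of any other taxon,
giving it >90% of each donor's signal. Fecal glycerol is log-normal
(median 2.0 µmol/g, log-sd 0.75) clipped to 0.2–19.4 µmol/g; SCFA
profiles are Dirichlet (41, 5.2, 11) shares of a log-normal total,
acetate-dominant.

What the generator does **not** emulate: pharmacokinetic delay between
dinner and overnight excretion (the uplift is applied directly to the
overnight window), within-day circadian excretion patterns (amounts are
uniform per hour within a day apart from the uplift), correlations
between diet, microbiome and excretion across participants, missing
urine collections, and coffee-day effects. Passing tests therefore
demonstrate that the pipeline's arithmetic, aggregation and inference
behave correctly under the assumed data-generating process — not that the
biological effect sizes are as simulated.

## Statistical calibration checks

The null calibration of the overnight comparison is checked by simulation
at `overnight_effect = 1.0` with the participant-level intercept removed:
over 500 seeded cohorts the Mann–Whitney rejection rate at α = 0.05 is
0.058. With the participant intercept at its default (log-sd 0.25) the
pooled unpaired test is **conservative** (rejection rate ≈ 0 in 200
cohorts): every participant contributes nights to both exposure groups,
so between-participant variability cancels between groups while the
test's null variance assumes it does not — the classic behaviour of an
unpaired analysis of paired-structure data. Both facts are asserted in
the test suite; the conservativeness means the reported high-vs-low
p-values err on the safe side. Power at the default 1.5× uplift is 1.00
over 100 seeded cohorts.

Problem sizes used in the simulation-based tests — 100 cohorts for label
recovery and power, 500 for null calibration, 200 for the
conservativeness check — were chosen to bound the Monte-Carlo standard
error of each estimated rate below half of its decision margin.

## Known limitations

- The correction-factor default treats all fat as triolein; real menus
  span chain lengths, so absolute glycerol totals carry a few percent of
  systematic uncertainty.
- The mass-balance constants (η = 0.95, φ = 0.20) come from other model
  systems; the back-calculated acrolein is an order-of-magnitude
  estimate, and the mol% depends multiplicatively on the denominator
  convention.
- Pro-rating assumes uniform excretion within a collection interval; for
  intervals up to 24 h this flattens genuine within-day structure.
- The classifier treats days as exchangeable; it does not model
  within-participant trends or day-level covariates.
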