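# glycacro

From dietary glycerol to urinary acrolein biomarkers: an analysis pipeline
for standardized-diet intervention studies of intestinal glycerol
metabolism.

## The problem

Dietary fat is mostly triglyceride, and a few percent of its glycerol
backbone escapes small-intestinal hydrolysis and reaches the colon. Gut
bacteria carrying the cobalamin-dependent glycerol/diol dehydratase
(PduCDE, encoded in the *pdu* operon) dehydrate glycerol to
3-hydroxypropanal, which spontaneously forms **acrolein** — a highly
reactive α,β-unsaturated aldehyde. Acrolein is detoxified by glutathione
conjugation and shows up in urine as two mercapturic acids: **3-HPMA**
(N-acetyl-S-(3-hydroxypropyl)-L-cysteine) and **CEMA**
(N-acetyl-S-(carboxyethyl)-L-cysteine). This package connects the three
layers — what was eaten, what was excreted, and which microbes could have
done the transformation — for cohort studies with timed urine collections.

## What it computes

- **Diet** (`glycacro.diet`): per-item glycerol as `fat_g × f`, where
  `f` is the glycerol mass fraction of the fat (default 0.1040, the
  glycerol/triolein molar-mass ratio 92.09/885.45); per-meal and per-day
  aggregation; classification of study days into high/low dinner-glycerol
  exposure classes.
- **Urine** (`glycacro.urine`): interval concentrations (ng/mL) × volume
  (weight at 1 kg/L) / molar mass → µmol excreted; aggregation into study
  days (08:00→08:00) and overnight windows (20:00→08:00) with
  duration-pro-rated assignment of boundary-straddling intervals; daily
  CEMA/3-HPMA ratios.
- **Mass balance** (`glycacro.massbalance`): colonic glycerol delivery
  `(1 − η) · m/M_gly` with hydrolysis efficiency η = 0.95; intestinal
  acrolein `A = HPMA/φ` with excretion fraction φ = 0.20; mol%
  conversion `100 · A / pool`; coffee acrolein intake `c·V/M_acr`.
- **Phenotypes** (`glycacro.phenotype`): a participant is CEMA-phenotype
  when CEMA > 3-HPMA on a majority of days **or** the participant's median
  CEMA exceeds the median 3-HPMA, else 3-HPMA-phenotype; Mann–Whitney U
  for the high-vs-low overnight contrast; Kruskal–Wallis plus
  Bonferroni-corrected pairwise tests for day effects.
- **Community tables** (`glycacro.microbiome`): *pdu*-positive genomes
  from a presence/absence matrix, per-donor detected pdu species, taxon
  shares of absolute (qPCR-style) signal with LOD/2 substitution,
  prevalence, SCFA proportions and butyrate:propionate ratios.
- **Synthetic cohort** (`glycacro.simulate`): a seeded generator for all
  of the above — 20 participants, 11 days, four repeating menus,
  high-glycerol dinners on days 3/4/7/8, log-normal daily excretion with
  persistent phenotypes in a 14:6 split, and community tables — so the
  whole pipeline is testable without any study data.

## Worked example

The numbered scripts under `analysis/` run the full story on the default
synthetic cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_diet_glycerol.py
python analysis/03_urine_excretion.py
python analysis/04_overnight_comparison.py
python analysis/05_mass_balance.py
python analysis/06_phenotypes.py
python analysis/07_microbiome_summaries.py
```

Selected output (seed 42):

```
dinner glycerol: low 0.80-1.07 g, high 2.37-2.99 g
pooled median daily CEMA/3-HPMA ratio: 0.75
overnight 20:00-08:00, high vs low glycerol dinner:
  sum_umol   median high 0.79 vs low 0.54 umol, U=6836, p=3.3e-16
low-glycerol dinners: 0.47 mmol glycerol reach the colon; overnight
  3-HPMA 0.3 umol implies 1.49 umol intestinal acrolein
phenotype counts: {'HPMA': 14, 'CEMA': 6}
latent-label recovery: 100%
9 of 40 genomes carry a pduCDE subunit (22.5%)
detected pdu species per donor: min 7, median 8 (19 donors)
```

Overnight excretion is significantly higher after high-glycerol dinners,
the classifier recovers all 20 latent phenotype labels, and the estimated
mol% conversion is *lower* on high-glycerol days — the nonlinearity the
mass-balance model is designed to expose. The same stages are available as
a CLI (`glycacro simulate|diet|urine|massbalance|phenotype|compare|pdu|scfa|run-all`).

Worked single values, from the library:

```python
>>> from glycacro import massbalance
>>> round(massbalance.colonic_glycerol(0.44), 2)   # 0.44 g dinner glycerol
0.24
>>> round(massbalance.colonic_glycerol(1.26), 2)
0.68
>>> massbalance.acrolein_from_hpma(0.26)           # 0.26 umol 3-HPMA overnight
1.3
```

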