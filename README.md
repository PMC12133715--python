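# bcrecur

Population-based estimation of breast-cancer recurrence from linked
cancer-registry and administrative-claims data.

Most cancer registries record incidence and vital status but not recurrence.
`bcrecur` implements the claims-linkage approach used in registry studies of
non-metastatic breast cancer: women diagnosed with stage I–III invasive
breast cancer are followed through two linked ICD-9-CM–coded administrative
databases — hospital discharge data (HDD) and outpatient services (OPS) —
and a recurrence is ascertained as the earliest of four indicator classes
(restart of chemotherapy; restart of radiotherapy; mastectomy or admission
for malignant breast neoplasm; admission for secondary malignant neoplasm)
occurring after a subtype-specific surveillance start. The package is aimed
at registry epidemiologists and biostatisticians who want a tested,
reproducible version of the whole pipeline, and it ships a synthetic
linked-data generator so every stage can be validated without access to
confidential registry data.

## The method

**Cohort.** A fixed eligibility cascade removes, in order: prior cancer
(except non-melanoma skin cancer C44), synchronous cancer, diagnosis by
autopsy/death certificate only, zero survival time, death within 6 months,
missing stage, stage IV, and age over 74. Surrogate intrinsic subtype is
derived from immunohistochemistry: HER2+ if HER2 positive (any ER/PR);
HR+/HER2− if HER2 negative and ER or PR positive; TN if all three negative.

**Ascertainment.** Recurrence indicators are only counted from 12 months
after diagnosis (HER2−) or 24 months (HER2+), so that primary-treatment
claims are not misread as recurrence; the recurrence date is the date of the
first qualifying claim. Each woman's first event is then resolved among
recurrence, second primary cancer, death, emigration and the administrative
cut-off.

**Estimation.** The cumulative incidence of recurrence is estimated in a
competing-risks framework (second primary and death are competing events)
with the Aalen–Johansen estimator. With n_j women at risk just before the
j-th distinct event time and d_kj cause-k events,

    S(t_j)  = ∏_{i≤j} (1 − Σ_k d_ki / n_i)
    F̂_k(t) = Σ_{t_j≤t} S(t_{j−1}) · d_kj / n_j ,

with an Aalen-type variance estimator and log(−log)-transformed 95 %
confidence intervals. Crude rates per 1000 person-years, conditional CIFs,
and a six-state follow-up status at 10 years (alive/dead × event-free /
after recurrence / after second tumour) complete the outputs.

## Worked example

Run the full pipeline on a synthetic cohort of 2000 women (YAML config with
`outdir`, `seed` and a `simulation` block):

```bash
bcrecur run-all --config demo.yaml
```

```
cohort: 1989 of 2000 eligible
recurrences: 530 over 20485.6 person-years

cumulative incidence of recurrence (95 % CI):
  all cohort, 5y: 11.3 % (10.0 %-12.8 %)
  all cohort, 10y: 21.7 % (19.9 %-23.6 %)
  by stage:
    I: 5y: 6.7 % (5.3 %-8.3 %); 10y: 14.0 % (12.0 %-16.2 %)
    II: 5y: 13.5 % (11.1 %-16.2 %); 10y: 26.7 % (23.4 %-30.0 %)
    III: 5y: 23.6 % (18.6 %-29.0 %); 10y: 39.0 % (33.0 %-44.9 %)
```

11 of 2000 simulated women died within 6 months of diagnosis and were
excluded; of the 1989 eligible, 530 had an ascertained recurrence. The
estimated 10-year cumulative incidence of recurrence is 21.7 % overall and
rises steeply with stage (14.0 % → 39.0 %), the pattern the surveillance
algorithm is designed to measure. `summary.txt` plus CSV outputs
(`cohort.csv`, `outcomes.csv`, `cif_*.csv`, `rates.csv`, `status10y.csv`)
are written to the output directory; identical config and seed give
byte-identical outputs.

Stage-wise subcommands (`simulate`, `cohort`, `ascertain`, `estimate`,
`tabulate`) run the same steps on CSV inputs; real linked tables can be
supplied as `registry.csv`, `hdd.csv`, `ops.csv` (schemas in the module
docstrings).

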