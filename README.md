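# lcnet

Characterization toolkit for the uptake and clinical context of a newly
released diagnosis code — built around ICD-10-CM **U09.9** ("Post COVID-19
condition, unspecified", released October 2021) and its pre-release
placeholder **B94.8**.

When a new code enters clinical use, three questions matter to EHR
researchers: *who* receives the code (demographics and area-level social
determinants of health), *what else* appears in those patients' records
around the diagnosis (co-occurring conditions, procedures, new
medications), and *how fast* the code displaces older workarounds.  `lcnet`
implements that full analysis as a tested, reusable pipeline over
OMOP-flavored delimited-text extracts, and ships a synthetic EHR generator
with planted ground truth so every stage can be validated without access to
restricted enclave data.

## What it computes

**Cohort.** The index date is a patient's earliest U09.9 code inside the
closed window 2021-10-01 … 2022-05-26 (earlier codes may be retroactive and
never index).  Deceased patients and patients whose index falls inside an
inpatient stay are excluded; analyses run over the closed 0–60-day window
after index.  Sites must pass data-quality gates (≥ 25% inpatient lab
coverage, ≥ 75% valid inpatient end dates, date shift ≤ 30 days).

**Co-occurrence network.** Over the top-30 conditions by unique-patient
count (SNOMED-style names, collapsed from ICD-10-CM via a bundled
crosswalk), the edge weight w(i,j) counts distinct patients carrying both
conditions in-window.  Communities maximize the weighted Newman–Girvan
modularity

&nbsp;&nbsp;&nbsp;&nbsp;Q = (1/2m) Σᵢⱼ [Aᵢⱼ − γ kᵢkⱼ/2m] δ(cᵢ, cⱼ)

via **Louvain** (greedy two-phase, the headline algorithm), **Girvan–Newman**
(divisive by edge betweenness, distance = 1/weight) and **Walktrap**
(agglomerative on t-step random-walk profiles) — all implemented in this
package and cross-checked against independent references in the test suite.
Stability is assessed by patient bootstrap scored with the adjusted Rand
index; all analyses can be stratified by age group (<21, 21–45, 46–65, 66+).

**Disparities.** Area-level SDoH percentages (ACS-style, keyed by ZIP) are
banded high/medium/low at tertiles of the full reference table; cohort vs
comparator rates are tested with the g-test of independence
G = 2 Σ O·ln(O/E) with Bonferroni-adjusted post hoc 2×2 comparisons.
Released tables apply small-cell suppression (counts under 20 are masked)
with bounded ±1…5 perturbation of derivable complements, audited by an
interval-arithmetic recovery check.

**Summaries.** Informative procedures (encounter-only E&M codes removed)
rolled up to high-level categories with figure-style suppression (< 20
patients or < 1.0% of stratum); newly started medications (no record before
index, full lookback) rolled up to WHO ATC level 3; monthly unique-patient
uptake series for U09.9 vs B94.8 back to January 2018.

## Worked example

```python
from lcnet import (GeneratorConfig, generate_population, derive_index,
                   apply_exclusions, summarize, window_events,
                   CooccurrenceModel)

tables = generate_population(GeneratorConfig(n_patients=3000, seed=11))
index = derive_index(tables.coded_events)
cohort = apply_exclusions(tables.persons, tables.visits, index, tables.tests)
print(summarize(cohort).as_dict())
```

```
{'n_initial': 3000, 'n_excluded_inpatient_index': 252,
 'n_excluded_deceased': 0, 'n_base': 2748, 'n_hospitalized_acute': 267,
 'pct_hospitalized_acute': 9.7, 'n_severe': 65, 'pct_severe_of_all': 2.4,
 'pct_severe_of_hospitalized': 24.3, 'n_missing_covid_index': 1022,
 'pct_missing_covid_index': 37.2}
```

Of 3,000 indexed patients, 252 indexed during an inpatient stay and are
excluded, leaving a base cohort of 2,748; 9.7% were hospitalized during
their acute infection and 37.2% have no COVID index date on record (their
positive test happened outside the contributing systems).

```python
windowed = window_events(cohort, tables.coded_events, 60)
model = CooccurrenceModel.from_events(windowed, k=30)
result = model.fit(algorithm="louvain", seed=0)
print(result.summary())
```

```
Community detection on condition co-occurrence network
  algorithm:   louvain (resolution=1.0)
  nodes:       30
  communities: 4
  modularity Q: 0.4516

  community 0 (8 conditions):
    Dyspnea  (n=590)
    Atherosclerosis  (n=588)
    Chest pain  (n=585)
    ...
  community 1 (8 conditions):
    Headache  (n=581)
    Dizziness  (n=568)
    Fatigue  (n=565)
    ...
```

The four detected communities are exactly the generator's planted symptom
subtypes (cardiopulmonary, neurological, comorbid, gastrointestinal).
Bootstrap stability:

```python
report = result.stability(B=50, seed=0)
print(f"mean ARI {report.mean:.3f} over {report.B} replicates")
# mean ARI 1.000 over 50 replicates
```

The same stages are available from the shell:

```bash
lcnet synth  --out data --seed 1 --n-patients 3000
lcnet cohort --in data --out cohortdir
lcnet conet  --in cohortdir --algorithm louvain --by-age --out netdir
lcnet all    --out rundir --seed 1        # everything, with a run manifest
```

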