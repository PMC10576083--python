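# polyhcc

Histological diagnosis of tumor polyploidy in hepatocellular carcinoma
(HCC), as a tested, reusable pipeline.

A substantial minority of HCCs have undergone whole-genome doubling, and
those tumors behave more aggressively than their near-diploid counterparts.
Ploidy can be read directly from pathology sections: count FISH signals for
the pericentromeres of chromosomes 7, 11 and 16 in individual tumor nuclei,
take the predominant (modal) count per chromosome, and average the three.
`polyhcc` implements that caller and everything around it for pathologists
and computational researchers working with per-nucleus measurement tables:

- **FISH ploidy calling** (`polyhcc.ploidy`) — per-chromosome predominant
  copy number `c_k` = modal nonzero spot count over tumor nuclei; average
  ploidy `(c7 + c11 + c16) / 3`; a tumor is **polyploid** when the average
  is ≥ 2.5 (boundary inclusive). Zero counts are treated as hybridization
  failure; modal ties break to the larger count because FFPE sectioning
  only removes signals.
- **Nuclear image cytometry** (`polyhcc.cytometry`) — integrated DAPI
  intensity is proportional to DNA content; gating to HNF4α+/Ki-67− tumor
  nuclei and normalizing against the diploid non-tumor mode gives a
  per-nucleus C-value (`c = 2·I / mode(I_ref)`), binned into 2C/4C/8C/≥8C
  doubling classes.
- **PGCC quantification and the PUB score** (`polyhcc.pub`) — a polyploid
  giant cancer cell (PGCC) is a tumor cell whose nucleus is at least 3×
  the area of a regular cancer cell (baseline = median tumor nuclear
  area); a tumor is PGCC-abundant at ≥ 1 PGCC per 40× field. The PUB
  score is `1[PGCC-abundant] + 1[UBE2C moderate/strong]` ∈ {0, 1, 2};
  PUB = 2 is the surrogate call for polyploidy.
- **Cohort statistics** (`polyhcc.stats`) — one-sided Mann–Whitney U,
  Fisher exact, chi-square, Kaplan–Meier with two-sided log-rank, and the
  upper-tail hypergeometric gene-list overlap test (log-space for extreme
  significance).
- **Synthetic cohorts** (`polyhcc.simulate`) — a seeded generator that
  emulates the data structure of a 56-tumor surgical series (20 polyploid),
  with FFPE signal dropout, hybridization failure, DNA-proportional nuclear
  morphometry, planted PGCCs, ploidy-conditional marker grades, lognormal
  serum AFP and proportional-hazards survival, so the whole pipeline is
  testable without patient data.

## Worked example

Run the full pipeline on the default synthetic cohort:

```sh
polyhcc report --out run1 --seed 1
```

```
... INFO stage simulate: n_tumors=56 seed=1
... INFO stage call-ploidy
... INFO stage cytometry
... INFO stage pub
... INFO stage stats
... INFO done: 20/56 tumors called polyploid (35.7%)
pipeline complete; manifest at run1/run_manifest.json
```

`run1/` then contains the four input tables (`nuclei.csv`, `ihc.csv`,
`clinical.csv`, `survival.csv`), the stage outputs (`tumor_profiles.csv`,
`cytometry.csv`, `pub.csv`, `km_curves.csv`), and two reports.
`performance.json` cross-tabulates PUB = 2 against the ploidy call:

```json
{
  "tp": 15, "fn": 5, "fp": 3, "tn": 33,
  "sensitivity": 75.0,
  "specificity": 91.66666666666667,
  "sensitivity_rounded": 75,
  "specificity_rounded": 92
}
```

i.e. on this cohort the two-marker histology score identifies 15 of the 20
polyploid tumors (75% sensitivity) while mislabeling 3 of 36 near-diploid
tumors (92% specificity). `stats_report.json` holds the cohort comparisons
(e.g. serum AFP higher in polyploid tumors, one-sided Mann–Whitney
p ≈ 1e-6 on this cohort) and the log-rank tests behind the survival
curves in `km_curves.csv`.

The same stages are available individually (`polyhcc simulate`,
`call-ploidy`, `cytometry`, `pub`, `stats`) and as library functions:

```python
from polyhcc import GeneratorConfig, generate_cohort, call_cohort

cohort = generate_cohort(GeneratorConfig(seed=1))
calls = call_cohort(cohort.nuclei)
print(calls.n_polyploid, round(calls.pct_polyploid, 1))  # 20 35.7
```

## Documentation

`docs/methods.md` describes the generative model, the callers' decision
rules and tie-breaks, parameter defaults with units, and known
limitations.
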