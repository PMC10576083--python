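# Methods

## The diagnostic problem

Whole-genome-doubled (polyploid) hepatocellular carcinomas form an
aggressive subset that ordinary histopathology does not label. Two
section-based readouts identify them: (i) direct chromosome counting by
multicolor FISH, and (ii) a cheap two-marker surrogate — the abundance of
polyploid giant cancer cells (PGCCs) plus UBE2C immunostaining — combined
into the PUB score. `polyhcc` implements both, the image-cytometric
validation that links them, the statistics used to compare the resulting
groups, and a synthetic cohort generator that makes the entire pipeline
testable end to end.

## Ploidy calling from FISH spot counts

Per nucleus, the observed spot count for a pericentromeric probe
(chromosomes 7, 11, 16) estimates that chromosome's copy number. Per
tumor and probe, the **predominant copy number** is the modal nonzero
count over all tumor nuclei in the examined fields; the tumor's **average
ploidy** is the mean of the three predominant counts; the tumor is
**polyploid** iff average ploidy ≥ 2.5 (inclusive). Decision rules where a
convention was needed:

- **Zero counts** are excluded probe-wise as hybridization failure —
  whole-chromosome nullisomy is not a plausible predominant state, whereas
  5 µm FFPE sections routinely truncate nuclei and lose signals.
- **Modal ties** break to the **larger** count: sectioning only removes
  signals, so observed counts are biased downward and the larger tied
  value is the likelier truth.
- **QC, not errors**: fewer than 200 tumor nuclei or 5 fields clears the
  profile's `qc_pass` flag but still produces a call, so small specimens
  and fixtures remain analyzable. Both minima and the 2.5 cutoff are
  parameters; the cutoff is a fixed constant here because it derives from
  the bimodal shape of real cohorts, not from an algorithm this package
  could refit.
- Since the average of three integers is never exactly 2.5, the inclusive
  boundary is exposed directly as `classify_ploidy(average, threshold)`,
  the same rule `call_tumor` applies.

## Image-cytometric DNA index

Integrated nuclear DAPI fluorescence is proportional to DNA content, with
an unknown per-slide staining gain. The DNA index (C-value) of a nucleus
is `c = 2 · I / mode(I_ref)`, where the reference population is the
section's non-tumor nuclei (stroma and lymphocytes are diploid) and the
mode is located on a log2 histogram with bin width 0.05, anchored at the
sample minimum so a degenerate reference returns its value exactly. The
estimate is exactly gain-invariant. Analysis is gated to
HNF4α-positive/Ki-67-negative tumor nuclei: Ki-67+ cells are in S/G2/M and
carry 2–4C DNA regardless of ploidy, so including them would blur the
clonal signal. C-values are binned at half-integer log2 boundaries
(…, [1.5, 2.5) → 4C, …), the symmetric split between doubling classes; the
left tail below 0.5 log2 units (debris-scale values) falls into the 2C
bin. At least 20 reference nuclei are required.

## PGCCs and the PUB score

A PGCC is a tumor cell whose nucleus is at least **3× larger in sectional
area** than that of a regular cancer cell. The regular-cell baseline is
the **median area over all tumor nuclei** — robust as long as PGCCs are a
minority (the estimate degrades once they exceed roughly a third of
nuclei, which is outside the regime this score targets). A tumor is
**PGCC-abundant** when the mean density over examined fields is ≥ 1 PGCC
per 40× field; the mean-density reading (rather than "every field ≥ 1")
matches how per-field counts over five or more fields are reported in
practice. The **PUB score** is the sum of two indicators — PGCC abundance
and UBE2C staining moderate/strong — so it takes values 0, 1, 2. UBE2C
grades enter as data (`negative/weak/moderate/strong`, case-insensitive);
no attempt is made to quantify staining intensity from images. PUB = 2 is
evaluated against the FISH call as a diagnostic test, reported as the 2×2
table with sensitivity/specificity percentages (and integer-rounded
variants for reporting).

## Statistics

`polyhcc.stats` wraps well-tested routines (scipy.stats, lifelines)
behind explicit contracts; the test suite verifies them against
independent brute-force enumeration at small sample sizes. Mann–Whitney U
is one-sided with a declared direction (AFP and cytometry metrics:
polyploid > near-diploid), exact for combined n ≤ 20 without ties,
normal-approximated with tie correction otherwise. Fisher's exact test is
two-sided by pmf summation; chi-square is Pearson without continuity
correction by default and refuses tables with zero expected counts.
Log-rank is two-sided. The gene-list overlap test is the upper-tail
hypergeometric probability with a log-space tail (`logsf`), usable far
below the 1e-308 underflow limit; the universe size defaults to 20,000
protein-coding genes and is configurable.

## Synthetic cohort generator

The generator emulates the data structure of a 56-tumor surgical HCC
series with 20 polyploid tumors. Defaults (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| `n_tumors`, `prevalence_polyploid` | 56, 20/56 | cohort size and polyploid fraction |
| `truth_mode` | stratified | stratified fixes class counts exactly; stochastic samples them |
| `nuclei_per_tumor` | 250 | table size per tumor: 200 tumor + 50 non-tumor reference nuclei |
| `fields_per_tumor` | 6 | 40× fields, round-robin nucleus assignment |
| `signal_dropout` | 0.10 | per-signal loss probability (FFPE truncation) |
| `hyb_failure` | 0.05 | whole-nucleus hybridization failure probability |
| `p_tetrasomy_polyploid` | 0.14 | P(a polyploid tumor's chromosome is at 4 copies vs 3) |
| `p_trisomy_neardiploid` | 0.3 | P(a near-diploid tumor carries one trisomy) |
| `pgcc_rate_polyploid/_neardiploid` | 2.0 / 0.1 | planted PGCCs per field for abundant / sparse tumors |
| `afp_median_*` (ng/mL) | 9.8 / 193 | serum AFP medians, lognormal with log-SD 2 |
| `hazard_neardiploid` (events/yr) | 0.08 | exponential baseline hazard |
| `hazard_ratio_polyploid` | 3.5 | proportional-hazards effect of polyploidy |
| `censor_window` (yr) | (0.5, 5.0) | uniform right-censoring |

Model choices worth knowing:

- **Copy triples.** Polyploid tumors draw each chromosome's predominant
  copy from {3, 4} with P(4) = 0.14, putting the expected average ploidy
  at 3.14 — matching the cohort mean this structure is calibrated to.
  (Descriptions of such cohorts emphasize four-copy chromosomes, which
  sits in tension with a mean near 3.1; the generator prioritizes the
  mean.) Near-diploid tumors are (2,2,2) with at most one trisomy, keeping
  their averages ≤ 7/3 and preserving the bimodal gap at 2.5.
- **FISH noise.** Observed spots ~ Binomial(true copy, 1 − dropout) per
  probe, plus whole-nucleus failure zeroing all probes. Spot splitting
  (overcounting) is omitted as second-order. For dropout d < 1/3 the modal
  observed count still equals the true copy in expectation (for copy 2:
  (1−d)² > 2d(1−d) iff d < 1/3), so the caller recovers truth with high
  probability at the defaults — across the documented seeds, exactly.
- **Morphometry.** DNA content C is the copy-triple mean scaled so (2,2,2)
  ↔ 2C. Integrated DAPI = gain_t · C · lognormal(CV 10%), with a
  per-tumor gain (lognormal, CV 30%) that forces the cytometry
  normalization to be nontrivial. Nuclear area = 40 µm² · (C/2)^(2/3) ·
  lognormal(CV 15%), the section-area scaling of a volume proportional to
  DNA. Ki-67+ nuclei get a Uniform(1, 2) replication multiplier on C.
- **Planted PGCCs** carry 8× or 16× the clone's DNA (equal probability),
  i.e. 16C/32C on a diploid clone. Under the area model the 3×-area rule
  corresponds to ≥ 3^(3/2) ≈ 5.2× the clone DNA, so a 4×-DNA giant (area
  ratio 4^(2/3) ≈ 2.52) is by definition not a PGCC and is not planted —
  this keeps planted counts recoverable by the detector. In stratified
  mode the planted count is exactly `round(rate × fields)`; in stochastic
  mode it is Poisson.
- **Marker assignment.** Each tumor falls in one of four categories
  (both / UBE2C-only / PGCC-only / neither of the two PUB components) with
  class-conditional probabilities. Stratified mode allocates exact
  largest-remainder counts within each ploidy class, which pins the
  cohort-level (PUB = 2) × (true class) table at 15/5/3/33 for the default
  cohort — the unique integer table giving 75% sensitivity and a
  specificity that rounds to 92% at class sizes 20/36. Polyploid
  "not-both" tumors default to UBE2C-positive/PGCC-sparse, so 19/20
  polyploid tumors are UBE2C-moderate/strong.
- **Streams.** One seeded master generator per cohort; per-tumor
  sub-streams keyed by (seed, tumor index), so output tables are
  byte-identical across runs of the same configuration.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure — class composition,
count noise, DNA-proportional morphometry, marker conditionals, survival
hazards — not tissue reality. It has no spatial correlation within
fields, no segmentation artifacts (doublets, debris), no intra-tumor
clonal heterogeneity beyond one predominant clone plus PGCCs, no spot
splitting, and marker grades are assigned rather than measured from
staining. Passing tests therefore demonstrate that the callers implement
their stated rules and recover truth under the modeled noise, not that
the rules are optimal for real slides.

## Problem sizes and numerical choices

Cohort-level checks run the full 56-tumor, ~250-nuclei/tumor cohort at 20
replicate seeds (~15,000 nuclei per cohort); closed-form checks of the
noise model use single synthetic tumors of 10⁴–10⁵ nuclei. Exact-test
oracles enumerate all tables/assignments at totals ≤ 12. Histogram-mode
binning uses width 0.05 in log2 units; C-class bins are half-open on the
right; the PGCC area threshold and the 2.5 ploidy cutoff are inclusive.
Degenerate inputs raise typed errors (`UncallableTumorError`,
`EmptyGateError`, `InsufficientReferenceError`, …) rather than returning
silent defaults.

## Known limitations

- The median-area PGCC baseline biases upward when PGCCs are not rare.
- The DNA-index reference assumes the non-tumor compartment is diploid;
  heavily inflamed or regenerating liver could violate this.
- The ploidy caller reports one predominant clone; mosaic or multi-clonal
  tumors are out of scope.
- Survival simulation is exponential/uniform-censoring; real follow-up
  has more structure than a constant hazard.
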