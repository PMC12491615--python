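# Methods

## Scope and model

`germtriage` operates on germline small-variant call sets (SNVs and indels
shorter than 50 bp, GRCh38, 1-based chr-prefixed coordinates) from case
cohorts, with external annotations consumed as inputs: ClinVar assertion,
SIFT and PolyPhen-2 calls, Cancer Genome Interpreter (CGI) driver status,
LOFTEE pLoF flags, and gnomAD all-population / African-restricted minor
allele frequencies. The package does not align reads, call variants, or
compute any of these annotations; it also consumes — never computes —
ancestry fractions, MSI status and mutational-signature labels.

The pipeline is deliberately rule-based rather than statistical: every
decision is a threshold comparison whose outcome is recorded with a reason
code, so a triage run is an auditable funnel, not a fitted model.

### Classification rules

Writing `t_all`, `t_afr` for the gnomAD MAFs (a null value means absent
from databases and tiers as `unknown`, treated as rare):

- **PPV** — ClinVar pathogenic or likely pathogenic, max(t_all, t_afr) < 5%.
- **POV** — ClinVar VUS/absent (conflicting interpretations count as VUS;
  benign/likely benign is excluded outright), *functionally damaging*, a
  CGI driver, and max gnomAD MAF < 1%. "Functionally damaging" means SIFT
  deleterious **or** PolyPhen-2 damaging, or a stop/splice-junction
  disruption, or a frameshift carrying a LOFTEE pLoF flag. The OR-reading
  of SIFT/PolyPhen is the default (`sift_polyphen_mode: or`); an AND mode
  is available. The frameshift-via-LOFTEE path exists because frameshifts
  are not themselves stop/splice disruptions yet are legitimate
  loss-of-function candidates; both paths are recorded in the variant's
  functional flags. CGI driver status is a hard conjunct by default
  (`require_cgi_driver`), switchable to advisory for sensitivity analyses.
- **PSLF-PPV / PSLF-POV** — the corresponding class with gnomAD tier
  rare/unknown but a case-cohort MAF at or above the PSLF floor (1%)
  **backed by at least two alleles**. The two-allele requirement is a
  deliberate design choice: in a 31-patient cohort a single carrier is
  already 1/62 = 1.6%, and a lone observation cannot evidence a
  population-level low frequency. The African-restricted gnomAD MAF may
  exceed 1% without vetoing PSLF status; only the all-population tier must
  be rare.
- VUS at 1–5% gnomAD that do not qualify as PSLF are excluded
  (`low_frequency_maf`); P/LP variants in that band remain PPVs with their
  rarity tier recorded.

Candidates are then restricted to the DDR/PCa gene universe
(case-insensitive symbols); the known GT-panel subset is flagged for
prevalence reporting. All threshold comparisons are strict exactly as
written (`> 2%`, `< 1%`, `< 5%`, `< 0.3`); boundary-equal values take the
keep/lenient side.

### Frequencies

Cohort MAF is (het + 2·hom) / 2n under diploid counting for every locus,
including chrX, so that reported values sit on a single scale; a per-locus
ploidy override would be a straightforward extension but is not needed to
reproduce tabulated values. Pooled MAF sums allele counts over summed 2n
of disjoint cohorts. MAFs print to 4 decimals and VAFs to 6, which makes
output tables byte-stable under re-reads.

### Population-control screen

A variant is excluded when its southern African control (SAC) MAF, east
African control (EAC) MAF, or pooled SAC+EAC MAF exceeds 2%. One guarded
exception: a single control cohort exceeding the threshold by **at most
one allele** while the variant is absent from the other control cohort is
kept and flagged `borderline`. This encodes cautious retention of
singleton-scale control observations (2/98 alleles = 2.04%) without an
ad-hoc per-variant rule; the flag is persisted in the run summary so the
choice is visible.

### CHIP filter

Blood-derived "germline" call sets contain age-acquired clonal
hematopoiesis (CHIP). Carriers with VAF = alt/(ref+alt) < 0.3 are excluded
per carrier (a VAF of exactly 0.3 is retained). Within CHIP-associated or
CHIP-suspect genes an undeterminable VAF is excluded conservatively;
outside that scope it is retained with a warning. Retained carriers in
CHIP-associated genes carry the −0.5 ranking penalty. A variant survives
while at least one carrier does, and excluded carriers drop out of every
downstream frequency, ranking and prevalence computation, because only
inherited observations should be counted.

### Tumor evidence

LOH is called when a somatic copy-number **loss** segment overlaps the
germline position (segments are half-open `[start, end)`: a segment ending
exactly at the position does not overlap), or a somatic record at the
locus has allelic fraction > 0.65, or ≥ 15 **percentage points** above the
germline allele fraction (absolute on the fraction scale, not relative).
Allelic fractions are used raw, without purity/ploidy correction. A second
hit is any protein-altering somatic SNV/indel in the same gene at a
different position. TMB divides the somatic mutation count by a callable
genome size of 2,800 Mb by default (GRCh38 non-gap autosomal
approximation, configurable). TMB group comparisons use a pooled-variance
two-sample t-test on log10(TMB); non-positive values are dropped with a
warning, identical groups return (t=0, p=1), and zero within-group
variance with differing means raises rather than reporting an infinite
statistic.

### Ranking

Per-carrier score = sum of the applicable weights (defaults in
`RankingWeights`): CHIP-gene penalty −0.5; SAC **and** EAC MAF < 1% +1;
PPV over POV +1; pLoF +1; diagnosis age within 10 years below the cohort
reference mean +1, more than 10 years +2 (reference means 67 y SAPCS, 65 y
PPCG; scoring a cohort without a configured mean is an error); ISUP GG = 3
+0.5, ≥ 4 +1 (mutually exclusive); PSA > 60 ng/mL +1 (one conservative
threshold for all cohorts); family history of PCa +1 and of
breast/ovarian cancer +0.5 (additive when both); tumor-matched LOH and/or
second hit +1, or +0.5 when no tumor was available. Missing clinical
fields contribute 0 — absence of data is never penalized. Each carrier is
scored on their own clinical data.

Variant rank is the **sum** of carrier scores (recurrence-weighted; a
`mean` mode is available), and gene weight the sum of variant ranks.
Summation is the only aggregation under which a ten-carrier variant can
outrank any single carrier's maximum, which is the behaviour the ranking
is meant to express. Rare and PSLF variants are ranked in separate strata,
so a gene with both appears once per stratum. Ties break by carrier count
(descending) then gene symbol — rankings are fully deterministic.

Prevalence counts **unique** patients carrying ≥ 1 retained variant in the
gene filter over the case patients passing the ancestry floor (strict
`>`, default 0.9); percentages print to two decimals.

### Cross-cohort screen

"Overall MAF of the PPVs" per gene is implemented as the gene-level sum of
PPV allele counts over 2n (aggregate carrier frequency) — the only
aggregation invariant to cohort size; a mean-per-variant metric sits
behind `burden_metric: mean` since the definition is genuinely open.
Comparison cohorts are screened independently and a gene is excluded when
**either** exceeds the African burden strictly; equal burdens keep the
gene. Genes with zero comparison PPVs are flagged conserved. Shared
variants are reported with per-cohort frequencies; singleton-scale
presence in a comparison cohort annotates but never excludes.

## Synthetic cohorts

The generator emulates the study conditions: 186 + 31 cases with clinical
marginals (age normal, means 66.7/64.8 y, sd 9; PSA log-normal with means
233.6/60.8 ng/mL and log-sd 1.5; ISUP categorical with GG ≥ 4 mass
0.532/0.194; family-history Bernoulli 0.10/0.05; ancestry Beta(30,1) and
Beta(5,2); 116/31 matched tumors), 49 + 40 African controls, and
comparison cohorts (959 non-African cases, 3,209 healthy aged controls;
both scalable downwards — the tests use 300 each so that per-gene allele
budgets stay resolvable). The default variant panel plants 45 PPVs, 1
PSLF-PPV, 138 POVs and 16 PSLF-POVs plus benign, non-driver-VUS,
gnomAD-common, low-frequency, control-common, and off-gene-set decoys so
every exclusion path is exercised.

Genotypes are Hardy-Weinberg binomial(2, af) draws per patient, with
per-variant rejection resampling so that every planted variant has at
least one case carrier and its realized study MAF lies on the correct side
of the PSLF floor for its class — without this the planted label would not
be recoverable even by a perfect classifier. Carrier read depths are
Poisson(40); germline het carriers draw alt reads at Binomial(depth, 0.5),
homozygotes at fraction 1.0, and planted-CHIP carriers (probability 0.5
for carriers of CHIP-gene variants) at Binomial(depth, 0.15), which puts
the expected exclusion probability at the 0.3 cut at 0.991 and germline
retention at 0.994. A 5% fraction of PPCG carriers get no read counts to
exercise the missing-VAF policy. Tumors plant LOH with probability 0.35
(half as copy-number loss, half as high-fraction somatic records) and
second hits with 0.25 on pathogenic-class carriers, over a Poisson
background of 1.1 mutations/Mb.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, ancestry-specific site-frequency spectra, sequence
context (positions and alleles are uniform), annotation noise (SIFT/
PolyPhen/CGI calls are consistent with the planted class by construction),
and purity/subclonality of tumor fractions. Passing recovery tests
therefore demonstrate that the rules are implemented exactly and that the
filters separate the planted signal at the stated operating point — not
that the thresholds are optimal on real cohorts.

## Determinism and problem sizes

All randomness flows through one `numpy` generator seeded from the run
seed, and every iteration order is sorted, so a seed fixes the bundle and
every output byte; `run_summary.json` deliberately carries no wall-clock
field. The test suite runs the full pipeline on the default panel with
study-sized case/control cohorts, exact class recovery on a
10,000-variant panel, filter operating characteristics on 10,000 carriers
and frequency recovery over 1,000 simulations — sizes chosen so the whole
suite completes in well under a minute on one CPU while keeping binomial
sampling error an order of magnitude below the tested bounds.

## Known limitations

Structural variants are out of scope (a pLoF deletion in a candidate gene
would be missed, as would gain-of-function in oncogene candidates).
Build liftover is not performed; a run assumes a single reference build.
Age-aware CHIP modelling is not implemented — the VAF cut plus the
missing-VAF gene scope is the entire CHIP policy. The ranking weights are
fixed by design, not calibrated; the package reproduces and audits the
scheme rather than optimizing it.
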