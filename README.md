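# germtriage

Rule-based triage and weighted ranking of germline candidate variants for
prostate cancer (PCa) germline-testing panel design, aimed at cohorts of
under-represented ancestry where ClinVar and gnomAD coverage is thin.

Current PCa germline-testing (GT) panels were built almost exclusively from
European-ancestry studies. For an African-ancestry case cohort, `germtriage`
implements the discovery workflow such a study needs:

1. **Classification.** Each annotated small variant (SNV / indel < 50 bp,
   GRCh38) is labelled
   - **PPV** (potentially pathogenic): ClinVar pathogenic / likely
     pathogenic with gnomAD MAF < 5% (all-population and African-restricted);
   - **POV** (potentially oncogenic): a VUS that is functionally damaging
     (SIFT deleterious and/or PolyPhen-2 damaging, a stop or splice
     disruption, or a LOFTEE-flagged frameshift), called an oncogenic driver
     by the Cancer Genome Interpreter, and rare (gnomAD MAF < 1%);
   - **PSLF-PPV / PSLF-POV** (population-specific low-frequency): rare or
     absent in gnomAD yet at ≥ 1% frequency (≥ 2 alleles) in a case cohort;
   - or **excluded**, with one machine-parseable reason code.
   Candidates are restricted to a DNA-damage-repair (DDR) / PCa gene set.
2. **Cross-cohort screen.** Candidate genes are interrogated in non-African
   cases and healthy aged controls; a gene is dropped only when the
   comparison population carries a strictly higher aggregate PPV MAF.
3. **Population-control screen.** Variants with MAF > 2% in matched
   southern / east African controls (individually or pooled) are removed;
   a single-cohort excess of at most one allele with absence in the other
   control cohort is kept and flagged borderline.
4. **CHIP filter.** Carriers with variant allele fraction (VAF) < 0.3 are
   excluded as likely clonal hematopoiesis; carriers in CHIP-associated or
   CHIP-suspect genes with no determinable VAF are excluded conservatively.
   Filtering is per carrier — a variant survives while one carrier does.
5. **Tumor evidence.** Where a matched tumor exists: loss of heterozygosity
   (somatic copy-number loss over the locus, or a somatic allelic fraction
   > 0.65 or ≥ 15 points above the germline fraction) and Knudson second
   hits (protein-altering somatic hit in the same gene, different position).
6. **9-step ranking.** Each retained carrier is scored:
   CHIP-associated gene −0.5; control MAF < 1% +1; PPV over POV +1; pLoF +1;
   age ≤ 10 y below the cohort mean +1 (> 10 y: +2); ISUP GG 3 +0.5 (≥ 4:
   +1); PSA > 60 ng/mL +1; family history of PCa +1 (breast/ovarian +0.5);
   tumor-matched LOH and/or second hit +1 (no tumor available +0.5).
   Variant rank = sum over carriers (recurrence-weighted); gene weight =
   sum of variant ranks, with rare and PSLF variants ranked in separate
   strata. Prevalence counts unique carriers, optionally restricted to
   patients above an African-ancestry floor.

Because the patient genotype data such a study uses are access-controlled,
the package ships a first-class synthetic-cohort generator
(`germtriage.synthetic_data`) that emulates the study conditions — cohort
sizes (186 + 31 cases, 49 + 40 African controls, healthy aged controls),
clinical marginals, Hardy-Weinberg genotypes with planted variant classes,
Poisson-depth read counts separating germline (alt fraction 0.5) from
planted-CHIP (0.15) carriers, and matched tumors — together with a truth
table so recovery can be scored exactly.

## Worked example

```python
import germtriage as gt
from germtriage.synthetic_data import SimulationConfig, CohortSizes, simulate_cohorts

sb = simulate_cohorts(SimulationConfig(seed=1, cohorts=CohortSizes(mgrb=300, ppcg_euro=300)))
res = gt.run_pipeline(sb.bundle, gt.PipelineConfig(), out_dir="results/run1", seed=1)
print(res.funnel)
print(gt.report_prevalence(res))
```

prints the filter funnel

```
{'input': 334, 'candidates_classified': 236, 'gene_set_restricted': 206,
 'cross_cohort_screened': 206, 'control_screened': 200, 'chip_screened': 197,
 'excluded_by_reason': {'benign_clinvar': 40, 'chip_vaf': 3, 'common_maf': 10,
 'control_maf': 6, 'gene_set': 30, 'low_frequency_maf': 8,
 'not_cgi_driver': 22, 'not_functional': 18}}
```

— of 334 simulated panel variants, 236 classify as candidates, 30 fall
outside the DDR/PCa gene set, no gene is removed by the cross-cohort
screen, 6 are common in the African controls, 3 look like CHIP, and 197
survive (retained + excluded = input at every stage) — and the prevalence
block

```
Reported (PPV, known GT genes): 18/217, 8.29%
Cumulative predicted (PPV+POV, known GT genes): 94/217, 43.32%
Reported, African ancestry restricted: 16/177, 9.04%
Cumulative, African ancestry restricted: 84/177, 47.46%
Cumulative, all candidate genes: 184/217, 84.79%
```

i.e. 18 of 217 simulated cases carry a retained PPV in a known GT-panel
gene. `results/run1/` then holds `ppv.tsv`, `pov.tsv`, `pslf.tsv`,
`excluded.tsv`, `variant_ranking.tsv` (per-component score breakdown that
re-adds to each rank), `gene_ranking.tsv`, `gene_screen.tsv` and
`run_summary.json`.

The same flow is available from the shell:

```
germtriage simulate --seed 1 --out-dir sim --mgrb 300 --ppcg-euro 300
germtriage run --in-dir sim --out-dir results/run1 --seed 1
germtriage report --in-dir sim
```

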