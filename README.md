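# ibspanel

Candidate-gene variant analysis for irritable bowel syndrome (IBS)
case-control cohorts, focused on a seven-gene panel of carbohydrate
digestive enzyme and transporter genes: *SI*, *MGAM*, *LCT*, *TREH*,
*SLC5A1*, *SLC2A5* and *ALDOB*. Congenital deficiencies of these enzymes
produce abdominal pain, bloating and diarrhea that closely mimic IBS, so
the package asks two questions of a targeted-sequencing cohort: do common
variants in these genes shift IBS risk, and do any cases carry rare,
predicted-deleterious variation compatible with recessive monogenic or
oligogenic enzyme deficiency?

It is written for statistical geneticists and GI researchers who have a
joint-called VCF over the panel, a phenotype sheet (case/control status,
Rome-subtype, sex, site, self-reported ethnicity, 0-4 symptom ratings) and
a per-variant annotation table; and it ships a synthetic cohort generator
so every stage is testable against planted ground truth without access to
any private cohort.

## What it computes

1. **Genotype QC** — Hardy-Weinberg exact test (exclude p < 1e-6), minor
   allele frequency (keep MAF ≥ 0.01), call rate (keep > 0.95), and greedy
   windowed LD pruning (r² < 0.2, 50-variant window, 5-variant step);
   multiallelic records are split at read time and removed. For rare
   variants, a 70:30 allelic-ratio rule masks poorly balanced calls.
2. **Ancestry** — identity-by-state distances, classical MDS jointly with a
   labelled reference panel, nearest-superpopulation assignment over the
   first three components (AFR/AMR/EAS/EUR/SAS), and concordance with
   self-reported ethnicity.
3. **Association** — per-variant additive logistic regression of case
   status on minor-allele dosage adjusted for sex and the leading MDS
   components, with Wald 95% CIs: `logit P(case) = β₀ + β·g + γ'z`,
   reported as aOR = exp(β). Subtype scans compare one IBS subtype's cases
   with all controls. Genomic inflation λ is reported.
4. **Rare-variant prioritization** — a six-vote damage score (CADD > 12
   plus the categorical calls of SIFT, PolyPhen2, LRT, FATHMM, PROVEAN)
   and a four-vote conservation score (SiPhy > 12, GERP > 4.4,
   phyloP > 1.6, phastCons > 0.5); variants qualify by the voting matrix
   (damaging ≥ 4/6 and conserved ≥ 2/4, gnomAD MAF < 0.01) or by
   CADD/REVEL-style filters (MAF ≤ 0.05, CADD ≥ 10 or REVEL ≥ 0.3).
   Screens then report case-exclusive biallelic (potential compound
   heterozygous) genotypes per gene and digenic/oligogenic combinations
   across genes, with symptoms rescaled from the 0-4 Rome ratings to a
   0-10 scale.
5. **Burden testing** — a variance-component (SKAT-style) score test per
   gene over three marker sets (all variants; MAF ≤ 0.05; qualifying
   deleterious), `Q = (y-μ̂)' G W² G' (y-μ̂)` with Beta(1,25) MAF weights
   and a mixture-of-chi-squares p-value.

## Worked example

Run the whole pipeline on a simulated cohort with one planted common-variant
effect (per-allele OR 2.4) and planted recessive carriers:

```python
from ibspanel import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    seed=3,
    simulation=SimulationConfig(
        n_cases=360, n_controls=240, n_common_variants=50,
        planted_effects=((5, 2.4),),            # per-allele OR 2.4
        planted_monogenic=(("SI", 3, 0),),       # 3 biallelic SI cases
        planted_digenic=((("LCT", "SI"), 1),),   # 1 LCT+SI digenic case
    ),
)
bundle = run_pipeline(config)
top = bundle.artifacts["association_flagged"].iloc[0]
print(top.variant_id, round(top.aOR, 2), f"p={top.p:.2e}")
print(bundle.artifacts["monogenic_seqr"][["sample_id", "gene", "variant_id"]])
```

```
2:136578379:A:T 3.5 p=1.37e-05
  sample_id gene       variant_id
0     S0060   SI  3:164729596:G:C
1     S0060   SI  3:164730976:T:A
2     S0482   SI  3:164729596:G:C
3     S0482   SI  3:164730976:T:A
4     S0492   SI  3:164729596:G:C
5     S0492   SI  3:164730976:T:A
```

The top-ranked variant is exactly the planted one, with an estimated aOR
of 3.5 at this cohort size (n = 600; the estimate concentrates on the true
2.4 as n grows — the acceptance suite verifies 95% CI coverage at
n = 4,000 over 200 replicates). The biallelic screen reports exactly the
three planted *SI* carriers, each with the pair of qualifying heterozygous
variants that makes them candidate compound heterozygotes.

The same pipeline is available from the shell:

```bash
ibspanel simulate --seed 2 --out work/        # VCF + TSVs + truth ledger
ibspanel run      --seed 2 --out results/     # full pipeline + report.md
ibspanel qc --workdir work/                   # individual stages
```

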