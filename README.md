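# postgwas

Locus-to-gene inference after a genome-wide association study.

A GWAS of a complex disease — the motivating case is clear cell renal cell
carcinoma (ccRCC), where most risk variants are non-coding — ends with a
list of associated variants, not a list of genes. `postgwas` implements the
post-GWAS annotation pipeline that turns summary statistics and an LD
reference into per-locus target-gene assignments:

1. **Risk loci and conditional signals** — loci are anchored by lead
   variants with *P* < 5 × 10⁻⁸ separated by >500 kb; secondary signals are
   found by forward stepwise conditional analysis on summary statistics,
   `z_c|S = (z_c − r_cSᵀ R_SS⁻¹ z_S) / √(1 − r_cSᵀ R_SS⁻¹ r_cS)`,
   with retained signals mutually independent at r² ≤ 0.01.
2. **Fine-mapping** — per-variant Wakefield approximate Bayes factors,
   `log ABF = ½ log(se²/(se²+W²)) + ½ z² W²/(se²+W²)`, give posterior
   inclusion probabilities (PIPs); 95% credible sets are assembled by
   ranking PIPs above a 0.001 floor.
3. **Variant set enrichment (VSE)** — each locus's associated variant set
   (lead + r² ≥ 0.8 partners) is overlapped with epigenomic peaks; the
   mapping tally is compared with 50,000 LD-matched null variant sets for
   an empirical enrichment P.
4. **Activity-by-Contact (ABC)** — enhancer–gene scores
   `A_e·C_eg / Σ_{e'} A_{e'}·C_{e'}g` from ATAC/H3K27ac activity and
   chromatin-contact maps, over all elements within 2 Mb of a TSS, with
   top-150,000 selection and credible-variant linking.
5. **SMR/HEIDI** — `b_xy = b_GWAS/b_eQTL`,
   `T_SMR = z_G² z_E²/(z_G²+z_E²)` against χ²₁, with the HEIDI
   heterogeneity filter separating a shared causal variant from linkage.
6. **Two-sample MR and colocalisation** — Wald ratios, random-effects IVW,
   MR-Egger (intercept = directional pleiotropy), weighted median/mode,
   Steiger directionality, leave-one-out, PVE and power; plus
   approximate-Bayes-factor colocalisation (PP0–PP4).
7. **Motif disruption** — allele-specific log₂-odds PWM scoring with exact
   DP tail probabilities.
8. **Prioritisation ladder** — coding > SMR > ABC > closest gene, with
   SMR∩ABC consensus, union on discordance, and a low-confidence tier for
   proximity-only assignments.

A first-class synthetic-data module (`postgwas.synth`) generates every
input with planted ground truth — block-structured LD, case-control or
quantitative traits, eQTLs with shared/distinct causal variants, peak sets
with controllable enrichment, distance-decaying contact maps with planted
loops, and MR instrument sets — so the whole pipeline is testable without
any external download.

## Worked example

Run the full synthetic pipeline (four planted loci, each with an enhancer
looped to a target gene; half the loci also carry a shared-causal eQTL):

```bash
$ postgwas pipeline --seed 1 --n-loci 4 --out demo_run
{"n_loci": 4, "n_correct_targets": 4, "recovery": 1.0}
```

All four loci resolve to their planted target gene: two by SMR∩ABC
consensus, two by best ABC score (`demo_run/assignments.tsv` lists the
per-locus genes, sources and confidence tier).

The MR estimator suite on a synthetic instrument table (145 instruments,
planted log-odds effect 0.25 per SD of exposure, no pleiotropy):

```bash
$ postgwas mr --instruments inst.tsv --n-boot 500 --seed 1 --out mr.tsv
         method     beta       se            p  odds_ratio  n_snps ...  intercept  intercept_se  intercept_p
         IVW-RE 0.225123 0.039064 8.269379e-09    1.252477     145            NaN           NaN          NaN
       MR-Egger 0.180162 0.127887 1.610783e-01    1.197411     145       0.003285      0.008895     0.712426
weighted median 0.265443 0.053570 7.230003e-07    1.304008     145            NaN           NaN          NaN
  weighted mode 0.331781 0.133281 1.279812e-02    1.393448     145            NaN           NaN          NaN
```

All four estimators bracket the planted effect (OR ≈ 1.28 per SD); the
Egger intercept is consistent with zero, i.e. no directional pleiotropy —
exactly what was planted.

Each stage is also exposed separately (`simulate`, `loci`, `cojo`,
`finemap`, `vse`, `abc`, `smr`, `mr`, `coloc`, `motif`, `prioritise`); run
`postgwas --help` for options, and see `docs/methods.md` for the models
and their assumptions.

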