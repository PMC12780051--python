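# Methods

This note documents the models implemented in `postgwas`, the choices made
where the design was genuinely open, what the synthetic data does and does
not emulate, and the numerical conventions. Problem sizes quoted for tests
are the package's own desk-scale choices.

## Summary statistics, loci and conditional signals

All association inputs are tables of per-variant effect estimates
(effect allele A1, frequency, beta, SE, P) in the GCTA `.ma` dialect. The
LD reference is a genotype dosage panel aligned to the variant table;
correlations are always computed from the dosages.

Risk loci follow the threshold/distance rule: any variant with
*P* < 5 × 10⁻⁸ anchors a locus, and loci are >500 kb apart. The rule does
not by itself say how overlapping windows are resolved, so seeding is
greedy by smallest P: take the best remaining hit, remove all passing
variants within 500 kb on the same chromosome, repeat. This is
deterministic and invariant to input row order (ties break on position,
then identifier). Loci on different chromosomes never merge.

Conditional z-scores use the standard summary-data identity

    z_c|S = (z_c − r_cSᵀ R_SS⁻¹ z_S) / sqrt(1 − r_cSᵀ R_SS⁻¹ r_cS)

on standardized genotypes. Frequency/ploidy scaling of joint effects (as
in full COJO) is deliberately not modelled: at desk scale the standardized
form is exact for quantitative traits and an excellent approximation for
the liability-scale z-scores, and it is what the brute-force joint-OLS
oracle checks against (agreement |Δz| < 0.05 at n = 5000). A candidate
whose r² to the selected set exceeds 0.9 is skipped (the same style of
collinearity guard used by summary-data conditional tools; configurable);
a numerically singular selected-set matrix falls back to a logged ridge
(1e-8). Secondary signals come from forward selection at the genome-wide
threshold, and a final greedy pruning by ascending P enforces pairwise
r² ≤ 0.01 among retained signals.

## Fine-mapping

Per-variant evidence is the Wakefield approximate Bayes factor with a
N(0, W²) effect prior. W is not identified by the study design, so the
coloc conventions are adopted: W = 0.2 for binary-trait log-odds effects
and 0.15 for quantitative traits. PIPs are ABFs (optionally multiplied by
user-supplied per-variant prior weights, e.g. externally estimated
functional priors) normalised in log space; normalisation is exact to
1e-9 by construction.

Multi-signal loci are handled by conditioning: for each signal, every
variant's z is conditioned (via the identity above) on the *other*
signals, and single-effect PIPs are computed from the conditioned z with
the original SE. This preserves credible-set semantics for several
independent signals without re-implementing a sum-of-single-effects
model; it is a stand-in, not a SuSiE clone, and it has no analogue of
"allow two causal variants at a single-signal locus".

Credible sets: variants with PIP ≤ 0.001 are ineligible; eligible
variants are ranked by PIP and added while the cumulative PIP is below
0.95 (the variant that reaches the level terminates the set). If the
eligible mass cannot reach 0.95 the set is flagged unresolved rather than
silently returned. Empirical coverage of the planted causal variant
exceeds 90% over 500 simulated single-causal loci.

## Variant set enrichment

The associated variant set (AVS) of a locus is the lead plus all panel
variants with r² ≥ 0.8 to it. The observed statistic is the mapping
tally; following the variant-set-enrichment literature the default tally
is per-locus binary (a locus counts once however many of its variants sit
in peaks); a per-variant mode is exposed as an option since the wording
of tallies differs between descriptions of the method. Null sets replace
each AVS with the AVS of a random panel variant whose LD-partner count is
closest to the real AVS size (ties uniform; "same LD characteristics" is
operationalised as partner-count matching because partner count is the
dominant determinant of overlap opportunity). The empirical P is the
literal proportion of null tallies ≥ observed; a (r+1)/(n+1) smoothed
variant is available. Null variants may optionally be restricted to
non-risk variants (`exclude_observed`), matching designs that sample from
a null-variant database.

Two caveats are measured rather than hidden. First, the tally is
discrete: because P includes ties (≥), its null mean exceeds ½ by half
the tally's point mass, so the null P distribution is close to, but not
exactly, uniform — a Kolmogorov–Smirnov statistic of ~0.1 remains at desk
scale even though the operating tail is calibrated (fraction of P ≤ 0.05
within [0.03, 0.08] over 500 null datasets). Second, the permutation
null needs a variant pool much larger than the risk set; the test
configuration uses 20 risk blocks embedded in a 150-block panel.

## Activity-by-Contact

Element activity is the geometric mean of ATAC and H3K27ac counts after
each track is scaled to reads per million, so uniform rescaling of either
track (or of the contact map) leaves scores unchanged. Contact is the
map entry at (element-midpoint bin, TSS bin) plus a pseudocount equal to
the fitted expected count at 1 Mb; the expectation comes from a log-log
regression of mean diagonal count on bin distance, and is also the
fallback for bin pairs outside the map. Scores are normalised per gene
over all candidate elements within 2 Mb of the TSS, promoters included
(self-promotion is part of the normalising sum, per ABC convention);
selection keeps the global top 150,000 interactions with boundary ties
retained. Raw counts are used directly — matrix balancing is upstream
processing, not part of the model. Defaults gamma = 1.0 and reference
distance 1 Mb are declared choices, configurable.

A locus links to a gene when any credible-set variant lies inside an
element of a selected interaction targeting that gene; per-locus links
report the best supporting score, and a cross-cell comparison flags loci
whose linked gene sets are identical between two cell contexts.

## SMR and HEIDI

SMR at the top cis-eQTL variant: b_xy = b_GWAS/b_eQTL and
T_SMR = z_G²z_E²/(z_G²+z_E²) against χ²₁. HEIDI tests whether b_xy is
constant across the cis window: deviations d_i = b_xy(i) − b_xy(top) get
a delta-method covariance from the two studies' SEs and the panel LD, and
the sum of squared standardised deviations is referred to a seeded
Monte-Carlo sample (default 10,000 draws) of its null multivariate
normal — exact at any size, in place of a moment-matching approximation.
Eligible variants: eQTL P < 1.6 × 10⁻³, r² to the top variant within
[0.05, 0.9], capped at the 20 strongest (the conventions of the SMR
software family); fewer than three eligible variants makes the test "not
testable", which the retention filter treats as a flagged pass
(configurable) so sparse windows are not silently discarded. Retention:
top eQTL variant within 100 kb of a risk variant, P_SMR < 0.05,
P_HEIDI ≥ 0.05.

## Two-sample MR and colocalisation

Instruments: exposure P < 5 × 10⁻⁸, MAF > 0.01, greedy pruning to
pairwise r² < 0.01. Harmonisation aligns outcome effects to the exposure
effect allele and drops palindromic variants with allele frequency in
[0.4, 0.6]. Estimators follow the conventions of the standard two-sample
MR toolkits: first-order Wald SEs; IVW under multiplicative random
effects with the residual scale floored at 1; MR-Egger on instruments
oriented to positive exposure effect, weighted by inverse outcome
variance, t-based P with k−2 df and the same scale floor (two instruments
give an exact fit, flagged); weighted median by interpolated weighted
CDF; weighted mode as the argmax of a weighted Gaussian-kernel density
with a MAD-based bandwidth scaled by a tuning factor (default 1).
Median/mode SEs come from seeded parametric bootstraps (default 5000
draws). Steiger compares summed per-variant r² (z²/(z²+n−2); for the
binary outcome this is the observed-scale approximation — the stated
prevalence is reported alongside, not used to rescale) via Fisher-z.
PVE = Σ 2f(1−f)β² on the standardized exposure; analytic power uses the
non-centrality approximation with the outcome case fraction.

Colocalisation enumerates H0–H4 from per-variant Wakefield log-ABFs with
priors p1 = p2 = 1e-4, p12 = 1e-5. All sums are in log space; the H3 term
ΣA·ΣB − Σ(A_iB_i) cancels catastrophically when one variant dominates
both traits, so for windows up to 2000 variants the off-diagonal pair sum
is computed exactly (O(m²)), with the log1p fallback above that.

## Motif disruption

Position frequency matrices (JASPAR dialects, parsed with Biopython)
become log₂-odds weight matrices with a total pseudocount of 0.8 split in
proportion to the background (default uniform 0.25, configurable).
Scanning takes the maximum over both strands and all windows; for allele
scoring, only the windows covering the variant (flanks trimmed to k−1)
are examined — the disruption question, not genome-wide scanning.
Ambiguous bases contribute the background-expected score at their
position. The score's significance is the exact background tail
probability computed by convolving per-position score distributions on an
integer grid of step epsilon (default 1e-3 bits); the convolution is
exact on the discretised scores (it matches 4^k enumeration to 1e-9) and
the discretisation perturbs the score threshold by at most k·epsilon/2.
The allele effect class uses absolute score-change thresholds in bits
(strong ≥ 1.0, weak ≥ 0.4; configurable). The log-odds scoring variant is
implemented and so labelled; information-content weighting is not.

## Target-gene prioritisation

Evidence priority: coding > SMR > ABC > closest gene. Coding evidence
(a credible-set coding variant; deleteriousness annotations such as CADD
are input columns, never computed here) settles a locus. "Consensus" of
SMR and ABC is their intersection; an empty intersection ("discordant")
retains the union; ABC alone contributes its single best-scoring gene;
the closest-gene fallback is the only route to the low-confidence tier.
Equidistant closest genes are all reported with a tie flag, and an
intronic flag marks leads inside a gene body when bounds are provided.

## Synthetic data

The generators are pure functions of (configuration, seed); per-stage
child seeds are fixed offsets of the global seed, so each stage is
independently reproducible. LD is block-diagonal: two latent haplotypes
per individual from an equicorrelated normal (correlation rho within a
block, zero across), thresholded at each variant's MAF quantile —
controllable r² without coalescent machinery. Quantitative traits add
unit normal noise to the planted genetic score; binary traits threshold
the liability at the case fraction and are analysed by per-variant
logistic fits. eQTLs share the GWAS causal variant or use a distinct
variant from the same block. Peaks are uniform background intervals plus
a covering peak per designated target with probability 1 − 1/enrichment,
merged to non-overlap. Contact maps are symmetric Poisson draws around a
(d+1)^(−gamma) expectation with planted loop counts added. MR instrument
tables are oriented to the exposure-increasing allele (as harmonised
tables are), so a constant planted pleiotropy term is directional and
recoverable by the Egger intercept.

Deliberately not emulated: recombination-map realism, population
structure, imputation error, strand ambiguity in the exposure study,
overlapping GWAS/eQTL samples, read-level noise in activity counts. A
passing suite therefore demonstrates correctness of the statistical
machinery under its stated assumptions, not robustness to those
real-data complications.

Default study conditions in the test suite: panels of 250–5000
individuals; single-block loci of 12–40 variants with rho 0.3–0.85;
planted standardized effects 0.25–0.3; VSE panels of 150 blocks of 8
variants with 20 risk loci; MR sets of 30–145 instruments with exposure
effects 0.03–0.10 (SE 0.003) and outcome SE 0.03. These are sized so the
full suite runs in a few minutes while keeping every Monte-Carlo check at
the replicate counts stated in its test.

## Known limitations

* The fine-mapping stand-in assumes one causal variant per signal after
  conditioning; heavily overlapping signals degrade its credible sets.
* HEIDI's delta-method covariance needs reasonably large samples; its
  type-I error runs slightly above nominal at n in the hundreds.
* The VSE empirical P is discrete; see the calibration caveat above.
* The ABC contact model uses raw counts plus a fitted pseudocount;
  normalised/balanced matrices are accepted but not produced.
* Steiger's binary-outcome r² is an observed-scale approximation.
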