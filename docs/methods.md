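# Methods

## Scope and model

`mirsnp` analyses the genetics of variants lying in (or near) miRNA
binding sites of inflammatory genes, in two stages: candidate
prioritization (GWAS screen → LD-proxy expansion → binding-site
intersection → pathway filter) and case-control association (HWE,
genetic-model odds ratios, haplotype/LD statistics, cumulative two-locus
genotype comparisons). All coordinates are 0-based half-open internally;
VCF converts at the boundary, BED is taken as-is.

## Prioritization

**GWAS screen.** Hits with p < `gwas_p_threshold` (default 1e−6) enter the
expansion. The threshold is strict (<), matching the usual reading of a
"minimum significance level".

**LD-proxy expansion.** For each index variant present in the phased
panel, every variant on the same chromosome within `proxy_window_bp`
(default 1 Mb — a conventional proxy-search bound; the window is a design
choice, not a biological constant) with r² ≥ `r2_threshold` (default 0.6,
inclusive) is a candidate. r² is the LD measure used for thresholding;
D and D′ are computed alongside for reporting. An index absent from the
panel is recorded in a skipped list, never fatal. Pairwise r² on a phased
panel is exact gamete counting; no block-partitioning algorithm is
implemented — only pairwise statistics are reported.

**Binding-site intersection.** Sites are half-open intervals; each is
extended by `flank_nt` (default 25 nt) per side, clamped at zero. The
boundary is inclusive in the ±25 sense: a variant exactly 25 bp upstream
of the site start is a flank hit; 26 bp is out. Placement is `in_site`
when the position falls in [start, end), `flank` otherwise within the
extension. Overlapping sites each yield their own interaction (counts are
per miRNA:site pair, not per unique variant), and strand is carried for
reporting but does not affect intersection. The implementation uses an
interval tree; its contract is checked against an O(n·m) double loop in
the tests.

**Pathway filter.** An interaction survives if its gene belongs to at
least one pathway (restricted to inflammatory-flagged pathways by
default); multiple memberships become multiple annotations on a single
interaction.

## LD and EM haplotype estimation

Conventions: allele 1 = alt; D = f(alt,alt) − p₁p₂;
D′ = D / min(p₁(1−p₂), (1−p₁)p₂) for D > 0, else
D / min(p₁p₂, (1−p₁)(1−p₂)); r² = D²/(p₁(1−p₁)p₂(1−p₂)). A monomorphic
locus gives a flagged `defined=False` result with zeros rather than NaN
propagation, so downstream tables stay printable.

Unphased two-locus haplotype frequencies come from EM on the 3×3 joint
genotype table. Only the double heterozygote is phase-ambiguous; the
E-step splits it between cis (AB/ab) and trans (Ab/aB) in proportion to
the current frequency products, and the M-step renormalizes expected
haplotype counts. Initialization is at linkage equilibrium from the
observed allele frequencies, which the EM updates preserve exactly (both
phase resolutions contribute the same allele counts); an exactly
symmetric likelihood therefore stays at the initialization fixed point
and is flagged with a note. Defaults: tolerance 1e−10 on the max
frequency change, 1000 iterations; non-convergence sets
`converged=False` instead of raising. The log-likelihood trace is stored
and asserted monotone in tests.

## Association statistics

**HWE.** χ² goodness of fit with df 1 and *no* continuity correction:
recomputing the published control-group p-values (0.079, 0.054) from the
corresponding genotype counts succeeds only without Yates correction
(with it, ≈0.10), which locks the choice. Controls only, per BMI stratum.
Monomorphic variants are flagged undefined.

**Genetic models.** Dominant (carriers vs ref-hom), recessive (alt-hom vs
rest), overdominant (het vs both homs), three codominant pairings, and
allelic (2n allele counts). The first-listed class is the reference
(OR = 1) row. Crude OR is the cross-product with Woolf CI; any zero cell
triggers Haldane–Anscombe +0.5 (flagged `corrected`); a zero margin
leaves the OR undefined rather than infinite.

**Adjustment.** Logistic regression by maximum likelihood (Newton/IRLS,
via statsmodels behind the module surface) with Wald CIs and p-values —
Wald rather than likelihood-ratio because it matches conventional OR/CI
reporting. The default covariate set is age, sex, diabetes, family
cancer history and smoking, configurable. Complete separation is flagged
with no estimate reported; rank deficiency raises naming the collinear
columns. With a sole binary predictor the fitted exp(β) equals the crude
cross-product OR (saturated identity, tested to 1e−6).

**Cumulative genotypes.** Per group, joint genotype frequencies over
complete cases (typed at both loci) plus EM haplotype frequencies.
Pairwise group comparisons per genotype class use Pearson χ² without
correction, switching to Fisher's exact test when any expected count is
below 5 (a fixed rule, since published practice mixes both tests without
stating one); both Fisher sidednesses are computed and the two-sided
value reported.

**Multiplicity.** No multiple-testing correction is applied (α = 0.05
per test); reports carry the number of tests performed so readers can
apply their own.

**Contrasts.** Strata are derived from BMI with cutoffs 25/30 (25.0 →
overweight, 30.0 → obese, per the inequalities 25 ≤ BMI < 30 and
BMI ≥ 30; BMI < 18.5 is excluded at ingest). Contrasts are fully
user-specified as `status:stratum` pairs — this sidesteps the ambiguity
of whether BMI-only comparisons pool cases and controls; the defaults
provide both pooled (`any:obese` vs `any:overweight`) and case-only
versions. Strata under 10 samples are skipped with a warning.

## Synthetic data

The generator emulates the study conditions: a phased reference panel
standing in for a haplotype resource, and a 430-subject cohort (215
cases, 215 controls by default) with the demographic shape of a
mid-sized case-control study — age ~ Normal(56, 11) years, ≈47% male,
BMI mixture 27/44/29% normal/overweight/obese (uniform within class
bands), covariate prevalences 12% diabetes, 23% family cancer history,
20% smoking, with log-odds effects on case status of 0.02/yr (age), 0.3
(sex), 0.5 (diabetes), 0.4 (family history), 0.4 (smoking). All
configurable.

LD is induced by copy-with-redraw rather than coalescent simulation: a
proxy column copies its parent and, with probability e, redraws from
Bernoulli(MAF). At matched MAFs the allele correlation is exactly 1 − e
in expectation, so e = 1 − √r² hits any feasible target; the pairwise LD
the analyses consume is all the structure needed. Genotypes pair two
panel chromosomes at random; case status follows a logistic model whose
intercept is solved by root-finding so the expected case fraction matches
the spec; genotype effects enter as model-encoded terms with planted
odds ratios. Missingness is completely at random.

What the generator does **not** emulate: recombination maps, population
structure/admixture, genotyping error beyond MCAR missingness, covariate
correlation with genotype (no confounding by design), and realistic
binding-site sequence context. Passing tests therefore demonstrate the
statistical machinery is correct under the stated model, not that real
cohort data meet its assumptions.

## Numerical choices and problem sizes

- EM oracle in tests: brute-force likelihood grid (coarse 0.01 full
  simplex, fine 1e−3 locally) on 20-sample tables; agreement within
  2e−3.
- Recovery runs use n = 20,000 (point estimate) and 200 replicates at
  n = 2,000 (CI coverage); calibration uses 2,000 HWE replicates at
  n = 200, MAF 0.3, and 500 null cohorts at n = 430 — sizes chosen to
  make sampling noise small relative to the tolerances while keeping the
  default runs quick.
- Threshold comparisons (r², flanks) are inclusive; ties in the EM at
  exact symmetry resolve to the documented fixed point.
- Seeds: every stochastic routine takes an explicit seed; identical
  seeds give byte-identical outputs (integer-state PCG64 generator).

## Known limitations

- Two-locus haplotypes only; no multi-locus phasing or haplotype blocks.
- The published adjusted odds ratios cannot be recomputed without the
  original individual-level covariates; the package instead verifies the
  estimator's identities and its recovery of planted effects.
- Binding-site coordinates are build-agnostic: all inputs must share a
  genome build; no liftover is performed.
- Pathway membership is a flat gene-set lookup; no topology or evidence
  weighting.
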