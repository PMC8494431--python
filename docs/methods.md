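# Methods

## Data model and quality control

Genotypes are biallelic autosomal hard calls (0/1/2 copies of the B allele,
or missing; never imputed), read and written in PLINK text (PED/MAP) and
binary SNP-major (BED/BIM/FAM) layouts. Coordinates are 1-based inclusive
base pairs, the map-file convention; BED export converts to 0-based
half-open at write time. Only chromosomes 1–22 are modelled; non-autosomal
rows are dropped at read time with a logged count.

Pre-analysis QC applies, in a fixed order chosen so drop reports are
reproducible: minor allele frequency ≥ 0.05 (all samples, non-missing
calls), per-variant missingness ≤ 3%, Hardy–Weinberg exact-test p ≥ 10⁻⁶
among controls, then sample call rate ≥ 97%. The HWE test is the plain
two-sided exact test (probabilities of all heterozygote counts with the
same allele totals no larger than the observed configuration are summed);
a mid-p variant and a 1-df chi-square alternative sit behind flags.
Monomorphic input returns p = 1 by convention. MAF and missingness are
computed over all samples because the control-only restriction is specific
to the HWE filter; this is a declared choice. Surviving samples gain a
`missing_fraction` covariate (missing calls / variants after variant QC).

## ROH calling

The caller is a native implementation of the two-step sliding-window
procedure with the 1.5-Mb parameter set: 50-SNP windows, ≤ 1 heterozygote
and ≤ 5 missing calls per homozygous window, 5% hit threshold, and segment
thresholds of ≥ 100 SNPs, ≥ 1,500 kb, ≤ 50 kb/SNP average density, ≤
5,000 kb maximum internal gap. Decisions the procedure's prose leaves open,
fixed here:

- **Window edges.** Near chromosome ends a SNP is covered by fewer than 50
  windows; the hit ratio's denominator is the number of windows that exist,
  so edge SNPs remain flaggable. A chromosome shorter than one window is
  scanned with the single truncated window.
- **Run assembly.** Candidate runs are maximal flagged stretches; there is
  no additional run-level heterozygote cap beyond the window rule. The
  >5,000 kb gap rule splits runs *before* thresholding, so an oversized gap
  can never be internal to a segment. Run ends are trimmed inward to the
  nearest non-missing homozygous genotype so segments start and end on
  evidence.
- **Lengths.** `length = end − start + 1` bp over the member SNP positions;
  alternative endpoint conventions differ by a few bp, far below every
  threshold's granularity.
- Because one heterozygote per window is tolerated, flags typically start
  one SNP inside a homozygous island and may extend a few SNPs into a
  homozygous-by-chance flank; called segments therefore track planted
  tracts to within roughly one inter-SNP spacing per end.

The scan is vectorized across samples per chromosome (cumulative-sum window
counts); calling a 4,000-sample study on a 10,000-SNP map takes a few
seconds on one core.

## Burden metrics

`FROH` sums segment lengths and divides by 3×10⁹ bp, the conventional
autosome size. Under chromosome-exclusion sensitivity analyses the
denominator stays 3×10⁹ so that effect sizes remain comparable across
runs; a `renormalize` flag subtracts excluded chromosome lengths instead.

`F3` ("correlation between uniting gametes") averages
`[x² − (1+2p)x + 2p²]/[2p(1−p)]` over non-missing SNPs with 0 < p < 1.
Per genotype the term is `p/(1−p)` (x=0), `−1` (x=1), `(1−p)/p` (x=2),
which the implementation exploits as three weighted counts; the tested
contract is exact agreement (≤ 10⁻¹²) with the naive per-SNP loop. Allele
frequencies are estimated per study from all non-missing calls
(cases + controls), mirroring per-study analysis.

## Association testing

Principal components come from genotypes standardized by mean 2p̂ and sd
√(2p̂(1−p̂)) with missing calls mean-imputed for this step only, via a
seeded randomized SVD; scores are unit-variance with signs fixed by making
each component's loading sum positive, so repeated runs are identical. No
LD pruning is applied at these desk scales; it is an option, and real-data
fidelity of PCs is out of scope.

The burden and bin models are logistic regressions fit by Newton/IRLS
(statsmodels backend, ≤ 50 iterations), adjusting for age, sex, missing
fraction and PC1..PC10 where present. Constant covariate columns — e.g.
sex in an all-female study — are dropped with a logged warning. Wald SEs
come from the observed-information inverse; detected separation or
non-convergence is reported as `converged=False`. A Firth-penalized fit
(Jeffreys-prior score correction) is available behind a flag for sparse
exposures.

The bin scan tiles each autosome with 500-kb bins anchored at position 1
(the anchor is unstated in the procedure; position 1 is the declared
choice). Each segment contributes its midpoint `floor((start+end)/2)` to
exactly one bin; a sample is exposed at a bin iff any of its segments'
midpoints land there (indicator, not count). Bins with fewer than 5 exposed
individuals overall, or with exposure confined to one arm, are reported as
skipped with a reason rather than fit — a guard against separation; the
choice is declared, not inferred from the original pipeline.

## Meta-analysis

Burden estimates combine by DerSimonian–Laird random effects: weights
w = 1/SE², Q = Σw(β−β_FE)², τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)),
re-weights 1/(SE²+τ²), normal two-sided p. The bin scan combines by
inverse-variance fixed effects (the effect-size scheme of the standard
GWAS meta tool); either method can be requested for either analysis.
I² = max(0, (Q−(k−1))/Q)·100 and p_het is the upper chi-square(k−1) tail
at Q. No continuity or Hartung–Knapp adjustment is applied, matching the
named tools' defaults. Leave-one-out rows re-run the chosen method with
each study omitted. Bonferroni control divides α = 0.05 by the number of
combinable bins, literally.

## Synthetic cohorts

The generator plants autozygosity explicitly rather than simulating
pedigrees: ground truth must be exact per sample for recovery tests, and
pedigree realism is a non-goal. Per genome, a Poisson(λ = 6) number of
tracts with lengths 1,600 kb + Exponential(mean 900 kb) are placed
uniformly over the positions that keep each tract inside a chromosome and
disjoint from earlier tracts (exact feasible-start sampling, so placement
fails only when the genome is genuinely full). Inside a tract the genotype
is homozygous with the B allele chosen by its frequency; outside,
Hardy–Weinberg draws; every call flips to a heterozygote with error
probability ε = 0.002, small enough that the 1-het-per-50-SNP window
allowance keeps planted tracts callable. Two subpopulations with
Balding–Nichols divergence (Fst = 0.005) supply mild stratification.

Disease status follows logit P(case) = α + β_FROH·FROH_true +
β_age·(age−60) + β_sex·male (defaults α = −1, β_FROH = 20, β_age = 0.02,
β_sex = 0.3), sampled retrospectively: candidates are drawn until the case
and control quotas are met exactly, as in case-control designs, and
genotypes are generated only for selected samples. An optional risk locus
adds, with probability q, an extra tract centred on a chosen region and an
extra log-odds term for carriers — the mechanism behind planted-risk-bin
tests. All randomness flows from one seed through a splittable generator.

**Default scale and what it shows.** The default genome is 2 chromosomes ×
60 Mb with 10,000 SNPs (~12 kb spacing), so a minimum-length tract holds
~130 SNPs and remains callable; tract intensity puts the median FROH
(fixed 3×10⁹ denominator) at ≈ 0.5%, inside the 0.38–0.77% band observed
across real outbred GWAS. One scale artifact follows: F3 averages over
*typed* SNPs, so on a 120-Mb simulated genome its magnitude is the tract
fraction of the simulated genome (~25× FROH), whereas on a real 3-Gb
autosome the two coincide. Tests therefore compare each metric to its own
truth scale. The generator omits LD, imputation error and somatic
mosaicism; passing tests demonstrate correctness of the pipeline's
inference given the stated error model, not robustness to those
real-data features.

## Validation problem sizes

The recovery suite runs 100 studies of 2,000 cases / 2,000 controls at the
default genome and checks that the full caller→burden pipeline covers the
true β = 20 within ±2 SE in ≥ 93 studies; null calibration uses 500
association-stage replicates at 250/250. Caller specificity uses 20 seeded
all-HWE genomes of 50 samples × 20,000 SNPs (zero segments expected);
sensitivity uses 50 planted tracts of 2.0–3.5 Mb at ε = 0 (all detected).
Bin-scan checks use a 60-bin grid with a planted OR-3 locus (~500 exposed
of 4,000) and 20 null pipeline scans for the Bonferroni false-positive
count. `scripts/acceptance.py` repeats these at 40 studies / 300
replicates / 8 null scans.

## Known limitations

- Hard calls only: no dosages, multi-allelic sites, X chromosome or
  imputation.
- The caller reproduces the sliding-window heuristic, not LOD-score or
  IBD-based segment methods; homozygosity below 1,500 kb is by design
  unmeasured.
- PCs are computed without LD pruning; adequate for the simulated
  stratification, not a substitute for a production ancestry pipeline.
- The HWE filter removes variants at loci where autozygosity itself is
  common (excess homozygosity mimics HWE failure); planted-risk-locus
  simulations keep locus frequencies modest for this reason, and the same
  caveat applies to any real recessive locus of high carrier frequency.
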