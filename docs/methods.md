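# Methods

This note documents the statistical models implemented in `tropiscan`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that affect results.

## Weir–Cockerham Fst

For each biallelic locus and each population *i* the estimator uses the
diploid sample size *nᵢ* (non-missing calls only), the alt-allele frequency
*p̃ᵢ* and the observed heterozygote frequency *h̃ᵢ*. With *r* populations,
n̄ = Σnᵢ/r, n_c = (Σnᵢ − Σnᵢ²/Σnᵢ)/(r−1), p̄ and h̄ the nᵢ-weighted means,
and s² the weighted among-population variance of *p̃ᵢ*, the components are

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄) ]
    c = h̄/2

and θ̂ = Σa / Σ(a+b+c) over informative loci (ratio of sums, not mean of
ratios). Conventions:

* **Missing data** are handled complete-case per locus within each
  population, so *nᵢ* varies across loci. This is the only defensible
  choice without imputation and it changes n_c per locus.
* Loci with a+b+c = 0 (e.g. monomorphic across the populations compared),
  with fewer than two populations called, or with n̄ ≤ 1, are flagged
  uninformative and excluded from the ratio.
* Negative θ̂ is reported as-is; clamping to 0 is a display decision, not an
  estimator property.
* The permutation test shuffles individuals between the two labels with
  group sizes preserved ("randomization of the dataset" is read as label
  randomization); p uses the add-one rule so it can never be 0.

## r² and LD decay

Phased r² counts the four haplotype classes directly. Genotype r² runs EM on
the four haplotype frequencies; only the double-heterozygote class is
phase-ambiguous and is split between coupling and repulsion by the current
iterate. EM is initialised at linkage equilibrium (p_A·p_B products), making
it deterministic — no random restarts; convergence tolerance 1e-8 on the
frequency vector, cap 1000 iterations (a non-converged pair warns and
returns the last iterate; the observed-data log-likelihood is available and
non-decreasing). Monomorphic loci yield NaN ("undefined"), never 0.

Decay profiles bin all intra-chromosomal pairs with gap ≤ max_dist into
half-open [lo, hi) bins (default 10 kb up to 1 Mb); the "r² at 10 kb"
summary is the mean of the [0, 10 kb) bin. No pruning is applied — every
marker pair enters its bin.

## EHHS, iES, ln(Rsb)

EHHS at focal *s*, extension *x* groups the N haplotypes by identity over
every marker from *s* through *x* inclusive and uses the unbiased
homozygosity H(s,x) = Σₖ nₖ(nₖ−1)/(N(N−1)), normalized by the focal-site
homozygosity H(s,s) from grouping on the focal allele alone. EHHS is 1 at
the focus and non-increasing outward (extension refines the grouping), which
the scan exploits: once EHHS falls below the integration threshold the
profile is finished.

iES integrates EHHS over physical position by trapezoids, each direction out
to the last marker with EHHS ≥ 0.05 (truncation threshold) and never across
an inter-marker gap above 500 kb. Both values are configurable; 0.05 is the
conventional EHH support cutoff and 500 kb prevents chip gaps from
contributing fictitious area. An isolated SNP has iES = 0 and is excluded
from the contrast.

ln(Rsb) = ln(iES_A/iES_B) per SNP, standardized genome-wide as
(x − median)/SD. Thresholding is applied to the standardized scores; raw
scores are emitted alongside so either convention can be reproduced. The
significance rule flags the empirical two-sided tail of total mass 1%
(0.5% per side), excluding ties at the cutoff: with n SNPs, exactly
⌊0.005·n⌋ distinct scores per side. One-sided modes are available. The
two-sided default reflects that sweeps in *either* population are of
interest and that the flagged fraction should total ~1%. Intervals cluster
significant SNPs per chromosome while the gap to the previous member is
< 1 Mb *and* the score sign is unchanged, and are emitted with ≥ 2 members;
sign-homogeneity makes each interval attributable to one population
(negative = slower decay in population B of the contrast).

## Population structure

PCA mean-imputes missing dosages per locus, estimates the allele frequency
with a pseudocount p̂ = (1 + Σg)/(2 + 2n) and scales entries as
(g − 2p̂)/√(2p̂(1−p̂)) (the EIGENSOFT family of normalizations), then takes
the SVD of the centred matrix. Monomorphic loci are dropped; output is
deterministic up to component sign.

The p-distance on genotypes is the allele-sharing distance
d = mean(|gᵢ − gⱼ|)/2 over loci complete in both individuals — the standard
genotype analogue of a sequence p-distance; population-level distances
average d over cross-population pairs. Neighbor joining uses the Q
criterion with ties broken at the smallest taxon-index pair (deterministic),
clamps negative branch lengths to 0, and resolves the final three nodes by
the three-point formulas. Bootstrap support resamples loci with replacement
and reports, per internal edge of the full-data tree, the fraction of
replicates containing the same leaf bipartition.

## Enrichment

Genes overlap an interval if their (optionally flank-extended) span shares
≥ 1 bp with it; coordinates are 1-based inclusive internally, converted at
BED boundaries. Over-representation is the one-sided hypergeometric tail
P(X ≥ k) with universe N, set size K, list size n — by default the universe
is every gene in the supplied annotation (overridable, since enrichment is
sensitive to the universe). Benjamini–Hochberg step-up adjusts the p-values;
sets disjoint from the universe are skipped with a recorded reason.

## The synthetic-data generator

The generator is the package's test substrate and benchmark input; its
defaults define the study conditions used by the test suite and the
acceptance script.

* **Differentiation**: ancestral frequencies Uniform(0.05, 0.95); population
  frequencies Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with target
  F = 0.05 by default (the regime of a breed population recently split from
  its source).
* **LD**: per population, 20 founder haplotypes drawn site-wise from the
  population frequencies; each sample haplotype is a founder mosaic with
  per-gap switch probability 1 − exp(−ρd), ρ = 5e-6/bp. 2000 markers at
  ~60 kb mean spacing on a 120 Mb chromosome emulate one chromosome of a
  50K bovine chip.
* **Sweep**: a fraction f (default 0.9) of one population's haplotypes have
  the window ±core/2 around a focal marker overwritten by a single donor
  (founder 0 of that population — deterministic), leaving long shared
  haplotypes detectable by the scan. A truth BED records the core.
* **Genotypes**: haplotype row pairs summed, with optional independent
  missingness. `simulate_genotypes` additionally provides direct
  Binomial(2, p_il) sampling — the infinite-founder limit.

Two generator trade-offs matter for interpreting test results:

1. **Founder drift inflates realized Fst.** A K-founder bottleneck adds
   ≈1/K of drift on top of the Balding–Nichols target, so mosaic
   populations at target 0.05 realize Fst ≈ 0.1–0.15. Analyses whose
   object is Fst recovery therefore use the Binomial path, which is
   unbiased; the mosaic path is used where LD/haplotype structure is the
   object.
2. **LD magnitude vs haplotype diversity.** Short-range r² in the mosaic is
   ≈1/(K−1); reproducing chip-like r² ≈ 0.45 at 10 kb would need K ≈ 3
   founders, which makes most loci monomorphic per population and gives
   EHHS a high long-range plateau that masks sweeps. K = 20 and ρ = 5e-6
   keep the EHHS plateau (~2/K) near the 0.05 truncation threshold and the
   decay scale at ~100 kb (the shape of breed-panel LD decay), at the cost
   of r² magnitude: the default panel measures mean r² ≈ 0.06 in [0,10 kb)
   falling to ≈ 0.03 at 100 kb. Passing tests therefore demonstrate decay
   *shape* and scan calibration/power, not chip-level LD magnitude.

A known structural effect of the hard-edged sweep model: every SNP inside
the core integrates essentially the same shared span, so all ~17 core SNPs
(1 Mb at 60 kb spacing) receive near-identical extreme scores and compete
for the ~⌊0.005·n⌋ = 10 lower-tail slots of a 2000-SNP scan. Interval-level
recovery of the sweep is near-certain, but the *focal* SNP specifically is
flagged in only ~40–60% of replicates; a smoothly decaying sweep edge (real
recombination) would not show this flat-top degeneracy.

The generator does not model demography (bottlenecks, admixture, growth),
mutation, gene conversion, realistic recombination maps, genotyping error,
or chip ascertainment bias. Results on synthetic data bound what the
methods can do under a clean two-level model; they do not certify behaviour
under those real-data complications.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 20 seeds × 5000 loci ×
2 × 30 diploids for Fst recovery; 200 (tests) / 100 (script) repetitions ×
200 permutations for type-I error; 20 seeds of the default 2 × 40-diploid,
2000-marker panel for scan power; 100 bootstrap replicates over 2000 loci
for tree support; 100 random ≤ 8-taxon additive matrices for NJ exactness.
All stochastic steps flow from explicit integer seeds through
`numpy.random.default_rng`; pipeline runs of the same config are
byte-identical (the manifest records SHA-256 checksums of every artifact).

## Other conventions and edge cases

* Coordinates 1-based inclusive internally; BED output is 0-based
  half-open. Missing genotype sentinel is −1, never conflated with dosage 0.
* PED input with no declared reference allele counts the lexicographically
  later observed allele as alt (all downstream statistics are orientation
  invariant); single-allele loci take "." as the unseen alt and dosage 0.
* The package does not phase: phased input is a precondition of the EHH
  statistics, and unphased or missing GT fields in a VCF are errors, not
  warnings.
* LD pruning (for PCA/tree inputs) is greedy per sliding window; the
  lower-MAF member of an offending pair is removed (tie: later position),
  making the output deterministic. The scan and LD-decay profile never
  prune.
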