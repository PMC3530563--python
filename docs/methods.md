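# Methods

This note documents the models, estimators and numerical choices behind
`fecalpop`, and what the synthetic-data generator does and does not emulate.

## Genotyping error model and consensus calling

Faecal extracts are genotyped in replicate PCRs.  The observation model for
one replicate of one locus has two parameters:

* **allelic dropout** *d* — each true allele copy independently fails to
  amplify with probability *d*; a heterozygote with one dropped allele looks
  homozygous, and a replicate with both copies dropped is recorded as a
  failure;
* **false alleles** *f* — with probability *f* one of the two surviving
  allele calls is replaced by a uniformly chosen different allele of the
  locus.

Consensus calling follows the multiple-tubes thresholds: heterozygote
`(a,b)` when that exact pair is seen in ≥ `het_threshold` (default 2)
replicates, homozygote `(a,a)` when *a* is the only allele ever observed and
appears in ≥ `hom_threshold` (default 5) clean replicates; anything else
fails.  An allele seen in a single replicate is treated as a putative false
allele — it can never support a call, but a second allele observed at all
still contradicts a homozygote.  Two distinct replicated heterozygote pairs
at one locus are a conflict and fail the locus.

**Reliability** of a called genotype is the posterior probability that the
call is the true genotype, computed per locus by Bayes' rule over a
candidate-truth set (all genotypes composed of the sample's observed alleles
plus one "unseen allele" pseudo-candidate) with a uniform prior, using the
exact replicate likelihood above, and multiplied across loci.  A uniform
prior is used deliberately: population allele frequencies are not yet known
at this stage of the pipeline.  Samples with reliability below 0.99 are
flagged for further replication.

**Error-rate estimation** maximises the likelihood of replicate category
counts (pair seen / one allele / failure / extraneous allele) given a
reference genotype per sample-locus.  When the reference is the consensus
call itself, the data are conditioned on the locus having been called — a
called heterozygote necessarily showed its pair ≥ 2 times — so the
likelihood divides by the calling probability; without this correction the
estimates are biased low by roughly 20% at *d* = 0.2 with four replicates.
With simulated truth as reference no conditioning applies.

## Identity and recapture matching

P(ID) and P(ID)sib use the standard unbiased-frequency formulas per locus
and multiply across loci.  Samples are matched into individuals as connected
components of a match graph: an edge requires identical genotypes at every
mutually called locus, with at least 8 mutually called loci (bounding the
false-merge probability), no sex contradiction and no mtDNA haplotype
contradiction.  In populations flagged for exhaustive sampling, a single
allele difference at a single locus is additionally tolerated when sexes
match — the signature of one undetected dropout.  Allele differences are
counted at the allele level: `(100,120)` vs `(100,100)` and `(100,120)` vs
`(100,140)` are both one allele apart and both qualify.  Contradictions that
arise inside a component only through transitivity are reported as QC
failures, never silently merged.  Molecular sexing requires two two-band
(Zfx+Zfy) replicates for a male and three one-band replicates with *no*
two-band observation for a female, because dropout can hide the Y band but
never create it.

## Differentiation statistics

* **Weir–Cockerham θ**: variance components a (among populations),
  b (among individuals within populations), c (within individuals) per
  allele per locus; the multilocus estimate is Σa / Σ(a+b+c).  Negative
  estimates are reported as computed, not truncated.
* **AMOVA Φ_ST**: pairwise molecular distances (K2P by default) play the
  role of squared Euclidean distances in the sum-of-squares decomposition
  SS_total = SS_among + SS_within; Φ_ST = σ²ₐ/(σ²ₐ+σ²_w).
* **Significance**: permutation of individuals between the two populations,
  p = (1 + #{stat_perm ≥ stat_obs}) / (n_perm + 1), default 10,000
  permutations with a fixed seed.
* **HWE**: conditional exact test on the genotype table given allele counts;
  complete enumeration for two alleles, Monte-Carlo re-pairing of the allele
  multiset otherwise.  **LD**: permutation G-test on the composite-genotype
  contingency table.  A Bonferroni helper adjusts p-value families.
* **H_E** uses the 2n/(2n−1) small-sample correction; π is the mean
  pairwise sequence distance within a population, reported in percent.

## Phylogeny

K2P distances use the closed form d = −½ln[(1−2P−Q)√(1−2Q)] with gaps and
ambiguous sites pairwise-deleted; when the log argument is non-positive
(saturation) the distance is capped at 5.0 with a warning.  "HKY distances"
are pairwise maximum-likelihood branch lengths under the HKY rate matrix
with empirical base frequencies and κ either fixed or moment-estimated from
the pooled transition/transversion decomposition (capped to [1, 100] since
κ is unidentifiable without transversions); with κ = 1 and equal base
frequencies they reduce to Jukes–Cantor within optimizer tolerance (1e-6).
Neighbour joining is the Saitou–Nei Q-criterion algorithm with deterministic
first-minimum tie-breaking; it reconstructs any additive matrix exactly, and
negative branch lengths are clamped to zero with a count kept on the tree.
Bootstrap support resamples alignment columns with replacement and counts
bipartition recurrence.  Clade assignment gives each query leaf the clade of
its patristically nearest reference; exact ties are reported as ties.

## Admixture model and K selection

The Gibbs sampler alternates: allele-origin indicators
z ∼ P(z=k) ∝ q_ik·p_{k,l,a} (Gumbel-max categorical draws, vectorised over
all allele copies); allele frequencies P | Z ∼ Dirichlet(λ + counts),
λ = 1; ancestries Q | Z ∼ Dirichlet(α_i + counts).  Missing alleles are
skipped.  Per sweep the marginal data log-likelihood
L = Σ log Σ_k q_ik p_{k,l,a} is recorded; a run's ln P(D) is estimated as
mean(L) − var(L)/2 over post-burn-in sweeps, and ΔK follows the Evanno
second-difference statistic |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd L(K)
across replicate runs.  `run_length` counts total sweeps including burn-in.

α is fixed at 1.0 by default; an optional Metropolis update (uniform prior
on (0, 10], Gaussian random-walk) lets the sampler infer small α when
clusters are discrete, which sharpens posterior ancestries.  The
location prior is a simplified Dirichlet-mean parametrisation: individuals
from sampling location g get α_i = α·K·η_g with per-location mean-ancestry
vectors η_g updated by Metropolis–Hastings — a deliberate simplification of
the published location-prior model, adequate for its role of boosting
weak-signal clustering.  Label switching across replicates is resolved by
exhaustive column-permutation alignment to the highest-ln P(D) replicate.
Chains are seeded per (seed, K, replicate) and bit-reproducible.  Reference
MCMC lengths for field data are burn-in 100,000 / 1,000,000 total with 20
replicates for K = 1..9; simulated desk-scale data mix in a few thousand
sweeps, and the test suite uses 5,000 burn-in / 20,000 total.

## Source assignment

For each focal individual and candidate population: nuclear log-likelihood
Σ_loci log P(genotype | HWE, candidate sample frequencies) with a
rare-allele frequency floor of 1/(2n+1); mtDNA component
log P(haplotype | candidate haplotype counts with pseudocount 0.5); combined
and per-marker rankings are all reported, ties as ties.  **Side-of-origin**
is a separate maternal-lineage question: with philopatric females a
colonist's haplotype belongs to one side's pool, while nuclear markers at
F_ST ≈ 0.01 carry essentially no side information and only add noise to a
combined score (at these sample sizes a combined top-candidate rule
misassigns ~5–7% of focals purely through nuclear sampling noise; a
Rannala–Mountain posterior-predictive variant behaves the same).
`assign_side` therefore ranks sides by the mtDNA component and falls back
to the combined score only when no haplotype is available.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure of a barrier-split
elephant metapopulation: five demes (two east, two west, one focal
recolonised area) with study-scale sizes (47/39/112/59/55 individuals),
12 microsatellite loci with 7 possible alleles (dinucleotide ladders in bp),
nuclear deme frequencies from the Balding–Nichols F-model at target
F_ST = 0.01 (a migration rate can be given instead and is mapped through
the island-model relation F_ST = 1/(1+4Nm)), a 650 bp mtDNA fragment with
side-specific haplotype pools separated by ~25 substitutions (≥10× the
within-side divergence, mirroring the deep forest/savannah clade split),
same-side demes sharing maternal pools (within-side Dirichlet concentration
500, calibrated so the two west-side demes are statistically
undifferentiated, as observed between the two west-side parks), focal
individuals drawn from west-side demes (colonists), heavy recapture in the
focal deme (mean 2.8 samples/individual vs ~1.05 in parks), five PCR
replicates per sample (matching the homozygote replication floor), and
dropout/false-allele rates d = 0.2, f = 0.05 — conventional values for
faecal DNA, since no empirical rates were available; they are config
parameters, not estimates.

Not emulated: stepwise microsatellite mutation and coalescent genealogy
(frequencies are drawn, not evolved), PCR stutter and platform-specific
allele binning, sequencing error in mtDNA reads, relatedness structure
within demes (all individuals are unrelated draws), and temporal change
between sampling seasons.  Passing recovery tests therefore demonstrates
correctness of the estimators under the assumed error and frequency models,
not robustness to stutter artefacts or family structure in real data.

## Problem sizes and numerical choices

Simulation-based tests use scaled problem sizes chosen to keep the whole
suite fast while leaving Monte-Carlo error well inside the asserted
margins: 100-replicate regime checks run five demes of 15–25 individuals;
calibration checks use 500 null datasets with 199–400 resamples each;
sampler checks use 100 individuals × 12 loci.  Permutation p-values include
the observed arrangement (add-one rule), making them valid and slightly
conservative.  Dirichlet draws use gamma sampling; categorical draws use
Gumbel-max; probabilities are floored at 1e-300 before logs.  All stochastic
stages take explicit seeds, and the pipeline derives per-stage seeds from
the global seed with fixed offsets so stages can be re-run in isolation.
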