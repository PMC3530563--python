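# fecalpop

Population genetics from non-invasively collected faecal DNA.

Savannah-elephant populations in fragmented landscapes are typically studied
from dung rather than blood: DNA is degraded, PCR replicates disagree, and
the same animal is often sampled more than once.  `fecalpop` implements the
complete inference chain for such data:

1. **Consensus genotyping** (`fecalpop.consensus`) — the multiple-tubes
   protocol: a heterozygote needs both alleles seen together in ≥2
   replicates, a homozygote a single uncontradicted allele in ≥5; each
   multilocus genotype gets a Bayesian reliability score under the standard
   two-parameter error model (allelic dropout *d*, false alleles *f*), and
   (*d*, *f*) are themselves estimated by maximum likelihood from replicate
   discordance.
2. **Identity analysis** (`fecalpop.identity`) — probability of identity
   P(ID) = Σpᵢ⁴ + ΣΣ(2pᵢpⱼ)² and its full-sibling analogue
   P(ID)sib = 0.25 + 0.5Σpᵢ² + 0.5(Σpᵢ²)² − 0.25Σpᵢ⁴ per locus and as a
   product across loci; recapture matching (exact multilocus match, with an
   optional one-allele-mismatch rule for exhaustively sampled populations);
   molecular sexing from Zfx/Zfy band-call replicates.
3. **Differentiation statistics** (`fecalpop.popgen`) — per-population A,
   H_E, H_O and percent nucleotide diversity π; exact/Monte-Carlo
   Hardy–Weinberg and permutation linkage tests with a Bonferroni helper;
   pairwise Weir–Cockerham θ (variance components a, b, c;
   θ = Σa/Σ(a+b+c)) for microsatellites and AMOVA Φ_ST
   (Φ_ST = σ²ₐ/(σ²ₐ+σ²_w) from the molecular-distance sum-of-squares
   decomposition) for mtDNA, both with permutation p-values; regional
   subdivision re-analysis.
4. **Haplotype phylogeny** (`fecalpop.phylo`) — p-distance, Kimura
   2-parameter (d = −½ln[(1−2P−Q)√(1−2Q)]) and HKY maximum-likelihood
   pairwise distances; Saitou–Nei neighbour joining (exact on additive
   matrices); column-bootstrap support; clade assignment of query haplotypes
   against labelled references.
5. **Clustering and source assignment** (`fecalpop.assignment`) — a Gibbs
   sampler for the admixture model (latent allele origins Z, Dirichlet
   allele frequencies P, ancestries Q), an optional location-informed
   ancestry prior for weak structure, Evanno ΔK model choice, and
   likelihood-based ranking of candidate source populations for focal
   (colonist) individuals, with a maternal-lineage side-of-origin call.
6. **Synthetic data** (`fecalpop.synthetic_data`) — metapopulations with the
   structure these analyses assume: demes split by a barrier,
   near-disjoint maternal haplotype pools across it (female philopatry),
   weak nuclear differentiation (male-mediated gene flow, Balding–Nichols
   F-model), recaptures, dropout and false alleles.

Everything is orchestrated by `fecalpop.pipeline` and the `fecalpop` CLI
(`simulate`, `consensus`, `individuals`, `stats`, `structure`, `convert`,
`run`), with seeded, bit-reproducible runs and a checksummed manifest.

## Worked example

```python
import numpy as np
from fecalpop import synthetic_data as syn, consensus as cns, identity as idy, popgen, phylo
from fecalpop.io_formats import SequenceSet

cfg = syn.SimulationConfig(seed=1, deme_sizes={"AM": 20, "MM": 20, "CCA": 30, "SE": 20, "TA": 20})
truth, table, meta, seqs, truth_map = syn.simulate_dataset(cfg)

calls = cns.call_consensus(table)                      # multiple-tubes consensus
d_hat, f_hat = cns.estimate_error_rates(table, calls)  # ML error rates
pops = dict(zip(meta["sample_id"], meta["population"]))
arr = cns.consensus_to_array(calls, populations=pops)
individuals, audit, conflicts = idy.match_samples(arr, one_mismatch_populations={"CCA"})
ind_arr = idy.individuals_to_array(individuals, arr.loci)

park = ind_arr.subset([i for i, p in enumerate(ind_arr.populations) if p != "CCA"])
side = ["west" if p in ("MM", "SE") else "east" for p in park.populations]
theta = popgen.weir_cockerham_theta(park, side)
first = {ind.individual_id: ind.member_sample_ids[0] for ind in individuals}
park_seqs = SequenceSet(park.ids, [seqs[first[i]] for i in park.ids])
phi = popgen.amova_phi_st(phylo.pairwise_distances(park_seqs, model="K2P").values,
                          np.array([0 if s == "west" else 1 for s in side]))
print(f"d={d_hat:.3f} f={f_hat:.3f}  individuals={len(individuals)} (samples={len(meta)})")
print(f"east-west nuclear theta={theta:.4f}  mtDNA Phi_ST={phi:.3f}")
```

prints

```
d=0.201 f=0.054  individuals=122 (samples=184)
east-west nuclear theta=0.0038  mtDNA Phi_ST=0.945
```

The estimator recovers the simulated dropout (0.2) and false-allele (0.05)
rates; the 184 dung samples collapse to 122 inferred animals (110 simulated
— residual over-splitting comes from loci that fail the replication
thresholds); and the barrier contrast shows the philopatry signature:
mitochondrial Φ_ST two orders of magnitude above nuclear θ, which is what
lets the colonists' source population be read off their maternal
haplotypes.

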