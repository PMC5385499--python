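# coralpopgen

Population genetics of partially clonal, subdivided populations from
diploid microsatellite genotypes — built around the analysis workflow used
for deep-sea corals sampled across seamounts, where colonies may reproduce
both sexually and asexually and sites are structured by seamount and by
depth.

## Who this is for

Researchers analysing co-dominant multilocus genotypes (microsatellites)
of organisms where clonality, null alleles and hierarchical spatial
structure all complicate standard population-genetic inference: benthic
invertebrates, corals, seagrasses, clonal plants.

## What it computes

* **Clonality** — partition of a sample into multilocus genotypes (MLGs)
  with a missing-data wildcard; for every repeated MLG the probability of
  the genotype under random mating, `P_gen = Π p_a²` (homozygote) or
  `Π 2 p_a p_b` (heterozygote), and the probability `P_sex` that its
  `k` observed copies arose through independent sexual events (binomial
  tail over the remaining `N − 1` individuals); genotypic richness
  `R = (G − 1)/(N − 1)`; clone condensation to one representative per MLG
  per site.
* **Diversity and HWE** — observed and unbiased expected heterozygosity,
  the exact Hardy–Weinberg probability test with Markov-chain Monte Carlo
  p-values (default 10,000 iterations after 1,000 dememorisation steps),
  Weir–Cockerham `F_IS`, rarefied allelic richness `A_r(g)`, private
  alleles, Bonferroni correction over the full locus × site family, and a
  one-way ANOVA comparing diversity between fished and unfished sites.
* **Null alleles** — per-site null-frequency estimate
  `r = (He − Ho)/(1 + He)`, locus flagging, and an adjusted dataset in
  which expected hidden null heterozygotes are recoded as heterozygous for
  a synthetic allele one repeat unit above the largest observed allele.
* **Differentiation** — Weir–Cockerham θ (variance components), Hedrick's
  standardised `G'_ST` and Jost's `D` (Nei–Chesser corrected `H_S`, `H_T`),
  with permutation p-values; hierarchical AMOVA (sites within seamounts);
  principal coordinates; Mantel isolation-by-distance on great-circle
  distances.
* **Gene flow and Ne** — `N_e m = (1/F_ST) − 1` (and the island-model form
  `(1 − F_ST)/(4 F_ST)`); the Barton–Slatkin private-alleles method; and
  contemporary `N_e` from the mean squared Burrows allelic correlation
  `r²` with the Waples sample-size correction.
* **Clustering** — a Gibbs sampler for the admixture model (independent
  Dirichlet allele-frequency priors), replicate runs with label alignment,
  and K selection summaries by mean log-likelihood `L(K)` and Evanno's ΔK.
* **Simulation** — a forward-time island-model simulator of partially
  clonal diploid demes with stepwise microsatellite mutation and heritable
  null alleles, which provides ground truth for every estimator above.

## Worked example

Genotypic richness from a published-style genotypic diversity table
(per-site sample count `N` and unique-genotype count `Ng`):

```python
>>> from coralpopgen import genotypic_richness
>>> round(genotypic_richness(34, 20), 2)   # 20 unique genotypes in 34 samples
0.58
>>> round(genotypic_richness(37, 9), 2)    # heavily clonal site
0.22
>>> from coralpopgen.datasets import solenosmilia_genotypic_table
>>> round(solenosmilia_genotypic_table()["R"].mean(), 2)
0.56
```

`R = 0.58` means that 58% of the maximum possible genotypic diversity is
present: most colonies at that site are distinct genets, while `R = 0.22`
indicates a stand dominated by a few clonal lineages. The mean of 0.56
across all 17 sites summarises a species in which roughly half of sampled
colonies are clonal replicates.

An end-to-end run on simulated data:

```sh
coralpop run-all --preset solenosmilia_like --seed 1 --out out/
```

writes the clone report, diversity + HWE tables, null-allele screen and
adjusted dataset, pairwise θ/`G'_ST`/`D` matrices (dual-triangle layout: θ
below the diagonal, Jost's `D` above), AMOVA, PCoA coordinates, Mantel
test, gene-flow and Ne reports, Q-matrices with the Evanno table, and a
seeded JSON manifest of every statistic.

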