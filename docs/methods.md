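# Methods

This note documents the statistical models, estimators and numerical
choices implemented in `coralpopgen`, the assumptions behind them, and the
design decisions made where the literature leaves room.

## Data model

Genotypes are unordered diploid allele pairs of integer fragment sizes
(bp); a genotype is either fully scored or fully missing (the GenePop
all-zero convention — single-allele calls are not representable). Each
individual belongs to exactly one site. Site metadata (seamount, region,
coordinates, depth stratum, fished flag) travel in a CSV sidecar because
GenePop `Pop` blocks are anonymous; the sidecar assigns site ids in block
order. Depth strata are carried as metadata rather than derived from depth,
because sampling designs typically use discontinuous strata (e.g. <500 m,
1000–1400 m, >2000 m) that no threshold rule reproduces.

Fragment-size binning snaps each allele to the lattice
`anchor + k·repeat_unit`, where the anchor is the modal raw allele of the
locus (smallest mode on ties) and exact half-unit ties round toward the
anchor. The operation is idempotent; it replaces interactive binning tools
with a deterministic rule.

The `n > 12` site-inclusion filter is strict (a site with exactly 12
individuals is removed) and is applied to all site-level statistics but
*not* to the clone report, which is computed on the full sample.

## Clonality

Two individuals share a multilocus genotype (MLG) iff they are identical
at every locus scored in both and each has at most `max_missing` missing
loci (default 1); matching is transitively closed, and individuals with
more missing loci are singletons flagged "unassessed". The wildcard
policy reflects sled-collected material with allelic dropout; it can in
principle merge distinct genotypes that differ only at an unscored locus,
which is why the missing budget is kept at one locus.

For a repeated MLG, `P_gen` multiplies Hardy–Weinberg genotype
probabilities across scored loci using allele frequencies from the pooled,
un-condensed sample of the site(s) where the MLG occurs — i.e. clonal
copies are *included* in the frequencies, matching how such probabilities
are computed before any clone correction. `P_sex` is the binomial tail
`P[X ≥ k − 1]`, `X ~ Binomial(N − 1, P_gen)`: given one observed copy, the
chance that at least `k − 1` of the remaining individuals carry the same
genotype through independent sexual reproduction. The binomial form
generalises the pairwise `1 − (1 − P_gen)^{N−1}` to MLGs with many members.

Genotypic richness is `R = (G − 1)/(N − 1)` (0 = monoclonal,
1 = all unique; undefined for `N < 2`). Clone condensation keeps the
lexicographically smallest individual id per MLG per site — a
deterministic choice so that downstream permutation tests are exactly
reproducible; an MLG spanning several sites keeps one representative in
each.

## Diversity and exact HWE testing

Expected heterozygosity uses the unbiased small-sample correction
`He = (2n/(2n−1))(1 − Σp²)`. The exact Hardy–Weinberg test is the
probability-test variant: conditioning on the observed allele counts, the
p-value is the total Levene probability of genotype tables no more
probable than the observed one. The Monte-Carlo chain operates on the
vector of `2n` gene copies: a step proposes swapping two uniformly chosen
gene positions. Because the uniform distribution over assignments of the
allele multiset to gene slots induces exactly the Levene distribution on
tables, the proposal is symmetric, every step is accepted, and no
Metropolis ratio is needed. Defaults are 10,000 iterations after 1,000
dememorisation steps, seeded. The reported standard error uses batch
means (20 batches) to respect chain autocorrelation. Heterozygote
deficit/excess is reported separately as the sign of `Ho − He`. Monomorphic
site × locus combinations are flagged undefined and excluded from the
Bonferroni family size, so the number of *defined* tests is reported
alongside the adjusted flags; the Bonferroni family is all locus × site
tests of one dataset, not per-locus families.

`F_IS` is Weir & Cockerham's small-f from within-population variance
components (`b`, `c`) summed over alleles and loci. Note that a sample in
exact Hardy–Weinberg *proportions* gives `f = 1/(2n−1)`, not 0 — the
estimator is unbiased about the population value, not the sample
proportions.

Rarefied allelic richness uses the closed-form hypergeometric rarefaction
`A_r(g) = Σ_i [1 − C(2n−N_i, g)/C(2n, g)]`, with `g` defaulting to the
smallest per-site gene count in the comparison. Private alleles are
alleles observed in exactly one site. The fished/unfished comparison is a
one-way fixed-effects ANOVA per metric (allelic richness, mean He) across
sites.

## Null alleles

The null frequency per site × locus is the Van Oosterhout-style
excess-homozygosity estimate `r = (He − Ho)/(1 + He)` (plug-in `He`,
truncated at 0). A locus is flagged when `r` exceeds 0.05 at a strict
majority of the sites where it is polymorphic. The adjustment recodes, at
each flagged locus and site, the expected number of hidden null
heterozygotes among observed `A/A` homozygotes — each is truly `A/null`
with probability `2r/(q_A + 2r)`, with visible frequencies rescaled by
`(1 − r)` — as heterozygous for a synthetic null allele labelled one
repeat unit above the locus's largest observed allele (shifting further on
collision). The choice of *which* homozygotes to recode is seeded and
deterministic. The exact recoding rule of the original fragment-analysis
software is not documented at this granularity; this expected-count
reconstruction is this package's own.

Two caveats are deliberate: (i) the estimator assumes HWE within sites and
is biased low by design (its large-sample ceiling is `(1 − Q²)/(2 − Q²) ≈
0.17` at a true null frequency of 0.2), which is why recovery is assessed
on the mean over replicates with a ±0.05 band; (ii) the familiar claim
that adding the null allele can only increase `He` holds for loci with few
visible alleles but fails for highly polymorphic loci, where the synthetic
null collects recoded copies from every allele and may itself become
common. Downstream statistics should always be run on both the raw and
adjusted datasets for comparison, and the pipeline does so whenever a
locus is flagged.

## Differentiation

θ is Weir & Cockerham (1984): per-allele variance components `a` (among
populations), `b` (among individuals within), `c` (within individuals),
summed over alleles and loci, `θ = Σa / Σ(a+b+c)`. `G'_ST` and Jost's `D`
are computed from Nei–Chesser sample-size-corrected `H_S` and `H_T`
(harmonic-mean sample size, observed-heterozygosity correction);
`G'_ST = G_ST / G_ST(max)` with `G_ST(max) = (k−1)(1−H_S)/(k−1+H_S)`, and
`D = (k/(k−1)) (H_T−H_S)/(1−H_S)`. Multi-locus combination differs by
statistic: θ sums its variance components, `G'_ST` uses locus-averaged
`H_S`/`H_T`, and `D` uses the harmonic mean of per-locus values — except
when any per-locus `D` is non-positive (common under weak
differentiation, where the harmonic mean is undefined), in which case the
arithmetic mean is used. Raw, possibly negative estimates are stored;
report tables floor displayed values at 0.000.

Permutation significance shuffles individuals among groups with group
sizes fixed; `p = (1 + #{perm ≥ obs})/(1 + n_perm)` (one-tailed, +1
smoothing so p is never 0). Defaults are 9,999 permutations for pairwise
tables. Pairwise p-values are reported unadjusted.

AMOVA uses allele-mismatch distances (0/1/2 mismatches per locus as the
squared distance, summed over loci scored in both individuals, no
rescaling for missing loci) with Excoffier-style sums of squares and the
standard unequal-sample-size coefficients. `Φ_CT` is tested by permuting
whole sites among groups, `Φ_SC` by permuting individuals among sites
within groups, `Φ_ST` by permuting individuals among all sites. When every
group contains exactly one site the within-group level is empty: `σ_b` is
set to 0 (so `Φ_CT` collapses to the single-level estimate) and `Φ_SC` is
flagged undefined. A stepwise-weighted (R_ST-style) distance is
deliberately not offered.

PCoA applies Gower double-centering to `−D²/2` and returns coordinates for
positive eigenvalues, axes ordered by eigenvalue, with each axis's first
non-zero loading made positive for sign stability. The Mantel test
correlates off-diagonal pairwise `F_ST` (optionally linearised
`F_ST/(1−F_ST)`) with great-circle distances (haversine, R = 6371 km),
with a one-tailed p from jointly permuting rows and columns of the genetic
matrix.

## Gene flow and effective size

`nem_wright` implements `N_e m = (1/F_ST) − 1` as its primary form, with
the island-model rearrangement `(1 − F_ST)/(4 F_ST)` behind a flag;
published analyses are inconsistent about which is quoted, so both are
available and the choice is logged. The private-alleles method uses the
Barton–Slatkin regressions `ln p(1) = a + b ln(N_e m)` at reference sample
sizes 10/25/50, interpolated log-linearly in sample size; `p(1)` is the
mean within-site frequency of alleles private to one site.

LD-Ne follows Waples & Do: the mean squared Burrows composite correlation
`r̂² = Δ̂²/(p_A q_A p_B q_B)` over all allele pairs of all locus pairs
(alleles below a 0.02 frequency cut-off excluded; `Δ̂` with the
`n/(n−1)` correction), minus the random-mating sampling expectation
(`1/n + 3.19/n²` for n ≥ 30; `0.0018 + 0.907/n + 4.44/n²` below),
converted to `N_e` with the corresponding quadratic inversion. A
non-positive drift component maps to an infinite estimate — the expected
outcome when `N_e` is in the thousands and the sample is small. The CI is
parametric (chi-square on the number of allele-pair comparisons), which
understates uncertainty when comparisons are correlated; a jackknife is a
known better choice and is out of scope.

## Clustering

The admixture model: each allele copy of individual `i` originates in
cluster `k` with probability `q_ik`; cluster allele frequencies have
independent Dirichlet(1) priors per locus; `q_i ~ Dirichlet(α)` with a
Metropolis-updated scalar α (uniform prior on (0, 10], normal proposal,
sd 0.25). Gibbs updates cycle latent origins, frequencies and ancestries.
The *independent*-frequencies prior is a deliberate simplification of the
correlated-frequencies model used by the STRUCTURE program: it mixes
faster at desk scale and its adequacy is established by recovery of known
groupings in simulated data, not by replicating any particular program's
output. `L(K)` is reported as the posterior-mean data log-likelihood
(no harmonic-mean or variance correction). Replicate runs are aligned by
greedy best-correlation matching of Q columns to the first replicate
(full permutation search as in CLUMPP is out of scope) and averaged.
Evanno's `ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K))` is reported for
interior K with positive replicate sd; because ΔK and `L(K)` frequently
disagree (ΔK structurally cannot select K = 1), the package reports both
and never auto-selects a K. Desk-scale MCMC defaults are 5,000 burn-in /
50,000 iterations; the pipeline uses smaller, configurable settings.

## The simulator and what passing tests mean

The generator is a forward-time Wright–Fisher variant: K diploid demes of
constant size, non-overlapping generations. Each offspring is, with
probability `c`, an exact clonal copy of a uniform resident (genotype and
lineage id inherited, no somatic mutation, so MLG ground truth is exact);
otherwise two parental gametes are drawn independently with deme-of-origin
probabilities from the migration kernel's destination column (gamete
dispersal — the standard island-model calibration; whole-individual
migration is available via the kernel structure). Mutation is strict
stepwise (±1 repeat unit, symmetric, reflecting at the fragment-size
bounds so 3-digit GenePop coding is preserved). Null alleles are heritable
allelic states: at sampling, null/visible is emitted as a visible
homozygote and null/null as missing, so the null frequency is a
well-defined population quantity for recovery tests.

Two parameter conventions matter. First, scaled-down demes (tens to
hundreds of individuals) keep *composite* parameters realistic rather than
per-capita rates: mutation defaults to `4·N_e·μ = 2`, matching
microsatellite-level diversity (He ≈ 0.6–0.7, a handful to tens of alleles
per locus) at any deme size. Second, clonality interacts with drift:
with clonal fraction `c` the effective number of lineages is roughly
`N(1−c)`-scaled, so high clonality both lowers genotypic richness and
amplifies allele-frequency drift. The partially clonal preset therefore
pairs `c = 0.9` (which yields per-site R ≈ 0.3–0.8 at realistic sampling
fractions) with a per-gamete migration rate of 0.3, producing an emergent
global θ ≈ 0.10 and pairwise θ ≈ 0.01–0.28 — the combination observed in
strongly structured, heavily clonal coral populations. The
depth-stratified preset uses three blocks of demes with free
within-stratum and near-zero between-stratum migration and `c = 0.005`,
yielding >98% unique genotypes, within-stratum θ < 0.01 and clustering
that follows stratum, not seamount.

What the simulator does *not* emulate: somatic mutation within clones,
genotyping error and allelic dropout beyond null alleles, overlapping
generations, selection, uneven deme sizes, and oceanographically realistic
dispersal fields. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to these
complications in field data.

## Problem sizes used in verification

The verification suite runs at deliberately modest scale, chosen as the
smallest sizes at which each statistical claim is informative: island
calibration uses 8 demes × 50 diploids × 9 loci with 500 generations
(10·N_e burn-in) and 20 replicates per migration level; null recovery uses
n = 200 samples from a freshly mated population of 500 with 100
replicates; permutation calibration uses 1,000 panmictic datasets at 199
permutations each; clustering recovery uses 10 two-deme datasets (n = 50
per deme) plus 10 Evanno experiments over K = 1–4 with 4 replicates each;
LD-Ne uses 100 replicates at N_e = 50 and 25 at N_e = 5,000. Pipeline
determinism runs the full workflow twice at reduced preset scale.
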