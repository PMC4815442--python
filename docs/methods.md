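# Methods

This note documents the models, estimators and numerical choices behind
`hybridcline`, and what the synthetic data used by the test suite do and do
not establish about real data.

## Forward simulation of the hybrid zone

The simulator follows a metapopulation of `n_demes` (default 9) demes on a
line, each regulated to carrying capacity K (default 1000) with
non-overlapping generations. Individuals are hermaphroditic; each offspring
draws two parents independently within its deme, with replacement, with
probability proportional to fitness (fecundity selection; selfing is
possible). Each parent transmits one uniformly chosen allele copy per locus
— loci are unlinked and bi-allelic, so the state is stored as a per-locus
dosage in {0,1,2} of the allele representative of the second ("southern")
species, and transmission is Bernoulli(dosage/2). Snapshots expand back to
explicit allele pairs in the standard genotype container.

A single quantitative trait is controlled by `n_trait_loci` (default 40)
loci with allelic effects −1/+1; the genetic value G is the sum of effects
over the 2·L allele copies. Phenotypes are P = G + ε with ε normal and
variance V_E = V_G(1−h²)/h², where V_G is the metapopulation variance of G
recomputed each generation — this keeps realized heritability at the
configured h² (default 0.5) under the reading that heritability is
"constant". The per-deme alternative was rejected because the parental demes
start with V_G = 0. Fitness is Gaussian stabilizing selection around the
deme's optimum, W = exp(−(P−Z_opt)²/(2ω²)), with ω = 10 and clinal optima
(−5,−5,−4,−2,0,2,4,5,5) by default.

Migration happens after reproduction: each individual emigrates with
probability m, moving to a uniformly chosen adjacent deme (stepping stone;
edge demes have one neighbour) or to a uniform other deme (island). m is a
free parameter; the default is 0.05, which produces a stable multi-deme
cline at these sizes, and the simulation-level checks are run across
m ∈ {0.01, 0.05, 0.1} because no single value is canonical. There is no
mutation. The founding state is secondary contact: the three demes at each
end fixed for their species' alleles, the central three empty and colonized
by migration.

### Scoring simulated individuals

Simulated genotypes are scored the way field data are scored: the current
end-deme triplets serve as the parental reference panels, and hybrid index /
interspecific heterozygosity are computed against their current allele
frequencies. This matters for long runs. Drift erodes polymorphism
genome-wide, so the raw fraction of heterozygous loci in the admixed demes
is bounded by the metapopulation's surviving diversity (≈0.29 at generation
10 000 for 9×1000 individuals, essentially independent of m). Panel-based
scoring instead conditions on the loci still differentiated between the
parental demes (differential > δ_min), which is exactly what an
INTROGRESS-style analysis of the output sees; on those assessable loci the
admixed demes hold interspecific heterozygosity near 0.4 at generation
10 000, and parental individuals map to h ≈ 0 and 1 by construction, which
is why distinct parental and hybrid clusters persist for thousands of
generations under stepping-stone migration while the island model collapses
them within ~100 generations.

## Hybrid index and interspecific heterozygosity

The hybrid index h of an individual is the fraction of its genome derived
from the second species, estimated by maximizing
Σ log[h·p_E(a) + (1−h)·p_W(a)] over all non-missing allele copies a, where
p_E/p_W are panel frequencies. The maximization is a grid search (step
5×10⁻⁴) rather than a closed form: it is robust to multi-allelic loci and
boundary maxima, and matches a 10⁻⁵-step dense search to within one grid
step. The 2-unit log-likelihood support region gives the interval. Loci
whose alleles are absent from both panels are skipped with a warning;
missing genotypes are skipped, never imputed. For complete bi-allelic
matrices a vectorized version evaluates the same likelihood as two matrix
products.

Interspecific heterozygosity is the proportion of loci carrying one allele
assigned to each species, with hard assignment by the parental frequency
differential (allele is E if p_E−p_W > δ_min, W if the reverse, else
ambiguous; δ_min = 0.2 by default, trading marker informativeness against
locus loss). Only loci where both copies are unambiguous enter the
denominator. Hard assignment means weakly differentiated within-species
polymorphisms can count as interspecific heterozygosity in pure parental
individuals; fully diagnostic panels give exactly 0 for parentals and 1 for
F1 hybrids. Reference panels are user-designated populations (for synthetic
data, the known parental demes); an optional purge drops panel members whose
own hybrid index leaves [0, 0.1] ∪ [0.9, 1].

## Geographic clines

Allele-frequency clines are the symmetric two-parameter sigmoid
p(x) = (1+tanh(2(x−c)/w))/2 with fixed asymptotes 0/1 — center c at the
steepest point, width w the inverse of the maximum slope, so the per-100-km
slope satisfies |slope|·w = 100 identically. Fitting maximizes the binomial
log-likelihood of per-population allele counts (probabilities clamped to
[10⁻⁶, 1−10⁻⁶]) with a deterministic multi-start L-BFGS-B on (c, log w) for
both orientations; ties go to the first optimum found. Bounds are
c ∈ [0, 2000] km and w ∈ [50, 10⁶] km on the transect axis (the width floor
mirrors the truncation evident in published cline tables for this system)
and c ∈ [0, 4000] m, w ≥ 100 m on the elevation axis. Data with identical
observed frequencies everywhere are flagged "no cline". Width is weakly
identified from a single dataset when the cline transition spans about one
inter-population gap; recovery checks therefore bound the across-replicate
mean rather than each replicate.

The shared-center model (one c, per-locus w) is fitted by profiling: for
each candidate c, each locus's width is optimized one-dimensionally, with a
41-point grid scan refined by bounded scalar minimization. AIC = 2p − 2logL
compares it against independent per-locus (c, w) fits; for a single locus
the two models coincide and ΔAIC = 0.

Multi-allelic SSRs enter cline fitting after compound-allele reduction: each
allele joins the species where its panel frequency is higher (ties to W),
replacing the original ordination-based assignment with a deterministic
frequency rule. Loci monomorphic across both panels are excluded.

## Genomic clines

For a bi-allelic locus oriented so p_E ≥ p_W, an individual with hybrid
index h draws each allele copy E with probability q = h·p_E + (1−h)·p_W,
giving neutral genotype probabilities (q², 2q(1−q), (1−q)²) for (EE, WE,
WW). Observed genotype classes are fitted by multinomial logistic regression
with design (1, u, u²), u = logit(h) clamped to [10⁻³, 1−10⁻³]. The basis is
quadratic on the logit scale rather than in h itself because the neutral
model's class logits are linear in logit(q) — for a diagnostic locus exactly
2·logit(h) and logit(h)+log 2 — so the basis can represent neutrality
exactly while the quadratic term lets single classes (notably heterozygotes)
bend away; a quadratic in raw h cannot track the neutral curves closer than
~0.05 even at n = 10⁴. The fit is a damped Newton iteration with a tiny
ridge (10⁻⁸); separation (non-convergence or |coef| > 50) triggers a
ridge-stabilized refit (10⁻²) and a flag, and single-class data are flagged
degenerate.

The null is parametric: B replicates (default 1000, following common usage
"1000 permutations") draw each individual's genotype from its neutral
probabilities and refit the model — vectorized across replicates, which is
what makes 10⁵-fit calibration suites affordable. The statistic is
−2(logL_neutral − logL_fit); p = (1+#{replicate ≥ observed})/(B+1), so the
smallest attainable p is 1/(B+1) — an alpha of 10⁻⁴ therefore needs
B ≥ 10⁴, and analyses pairing B = 1000 with alpha = 10⁻⁴ (as in published
work) cannot reject by rank; the classifier's alpha is configurable and the
test suite pairs alpha with an attainable B. Pointwise 2.5/97.5% quantiles
of replicate fitted curves form the neutral envelope.

Classification uses envelope excursions on the interior grid h ∈ (0.1,
0.9): a class escaping up (down) over ≥20% of the interior grid with the
largest integrated excursion area gives EE±/WW± (directional selection
toward a species) or WE± (over/underdominance); exactly one homozygote
escaping upward with every other class inside everywhere is epistasis. The
20% threshold and interior restriction are package choices (the verbal
definitions in the literature give no algorithm) and are configurable. Loci
with parental differential below δ_min are excluded before fitting, and the
module accepts only bi-allelic input. Climate-genotype association is a
Kruskal-Wallis rank test of the climate variable across genotype classes
(≥2 classes with ≥5 individuals).

## Diversity statistics

H_e = 1 − Σp² (no small-sample correction, matching common co-dominant
toolchain defaults), H_o the observed heterozygote fraction, F_is = 1 −
H_o/H_e (undefined marker when H_e = 0), H_t from pooled frequencies,
private alleles counted over exactly-one-population occurrences. HWE is a
χ² goodness-of-fit over genotype classes with expected counts < 1 pooled
and df = #classes − #alleles (floor 1) — a deliberate replacement of exact
Markov-chain tests. F_st is Weir-Cockerham θ (variance components summed
over alleles and loci; negative estimates reported as computed), verified
against an independent ANOVA-mean-squares oracle to 10⁻¹⁰. Rarefied allelic
richness is Σ_a[1 − C(N−N_a, g)/C(N, g)] computed with log-gamma; the
default standard size g is the smallest per-population gene-copy count at
each locus. The Mantel test correlates off-diagonal distances with
simultaneous row/column permutations (two-sided, 1000 permutations default)
on F_st/(1−F_st) vs transect distance. The transect profile reports summed
allele counts and mean H_e per population against distance, and each
profile peak's signed offset from the mean cline center (positive =
southern/Engelmann side).

## Synthetic 13-population dataset

`make_fixture_dataset` emulates the structure of a wide two-species conifer
hybrid zone: 13 populations on a ~2000 km north-south transect (sample
sizes 13-114, ~805 individuals), elevation and climate covariates (MAT,
MAP, PAS, SHM) correlated with transect position, one pure northern and
three pure southern reference populations, and clinal admixture proportions
in between (individual ancestry normal around the population proportion,
sd 0.12). Panels: 10 SSRs with 5-20 alleles and species-leaning Dirichlet
frequency profiles; 86 SNPs with differentials spanning diagnostic (1.0) to
weak (0.05) in random orientation, genotypes drawn copy-wise from the
individual's ancestry mixture. What it does not emulate: linkage, null
alleles and genotyping error, family structure within populations,
isolation-by-distance within the parental species, and locus-specific
selection (each individual's loci are exchangeable given its ancestry) — so
passing tests demonstrate estimator correctness under the admixture model,
not robustness to those real-data complications.

## Problem sizes used by the checks

Simulation-level checks run the 9-deme model at full K = 1000: the long-run
heterozygosity level uses five 10 000-generation replicates (plus two per
alternative migration rate), cluster persistence uses 3000 generations with
10/40 selected loci, and island-model merging 100 generations. Statistical
calibrations use 500 neutral loci (B = 199, n = 200) for type-I error, 100
replicates per selection mode at n = 711, 100 seeds for cline parameter
recovery, and 1000 replicates for HWE/martingale checks. These sizes were
chosen so each check's Monte-Carlo error is small against the band it
asserts.

## Known limitations

- The simulator's dosage representation assumes unlinked loci; linked
  ancestry tracts are out of scope.
- Hard allele-to-species assignment inflates interspecific heterozygosity
  at weakly differentiated loci (see above); a frequency-weighted
  definition would differ there.
- The two-parameter sigmoid has fixed 0/1 asymptotes; stepped clines with
  introgression tails are not modeled.
- The genomic-cline classifier is a reasoned formalization of verbal
  definitions; its thresholds (interior grid, 20% excursion, tie-breaking
  by area) are conventions, not estimates.
- Mantel permutation p-values are known to be anti-conservative under
  strong autocorrelation; they are used here as in the standard toolchain.
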