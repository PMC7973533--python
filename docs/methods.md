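# Methods

This note documents the models behind `breeddiv`, the parameter choices that
matter, what the synthetic-breed generator does and does not emulate, and the
numerical conventions a maintainer would need to reproduce or change
behaviour.

## Pedigree model

A pedigree is a topologically ordered list of animal records (id, sire, dam,
sex, birth year, country, two disease-test statuses). Parents referenced but
never defined are auto-created as founders with a warning — real registries
contain dangling references and treating them as fatal would make most
studbooks unreadable. Cycles and duplicate ids are fatal. Sex/parent-role
conflicts are warnings: they are data errors, but not errors this package
can adjudicate. Missing birth years of ancestors may be filled with a
placeholder (1950 by convention); placeholder years carry a flag and are
excluded from generation-interval and trend computations.

## Inbreeding, kinship and rates

Inbreeding coefficients use the Meuwissen & Luo tabular recursion: for each
animal the combined ancestor contributions L and within-family variances
d_j = ½ − ¼(F_s + F_d) give 1 + F = Σ L_j² d_j, computed per animal with a
max-heap over ancestor indices. This is O(n · ancestors) time and O(ancestors)
memory, and agrees with exhaustive Mendelian-transmission enumeration to
1e-12 on all small-pedigree test cases. Founders and animals with an unknown
parent get F = 0; a cohort analysis treats F as *undefined* when neither
parent is known, and flags animals with EqG ≤ 1 ("one traceable generation")
so trend plots can exclude them.

Kinship Φ(a,b) is the standard tabular recursion through the later animal's
parents, memoized over pairs; Φ(a,a) = (1 + F_a)/2. Full-registry kinship
matrices are refused above 20,000 animals by design (quadratic memory);
explicit subsets and single pairs are always available.

Rates: ΔF = 1/(2N_e) (reported to 3 decimals, half-up); ΔF_i =
1 − (1−F)^(1/(EqG−1)) defined only for EqG > 1; F_EqG = 1 − (1−ΔF_i)^(ĒqG−1)
with the population mean ĒqG supplied by the caller and held fixed across
years in trend analyses (a per-year mean would confound depth changes with
inbreeding changes). ΔF_i and F_EqG are exact mutual inverses at equal
depth, which the tests exploit as an algebraic oracle. Realized pedigree
N_e = 1/(2·mean ΔF_i) over cohort members with defined ΔF_i; this is the
individual-increase estimator and recovers census size within 25% on
constant-size random-mating simulations of depth ≥ 8 generations.

## Probabilities of gene origin

Founder contributions q_k are propagated bottom-up (halving per parent link)
and averaged over the reference cohort. Tracing is capped at 20 generations;
an ancestor at the tracing frontier is treated as an origin itself, so Σq = 1
always holds and the cap only matters for pedigrees deeper than 20
generations. An animal with exactly one known parent contributes half its
genome from an anonymous per-record origin, which keeps the normalization
exact instead of silently losing mass.

Effective ancestors follow Boichard's iterative scheme. Each round: (1)
member genome flows upward, halving per link, absorbed at already-selected
ancestors; (2) each candidate's marginal contribution is its arriving flow
discounted by the fraction of its own genome descending from selected
ancestors (computed by a downward pass); (3) the largest marginal wins, ties
broken by earlier birth year then lexical id; stop below 1e-6 marginal or at
500 ancestors. f_a = 1/Σp². A caveat found during validation: f_a ≤ f_e is
*not* a theorem of this construction. On pedigrees without a genuine
bottleneck the marginal decomposition can be slightly more even than the
founder vector (observed up to ~3% inversion on simulated no-bottleneck
breeds, with Σp = 1 exact). The report therefore warns, rather than fails,
if f_a exceeds f_e by more than 5%.

Founder genome equivalents N_g use Monte-Carlo gene dropping (default 500
replicates, seeded): founders carry two uniquely labelled alleles, each
transmission is a fair coin, and N_g(rep) = 1/(2Σp_i²) over surviving
founder-allele frequencies in the cohort. The replicate mean and SD are
reported. The sum Σp_i² has expectation equal to the cohort's mean kinship
including self-pairs, which the tests use as an exact cross-check; the N_g
point estimate itself carries a small upward Jensen bias relative to
1/(2·mean Φ), which is why the closed form is a cross-check and not the
estimator.

## Molecular statistics

Genotypes are stored as minor-allele (A1) dosage, assigned once at read time
(ties broken lexically) and *frozen* through all downstream subsetting: the
carrier-removal analysis reports signed allele-frequency changes, and
re-polarizing after removal would corrupt the sign of losses.

QC order: individuals with missingness > `mind` (0.2), then SNPs with
missingness > `geno` (0.25), then SNPs with MAF < `maf` (0.02). The `geno`
threshold follows the conventional flag semantics (remove SNPs *missing* in
more than 25% of calls); the alternative reading "call rate < 25%" would be
a near-no-op filter and is not implemented.

Heterozygosity: Ho is the observed heterozygote fraction; He = 2p(1−p),
uncorrected by default with a 2n/(2n−1) small-sample correction available.
MLH = (N − O)/N per individual. The method-of-moments inbreeding estimate
uses E_hom per SNP = 1 − 2p(1−p)·2n/(2n−1) (the usual `--het` convention)
and F = (O_hom − E_hom)/(N − E_hom) per individual; it is unbiased near zero
under HWE and recovers F ≈ ½ on one-generation selfing simulations.

The GRM is the VanRaden/GCTA standardized-dosage cross-product averaged per
pair over SNPs non-missing in both individuals; monomorphic SNPs contribute
nothing. IBS distance is 1 − mean shared-allele proportion. Relationship
pruning is greedy and deterministic: while any pair exceeds the cutoff, drop
the member of the worst pair with the higher mean relatedness (ties: higher
missingness, then later input order).

Marker thinning cuts the map into 12,001 equal-SNP contiguous segments,
samples 10,000 without replacement and takes one uniform SNP per segment
(all seeded). Desk-scale maps use proportionally smaller segment counts.

## Runs of homozygosity

The two-phase scanning-window algorithm is implemented literally: windows of
50 SNPs pass with ≤ 1 heterozygous and ≤ 5 missing calls; a SNP is eligible
when ≥ 5% of the complete windows covering it pass (windows are never
truncated at chromosome ends, so terminal SNPs are covered by fewer
windows); eligible stretches are split at gaps > 100 kb and kept if they
have ≥ 50 SNPs, ≥ the class minimum length, and ≥ 1 SNP per 50 kb.
Coordinates are 1-based inclusive; length = end − start + 1. Longer length
classes (> 2, 4, 8 Mb) are re-detected with their own minimum length rather
than filtered from the 1 Mb set, because the SNP-count and density
constraints interact with length. The implementation is frozen against a
literal window-enumeration oracle on hundreds of random fixtures.

F_ROH divides summed run lengths by the array-covered autosome length
(per-chromosome last-minus-first SNP positions, summed). Population F_ROH
(sum over all individuals / covered length × n) equals the mean individual
genome proportion under this definition; published tables that print the two
as different orders of magnitude are internally inconsistent and only the
definition above is supported.

## LD effective population size

Mean squared composite (dosage-correlation) r² over admissible SNP pairs:
different chromosomes, or same chromosome separated by ≥ 5 Mb (physical
linkage inflates r², and a thinned panel leaves mostly distant pairs
anyway). The finite-sample expectation 1/S + 3.19/S² (random mating,
S ≥ 30) is subtracted and N_e solved from E(r²) = 1/(3N_e) + 0.69/N_e²,
i.e. N_e = (1/3 + √(1/9 − 2.76 r²'))/(2 r²'); non-positive corrected r²
yields an infinite estimate with a flag. The 95% CI treats n′·r̄²/E(r²) as
χ²(n′) with n′ = number of pairs — with millions of pairs the interval is
very tight, matching how such CIs are reported in practice. The random-mating
(not monogamy) correction is used because dog breeding is polygynous. The
estimator recovers a true N_e of 100 within 20% in ≥ 90% of seeded
Wright–Fisher replicates (200 sampled offspring, 5,000 unlinked SNPs).

## Mixed-model association and q-values

The scan fits y = μ + g + e once by REML on the null model with cov(g) =
σ²_g·GRM. With a single random effect the restricted likelihood is
one-dimensional in λ = σ²_g/σ²_e on the GRM eigenbasis (GLS intercept and
scale profiled out in closed form), so it is solved exactly by bounded
scalar minimization rather than iterative AI/EM updates. Each SNP is then
tested by GLS at the fitted covariance, vectorized across SNPs; binary
carrier status is treated as a quantitative 0/1 trait, as the MLMA
convention does. Monomorphic SNPs get p = 1. Calibration: empirical type-I
error at nominal 0.05 stays within (0.03, 0.07) over 1,000 null replicates
(n = 200, 500 SNPs), and with an identity GRM the scan reduces to ordinary
regression to 1e-6.

q-values are Storey's, computed within each chromosome, with π₀ from the
smoother (cubic spline over λ ∈ [0.05, 0.95], clipped at 1). Groups with
fewer than 20 tests or an unusable π₀ estimate fall back to
Benjamini–Hochberg (π₀ = 1) with a warning; fallback q-values are never
below their BH counterparts since they are exactly BH.

## Carrier-removal impact

The cleared cohort removes carrier and affected animals of one disease;
untested animals stay in both cohorts (removal is something a breeder can
only do to tested dogs). ΔMAF = freq_cleared − freq_full per SNP on the
frozen A1; SNPs beyond |ΔMAF| ≥ 0.05 and 0.10 are listed, and the chromosome
carrying the causal locus gets a sub-report. MLH, Ho/He, F_ROH and the ROH
summary are recomputed on the cleared cohort. On the simulated breed,
removing all carriers of a planted q ≈ 0.12 recessive zeroes the causal
allele exactly and the allele-frequency loss around the mutation exceeds the
genome-wide background shift in ≥ 95% of seeded runs.

The mutual-kNN network links two individuals when each is among the other's
k nearest IBS neighbours (k = 10 default, ties by id); carrier lineages
appear as over-connected same-status neighbourhoods, tested against a
permutation null.

## Synthetic breed generator

The generator's defaults are the study conditions for every seeded analysis
in this package: a closed studbook over 1950–2015 founded by 60 dogs, 10
litters/year with Poisson litter sizes (mean 4.5), breeding ages 2–8, and
sire selection proportional to per-male Gamma(0.7) popularity weights
(smaller shape ⇒ stronger popular-sire skew) — about 2,900 dogs with a
2005–2015 reference cohort near 500, mean cohort F ≈ 0.12 and EqG ≈ 12,
values in the regime reported for intensively studied closed breeds.

Genotypes: 10,000 SNPs on 38 autosomes of ~5.26 Mb at ~20 kb spacing. The
genome is deliberately *compressed* relative to a real dog genome
(~2.2 Gb): it keeps SNP density in the range where the ROH caller's density
and SNP-count constraints behave like they do on a 170k array, while making
whole-pipeline runs take seconds. Founder haplotype frequencies are uniform
on [0.02, 0.5] (the real array site-frequency spectrum is unknown; this is a
labelled assumption), recombination is 1 cM/Mb with Poisson crossovers, and
haplotypes are stored as founder-origin labels so identity-by-descent is
exact: true inbreeding, allele conservation and disease genotypes are read
off the labels, not re-inferred.

Disease loci are planted by choosing a founder haplotype whose *realized*
IBD frequency in the genotyped cohort already lies in a band around the
target (TNS-like 6.5%, NCL-like 3.5% by default; the high-frequency 12%
regime used in impact experiments needs a prominent founder line and hence a
more skewed configuration). Planting rewrites the nearest marker into a
perfect tag of that haplotype. This preserves the genuine IBD structure
around the mutation — required for the regional ΔMAF experiments — instead
of forcing frequencies by fiat. Testing ascertainment is a plain Bernoulli
per dog (default 0.5); relative-of-carrier ascertainment uplift is not
modelled.

What the simulator does **not** emulate, and hence what passing tests do not
show about real data: realistic LD decay from ancestral coalescence
(founders are unrelated with independent loci), genotyping error and
missingness structure of real arrays (both default to zero, rates are
configurable), registry data errors (duplicate animals, wrong parentage),
immigration (the breed is fully closed), and selection on phenotypes. The
compressed genome also bounds the correlation between pedigree F and
realized IBD/F_ROH: with ~38 weakly recombining chromosomes the sampling
variance of realized inbreeding is large, so F_ped–F_ROH correlations land
in the 0.5–0.7 range rather than near their infinite-genome ceiling — which
is, usefully, the same moderate-correlation regime reported from real
array data.

## Numerical conventions

- Reported F-type quantities round to 3 decimals, ratios to 2; rounding is
  half-up (Decimal-based where printed decimal inputs would otherwise fall
  on binary-float half-way artefacts, e.g. Hardy–Weinberg percentages).
- HWE class percentages are reported independently rounded by default (the
  convention of published tables, which may sum to 99.99); a
  largest-remainder reconciliation to exactly 100.00 is available via
  `reconcile=True`.
- All Monte-Carlo components (gene dropping, thinning, simulation, planting)
  take explicit seeds and are bit-reproducible; fixture emission is
  byte-identical for equal seeds.
- Kinship/inbreeding comparisons against enumeration oracles use 1e-12
  absolute tolerance; PSD checks of relationship matrices use 1e-8 on the
  smallest eigenvalue.

## Known limitations

- Genotype imputation, CNV calling and X-chromosome analyses are out of
  scope; autosomes only.
- The pedigree N_e estimator is the individual-increase form; other
  estimators (log-regression on F over generations, family-variance) are
  not implemented but the ΔF_i machinery they need is exposed.
- `effective_ancestors` is quadratic in (rounds × pedigree size) in Python;
  fine to ~10⁵ animals and a few hundred ancestors, not tuned beyond that.
- The mixed-model scan treats binary status as Gaussian; for very rare
  status classes a logistic mixed model would calibrate better.
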