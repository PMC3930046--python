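# Methods

## The octoploid dosage model

"High chromosome number" sturgeons carry two paralogous tetrasomic copies of
each nuclear locus, eight allele copies in total. Reads from both paralog
sets co-map to the same EST position, so the B-allele read fraction at a
site is governed by the total B-dosage d ∈ {0..8} across both sets. With a
symmetric per-read error rate e (a B read misread as A exactly as often as
the reverse), the expected B fraction is

    p_d = (d/8)(1 − e) + (1 − d/8) e .

Observed counts are modelled as count_b ~ Binomial(depth, p_d), i.e. reads
sample the eight copies uniformly and independently. Site classification is
maximum likelihood over the nine dosages rather than a hard window around
the 3:1 and 1:1 ratios: the likelihood rule is well defined at any depth,
and at high coverage it reduces to the ratio heuristics (d = 2 or 6 ↔ ~3:1,
one paralog fixed and the other a balanced heterozygote, a genotypable SNP;
d = 4 ↔ ~1:1, a fixed paralog difference, not a polymorphism). Exact
likelihood ties are resolved to `other_heterozygous`, the conservative class
that keeps a site out of the panel; in practice ties only arise at depth 0,
where the coverage gate fires first.

Assumptions worth stating: uniform sampling of the eight copies (no
allele-specific expression or mapping bias), a single error rate shared by
all sites, and statistical independence of reads. Real RNA-seq pileups
violate all three to some degree; the coverage threshold and the
quality-filtered input contract absorb part of this, but the classifier's
error rates on real data will be worse than on simulated counts.

Panel candidates are ranked by descending coverage, then by descending
likelihood margin (best minus runner-up log-likelihood), then by
(est_id, position). Coverage leading the sort reflects how panel sites are
chosen in practice (depth is the dominant quality signal); the margin as a
secondary key is this package's own tie-breaker and is documented as such.

Defaults: `error_rate = 0.01` (a typical post-filter short-read substitution
rate; the model is insensitive to the exact value at depth ≥ 100),
`min_coverage = 100`, `max_panel = 384` (one multiplexed genotyping plate).

## Locus QC

Genotyping-assay calls for an octoploid are coded functionally diploid
(AA/AB/BB, i.e. 0/1/2): the assay's intensity clusters cannot resolve
tetrasomic dosage. Two artifact signatures are removed before any
population statistic: loci heterozygous in every individual (the two
paralogs fixed for alternative alleles — the assay always sees both) and
loci with one genotype in all individuals (monomorphic, including loci
fixed at the same allele in both paralogs). Loci with no calls at all are
tallied in their own `all_missing` category rather than folded into
`monomorphic`, so report counts always partition the input exactly. The
filter is idempotent.

Percentages of mapped reads are rounded half-up (not banker's), matching how
such numbers are conventionally reported.

## Population statistics

**Allele frequencies** are simple allele-count ratios per population per
locus; a population with no call at a locus gets NaN there and the locus is
excluded pairwise from distances.

**Latter's F_ST distance** between populations with biallelic frequency
vectors x, y per locus:

    D = [ Σ_loci Σ_alleles (x − y)² / 2 ] / [ Σ_loci (1 − Σ_alleles x·y) ] ,

squared frequency differences normalised by expected between-population
heterozygosity, the form used by frequency-based population tree builders.
Two populations identically fixed at every shared locus have a zero
denominator; the distance is defined as 0 (they are indistinguishable) and
the case is logged. No small-sample bias correction is applied — the
distance is computed from plain frequency estimates; a bias-corrected
variant would change population trees only at very small sample sizes.

**Weir–Cockerham θ** uses the 1984 a/b/c variance components per locus
(computed from per-population sample sizes, frequencies and observed
heterozygote proportions, with populations missing all calls at a locus
dropped for that locus), and the multilocus estimate is the ratio of summed
components. Overall-monomorphic loci have undefined θ and are excluded from
the sums. The estimator is validated by parameter recovery: genotypes
simulated under Balding–Nichols drift at F return multilocus θ within 0.03
of F at 2,000 loci (and the maximal-differentiation and panmictic-split
limits behave correctly).

**UPGMA** is implemented directly (size-weighted average-linkage
agglomeration; node height = merge distance / 2) rather than through a
generic clustering routine because the tree contract requires a
deterministic tie-break: among tied minimal pairs, the pair whose
smallest-leaf labels sort first lexicographically merges first. The
implementation is verified against an independent brute-force oracle
(cluster distances recomputed as plain means of original leaf-pair
distances) on 500 random matrices per run, and output trees are ultrametric
to 1e-12.

**Bootstrap supports** resample loci (not individuals) with replacement,
matching the unit of information in a frequency-based tree; each internal
node of the full-data tree gets the percentage of replicates containing its
leaf set as a clade. The root is left unannotated (its clade is trivial).

## Assignment

Assignment likelihood is the product over loci of HWE genotype
probabilities under each population's frequencies. Frequencies of exactly 0
or 1 are replaced by 1/(2n+1) and 2n/(2n+1), with n the population's
non-missing sample size at the locus — the standard convention that keeps a
single novel allele from imposing an infinite penalty. A reference
population with no data at a locus (possible after leave-one-out at n = 1)
contributes an uninformative probability of 0.5 at that locus rather than
dropping the locus for all populations. Argmax ties are reported as
unassigned and counted incorrect — the conservative accuracy. HWE genotype
probabilities are used even though the organism is octoploid, because the
assay calls being classified are functionally diploid codes.

Leave-one-out accuracy recomputes the focal individual's own population
frequencies without it (an O(1) count update per individual); other
populations keep full-sample frequencies. Note the known repulsion bias:
under a true null (one population relabelled as two) leave-one-out accuracy
sits slightly *below* chance, because removing the individual shifts its own
population's frequencies away from it.

Locus ranking simulates datasets by drawing individuals per population from
the observed allele frequencies under HWE — default sizes 100, 100, 100 and
500, the resampling design used for panel selection in this study system —
and scores each locus by its mean single-locus leave-one-out log-likelihood
ratio (true population vs best other). The consensus panel keeps loci
ranked in the top K (default 12) of every dataset, ordered by mean score.
The score is one of several defensible choices (per-locus correct-assignment
frequency is another); it is isolated in one function and swappable.
Minimal-panel selection walks prefixes of the consensus ranking until the
leave-one-out accuracy target is met, returning the full candidate list with
a flag when the target is unreachable.

## Synthetic data

The simulator provides the two ground-truth structures the analyses assume:

* **Octoploid sites**: count_b ~ Binomial(depth, p_d) with the true dosage
  attached, for classifier sensitivity/specificity measurement.
* **Population genotypes**: Balding–Nichols drift — each population's
  frequency at a locus is Beta(p0(1−F)/F, (1−p0)(1−F)/F) around an
  ancestral frequency p0 ~ Uniform(0.1, 0.9) — followed by HWE genotype
  sampling, Binomial(2, p). F = 0 is handled as the exact copy limit. The
  single drift parameter maps to expected F_ST, which is what makes
  estimator-recovery tests possible. Hierarchical scenarios (lineages that
  split into near-identical population pairs) are built by composing
  `drift_frequencies` twice.

The default study scenario is five populations of sizes 14, 14, 5, 28 and 5
at 123 biallelic loci, with per-population divergence F = (0.02, 0.02,
0.08, 0.15, 0.30) for Volga, Ural, Azov, Persian and Siberian samples: the
two Caspian river populations nearly indistinguishable, the Azov population
modestly diverged, the Persian sturgeon clearly separated and the Siberian
sturgeon the outgroup. The F values are this package's choice (chosen once
to reproduce the qualitative structure of the system: star-shaped
Balding–Nichols drift cannot encode the true shared history, only the
relative magnitudes of differentiation).

What the simulator does **not** emulate: linkage between loci, ascertainment
bias from discovering SNPs in a single Volga individual (which inflates
within-Caspian polymorphism relative to other populations in the real
panel), genotyping-chemistry failure modes other than uniform random
missingness, and allele-frequency correlation between populations beyond
the star phylogeny. Passing tests therefore demonstrate the estimators and
selection procedures are correct under their stated models, not that any
particular real dataset will reach a given accuracy: with the default
diffuse divergence, small (8–12 locus) panels assign merged Caspian / Azov /
Persian groups at ~0.7, while strongly diagnostic planted loci (F = 0.5)
push small-panel accuracy past 0.9 — panel size requirements are a property
of the data's divergence structure, as the monotonicity tests document.

## Numerical and problem-size choices

* Binomial log-likelihoods via `scipy.stats.binom.logpmf`; dosage argmax
  ties detected at absolute tolerance 1e-12 (only exact ties occur in
  practice); assignment log-likelihood ties at 1e-9.
* Distance matrices validated symmetric at 1e-12; ultrametricity asserted
  at 1e-12.
* Test problem sizes are chosen so statistical assertions have comfortable
  margins at fixed seeds: 10,000 sites for classifier operating
  characteristics, 2,000 loci / 100 diploids per population for θ recovery,
  500 random matrices per run for the UPGMA oracle, 100 bootstrap
  replicates for support checks, 20 replicate simulations for mean-accuracy
  monotonicity. All randomness flows through `numpy.random.default_rng`
  with explicit seeds; every stochastic operation is bit-reproducible under
  a fixed seed.

## Known limitations

* The dosage classifier assumes exactly two tetrasomic paralog sets; it has
  no concept of copy-number variation between individuals or collapsed
  repeats beyond the 8-copy model.
* GenePop I/O is deliberately restricted to the biallelic 01/02/00 coding;
  richer allele codes are rejected, not coerced.
* Latter distances and UPGMA are the only tree route provided (no
  neighbor-joining, no corrected distances); the bootstrap resamples loci
  only.
* Assignment is pure frequency maximum-likelihood; no Bayesian smoothing or
  admixture modelling.
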