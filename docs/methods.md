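# Methods

## ROH detection

Detection works per individual and per chromosome on biallelic calls
coded 0/1/2 with an explicit missing sentinel (never 0, so missing and
homozygous-reference cannot be conflated).

A window of `window_size_snp` consecutive SNPs (default 50) slides one
SNP at a time. A window is *homozygous* when it contains at most
`max_het_in_window` heterozygous (default 1) and at most
`max_missing_in_window` missing (default 5) calls. Each SNP receives
the proportion of homozygous windows among the windows covering it; a
SNP is *eligible* when that proportion is at least
`1 − window_threshold` (default 0.95). Chromosomes shorter than the
window are treated as a single window. Maximal runs of eligible SNPs
are split wherever two adjacent SNPs lie more than `max_gap_bp`
(default 500 kb) apart, and the pieces are kept when they contain at
least `min_snp` SNPs (50), span at least `min_length_bp` (1 Mb) and
have at least one SNP per `min_density_bp_per_snp` (50 kb), the
density being assessed on the whole run.

Numerical choices worth knowing:

- Run length is `end_bp − start_bp` over the first/last SNP of the run
  (the detectRUNS convention), not `+1`.
- Length classes are half-open Mb bins [1,2), [2,4), [4,8), [8,16),
  [16,∞), so the five classes partition [1 Mb, ∞) and a run of exactly
  16 Mb lands in >16.
- The per-SNP proportions are ratios of small integer counts, so the
  eligibility comparison is exact; the test suite verifies the
  vectorised scan and run construction against a quadratic
  window-enumeration and interval-enumeration oracle, interval by
  interval.
- Whether heterozygotes are allowed inside a run at all is a parameter
  (`max_het_in_window=0` forbids them); one per window is the common
  array default.

Segment length converts to age as g = 100 / (2 L cM). The cM↔Mb
conversion defaults to 1:1 (appropriate for the salmonid arrays this
targets) and is configurable for other maps.

## Quality control

Filters run in a fixed order — sample call rate, marker call rate
(recomputed on retained samples), minor allele frequency (non-missing
calls only), exact Hardy–Weinberg test — and each marker is charged to
the first filter that removes it, so the `QCReport` counts partition
the input panel and runs are reproducible. The HWE test is the exact
conditional test (enumeration of heterozygote counts given allele
counts via a stable two-way recurrence, two-sided by summing
configurations no more probable than the observed one); a mid-p
variant is flag-selectable. Defaults follow array practice: call rate
≥ 0.90, MAF ≥ 0.01, HWE p ≥ 1e-6. Cross-population analyses first
restrict every cohort to the markers that segregate in all of them.

## Inbreeding estimators

*F_ROH* divides summed run length by L_AUTO. Two denominator modes
exist: `panel` (sum of per-chromosome spans between first and last
marker — the default, and the only mode with a per-chromosome
analogue) and `fixed` (a constant, default 1,685,790,000 bp, the span
of the 200K coho salmon array this package was built around). Length-
restricted values are cumulative thresholds (≥ L), not disjoint bins,
so the ≥1 Mb row equals the genome-wide value and the sequence is
non-increasing in L; a disjoint-bin mode is available but off by
default.

*F_HOM* computes O_hom and E_hom over each individual's non-missing
markers with allele frequencies estimated in the analysis sample (a
pooled-frequency mode is available through the `allele_frequencies`
argument). When every observed marker is fixed the value is undefined
and reported as NaN.

*F_GRM* builds G = ZZ′ / (2 Σ p(1−p)) with missing dosages mean-imputed
(zero after centring). The default diagonal reading is `G_jj − 1`,
consistent with E[G_jj] = 1 + F; the `two_gjj_minus_1` mode reports
2G_jj − 1 instead. The mode used is recorded in the output metadata
rather than silently normalised, because both conventions circulate.

A caveat the simulator makes vivid: with in-sample frequencies, F_HOM
and F_GRM measure inbreeding *relative to the current sample's gene
pool*. In a drifted closed line their population means sit near zero
(and in an admixed F1 cohort well below zero) even when autozygosity
from the founders is substantial; only F_ROH and F_PED are anchored to
the founder generation. Population means of F_HOM therefore are not
expected to vanish outside an unstructured random-mating sample.

Estimator comparison uses Pearson correlations (two-sided t-test
p-values) within each population and pooled; zero-variance estimators
yield NaN, not 0. Group differences per estimator are pairwise Welch
t-tests at α = 0.05 without multiplicity correction — a deliberate,
easily swapped choice — rendered as a compact letter display computed
from the maximal cliques of the not-significantly-different graph.

## Pedigree inbreeding

Pedigrees are 3-column (id, sire, dam) records; "0"/empty marks an
unknown parent, parents without records become implicit founders, and
records may arrive in any order (a stable topological sort is applied;
cycles are an error naming the individuals involved). F is computed by
the Meuwissen & Luo recursion: for individual i,
A_ii = Σ_j L_ij² d_j over its ancestors, with d_j the within-family
segregation variance and L_ij accumulated by halving coefficients up
the pedigree; F_i = A_ii − 1. Memory stays linear in pedigree size. An
unknown single parent behaves exactly as a unique phantom founder. A
memoised kinship recursion and a Wright path-counting implementation
serve as cross-checks in the test suite, along with a 10,000-replicate
single-locus gene-dropping Monte-Carlo bridge.

## PCA

Markers are centred by 2p and by default scaled by √(2p(1−p)) — the
same standardisation as the GRM, so both derive from one Z matrix (an
unscaled mode shares eigenvectors with the GRM exactly). Monomorphic
markers are dropped; missing calls are mean-imputed. The
individual-by-individual covariance is eigendecomposed; variance
proportions are eigenvalues over the trace, and each component's sign
is fixed by making its largest-magnitude score entry positive.
Degenerate inputs (no polymorphic marker, zero total variance) raise
rather than returning arbitrary axes. Scores and eigenvalues are
emitted as TSV for external plotting; no figures are rendered.

## Gene-dropping simulator

Founder chromosomes carry globally unique haplotype labels. Each
meiosis draws crossovers as a Poisson process at `cm_per_mb` (default
1 cM/Mb; Haldane model, no interference — the simplest process
consistent with the 100/(2g) segment-length expectation), picks a
random starting phase and splices the two parental mosaics. Genotypes
are read off marker positions from founder allele arrays whose
per-marker alternate-allele frequencies are drawn from Uniform(0.05,
0.5) by default. True autozygosity is the exact base-pair fraction
where an individual's two mosaics carry the same label.

`make_study_design` emulates a two-line breeding nucleus: a pool of
2·n_per_gen unrelated founders split disjointly into two closed lines,
each bred for `g_line` discrete generations of `n_per_gen` offspring
with parents drawn at random from the previous generation (sires from
even, dams from odd positions; no full-sib avoidance), plus an
optional F1 cohort mating line-A sires of generation g_line−1 to
line-B dams of generation g_line. Defaults — 8 generations, 30 per
generation — give per-line mean F around 0.10–0.15 after eight
generations, the regime of interest for comparing estimators. The
default desk-scale genome is 5 chromosomes × 50 Mb at 100 markers/Mb
(problem sizes chosen so the whole validation suite runs in well under
a minute per simulation); a 30-chromosome preset totalling 1685.79 Mb
is provided for full-scale runs.

What the simulator deliberately does not model: selection (real
breeding lines are selected, which concentrates autozygosity around
trait loci; drift alone reproduces the overall inbreeding accumulation
but not its genomic localisation), mutation, genotyping error, sex
chromosomes, overlapping generations, and crossover interference.
Passing tests therefore demonstrate correctness of the estimators
under drift, recombination and array-like marker densities — not
robustness to assay artefacts or selection signatures.

Because the two lines share no founder, F1 individuals have exactly
zero true autozygosity; their (near-absent) ROH are pure
identity-by-state noise, the designed analogue of an admixed cohort's
missing long-ROH classes.

All randomness flows through one seeded `numpy` generator; every
output is reproducible byte-for-byte from (configuration, seed).

## Pipeline

`run_pipeline` executes QC per population, marker intersection, ROH
detection and summaries per population, inbreeding estimation (joined
with F_PED when a pedigree is supplied), estimator comparison, and PCA
on the merged cohorts, writing TSV/JSON outputs plus the verbatim
configuration and a run log. Stage failures abort with the stage name.
Reruns of the same configuration produce byte-identical numeric
outputs.

## PLINK I/O

Both the text (PED/MAP) and binary (BED/BIM/FAM, v1.9 SNP-major)
dialects are supported in both directions. One asymmetry is inherent
to the formats: a MAP file carries no allele columns, so when reading
PED the reference allele of each marker is the first allele observed
in file order, and a write→read round trip can flip 0/2 polarity at
markers whose first non-missing genotype is hom-alt. Passing the
writer's marker map as `map_hint` (or using the BED dialect, whose BIM
stores both alleles) pins polarity and makes round trips exact.

## Known limitations

- ROH parameters interact with marker density; the defaults assume
  array-scale density (≥50 SNPs/Mb). At sparse densities the 50-SNP
  minimum dominates and short classes become unobservable.
- The exact HWE filter assumes autosomal biallelic markers;
  multi-allelic sites and sex chromosomes are out of scope.
- Bayesian admixture clustering is not implemented; the simulator's
  known ancestry fractions and PCA cover structure validation.
- Welch-without-correction letter displays are anti-conservative when
  many estimators are compared; treat letters as descriptive.
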