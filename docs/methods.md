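# Methods

This note documents the statistical and physical models implemented in
`skagerrak`, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Genotype data model

A cohort is an individuals × loci array of unordered diploid allele pairs.
Allele labels are raw fragment sizes in base pairs, never recoded indices,
so "the same allele" means the same thing across populations and
private-allele comparisons stay meaningful. Missingness is per genotype: a
half-called input genotype (one allele present) is coerced to fully missing
with a warning, because a single gene copy cannot enter frequency,
heterozygosity or variance-component formulas coherently. Population order
is order of first appearance and is preserved in every report.

GenePop is read and written with 3-digit allele coding by default (2-digit
supported). GenePop names populations after the last individual of each POP
block, so a write/read round trip is lossless up to that naming convention
(the partition, calls, loci and individual IDs are preserved exactly).

## Diversity statistics

- **H_O**: fraction of heterozygous individuals among non-missing calls.
- **H_E**: gene diversity 1 − Σp². Per-population tables use Nei's
  small-sample correction 2n/(2n−1) (with 2n the gene-copy count); pooled
  per-locus panels use the uncorrected form. Both conventions are common;
  reports label which is used.
- **Allelic richness A_R(g)**: hypergeometric rarefaction,
  A_R(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)]. Rarefaction operates at the
  gene-copy level, so missing data shrinks N per (population, locus). The
  default standard g is the per-locus minimum N across populations (the
  smallest sample sets the standard, as in the HP-RARE convention);
  per-population means are then taken over loci.
- **Private alleles** are raw presence/absence counts of (locus, allele)
  pairs exclusive to one population or pooled group — not rarefied, because
  the pooled-group comparison in the motivating analysis is a raw count.

## Hardy–Weinberg and linkage tests

The HWE test is a Monte-Carlo exact test: the observed 2n gene copies are
shuffled into n random diploid pairings (default 100,000 arrangements), and
each arrangement is scored by its conditional probability given the allele
counts (computed in log space; the arrangement-independent factorial terms
cancel). p is the smoothed proportion of arrangements no more probable than
the observed table — the conditional-probability ordering, two-sided by
construction, matching the behavior of the standard "exact test" tools
rather than a one-sided heterozygote-deficit statistic. Monomorphic loci
return NA ("test not applicable"), consistent with NS-style report cells.

The linkage-disequilibrium test is genotypic: the G statistic of the
genotype × genotype contingency table of two loci, with the null built by
permuting one locus's single-locus genotypes across individuals (default
10,000 permutations). This preserves both single-locus genotype
distributions exactly — including any HWE departure — while breaking the
association, so it remains valid when loci are out of HWE.

All permutation/Monte-Carlo p-values use +1 smoothing,
p = (1 + #extreme)/(reps + 1), so p = 0 never occurs and the minimal p is
1/(reps+1).

**Multiple testing.** Test families are corrected with the single-threshold
Benjamini–Yekutieli rule α / Σ_{i=1..k} 1/i, valid under arbitrary
dependence. For a 6-population × 6-locus cohort this gives 0.00984 for the
90-test LD family and 0.01198 for the 36-test HWE family (both reported to
5 decimals). Report stars (5%, 1%, 0.1%) are assigned against the adjusted
threshold.

## Genetic distance, trees, ordination

The Cavalli-Sforza & Edwards chord distance is computed per locus from
square-root frequency geometry, d_l = (2/π)√(2(1 − Σ_a √(x_a y_a))), and
combined across loci by arithmetic mean by default. The quadratic-mean
variant √(mean d_l²) is available behind `combine="rms"` because historical
implementations differ and the choice is not always documented; the two are
monotonically related for a single locus but not for multi-locus profiles.
Loci with no typed copies in either population are dropped (with a warning)
and the locus count decremented.

Neighbor joining is the standard Saitou–Nei Q-criterion algorithm,
hand-implemented for two deliberate behaviors: ties in Q are broken by
lexicographic label order (bit-reproducible trees), and negative branch
lengths are clamped to zero with the deficit moved to the sibling branch of
the same join (preserving the pair's summed length, the common practice).
On additive matrices the clamp never triggers and the generating tree is
recovered exactly; the test suite cross-checks topologies against
scikit-bio's independent NJ.

Bootstrap supports resample **loci** with replacement (default 2000
replicates), rebuild the chord matrix and NJ tree each time, and score each
internal split of the point-estimate tree by the fraction of replicates
containing that bipartition. Splits with support > 0.70 are flagged, the
conventional cutoff for reading bootstrap proportions as significant. Two
caveats are documented deliberately: supports are computed against the
point tree's splits (not a consensus tree), and bootstrap proportions are
*not* null-calibrated p-values — with few loci, structure-free data can
still produce an occasional high support, so the flag should be read as
descriptive, not as a test at level 0.30.

PCoA is classical Torgerson scaling: double-center −D²/2, eigendecompose,
scale eigenvectors by √eigenvalue; axis percents are taken over positive
eigenvalues only (negative eigenvalues, possible for non-Euclidean
distances, are dropped).

## Weir–Cockerham θ

Pairwise differentiation is the Weir–Cockerham (1984) estimator with r = 2
demes: per locus and allele, variance components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed from sample sizes, allele frequencies and observed heterozygote
frequencies, and θ = Σa / Σ(a+b+c) as a ratio of sums over all alleles and
loci. Missing genotypes shrink per-locus sample sizes; loci typed in only
one deme are excluded for that pair. θ may be negative and is reported as
computed — near-zero magnitudes are meaningful in weakly structured data,
and truncation would bias permutation tests. Significance is tested by
pooling the two samples and permuting individuals between them, preserving
sample sizes (default 10,000 permutations); pairs are tested independently
with no across-pair correction, matching per-pair star conventions.

## Larval drift model

Larvae are passive surface drifters: single-layer 2D fields, no behavior,
no random walk, no mortality other than the two physiological gates. This
reduction is intentional — the vertical dimension matters only through
behavior, which is excluded by design, and the resulting determinism makes
every simulation property exactly testable.

- **Advection**: explicit Euler x ← x + u·dt (default dt = 3600 s); RK4 is
  available behind a flag and agrees with Euler to O(dt) in smooth fields.
  Fields are sampled bilinearly in space using water cells only (weights
  renormalized near land) and linearly in time.
- **Development**: degree-days accrue as max(T − T_base, 0)·dt/86400 from
  the temperature at the pre-step position. T_base defaults to 0 °C; the
  recruitment requirement (225 °C·day) was published without a stated base,
  so the base is configurable and all asserted simulation properties either
  hold for any base or state it.
- **Settlement**: first contact with the coast (attempted entry into a land
  cell) sticks the larva at its last water position and classifies it
  immediately: survived iff DD ≥ 225 and landing-site T ≥ 18 °C (both
  inclusive); no resuspension or continued drift after contact. Larvae
  leaving the domain or exceeding the maximum pelagic duration (default 60
  days from release) expire.
- **Aggregation**: survived landings are binned on an axis-aligned,
  half-open 50 × 50 km grid anchored at the domain origin, and attributed
  to named regions by point-in-polygon on the landing position.

Consequences used as acceptance properties: fates partition the release
(released = survived + failed + expired); DD is non-decreasing along every
trajectory; if T < 18 °C everywhere no larva survives; and because
temperature does not feed back on velocity, raising T uniformly never
decreases the survived count.

## Synthetic generators

**Genotypes (F-model).** Ancestral frequencies per locus are a flat
Dirichlet draw over the configured allele count; each population's
frequencies are Dirichlet(p0·(1−F)/F), so E[Var(p)] = F·p0(1−p0) and the
divergence parameter F is exactly the coancestry that θ estimates —
verified by recovery tests (mean θ̂ within ±15% of F at F = 0.02–0.1,
n = 50, 6 loci). F = 0 copies the ancestral frequencies exactly (documented
special case, no division by zero). Genotypes are drawn under
within-population HWE; an inbreeding-style generator distorts P(het) by
(1 − F_IS) for HWE-test power and calibration fixtures. Missingness is
completely at random (default rate 0.004, the sporadic level of the
emulated cohort: a handful of failures among ~1600 genotype calls). The
default layout copies the study design — populations N_B (n=12), N_G, N_I,
N_O, S_S, D_A (n=50 each) and the six-marker panel with its published
fragment-size ranges — so report shapes can be tested realistically. What
the F-model does **not** emulate: mutation (no stepwise-mutation allele
spectra), linkage, null alleles/allelic dropout, or isolation-by-distance;
passing recovery tests therefore validates the estimators under their own
assumptions, not robustness to those artifacts.

**Ocean scenarios.** A rectangular basin (default 75 × 60 cells of 4 km;
chosen as a computationally light stand-in for a high-resolution coastal
hindcast) with land strips on the donor (south) and recipient (north)
edges. Velocities are finite differences of a corner stream function —
exactly divergence-free in flux form — giving either a uniform
donor→recipient stream (default transit ~12 days) or a single gyre.
Temperature is baseline 19 °C + a seasonal half-sine (amplitude 2.5 °C)
− 0.012 °C/km northward + a scenario offset; the cold (−6 °C), moderate
(0 °C) and warm (+4 °C) presets differ **only** in that offset, so the
temperature gate is the single cause of outcome differences between
"years": cold caps the basin at 15.5 °C (zero survival), warm lands every
larva with ~250–280 DD, moderate splits the cohort by release timing. The
generator does not attempt realistic Skagerrak bathymetry, tides, wind
events or mesoscale variability, and the published absolute landed counts
of the original hindcast-driven study are therefore not reproduction
targets — only the structural and monotonicity properties above are.

## Numerical and design choices

- Rarefaction uses log-binomials (gammaln); it agrees with exhaustive
  subsample enumeration to 1e-9 for N ≤ 12 and is monotone in g by
  construction.
- HWE arrangement scoring compares log-probabilities with a 1e-9 tie
  tolerance; permutation G-statistics likewise.
- θ permutation tests batch permutations (default 200 at a time) through a
  vectorized variance-components kernel; the per-pair estimate is the same
  code path as the permuted ones.
- All model-level randomness flows from one root seed through named
  per-stage `SeedSequence` streams (hwe / ld / fst / boot), so a stage
  rerun in isolation reproduces its in-pipeline results.
- Monte-Carlo defaults (HWE 100,000; LD 10,000; θ 10,000; bootstrap 2,000)
  follow common practice for publication-grade reports; tests and the
  acceptance script use smaller, stated sizes (e.g. 2,000 HWE arrangements,
  199 permutations per calibration fixture, 100–200 fixtures) that keep the
  whole suite under half a minute while leaving binomial calibration bands
  comfortably resolvable.
- Degenerate inputs are defined, not accidental: all-missing loci give
  N = 0 and NA statistics; monomorphic loci give NA test p-values; single
  populations skip structure stages with a warning; sub-3-taxon NJ and
  single-locus bootstraps raise.

## Limitations

- The counting results tied to the study's real supplementary genotype
  table (typed-N per locus, pooled private-allele counts) can only be
  checked when that table is supplied at `data/s1_appendix_genotypes.csv`;
  the repository ships no copy of it.
- The exact multi-allele HWE enumeration (non-MC) is out of scope; the MC
  test's resolution is bounded by 1/(steps+1).
- Bootstrap supports are descriptive (see caveat above).
- The drift model's absolute landing counts depend entirely on the supplied
  fields; with the parametric generator they characterize the model's
  logic, not any real coastline.
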