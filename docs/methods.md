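# Methods

This note records the models the package implements, the numerical
conventions that make results reproducible, what the synthetic data do
and do not emulate, and the choices made where the design was genuinely
open.

## Coordinates, polarity, missingness

Physical positions are 1-based inclusive everywhere; only the BED
writer converts to 0-based half-open. Genotype codes count copies of
the alternate allele, or of the derived allele after polarization.
Polarization removes variants whose ancestral state is unknown or not
among the observed alleles and reports them; the unpolarized object is
left untouched for frequency-only analyses. Missing genotypes are
excluded per SNP (complete-case per site); there is no imputation.
Genetic maps interpolate linearly between map points and extrapolate
beyond the ends at the terminal interval rate, so statistics that
integrate genetic distance remain computable at chromosome ends.

## Weir–Cockerham F_ST

`wc_theta` is the Weir & Cockerham (1984) θ̂ = a/(a+b+c) computed from
per-group diploid sample sizes, allele frequencies and observed
heterozygote frequencies. SNPs monomorphic across the pooled groups
are undefined (NaN) and excluded from null distributions; negative
estimates are kept. Scans run at four level tags — global over
regions, global over populations, one region versus the pooled rest
(two groups), and populations within one region — after a pooled-MAF
filter (default 10⁻³). Empirical p-values sort the background by MAF,
cut it into consecutive bins of equal SNP counts (default 10,000;
scaled down for desk-size backgrounds) and rank the focal SNP inside
the bin containing its MAF with the add-one rule
p = (1 + #{bin ≥ observed}) / (bin + 1), ties inclusive, so p ∈ (0, 1].

## EHH, iHH, iHS, XP-EHH

EHH for a core SNP and allele class is the probability that two random
carrier haplotypes are identical over the inclusive interval from the
core to a flanking SNP. The implementation sorts the carrier rows
lexicographically once and derives every prefix partition from the
first-difference depths of adjacent sorted rows, which is
algebraically identical to stepwise partition refinement but runs in
O(n log n · L). A brute-force O(n²) pairwise-identity oracle checks it
in the tests.

iHH integrates EHH against genetic distance (cM) by trapezoids outward
from the core, stopping at the first SNP with EHH < 0.05 and including
the boundary trapezoid down to that SNP's actual value (no
interpolation to the exact crossing). The statistic is invalid — NA,
never a number — when a physical gap > 200 kb occurs between
successive SNPs inside the span ("gap") or when the chromosome ends
before the cutoff is crossed ("boundary").

iHS is ln(iHH_ancestral/iHH_derived), standardized to zero mean and
unit variance (1/n convention) within 5% bins of derived allele
frequency; bins with fewer than 20 valid scores merge into the nearest
bin. Significance is two-sided on |iHS| by default, since extreme
values of either sign are meaningful. XP-EHH delimits one shared span
per side where the EHH of the pooled test+reference sample drops below
the cutoff, integrates both populations over exactly that span, takes
ln(iHH_test/iHH_ref) and normalizes across the chromosome-wide track
per (test, reference) pair. Swapping test and reference negates every
raw score exactly; this and the core-relabeling antisymmetry of iHS
are asserted in tests.

## XP-CLR

Under the null, the test-population frequency drifts around the
reference frequency p1 as a Gaussian with variance ω·p1(1−p1), with
mass outside [0, 1] collapsed onto the boundaries. Under the sweep
alternative a linked lineage escapes with probability
c = 1 − exp(−r_d · (2/s) ln(max(2Ns, 2))) (Haldane recombination
fraction r_d, sweep duration (2/s)ln 2Ns generations), and the
post-sweep frequency is the two-point mixture: with probability p1 the
sweeping haplotype carried the coded allele (center c·p1 + 1 − c),
otherwise center c·p1. Weak selection or distance drive c → 1 and the
model collapses onto the null, which the tests assert to 1e-9. The
observed allele count is binomial around the drifted frequency; the
marginal likelihood uses fixed-order Gauss–Legendre quadrature
(order 64) so scores do not depend on adaptive-quadrature details.
Scores are 2·max over a logarithmic s-grid (10⁻⁴…10⁻¹, 20 steps) of
the windowed composite log-likelihood ratio, floored at 0.

Windows follow the grid convention: points every 4 kb, SNPs within
±half a genetic window (default total 0.1 cM), at most 200 SNPs kept
(uniform, seeded). Windows with fewer than `min_informative` SNPs
segregating in the reference score NaN — a composite likelihood over
one or two SNPs is dominated by single-SNP drift outliers, which the
thin-tailed Gaussian drift model over-rewards. For the same reason the
scan estimates ω robustly: the spec's method-of-moments mean of
(Δp)²/(p1q1) is replaced by the median rescaled by the χ²₁ median
(0.455), which is insensitive to the swept windows themselves and to
the heavy tails of real coalescent drift. The plain mean remains the
default of the public `estimate_omega`.

## Clusters and candidate regions

Empirical p-values use the add-one inclusive rank rule against a
same-statistic background. Clusters are maximal runs of sub-threshold
loci with inter-locus gaps ≤ 100 kb (configurable); singleton clusters
are allowed. Gridded statistics may pad cluster spans by half their
window width, since the value at a grid point summarizes SNPs across
the whole window. Candidate regions are interval intersections of
clusters from different tests, ranked by the number of supporting
tests and then by minimum p.

## Allele age

All carriers are assumed to descend from a single ancestor who
introduced the focal allele n generations ago. For each carrier
haplotype and side, the observation is the first marker discordant
with the carriers' consensus haplotype. With c_j the Haldane
recombination fraction from the focal site to marker j, the ancestral
segment survives past marker j with probability (1−c_j)ⁿ; beyond the
recombination point, markers still match by state with probability
equal to the population frequency of the consensus allele
(identity-by-state tail), and retained markers mutate with probability
1−(1−μ)ⁿ (μ = 10⁻⁶ per generation by default). The per-side outcome
probabilities sum to one exactly for any μ and match frequencies
(enumeration-tested). Sides and haplotypes are treated as independent
— a deliberate simplification that understates uncertainty when
carriers are closely related. The MLE maximizes over an integer grid
(default 1…5,000); the 95% CI is the profile-likelihood set within
1.92 log-units of the maximum; years = n̂ × generation time
(default 25). Modal carrier haplotypes are per-population per-marker
majorities among carriers, ties broken toward the across-population
carrier consensus and then toward the ancestral allele; the consensus
of those modal haplotypes plays the ancestor's role.

## Synthetic data: what it emulates, and does not

The neutral generator produces phased panels under an msprime
coalescent with a star-like demography — populations split from
regional ancestors (default 250 generations ago), regional ancestors
from a common root (default 500), deme size 4,000 diploids, optional
symmetric migration. Defaults give neutral inter-regional F_ST around
0.05–0.1, a realistic background spread rather than a point mass.
Ancestral alleles are simulation truth, so polarization is exact; a
configurable fraction can be masked "unknown".

The default geometry is a 3 Mb chromosome at mutation rate 6×10⁻⁹/bp
and recombination rate 2×10⁻⁷/bp (a 60 cM chromosome). The elevated
recombination rate is deliberate: it shrinks the sweep's footprint to
a few percent of the scanned chromosome, mimicking the situation of a
real chromosome-wide scan where the sweep occupies a small fraction of
the background, at desk-scale sequence length.

`impose_sweep` overlays a hard sweep on one region by forward
Wright–Fisher resampling with genic selection (default s = 0.15,
h = 0.5) and Poisson crossovers on the genetic map. The region's
sampled haplotypes are first expanded into a larger forward deme
(default 3,000 diploids): without this, a sample-sized deme evolved
for the sweep's age loses most of its chromosome-wide diversity to
drift. The sweep starts as ~15 identical copies of one founder
haplotype (a single origin that has just escaped loss), must cross the
target frequency (default 0.9, tolerance ±0.03) within the configured
age (default 180 generations, matching the dated expansion the package
is built around), and is then held at the crossing count — with
recombination continuing — for the remaining generations. Attempts
that lose the allele, overshoot the tolerance or fail to cross restart
with a fresh sub-seed. Holding the frequency is the conditioning
device: it fixes both the present-day frequency and the sweep's age,
which the haplotype statistics are sensitive to. Haplotypes outside
the target region are never touched. The forward phase adds no new
mutations; over 180 generations this slightly inflates test-region
homozygosity, which the chromosome-wide empirical ranking absorbs.

What the generator does **not** emulate: chip ascertainment (real
650K-style panels over-sample common variants, so empirical nulls here
are self-consistent rather than comparable to chip-based ones),
realistic human demography (growth, bottlenecks), gene conversion, and
genotyping error.

The 7-SNP gene fixture samples diploids from seven predefined
haplotypes at configured per-region frequencies (defaults follow the
regional profile of a warfarin-sensitivity haplotype: 89.6% in the
East-Asian analogue region, 4.4% in the African one, intermediate
elsewhere, giving a weighted global frequency near 50%). One
haplotype uniquely carries the derived allele at two designated SNPs,
so D′ = r² = 1 there by construction, and the all-ancestral haplotype
is planted as the H6 analogue.

## Problem sizes in tests and the acceptance script

The simulation studies use two regions of 40 diploids each on the 3 Mb
default chromosome (~2,300 SNPs): sweep-detection power uses 20
replicates in the test suite and 10 in the acceptance script; null
calibration uses two independent panels with ≥500 common SNPs scored;
age recovery uses 50 (tests) or 20 (script) genealogies of 17 carrier
haplotypes at a true age of 181 generations with 60 markers per side.
Null-calibration uniformity is asserted on common SNPs (MAF ≥ 0.05)
because rank p-values of a discrete statistic at rare-variant bins are
atomic and conservative rather than uniform.

## Known limitations

* The EM haplotype layer is exact in likelihood only at gene scale
  (≤12 SNPs); it is not a phasing engine for chromosome-scale data,
  which the package expects pre-phased.
* The XP-CLR drift model is Gaussian and therefore thin-tailed
  relative to real coalescent drift; empirical ranking, window minima
  and the robust ω estimate mitigate but do not remove this.
* The LD-block rule is a simple D′-chaining; published block
  definitions based on confidence intervals will differ near block
  edges.
* Age-estimation treats carrier haplotypes as independent; for
  star-like genealogies this is nearly right, for recent expansions it
  narrows the CI somewhat.
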