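# Methods

## Scope and model

`dsrscan` implements a differentiation genome scan for breed panels:
per-SNP Weir & Cockerham (1984, "WC84") F_ST between two groups of
breeds, genome-wide top-quantile outlier flagging, a two-rule scan for
differentially selected regions (DSRs), interval-overlap gene
annotation with Fisher/Bonferroni term enrichment, and the
population-structure side of such studies (neighbor-joining phylogeny
with locus bootstrap, Evanno ΔK over STRUCTURE output tables). A
Balding–Nichols simulator provides genotype panels with known truth so
every stage can be validated at desk scale.

## Filtering

The retention chain is fixed: autosomes only, then per-breed call
rate. A locus is kept iff, for **every** breed, the fraction of
non-missing genotypes among that breed's retained samples is ≥ the
threshold (default 0.7, boundary inclusive — 7/10 passes, 6/10
fails). Denominators are the samples actually present after any were
dropped at VCF read time, not nominal design counts. The MAF filter
(default ≥ 0.2, inclusive) and random locus subsampling serve only
the reduced panels used by structure-type analyses; MAF is computed on
the pooled retained samples by default, with a per-breed switch. Each
filter is idempotent and the report reconciles removed counts per
stage. Subsampling draws without replacement from a single PRNG
stream keyed by an explicit seed and preserves genomic order.

## The estimator

WC84 components a (among populations), b (among individuals within
populations) and c (within individuals) are computed per SNP from
(n_i, p_i, h_i) tallies; θ̂ = a/(a+b+c). Decisions:

* θ̂ is **undefined** when a+b+c = 0 (monomorphic, no heterozygotes)
  or when either group has < 2 genotyped individuals; undefined loci
  are excluded from quantile computation and scanning but kept (empty)
  in the plot-ready table.
* Negative estimates are **retained**, not clamped: they preserve the
  estimator's null distribution and can never reach the top quantiles.
* Multi-locus values are ratio-of-sums Σa/Σ(a+b+c), the standard
  weighting that is consistent under loci of varying information.
* The vectorised genome scan and the scalar per-locus path share the
  algebra and are cross-checked against each other and against an
  independently coded evaluation in the tests (1e-12).

Both groups are treated as single random-mating populations. When a
group pools several breeds (the intended use: all native breeds as
one population), within-pool structure inflates homozygosity (a
Wahlund effect) and the pooled group's frequency variance shrinks
relative to a single breed's — pooled-contrast multi-locus θ̂ against
a control is therefore systematically below the per-breed drift F.
This is a property of pooling, not an estimator defect; the
calibration checks in the tests therefore use a two-single-population
contrast, where multi-locus θ̂ recovers the simulated F directly.

## Outlier flags and quantiles

The cutoff at level q is the k-th largest defined θ̂ with
k = ceil((1−q)·L) (a small epsilon guards the ceil against binary
floating-point artifacts such as (1−0.99)·100 > 1). A locus is
flagged iff θ̂ ≥ cutoff, so ties at the cutoff are all flagged —
deterministic and order-independent, at the price of occasionally
flagging slightly more than the nominal 1%/5%. Quantiles are computed
genome-wide per contrast (not per chromosome), over defined θ̂ only.
Below 100 defined loci a warning marks the cutoffs as coarse.

## The DSR scanner

Flags are CORE (top 1%), SIG (top 5%; CORE implies SIG), NONE. Per
chromosome, maximal clusters of SIG SNPs are formed in which
consecutive SIG SNPs are separated by at most `gap_max` NONE SNPs
(default 2; the gap is counted in SNPs, not base pairs — the
stopping clause "no more than 2 sequential non-significant SNPs" is
read as: a gap of ≥ 3 terminates the cluster). A cluster containing a
CORE SNP becomes a CORE_SEEDED region bounded by its outermost SIG
members; a lone CORE SNP is a single-SNP region (the rule requires
only a core as a center). A maximal zero-gap run of ≥ `run_min` SIG
SNPs with no CORE becomes a SIG_RUN region; "more than 5 sequential"
is read strictly, so the default run_min is 6 (5 is available by
flag). Overlapping or SNP-adjacent regions merge unconditionally, the
merge inheriting CORE_SEEDED. Region boundaries are member-SNP
positions, 1-based inclusive; BED output converts to 0-based
half-open. The incremental scanner is verified against a brute-force
interval-predicate enumerator on thousands of random flag strings.

## Annotation and enrichment

Gene-model logic (exonic/intronic categories) is deliberately replaced
by plain interval overlap with a configurable flank (default 0 bp):
downstream analyses use genes only as set members. The enrichment
background defaults to all genes in the supplied interval file — a
stated, reproducible universe. Fisher's test is one-sided
(over-representation), p = P(X ≥ k) under the hypergeometric law;
Bonferroni multiplies by the number of terms actually tested (those
with ≥ 1 study hit) and is always reported. The conventional
retention rule (fold > 1 and p < 0.05) filters on the raw p by
default — the literal reading of the rule — with a flag to filter on
the corrected p instead.

## Phylogeny and ΔK

Individual-level distances are allele-sharing:
d(i,j) = 1 − Σ(2−|g_i−g_j|)/(2·L_ij) over co-called loci. Breed-level
distances are pairwise multi-locus WC θ̂ (clamped at 0 to keep the
matrix a distance matrix; negative values only arise under near-zero
differentiation). Which level a published tree used is often
unstated; individual level is the default here.

Neighbor joining is the classical Saitou–Nei agglomeration on
Q(i,j) = (N−2)d(i,j) − Σd(i,·) − Σd(j,·), with branch lengths from the
standard closed forms and the final three nodes joined by the
three-point formulas. Ties in Q break deterministically by the lowest
pair in creation order. Negative branch lengths are retained with a
warning (clamping is an option). On additive inputs the tree
reproduces the input distances exactly (tested to 1e-9); topology is
cross-checked against an independent NJ implementation.

Bootstrap supports resample loci with replacement, rebuild distance +
tree, and score each internal bipartition of the point tree by its
percentage occurrence (default 100 replicates — a desk-scale default;
published analyses often use 10,000, reachable by flag).

Evanno ΔK consumes a (K, replicate, lnP) table: per interior K,
ΔK = mean over replicates of |L(K+1) − 2L(K) + L(K−1)| divided by the
replicate standard deviation (ddof = 1) of lnP at K; the argmax
suggests the number of clusters. Requires ≥ 3 contiguous K and ≥ 2
replicates per K; zero variance at an interior K is an error, and a
zero-curvature profile is reported as a tie with a warning. The
Bayesian clustering itself (and CLUMPP/DISTRUCT post-processing) is
out of scope — only the published tools' numeric output is consumed.

## The simulator

Background loci follow the Balding–Nichols model: ancestral frequency
p_anc ~ U(0.05, 0.95); each breed draws
p_b ~ Beta(p_anc(1−F)/F, (1−p_anc)(1−F)/F) with F = background_F, so
Var(p_b) = F·p_anc(1−p_anc) and F is the expected locus-wise F_ST;
genotypes are Binomial(2, p_b), with uniform random missingness
(default 5%; a per-breed override exists to exercise the per-breed
call-rate filter).

**Windows.** A window is meant to emulate a region *differentially
selected* between two breed groups. Giving every breed an independent
high-F draw does not do that: two groups independently drifted at
F = 0.7 fix the *same* allele roughly half the time, so half the
window SNPs carry no between-group signal, and a scanner keyed to
runs of consecutive outliers cannot recover such windows reliably at
realistic sample sizes. Window loci therefore implant the divergence
by construction: the two groups' base frequencies are
p̄ ± √(F·p̄(1−p̄)) — the frequency pair whose parametric between-group
F_ST equals the window F exactly — with a random sign per locus
deciding which group carries the high allele, and p̄ equal to p_anc
shrunk into the feasible band [F/(1+F), 1/(1+F)] (outside it no
frequency pair attains the requested F_ST; biologically, a sweep
shifts the mean frequency). Every breed then drifts around its
group's base at background_F, so within-group variation in windows
stays at background levels while realised per-SNP θ̂ scatters around a
value somewhat above the implanted F (the residual breed drift adds
between-group variance).

The canonical desk-scale scenario is 8 breeds × 10 samples (seven
natives + one control), 5 chromosomes × 4,000 SNPs at 1 kb spacing,
background F = 0.05, ten 25-SNP windows at F = 0.7 (two per
chromosome), 5% missingness, fixed seed. Recovery is scored against
the truth windows at ≥ 50% reciprocal SNP-index overlap; under these
conditions the default pipeline attains sensitivity 1.0 with FDR
under 0.1 (the occasional false call is a single-SNP core region from
the background θ̂ tail).

**What the simulator does not emulate:** linkage disequilibrium (loci
are independent draws — defensible because every statistic here is
single-SNP, but it means the simulated flag sequences lack the
spatial autocorrelation real sweeps produce), demographic history,
migration, reference-bias or depth-dependent missingness, and
genotyping error. Passing tests therefore validate the statistical
machinery and the scanning rules, not the biological calibration of
thresholds on real data.

## Problem sizes and numerical choices

Tests and the acceptance script run the 20,000-SNP scenario, a
10,000-locus two-population calibration (F = 0.15 recovery within
[0.13, 0.17]), and 100-replicate bootstraps on 20-taxon trees — sizes
chosen so the full suite completes in seconds on one CPU while every
statistical claim is still sharply testable. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`;
reruns are byte-identical. Degenerate inputs (all-missing loci,
monomorphic loci, empty groups, single-replicate ΔK tables, pairs
with no co-called loci) raise informative errors or produce flagged
undefined values rather than silent numbers.

## Known limitations

* The two-group estimator treats a pooled breed group as one
  population; pooled-contrast θ̂ is not an estimate of the per-breed
  drift F (see above). Multi-population hierarchical F-statistics are
  out of scope.
* The scanner's gap rule counts SNPs, not base pairs; on panels with
  very uneven SNP density a bp-based rule could behave differently.
* Enrichment assumes the supplied interval file is the correct
  universe; no ontology traversal or term-hierarchy propagation is
  performed.
* Single-SNP CORE regions are admitted by design; on real data users
  may wish to post-filter regions by n_snps.
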