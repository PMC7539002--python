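# Methods

## The model

`dcescan` treats a chromosome as a sequence of fixed-width expression
bins and defines a *domain of co-ordinated expression* (DCE) as a run of
consecutive bins whose expression profiles across the samples of one
group are significantly inter-correlated, delimited by boundaries that
survive an explicit statistical test.  The calling strategy adapts a
TAD-style sliding-window segmentation from chromosome-contact maps to
correlation matrices; the substitution is legitimate because both
objects are symmetric, positionally ordered similarity matrices in which
a domain appears as a dense diagonal block.

The assumptions worth stating:

- **Co-expression is locally block-structured.**  The signal the caller
  looks for is a contiguous block of elevated pairwise correlation.
  Long-range (intra-chromosomal but non-adjacent) and inter-chromosomal
  co-expression is invisible by design; the correlation matrix is only
  ever computed within a chromosome.
- **Binning is a spatial smoother.**  A bin's value is the mean
  normalized expression of the genes overlapping it, so a domain
  boundary can never be localized more precisely than one bin
  (10 kb by default).
- **Monotone group-level normalization is sufficient.**  Spearman
  correlation makes every step invariant to monotone per-bin
  transformations; the RLE + gene-length normalization matters only
  insofar as it removes per-sample library effects that would otherwise
  correlate all bins of a sample.

## Pipeline stages and their parameters

### Preparation (`io_prep`)

Fixed composition order: biotype filter → duplicate filter → nonzero
filter → RLE → length normalization.  The excluded-biotype list covers
the fourteen pseudogene/antisense/non-coding classes irrelevant to the
analysis; spellings are normalized (lowercase, separators to
underscores) so that hyphen/space variants of the same biotype match.
Gene names annotated on more than one chromosome are dropped as
ambiguous; duplicates on one chromosome are collapsed to their union
span so names are unique.

RLE size factors are median-of-ratios against the per-gene geometric
mean over **all** samples jointly (healthy and patients together), so
groups stay on one scale; the output of median-of-ratios is defined up
to the geometric-mean reference, i.e. rescaling one sample changes the
whole normalized matrix by a single global factor — irrelevant
downstream, but the reason the scaling-invariance test compares matrices
after removing one global factor.  Gene length is the annotated body
span (end − start) in kilobases (`scale = 1000`): the spec of an
exon-union length would need exon features the gene-level table does not
carry, and binning uses body coordinates anyway; as a pure per-gene
rescaling it cannot change any rank correlation across samples.

SLEDAI stratification: low ≤ 2, intermediate 3–8, high > 8; healthy
passes through.  Cohort sizes are data-dependent, never assumed.

### Binning (`binning`)

Bins of `bin_size = 10 000` bp anchored at the first gene's start and
ending at `ceil` of the last gene's end.  A gene contributes to every
bin its span overlaps by ≥ 1 bp (`assignment = "overlap"`); the
alternative `"tss"` assigns it only to its strand-aware 5′ bin.  Overlap
is the default because typical genes exceed the bin size and dropping
all but one bin would discard most positional information.  Bins with no
genes, zero expression in the group under analysis, or zero variance are
flagged missing and removed before correlation; an index map converts
the surviving-bin axis back to genomic coordinates.

### Masked correlation (`correlation`)

Spearman ρ between all surviving bins (average ranks across the group's
samples, then Pearson on ranks, computed with matrix algebra so a
permutation round costs one rank pass plus one matrix product).  The
Monte-Carlo mask shuffles each sample's bin values independently,
rebuilds the full matrix once per round (`n_perm = 1000` by default,
reduced in the desk-scale benchmarks) and counts rounds whose
coefficient is at least as extreme as the observed one — two-sided on
|ρ|, since negative co-expression is as extreme as positive; a one-sided
variant is available.  p = count / n_perm (the plain fraction, so the
smallest attainable p is 0), and entries with p > `mask_alpha = 0.05`
become zeros.  Round *k* draws from `SeedSequence(seed, spawn_key=(k,))`,
which makes the mask bit-for-bit reproducible and chunkable.

Under a global null the retained off-diagonal fraction estimates the
mask's effective level: with the plain-fraction estimator and the
observed matrix exchangeable with the permuted ones, the expected
retention is (⌊α·n_perm⌋ + 1)/(n_perm + 1), ≈ 0.052 at α = 0.05 and
n_perm = 500 — the value the calibration benchmark reproduces.

### Domain calling (`detection`)

*Bin signal.*  Two juxtaposed `w = 3` bin windows slide with single-bin
steps; the value at position *i* is the mean of the w × w cross-window
block `masked_rho[i−w+1..i, i+1..i+w]` — cross-window entries only,
because the quantity of interest is how strongly the two flanks
correlate with each other, and masked (zeroed) entries count as zeros.
The value describes the junction between bins *i* and *i + 1*.  The
first and last w − 1 positions have no full window pair; they inherit
the nearest admissible value and can never open a domain or host a
minimum.

*Minima and initial domains.*  A cubic smoothing spline (penalty chosen
by generalized cross-validation; short or constant signals fall back to
the raw values) is evaluated at the bin positions, and strict
slope-sign-change minima — plateau minima take the leftmost bin — with
smoothed value below `threshold = 0.25` become candidate boundaries.
Because signal(*i*) describes the junction *i*|*i + 1*, a boundary
minimum at *i* closes the upstream segment inclusive of bin *i*.
Initial domains are the segments between consecutive qualifying minima
that contain at least one above-threshold bin; all-low segments are
background.  The 0.25 constant is the genome-average signal of the
reference (healthy) group in the motivating study; `threshold = "auto"`
recomputes it from a designated reference group.  Segments are broken
wherever they would bridge more than `max_missing_gap = 2` consecutive
missing bins in genomic space, which prevents spurious mega-domains
across gene deserts.

*Boundary evaluation.*  For each boundary, "within" is the set of
pairwise coefficients among the (up to) w domain bins adjacent to it and
"between" the w × w cross block spanning it; a one-sided Mann–Whitney
test (within > between) at `alpha = 0.05` either validates the boundary
or chops it one bin toward the domain centre and retests.  Domains
shrinking below `min_size = 2` bins (one bin has no within pair) are
discarded.  The left boundary is refined before the right; since the
tests share no bins once the domain is wider than 2w, the order only
matters for domains already near the discard limit.  Sample sizes here
are tiny (3 within vs 9 between at w = 3), so the test enumerates all
label assignments exactly on midranks up to 8 observations per side and
uses the tie-corrected normal approximation beyond.  This generous-
segment-then-chop design is what gives bin-level boundary precision: the
initial segments deliberately overshoot into the flanks and the test
walks them back to the last position where the interior is demonstrably
more correlated than the exterior.

*Fusion.*  A greedy left-to-right pass merges consecutive domains when
the gap holds 1–2 bins, every gap bin has raw signal < 0.25, the chain's
cumulative intervening low-signal bins stay ≤ 2, and the chain holds at
most 3 original domains.  Adjacent domains with no gap are never merged:
they are separated by a boundary that just passed the test, and undoing
it would contradict the evaluation step.  Fused domains keep the
outermost boundary p-values and recompute their mean signal over the
full span.

*Window tuning.*  `tune_window` re-runs the calling stages (the mask
does not depend on w) for each candidate and returns the w maximizing
mean within-domain masked correlation, ties to the smallest.

### Dynamics (`dynamics`)

Labels come from the bipartite overlap graph with fixed precedence:
no partner → *depleted* (reference side) / *emerged* (query side);
one domain overlapping ≥ 2 partners → *split* or *merged*; remaining
one-to-one pairs → *intact* when Jaccard ≥ `intact_jaccard = 0.8`, else
*expanded* / *contracted* by the query's relative length (equal lengths
count intact).  A one-to-many event is a fragmentation (split) when the
partners' union stays within the single domain ± one bin of tolerance;
partners that reach far outside it make the event a merge instead.  The
rule is swap-symmetric: exchanging reference and query maps
depleted↔emerged, split↔merged, expanded↔contracted and fixes intact.
The Jaccard cutoff and precedence are this package's reconstruction —
the category definitions leave the quantitative rule open — and both are
configurable and recorded in the output.  `min_overlap_frac` guards
against 1-bp contacts flipping a call.

BP distance between two segmentations (uncovered regions completed as
background segments so each set partitions the chromosome):

    d(A, B) = 1 − (1/N) Σ_{a∈A, b∈B} |a ∩ b|² / max(|a|, |b|)

symmetric, in [0, 1], zero exactly for identical partitions; reported
per chromosome and as a length-weighted genome mean.  Disruptor genes of
a split event must (i) overlap the reference domain, (ii) overlap no
query domain, and (iii) intersect the gap between the query fragments;
all three conditions are asserted per gene.

### Enrichment (`enrichment`)

The null model re-places the domain intervals uniformly at random within
their own chromosome's *eligible territory* — the surviving expressed
bins — preserving sizes and forbidding overlaps (stars-and-bars gap
sampling with randomized interval order, so every arrangement is equally
likely).  Placement within the chromosome preserves both size and
chromosome composition, the two first-order covariates of genomic
overlap statistics.  Empirical p-values here use (k + 1)/(n + 1) — an
enrichment call should not be able to report p = 0 — unlike the
correlation mask, which follows the plain-fraction convention;
the asymmetry is deliberate and documented.  Track enrichment measures
bp overlap per label, reports untestable labels (absent from covered
chromosomes) as NaN rather than zero, and corrects across testable
labels with Benjamini–Hochberg.

An enhancer–promoter link is *nested* in a segmentation when promoter
position and enhancer interval fall inside one domain, and *disrupted*
when nested in the reference but not the query; links never nested in
the reference are excluded from the denominator.  Cell-type proportion
entropy is H = −Σ p log₂ p (zero terms contribute 0, H ∈ [0, log₂ n]),
with groups compared by the same exact-when-small rank-sum test.

## The synthetic generator

`simulate` emulates exactly the structure the model assumes: genes tile
the chromosome (default one per bin, non-overlapping, fixed start
margins so the bin grid aligns with the planted geometry), each planted
block shares a per-sample latent factor g ~ N(0, 1) entering the
log-mean with loading λ (default 1), per-gene lognormal baseline means
(log-mean log 100, log-sd 1), independent lognormal noise (sd 0.3,
a realistic bulk biological CV), and negative-binomial sampling with
dispersion 0.1 (var = μ + 0.1 μ²).  Group differences are expressed only
through block presence and geometry — never through library-size
confounds — so recovery failures indicate caller defects.

Scenario layouts keep planted blocks under ~⅓ of the chromosome.  This
mirrors real transcriptomes (domain coverage in the motivating study is
9–19% of the genome) and is also a statistical requirement of
median-of-ratios normalization: if co-regulated blocks dominate the
gene set, the size factors absorb the block latent factor and re-export
it to every background gene as a common factor, manufacturing spurious
genome-wide correlation.  The generator therefore emulates the regime
the normalization is valid in.

What the generator does **not** emulate: isoform structure, GC and
mappability bias, batch effects, cell-type mixture shifts, distance-
decaying (rather than block-constant) co-expression, and overlapping or
nested domains.  Passing benchmarks therefore demonstrate correctness of
the machinery under the model's own assumptions, not performance on real
cohorts.

## Benchmark problem sizes

The synthetic benchmarks run at desk scale, chosen to keep the full
suite in minutes on one CPU while leaving every statistical conclusion
stable: boundary recovery on one 500-bin chromosome with ten blocks of
8–30 bins and 50 samples/group at 200 mask permutations; null
calibration on 40 i.i.d. bins × 30 samples at 500 permutations over ten
seeds; the null call rate on 200 shuffled bins over ten seeds; scenario
accuracy over 20 replicates per scenario at 200 permutations; oracle
equivalence on 100 random instances per primitive; and the fusion audit
over all 41 371 domain/gap layouts up to five domains with gaps ≤ 3
bins.

## Numerical choices and degenerate inputs

- Permutation extremeness uses ≥ on floats; exact ties with the observed
  coefficient count as extreme, matching the "same or more extreme"
  convention.
- The masked matrix keeps its unit diagonal; self-correlation is not
  subject to masking (no test downstream reads it).
- Constant bins (zero variance) are dropped before correlation and
  reported, not silently NaN-ed.
- The smoothing spline falls back to the raw signal for fewer than five
  points, constant input, or a singular GCV system.
- `rank_sum_test` enumerates C(n₁+n₂, n₁) assignments up to 8 per side
  (worst case 12 870), beyond which the normal approximation's tie
  correction applies.
- Empty domain sets are valid everywhere (classification labels nothing,
  coverage is 0, enrichment observes 0 in the depletion direction).
- All stage seeds derive from one master seed through fixed
  `SeedSequence` spawn keys, so any stage can be re-run independently
  with identical results.

## Known limitations

- Boundary placement is bin-quantized; sub-bin boundaries are invisible.
- The boundary test's exact p-values are coarse at w = 3 (minimum 1/220),
  so `alpha` effectively acts as a rank threshold there.
- One-to-many dynamics events involving heavily interleaved domains on
  both sides resolve by the bp-dominance rule and can be order-dependent
  in pathological layouts.
- The enrichment null preserves interval sizes and chromosome identity
  but not inter-domain spacing.
- CIBERSORT-style deconvolution, WGCNA module fitting, differential
  expression and network analysis are out of scope; their outputs
  (proportions, module gene lists, signatures) enter only as plain
  inputs.
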