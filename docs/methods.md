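# Methods

## The measurement being modelled

Linker-mediated PCR enrichment ligates a synthetic linker to sheared
genomic DNA and amplifies between the linker and an LTR-specific primer.
Every informative read therefore touches the 5'-LTR/genome junction on the
primer side and extends into flanking sequence as far as its sheared
fragment allows. In coverage space this produces a characteristic
asymmetric peak: a blunt edge exactly at the junction and a tail whose
decay is the survival function of the fragment-length distribution.
`ltrmap` exploits exactly this geometry — calling sites from coverage,
reading LTR polarity from which edge is blunt — and everything upstream of
aligned coordinates (trimming, alignment) is outside its boundary.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: three cat
populations of 7, 6 and 7 individuals, each population with a shared pool
of inheritable integration sites plus private per-individual sites.

Parameters (units, default, rationale):

- `fragment_mean` (bp, 400): the targeted shear size. `fragment_sd`
  (bp, 80) is a free shape parameter; fragment lengths are drawn from a
  normal truncated to [1, 3x mean].
- `read_length` (bp, 500): the mappable footprint cap per fragment,
  modelling the ~500 bp span of 2x250 bp paired-end reads. Keeping it above
  `fragment_mean` lets the fragment distribution, not the cap, shape the
  coverage tail, which is what makes polarity legible.
- `target_junction_depth` (reads, 200): per-site read counts are
  Poisson-distributed around this, reflecting the overdispersed-count
  character of enrichment libraries while keeping expected depth a direct
  control.
- `background_read_rate` (reads/Mbp, 100 = 0.1 per kbp): uniform
  off-target reads.
- `shared_site_pool_size` (30 per population), `inheritance_probability`
  (0.5), `private_site_rate` (8 per individual): chosen once as a
  desk-scale analogue of a cohort whose loci are roughly half inherited;
  they produce per-individual maps of ~20–25 sites on the default 15 Mbp
  toy genome (three chromosomes, two env loci each). Real per-individual
  totals are an order of magnitude larger on a 2.5 Gbp genome; the
  geometry per site is scale-free.
- `min_separation` (bp, 2000): placement rejects positions within this
  distance of an env locus or another site of the same individual — twice
  the downstream env-exclusion window, so truth sites are never
  collaterally flagged and never merge within an individual.

Env proviral loci emit the same junction-style read stack (anchored at the
locus edge, tail into flanking DNA) so the env-exclusion stage has real
work to do.

What the generator does **not** emulate: base-level sequence, sequencing
error, PCR duplicates, mappability variation, repeat-mediated multimapping,
or correlated fragment sizes. Passing tests therefore demonstrate that the
calling and comparison logic is correct under the stated geometric model,
not that real libraries are free of artefacts the model omits.

## Site calling

Coverage is an exact per-base pileup kept as collapsed runs (bedGraph
semantics). Candidate intervals are maximal regions with depth >=
`coverage_floor` (default 1). Filters are strict on all three bounds:
length > 100 bp, length < 1000 bp, peak depth > 100x. The depth cut applies
to the **peak** per-base depth of the interval: junction-anchored
enrichment concentrates its evidence at the junction, so the peak (not the
mean) is the natural reading of a depth threshold for this assay.

Polarity: an interval edge is blunt when depth reaches
`blunt_fraction` x peak (default 0.5) within `blunt_tolerance` bp (default
10) of the boundary. Exactly one blunt edge fixes polarity and puts the
junction at that boundary; zero or two blunt edges yield `ambiguous`, with
the junction at the interval edge nearer the coverage peak (nearest
peak-depth base, so plateaus resolve sensibly). The two blunt-edge
parameters are not dictated by the assay; 10 bp / 0.5 were chosen to
tolerate single-read ragged ends and are exposed in configuration.

Near-duplicate junctions within one individual (< 200 bp, the same
tolerance as the cross-individual rule) collapse to the deeper call before
env exclusion. A site whose interval, padded by `env_window` (1 kb) on both
sides, overlaps an env locus is flagged and reported in a secondary table
rather than dropped silently: these signatures arise from reference-fixed
proviruses, not from an integration private to the sampled individual.

Known limitation: with `coverage_floor` 1, a background read that happens
to overlap the junction-side edge of a site extends the interval past the
junction, defeating the blunt-edge rule; the call then goes ambiguous with
its junction at the extended edge. At the default background rate this
affects a few percent of sites (junction recall and precision at ±5 bp
measure ≈ 0.95 on the default design) and can be suppressed by raising
`coverage_floor`.

## Cross-individual unification

The "same locus if junctions differ by < 200 bp" criterion is not
transitive, so clustering is a deterministic greedy leader pass: per
chromosome in junction order, a call joins the open cluster iff its
junction is within the tolerance of the cluster's **leftmost** member,
else it founds a new cluster. This bounds within-cluster spread by the
tolerance and prevents unbounded chaining; consecutive leaders are >=
tolerance apart, so re-clustering leader representatives is a no-op. A
cluster's reported junction is the median of member junctions (the leader
junction is kept alongside). If one individual contributes two calls to a
cluster, the deeper call wins. Distances are measured between inferred
junctions (not interval starts); this choice is configuration-visible.

Prevalence classes follow the usual population-genetic reading: singleton
(one individual), present in at least k (default k = 10), fixed (all
individuals). "Unique" counts are cohort-wide singletons, not
per-population ones. The population comparison runs a Kruskal–Wallis test
implemented from the rank formula with mid-rank ties and tie correction,
p from the chi-square approximation with k−1 degrees of freedom (all-tied
input returns H = 0, p = 1 rather than erroring); an independent library
implementation serves as a test oracle only. The with/without-outlier dual
analysis drops the named individual's row (and its singleton loci) and
repeats both tests.

## Proximity annotation

Distances are measured from the cluster junction to the nearest gene-body
base (0 when inside the gene); the assay does not resolve which provirus
edge drives transcription, so a body-anchored distance is the conservative
choice. Enhancer distance: body within 1 Mb (the generally accepted
maximal reach of LTR enhancer action). Promoter distance: TSS within 1 kb
**downstream** of the junction, where downstream follows the cluster's
consensus LTR polarity (a promoter drives transcription off its 3' end);
clusters with ambiguous polarity, and runs with `promoter_oriented` off,
use an unoriented ±1 kb TSS window. The promoter set is always a subset of
the enhancer set. The interval-tree index is verified against an all-pairs
scan in tests.

## Expression overlay

CPM is plain library-size normalization; the expressed-gene filter keeps
genes with >= 1 CPM in at least ceil(0.25 x n_samples) samples. Contrasts
compare group-mean CPM with a 0.5-raw-count pseudo-count (converted to CPM
at the mean library size) inside a log2 ratio; significance combines a
label-permutation p-value on |logFC| (add-one estimator, seeded,
10,000 permutations by default) with Benjamini–Hochberg correction and the
effect-size rule |logFC| >= 1, q <= 0.05.

The permutation framework is this package's deliberate replacement for a
negative-binomial GLM with likelihood-ratio tests: it is self-contained,
exactly reproducible under a seed, and calibrated under the null (the
overlay's false-positive rate at the significance rule is verified to stay
within Monte-Carlo error of the nominal level). Its cost is granularity at
small n: with 4 vs 4 samples only 35 distinct splits exist, so the
smallest attainable p is 1/35 ≈ 0.029 and significance after correction is
reachable only on small per-site gene panels — which is the regime the
per-cluster promoter/enhancer contrasts actually operate in. LTR presence
is coded per individual (an expression sample carries a cluster when its
individual does), and a cluster is testable only with at least 3 carriers
and 3 non-carriers among the expression samples.

When panels are cut from the full matrix, library sizes are taken from the
whole library, never from the panel, so CPM stays on the library scale.

## Pipeline and determinism

One run-level seed governs every stage; per-stage and per-individual
streams are derived via independent seed sequences, so identical
configuration yields byte-identical outputs regardless of execution order.
Each run writes a manifest (version, seed, full parameter set, per-stage
record counts) and enforces three conservation invariants at run time:
pileup area equals summed read length; cluster prevalences sum to the
number of unified calls; the sharing matrix is symmetric with each
individual's total on the diagonal.

## Problem sizes used in the shipped checks

The automated checks run the default study design (20 individuals, 15 Mbp
toy genome) over 20 seeds for truth recovery, 100 random read sets up to
1 Mbp for coverage-oracle equivalence, 100 random group sets for the
rank-test oracle, and 5 x 250 null genes for overlay calibration — sizes
chosen so the whole suite completes in a few minutes on one core while
keeping Monte-Carlo error small relative to the tolerances asserted.
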