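# Methods

`ltrtx` quantifies transcription of LTR retrotransposons from two kinds of
transcriptome data that only admit *exact-match* placement: short sequencing
reads (30–51 nt, no strand information) and strand-tagged 60-mer tiling
probes carrying log2 intensities normalised against an intergenic baseline.
Because LTR sequences are highly redundant, the package never claims to
measure per-locus expression; it computes *bounds* and tests *hypotheses
about variation between loci* with permutation nulls.  This note documents
the models, the defaults and the numerical choices.

## Coordinates and feature model

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the I/O boundary.  A `FeatureCatalog` holds chromosome
sequences and a flat feature list (`ltr`, `retro_internal`, `gene`,
`intron`, `trna`, `snorna`).  Malformed annotation lines fail hard with the
line number; silently skipping annotation rows is a classic source of
irreproducible feature sets.

**LTR partition.** An LTR within `gap_tol` bp (default 50) of a
retrotransposon-internal sequence on its correct side is a *flanking* LTR;
every other LTR is *solitary*.  A chain LTR–int–LTR–int–LTR is modelled as
two elements sharing the middle LTR, so n elements own 2n − 1 distinct
flanking LTRs when one such chimera is present.  The 50 bp tolerance is an
annotation-hygiene allowance: curated annotations abut the features exactly,
but small gaps between an LTR record and its internal record should not
break the element.  An internal sequence with fewer than two adjacent LTRs
is excluded with a warning and its neighbours revert to solitary.

**Background.** Intergenic background excludes protein-coding genes padded
by 240 bp on both sides (a UTR allowance), tRNAs, snoRNAs, LTRs and
retrotransposon-internal sequence; only stretches ≥ 100 bp count.  Internal
retrotransposon sequence is excluded even though it is not one of the named
compartments — calling it "intergenic" would contaminate the baseline with
the very signal under study.

## Exact mapping and the exclusivity filter

A query's hits are all verbatim occurrences of its sequence (forward strand)
or of its reverse complement (reverse strand) anywhere in the genome.  No
mismatches, no indels; queries containing N are dropped.  Palindromic
queries yield one deduplicated forward hit per position.  Classification
against a target set uses full containment of the hit interval in a set
feature (partial overlap is out-of-set — the strictest reading):

* **unique** — exactly one genome-wide hit, inside the set;
* **exclusive** — two or more hits, all inside the set;
* **excluded** — anything else.

`unique_only` mode demotes exclusive records to excluded: this is the rule
for solitary-LTR probes and for all non-LTR reference features, whereas
reads and probes on the full-length element set may be exclusive (the two
flanking LTRs of an element are nearly identical, so demanding uniqueness
there would discard almost everything).  The matcher is a straightforward
per-chromosome string scan; correctness is asserted against an independent
byte-wise sliding-window oracle in the test suite, which is the actual
contract — the index structure is free.

Reads contribute to locus counts regardless of which genome strand they
matched (library strand information is absent); probes report transcription
on their strand tag.

## Bounding per-locus activity

Let a query hit the loci S (a locus may consist of several intervals — a
full-length element is two LTRs plus the internal sequence).

* **equal-split**: each locus in S receives signal / |S|.  Totals are
  conserved; this is the "all loci equally active" lower scenario.
* **single-locus-max**: every locus receives the full signal of every query
  that could have come from it, *independently per locus*.  This is a
  per-locus upper bound, deliberately not a globally consistent allocation —
  solving the joint assignment would be an optimisation problem whose answer
  the data cannot identify anyway.
* **unique-only**: the floor from uniquely-mapping evidence.

For every locus, unique-only ≤ equal-split ≤ single-locus-max (asserted as a
property test).  Locus abundance for cross-feature comparisons uses
log10(read count) rather than density: under 3'-biased library chemistry,
reads-per-bp is biased against long loci (full-length elements are among the
longest transcription units in a compact genome), while the absolute count
is length-agnostic.  The log10 pseudocount defaults to 0 and must be set
> 0 explicitly when zero counts are present.

## Solitary-LTR clustering, projection, flanks

Pairwise identity comes from a global alignment (match +1, mismatch −1, gap
−2) as identical columns / total columns — gaps count in the denominator, so
length differences are penalised.  Clusters are single-linkage components at
an identity threshold (default 0.70); a threshold-sweep table
(`cluster_size_sweep`) is provided as a diagnostic, with no automatic
selection rule.  Cluster order is canonical (smallest member id), making the
clustering input-order invariant.

Mappings are projected onto a multiple alignment (produced externally; the
aligned FASTA is an input) via the midpoint of the mapped interval —
left-of-centre for even lengths — transferred to that residue's column.
When a query hits several aligned loci, the first locus in the caller's set
order wins; for full-length elements the convention is to order each
element's 3' LTR first, so probes hitting both flanking LTRs land on the 3'
LTR.  Read density along the alignment is a centred 301-column moving
average divided by the number of aligned sequences; the window mean is
truncated at the alignment ends (the denominator is the number of columns
actually covered, so uniform input gives a flat profile).

Flank frames extend a solitary LTR by up to 500 bp on each side.  If the
nearest annotated feature is closer than 1000 bp, only half that distance is
used; if the half-distance falls below 60 bp, no flank is taken.  Frames are
truncated at chromosome edges.  The in-LTR vs flank contrast compares probe
intensities by compartment (assignment by containment of the probe's single
genome-wide hit) with Mann–Whitney tests.

## Statistics

**Mann–Whitney.** U is reported for the first-named group as #{x > y} plus
half the ties.  For n_x + n_y ≤ 12 the two-sided p is an exact enumeration
over all group assignments of the pooled values (ties included); larger
samples use the tie- and continuity-corrected normal approximation
(scipy).  Fully degenerate input returns p = 1.

**Between-locus variance test.** Observed statistic: sample variance (n − 1
denominator) of per-locus mean probe intensities, per strand.  Null: pooled
intensities reshuffled onto loci preserving each locus's probe count,
10,000 replicates by default.  When the count-preserving assignment space
has at most 10^5 members the full enumeration replaces sampling.  Empirical
p is (1 + k)/(N + 1) for sampled nulls and the exact k/N for exhaustive
nulls — with a complete enumeration the identity assignment is already one
of the N outcomes, so the add-one correction would double-count it.  The
test is invariant to locus relabelling and to affine transformation of all
intensities (both asserted).

**Meiosis profiles.** Stage profiles are uniquely-mapped read counts for
growth plus five meiotic stages M1–M5; log2 ratios are taken against growth
(pseudocount 0 by default — the selection thresholds of 30 total / 10
growth reads guarantee a nonzero baseline; a configurable pseudocount
handles zero stage counts).  LTRs enter the coupling analysis when they pass
both count thresholds and lie within 1000 bp upstream (gene-orientation
relative) of a protein-coding gene.  Two statistics are computed: the
Pearson correlation over all pairs' concatenated stage log-ratios, and the
median per-pair correlation (five meiotic points per pair; growth is the
baseline, not a data point).  The permutation null shuffles LTR values among
LTRs independently *within each stage* — preserving every stage's marginal
distribution while destroying the LTR–gene pairing — and records the median
correlation; two-sided p doubles the smaller tail (count/N) and is floored
at 1/N, so a single exceedance in 10,000 reports 2 × 10⁻⁴.  Pairs with a
constant profile (undefined correlation) are dropped with a log message.

**Set-level profiles.** Reads mapping exclusively to an LTR set divided by
the stage's library size, expressed as log2 versus growth.

## Synthetic data: what it emulates, and what it does not

The generator plants, on i.i.d. uniform background sequence: full-length
elements (ancestral LTR and internal sequence, per-element mutation, two
near-identical flanking LTRs, optionally one chimeric chain), solitary LTRs
from the same LTR ancestor at higher divergence, intron-bearing genes, and
a few structural RNA genes.  Transcripts: full-length elements run from
mid-5'-LTR to mid-3'-LTR (transcription initiates roughly halfway into the
5' LTR and terminates in the 3' LTR) on both strands, polyadenylated,
antisense at a configurable fraction of the sense rate; solitary LTRs span
the LTR only, both strands at equal rates, not polyadenylated; genes are
forward-strand and polyadenylated.  Probe intensities follow
log2((Σλ + b)/b) for the transcripts on the probe's strand containing an
exact probe hit, plus Gaussian noise (SD 0.3 log2 units).  Reads are
Poisson per transcript (rate × stage factor × depth), with start positions
weighted exp(β·u) toward the 3' end (β = 2 by default; β = 0 is uniform —
the exponential law is an artifact choice, only the existence and direction
of the bias being an empirical fact), lengths uniform on 30–51 nt, a 0.2%
N-injection rate, and a poly(A)-selection mode that multiplies
non-polyadenylated transcript rates by 0.1.

Key divergence defaults are derived from what exact 60-mer matching implies.
A probe window is unique to its locus essentially iff that window contains
at least one locus-specific substitution, so the unique-probe fraction of a
family is ≈ 60 × d.  Observed full-length-element data of this kind show
only ~4% uniquely mapping probes, giving d ≈ 0.0007 between family members
(`element_divergence`); the two flanking LTRs of one element are more
similar still (0.0005).  "Hot" loci (the few-hot-loci regime,
`hot_fraction`/`hot_share`) receive extra divergence (0.007): the
transcribed elements in the motivating system include frame-shifted
pseudogene copies, i.e. the active loci are also the diverged ones, and it
is precisely this coupling that makes unique probes informative about which
loci are hot.  Solitary LTRs use d = 0.10, placing pairwise identities near
0.80 — above the 0.70 clustering threshold but far too diverged to share
60-mers, so solitary probes are effectively always unique.

A configurable fraction of genes is planted with an upstream solitary LTR
100–800 bp away; those LTRs get a higher rate (they are the loci that pass
the read-count selection) and their meiotic stage factors are correlated
with the neighbour gene's at `gene_coupling_rho` (log2 factors N(0, 1),
gene factor = ρ·z_LTR + √(1−ρ²)·ε).

Not emulated: GC content and compositional heterogeneity, sequencing
errors and quality scores, paired-end reads, indel divergence, splicing
(gene reads are drawn from the unspliced extent so that every read occurs
verbatim at its source locus), and any chromatin- or pathway-level
regulation.  Passing tests therefore demonstrate the *procedures* —
filters, bounds, projections, permutation machinery — under a controlled
rate model, not performance on real libraries.

## Problem sizes and determinism

Default desk-scale conditions: one 200 kb chromosome, 13 full-length
elements (one chimeric chain), 40 solitary LTRs, 30 genes, 60-mer probes
tiled every 60 bp on both strands, depth 50 expected reads per unit rate
per stage.  Calibration runs in the test suite use 20 loci × 5 probes and
199-replicate nulls over 1000 datasets (type-I error), 500 datasets (power),
8 LTR–gene pairs with 400–2000-replicate nulls for the coupling analyses —
sizes chosen so the whole suite runs in about a minute while keeping Monte
Carlo error well inside the asserted intervals.  Every simulation and every
permutation test takes an explicit seed, and identical (config, seed) gives
byte-identical outputs; pipeline reports embed the seed.

## Known limitations

* `single_locus_max` bounds are not jointly attainable across loci; they
  are per-locus ceilings only.
* The exact matcher is a plain scan — fine at desk scale (≤ a few Mb ×
  10⁴–10⁵ queries), not built for mammalian genomes.
* Pairwise identity depends on one optimal global alignment; co-optimal
  alignments can differ in the third decimal, which is irrelevant at a 0.70
  threshold but means identities are not unique to machine precision.
* With fewer than ~5 LTR–gene pairs the within-stage shuffle null is too
  coarse for stable p-values; the pipeline reports and skips rather than
  guessing.
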