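# Methods

## Interval semantics

All coordinates are 0-based half-open (BED). *Overlap* means at least one
shared base, so bookended intervals `[a,b)`/`[b,c)` do not overlap; they do,
however, merge at gap 0, matching `bedtools merge` defaults. Gap-merging
joins intervals whose distance `next.start − prev.end` is ≤ the gap
(300 bp for dataset combination, 0 for final class unions), and two inputs
end up in one output interval exactly when a chain of within-gap neighbours
links them.

Two different semantics coexist deliberately and are kept separate in the
API. Merging collapses records into new spans. Filtering
(`intersect_any` / `subtract_nonoverlapping`) keeps or drops *original*
records unchanged — names, scores and duplicates included. The temporal
classifier is defined entirely in filtering terms (chains of keep/drop
steps), not on a precomputed occupancy matrix; the boolean occupancy truth
table is used only as a test oracle. The two views provably coincide when
site footprints correspond one-to-one across stages, which the synthetic
generator guarantees by construction (grid spacing ≫ peak width + jitter).
On real data with fragmentary overlaps they can diverge — e.g. a day-1
record overlapping two disjoint ESC records makes both ESC records "early"
— which is an inherent property of record-filtering pipelines, not a bug;
the disjointness audit still guarantees no site is reported in two classes.

Strand is ignored throughout: the inputs are unstranded peak calls.

## Dataset integration

Raw time labels are canonicalised onto five stages: 18 h folds into D1,
day 5 into D6, MEF/day 0 into D0, and SSEA1+/Thy1+ efficiency-sorted
fractions map to their nominal day (the pipeline models the bulk
population). All files for one factor/stage are concatenated before a single
merge pass; because gap-merging is associative this equals merging subsets
first, and the single pass is simpler to audit. Oct4 source datasets are
systematically larger than the others, so for co-binding statistics the Oct4
sets at D1, D3 and D6 are randomly downsampled (uniform, without
replacement, seeded) to the mean of the Sox2 and Klf4 counts at the same
stage, rounded half-up; ESC Oct4 is never downsampled and classification
always uses the full sets.

## Temporal classification

With stage sets MEF(KM), D1, D3, D6, ESC:

* early = ESC records overlapping D1; late = the complement within ESC.
* Early subclasses by successive D3/D6 intersection: stable (D3 ∧ D6),
  absent-D6, absent-D3, D1-only. Early splits again into MEF pre-bound
  (overlap the KM MEF set) versus de novo.
* Transient sites: seven intermediate-occupancy categories (each of
  D1/D3/D6 alone; each pair; all three). Single-stage categories subtract
  ESC first, then the other two intermediate stages, then the MEF set —
  that order is fixed in code because subtraction chains do not commute for
  fragmentary overlaps. Multi-stage categories keep the original records of
  *every* intersected file, merge them at gap 0, then subtract the remaining
  stage, ESC, and MEF. The transient class is the gap-0 union of all seven.
* MEF-lost sites: MEF records absent everywhere else, plus MEF records
  overlapping the transient union taken *before* its MEF-subtraction step.
  One deliberate tightening: MEF records overlapping ESC are excluded up
  front, because the class is defined by absence in ESCs and without this
  exclusion a wide MEF record spanning both a transient and an ESC site
  would violate the disjointness audit that the classification promises.

`audit_partition` checks all seven class sets for pairwise base-sharing and
hard-fails with a witness interval; it is run inside the pipeline, not just
in tests.

## Accessibility overlay

A site is "open" at a stage when it overlaps any called ATAC peak there
(any-overlap, consistent with how the intersections are defined elsewhere;
no centre-in-peak requirement). Class/stage fractions are flagged OPEN_MAJOR
strictly above 0.30; a class at exactly 30 % is CLOSED_MAJOR — the published
threshold language leaves the boundary open and the strict reading is fixed
here and in the tests. Peak calling itself is out of scope; ATAC inputs are
called peak BEDs.

## Gene assignment and expression

Site-to-gene assignment minimises |site midpoint − TSS| on the same
chromosome (ties to the lexicographically smallest gene id), dropping sites
whose nearest TSS exceeds the window: 1 Mb for genome-wide association,
2.5 kb inside the enhancer screen. TSS is the annotated start for + strand
genes and end − 1 for − strand; a GTF reader (5'-most transcript TSS per
gene) and a 4-column TSV reader are provided. Distance histograms use the
0/5 k/50 k/500 k/1 M bp edges.

Size factors follow the median-of-ratios definition: reference = per-gene
geometric mean across samples (genes containing any zero are excluded from
the reference), factor = per-sample median of count/reference. The median is
taken in ratio space; reference implementations that take it in log space
differ only in even-count interpolation, at the 1e-5 level.

The differential engine is deliberately transparent: Welch's t on
log2(normalized + 0.5), BH adjustment across all tested genes, strict
thresholds (|log2FC| > 0.58, padj < 0.05 by default; > 2 for the screen's
up-regulation filter). This trades the power of shrinkage-based NB models
for a desk-checkable statistic; genome-scale DEG counts from shrinkage
engines are therefore not expected to be bit-reproduced. Degenerate genes
(zero variance in both groups) get p = 1. Replicates are averaged
(arithmetic mean of normalised counts) per stage before median profiles, and
genes with zero normalised counts at every stage are excluded from profile
medians.

Small wet-lab formulas: relative expression 2^(−ΔCt) against a reference
gene; reprogramming efficiency = 100 · colonies / cells seeded; the
pooled-variance two-tailed t test (df = n_a + n_b − 2) with the zero-variance
convention t = 0, p = 1 for identical groups.

## The RIE screen

Filters run strictly in sequence over the de novo early-bound sites:
proximal (nearest TSS ≤ 2.5 kb, strict beyond), up-regulated (gene log2FC
> 2 and padj < 0.05, both strict), peak density (total individual O/S/K/M
peak overlaps across D1, D3, D6 and ESC must exceed 10; "peaks in
reprogramming" is read as the induced stages, excluding D0, and the stage
list is configurable). Every candidate carries an ordered filter trace, so
stage survivor counts are reconstructible. Survivors are ranked by total
peak count (descending, ties by position) — a presentation choice motivated
by the screen's preference for densely bound elements; the chain itself does
not rank. Adjacent survivors are grouped into co-bound regions by gap-merge
with a 1,000 bp default radius; the grouping radius is a package default,
not a published parameter.

## Synthetic study generator

The generator emulates the *input shape* of the integrated study: several
source datasets per factor whose peaks jitter (≤ 50 bp by default) around
shared true sites of width 400 bp placed on a 6 kb grid across 3
chromosomes; seven planted temporal classes (defaults: 160/80/80/80 early
stable/dynamic, 200 late, 300 transient, 100 MEF-lost; 40 % of early sites
MEF pre-bound); a fixed accessibility schedule per class (e.g. early-stable
open everywhere, late open only in ESCs); per-factor occupancy drawn at 0.7
per factor (KM only at D0), with planted RIE host sites forced to
all-factor binding at every induced stage so they clear the density filter
by construction; an annotation placing each planted RIE gene's TSS 1.2 kb
from its site and all other genes on a separate gene-only chromosome (so
they can never pass the proximal filter); and gamma-Poisson counts
(variance μ + αμ², α = 0.1 by default) over 8 stages whose log2 means
interpolate linearly from the MEF baseline to the planted ESC fold change
(log2FC = 3 for planted up/RIE genes, −3 for planted down genes, 0
otherwise).

Three replicates per stage are the default. With the plain Welch engine,
two replicates give df ≈ 2 and essentially no post-adjustment power at any
realistic noise level, so three is the minimum at which planted effects are
reliably detectable; the generator will still emit two-replicate matrices
on request to mirror the common experimental design.

`clean_config()` encodes the zero-noise study used for exact-recovery
checks: no boundary jitter, Poisson counts (dispersion 0), high baselines
(500–2,000), planted log2FC = 4. Under those conditions class recovery and
RIE recovery are exact by construction; under the jittered defaults class
recovery remains exact because jitter is far below half the grid spacing.

What passing these tests shows: the bookkeeping of every stage is correct
under ideal, well-separated peaks. What it does not show: behaviour under
fragmented or nested peak calls, mappability artefacts, correlated noise, or
regulatory-domain-based gene assignment — real-data headline counts are
documented expectations, not desk-scale test targets.

## Determinism and problem sizes

All randomness flows from explicit seeds (`numpy.random.default_rng`);
rerunning any stage with the same config, inputs and seed produces
byte-identical primary outputs, recorded as SHA-256 checksums in the run
manifest. The acceptance script works at the scale of ~5,000 sites for the
clean recovery study, 5 jittered studies of ~1,000 sites, 100 null count
matrices of 60 genes, and the exhaustive 31-pattern audit — sizes chosen so
the whole recomputation stays interactive while every metric is measured,
never asserted.
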