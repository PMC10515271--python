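# Methods

## The problem

The *Drosophila melanogaster* replication-dependent histone genes sit in a
single cluster of roughly one hundred tandemly repeated, nearly identical
~5 kb units, each carrying the five canonical histone genes (H1, H2A, H2B,
H3, H4), two divergent TATA-containing core promoters (H2A/H2B and H3/H4),
the TATA-less H1 promoter, and GA-repeat cis elements in the ~300 bp H3/H4
promoter. Because the copies are nearly identical, reads from the whole
locus can be collapsed onto a single repeat unit, summing ChIP signal
across copies. `hlbscreen` implements a screen over candidate DNA-binding
factors on this collapsed reference: input-normalized coverage, a
peak-emergence positivity criterion, four false-positive rules, and
element-level localization of positive peaks. A seeded simulator replaces
public ChIP datasets so the whole pipeline is testable against ground
truth at desk scale.

## Coordinate model

Coordinates are 0-based, half-open (BED convention); the unit is treated
as circular by the mapper and all track operations, because
junction-spanning reads from interior copies of a tandem array belong to
the locus. Strand is recorded in annotations but ignored downstream — all
tracks are unstranded.

The default unit layout is synthetic: no public base-pair annotation of
the array's internal coordinates exists, so a fixed stand-in with
realistic proportions is provided and any real annotation can be supplied
as BED6 (feature kind encoded as `name|kind`). Design constraints on the
layout: gene bodies at histone ORF scale (310–790 bp, 2280 bp total of
the 5000 bp unit), each gene and promoter at least 200 bp so peaks are
unambiguous at simulated read lengths, the H3/H4 promoter ~300 bp and
centered near the unit midpoint with two GA-repeat elements (60 and 50 bp)
flanked by the divergent pair's TATA boxes. The GA elements are at least
50 bp so that a pure-GA read at the artifact rule's inclusive 50 bp bound
can map at all; the real element is described in the literature as a long,
perfect GA repeat, which motivates the scale.

## Synthetic data

`build_reference` concatenates `flank + n_copies x unit + flank`; GA
features are perfect (GA)n repeats, every other unit and flank base i.i.d.
uniform ACGT from a seeded generator. Copies are exactly identical (the
real arrays are only nearly identical; that divergence is out of scope and
documented here as a simplification).

`simulate_pair` draws error-free single-end reads: a uniformly chosen copy
and a per-base start offset drawn from a mode-specific weight vector over
the unit, with half the reads reverse-complemented. Read sequences are
taken from the unit treated circularly — identical to slicing the linear
reference for every copy but the last, and it keeps last-copy junction
reads inside the locus rather than running into flank. Six modes:

| mode | ChIP weights | input weights |
|---|---|---|
| NONE | uniform | uniform |
| TRUE_PROMOTER | fold f on target element | uniform |
| INPUT_IDENTICAL | fold f on target | same as ChIP |
| GENE_BODY_BIAS | weight b on gene bodies | same |
| INTERGENIC_DEPLETION | weight b on intergenic | same |
| GA_ARTIFACT | uniform + injected pure-(GA)n reads | uniform |

Reference conditions (the defaults): 100 copies, 10 kb flanks, 50,000
reads per role, 75 bp reads (36 bp for GA_ARTIFACT — the artifact is a
short-read phenomenon), fold 8, bias weight 3 (gene-body) or 0.2
(intergenic), artifact fraction 5%. An optional uniform substitution-error
rate and a flank-read fraction exist as knobs, both 0 by default: the
classification criteria do not depend on sequencing error, and flank reads
are only needed to exercise the mapper's rejection path. There is no
fragment-size model — read starts are sampled directly, since
classification operates on read coverage.

What the simulator does NOT emulate: inter-copy sequence divergence, PCR
duplicates, base-quality structure, paired ends, chromatin accessibility
structure beyond the explicit bias modes, or genome-wide background
outside the flanks. Passing tests therefore demonstrate correctness of
the pipeline's logic under controlled conditions, not performance on real
libraries.

## Collapse mapping

A 5 kb unit does not need an external aligner. The mapper indexes every
circular position of the unit by exact 16-mers; read seeds (non-overlapping
k-mers plus one read-end k-mer, both strands) propose candidate placements,
full-length circular comparison counts mismatches, and placements within
`max_mismatches` (default 2; a 16-mer is effectively unique in a 5 kb
random-background unit) compete on mismatch count. Ties are broken to the
LEFTMOST best placement ('+' strand preferred at equal position), a
deterministic rule that concentrates repeat-derived reads into a single
pileup — this determinization is ours (how the original aligner resolved
multireads on the collapsed reference is not recorded) and is what makes
the GA-repeat artifact a reproducible, detectable object. `multimap_count`
records the number of tied placements. A vectorized batch path
(`map_reads`) implements the same semantics as the per-read reference
implementation (`map_read`); a property test holds them equal on clean,
mutated, reverse-strand, multimapping and unmappable reads.

Coverage is per-base (1 bp bins) on the circular unit via prefix sums,
with an exact conservation invariant (`sum = n_mapped x read_length`) and
a naive per-read per-base loop kept as the oracle. SAM export (wrap-split
records at the origin) and SAM/BAM import are interchange points that
bypass the internal mapper.

## Normalization

Both tracks are scaled to a common total (1e6 by default; plain
total-count scaling — on a single 5 kb reference, paired local-regression
scaling schemes are undefined and unnecessary, and the scaling label is
recorded on the track), then `log2((chip + p) / (input + p))` with
pseudocount p = 1. Smoothing is a circular centered moving average.

The smoothing window default is 75 bp — one default read length. The
window must span at least a read length: the GA artifact pileup is exactly
one read length wide (all multimapping artifact reads sit at one base), so
a narrower window can leave the smoothed spike below the 50 bp minimum
peak width and the artifact the screen must catch would never be called as
a peak. 75 bp is still far below promoter scale (250–300 bp), so true
promoter peaks are not blurred into their neighbors.

## Classification

Peak calling quantifies visual track inspection: threshold at
`mean + peak_z x SD` (z = 3) of the smoothed ratio track, maximal circular
runs strictly above threshold, minimum width 50 bp, summit = leftmost
maximum. A constant track (SD 0) yields no peaks.

Emergence: a ChIP peak is retained only if the depth-scaled, smoothed
input over the peak interval does not exceed the input's own
`mean + 2 x SD` — "a peak in the ChIP that is not present in the input".

The four false-positive rules:

1. **Gene-body overrepresentation** (input): mean scaled input coverage
   over gene-body interiors / overall mean > 1.5.
2. **Intergenic depletion** (input): same score over intergenic interiors
   < 0.5 (not applicable, and never flagged, when the annotation has no
   intergenic bases).
3. **Input-identical**: Pearson correlation of the scaled ChIP and input
   vectors > 0.95 AND both tracks individually contain a called peak —
   two flat tracks correlating is not the artifact. Zero-variance tracks
   give an undefined correlation, recorded, never flagged.
4. **GA artifact**: any called ratio peak overlapping a GA-repeat element
   in a dataset with read length <= 50 bp (inclusive bound). The rule is
   applied to all called peaks, not only emergent ones: with the leftmost
   multimap rule the GA pileup appears identically in ChIP and input, so
   the emergence test can remove the peak while the dataset remains
   artifact-bearing. The rule covers any GA-repeat feature in the
   annotation (in the default layout all of them are in the H3/H4
   promoter).

Rules 1–3 are dataset-level and evaluated on the INPUT track — these are
library/alignment biases that the input reveals and that normalization
then converts into misleading peaks; the same scores on the ChIP track are
recorded as diagnostics only. The bias scores are computed on region
interiors (edges eroded by one read length): raw coverage spreads one read
length of mass across every region boundary, which dilutes the region mean
below its analytic expectation from the read-start density; interior
scoring removes that read-length dependence (regions too short to erode
are scored whole). All cutoffs except the 50 bp read-length bound are
engineering quantifications of qualitative criteria and are overridable
config fields, snapshotted into every report.

**Label**: positive iff at least one emergent peak carries no GA flag and
none of the three dataset-level flags is set. A positive call always
carries at least one emergent peak (asserted on construction).

**Localization**: a peak is assigned to the promoters/genes that overlap
at least 25% of its width or contain its summit; the summit's element is
listed first. **Replicates** are combined conservatively: positive only if
all replicates are positive, flags unioned, localization the intersection
of the per-replicate top peaks' element sets (union plus a disagreement
diagnostic when the intersection is empty). Whether the original calls
were made per replicate or on overlays is not recorded; the all-positive
rule is ours.

No multiple-testing control is applied: the unit is a single 5 kb locus
with a handful of candidate windows, and the thresholds are
effect-size-based, matching the qualitative regime of the original
criteria.

## Numerical and degenerate-input choices

Population SD (ddof 0) throughout; strict inequalities at every cutoff;
peak ties broken leftmost; tracks with no mapped reads are degenerate
inputs (errors), while an unmapped read is a value. Reports are
deterministic: sorted JSON keys, no timestamps, atomic writes.

## Problem sizes

The shipped analyses use a 100-copy reference with 50,000 reads per role
for classifier scoring (6 modes x 20 seeds) and localization, and a
25-copy, 20,000-read-per-role cohort for the on-disk screen demonstration;
these sizes give per-base coverage of several hundred reads, the regime
where the screen's score expectations are sharp, while keeping every
analysis re-runnable on a laptop.

## Known limitations

Identical copies mean collapse correctness is exact by construction except
at GA repeats; real inter-copy variants would add mismatches the 2-mismatch
budget must absorb. The screen's thresholds quantify criteria that were
originally visual; on real data they should be treated as starting points
and are deliberately exposed in the config. ChIP-exo data is treated as
ordinary coverage. No attempt is made to reproduce calls on the original
public datasets.
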