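# Methods

This note records the model behind `anchorfuse`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the design choices made where the design was genuinely open.

## Read geometry and the split-alignment model

The caller assumes a BWA-MEM-style contract: one primary alignment row per
read, supplementary alignments described both as their own rows and in the
primary row's `SA:Z` tag (chrom, pos, strand, CIGAR, MAPQ, NM), alternative
placements of multi-mapping alignments in `XA:Z`.  Only the primary rows
and tags are consumed; supplementary rows contribute just their `XA` tags
(repeat rescue needs the alternatives of the specific MAPQ-0 segment).

Every alignment is reduced to a reference interval and a query interval in
as-sequenced orientation.  Hard clips are treated as query-consuming
placeholders, because an aligner hard-clips on a supplementary row exactly
the bases it soft-clips on the primary.  `=`/`X` fold into `M`; `N`
(splice gap, produced by spliced aligners but never by BWA-MEM) is kept as
a reference-consuming gap and never smoothed.  Insertions and deletions of
length ≤ `max_smoothed_indel` (default 1) flanked by `M` are absorbed into
the mapped block — a 1-base indel inside a segment is alignment noise, not
a second segment — applied left-to-right and repeated to fixpoint so
chains such as `M 1D M 1D M` collapse; an absorbed deletion keeps its base
on the reference, so reference spans are computed from the pre-smoothing
operations.

## Deduplication by UMI and ligation site

Anchored multiplex PCR reads begin at a ligated fragment end whose first
bases are often unmappable; the ligation site (LS) is therefore the
alignment start projected back through the leading soft clip (plus strand)
or the alignment end projected through the trailing clip (minus strand),
clamped at position 1.  Reads sharing (UMI, LS) are one molecule; the
representative kept is the read with the highest primary MAPQ, ties broken
by smallest read id — deterministic, and it favors the best-mapped
evidence.  Reads without a parsable UMI are each treated as unique, and
position-only collapse (`dedup=ls`) is opt-in, because collapsing plain
RNA-seq by position alone destroys real depth.  Distinct LS values per
junction ("partner ends") independently witness distinct ligation events
and are the evidence unit for calling.

## Candidate junctions

Two neighboring segments of one read are candidate fusion partners when
normal splicing cannot explain them: different chromosomes, same
chromosome at a breakpoint-to-breakpoint distance strictly greater than
`max_intron_distance` (750,000 bases — beyond the largest plausible human
intron), or opposite strands on one chromosome (an inversion cannot be a
splice; this inclusion is this package's choice, configurable via
`allow_inversion`).  The distance is measured between the junction-facing
termini (`right.ref_start − left.ref_end`), not segment midpoints, so the
rule is exact at the boundary: 750,000 is rejected, 750,001 accepted.

Breakpoints are read off strand-aware: the 5′ breakpoint is the left
segment's query-3′ reference terminus, the 3′ breakpoint the right
segment's query-5′ terminus.  Split alignments commonly share a few
identical query bases at the junction (seed extension across canonical
splice-site homology).  Those shared bases are attributed to the 5′ side
and the 3′ breakpoint is advanced past them *at candidate construction*,
slightly earlier than pure annotation would require, because grouping is
by exact breakpoint pair and reads with different homology extents must
land in one group.  Exact-junction grouping (no fuzz window) is deliberate:
the subclone analysis distinguishes fusions by exact junction.

In layouts of three or more segments the candidate junction is the
qualifying neighboring split, with breakpoints at the junction-adjacent
termini; interior segments go to the `mid` channel for separate
annotation.  If no neighboring pair qualifies but the outermost pair does
(two sub-threshold steps on one chromosome adding past the threshold), the
outermost pair forms the candidate with interiors as mid.

## Filters

Per-read candidates must satisfy: query overlap ≤ `max_overlap` (6), query
gap ≤ `max_gap` (5), per-side exclusive (non-shared) mapped length ≥
`min_exclusive_len` (15), and end-specific minimum mapped lengths.  In
anchored mode the segment containing read-1 base 1 is the ligation end
(cutoff `min_map_len_ligation` = 25) and the segment containing the final
base is the anchored end (cutoff `min_map_len_anchored` = 18); the
asymmetry reflects that the anchored side's specificity is already
enforced by the nested gene-specific primers, while the ligation side
carries the burden of placing the unknown partner.  Plain RNA-seq has no
such asymmetry; a single cutoff (`min_map_len_plain`, default 18, the
sensitivity-leaning value) applies to both ends.  The overlap/gap and
exclusive-length defaults are this package's own calibration: large enough
that canonical splice-site micro-homology (≤ 6 bases) survives, small
enough that spurious seed matches do not.  All are configurable.

## Annotation, exon boundaries, and evidence thresholds

Gene models come from UCSC refFlat or GTF (exon + CDS features); both are
converted to 1-based inclusive coordinates and indexed with interval
trees.  One canonical transcript per gene is chosen (longest CDS, then
longest transcript, then smallest id); boundary checks consult all
isoforms.

The gene at a breakpoint is looked up `annotation_shift` (6) bases inward
into the breakpoint's own aligned segment — junction micro-homology can
drag the raw coordinate a few bases into the partner gene's territory, and
the inward lookup is robust to that.  The exon/intron label and cDNA
position are then computed at the raw junction coordinate within the
selected transcript, and the raw coordinate is what is reported: a
junction three bases into an intron is reported as intronic, which is what
a reviewer comparing against a genome browser needs.  Boundary status asks
whether the 5′ junction equals an exon 3′ terminus (donor side) and the 3′
junction an exon 5′ terminus (acceptor side) of any isoform, with exact
equality after the overlap assignment above (`boundary_tolerance` exists,
default 0, for degraded data).

Fusions created by genomic rearrangement followed by normal splicing land
exactly on exon boundaries, so boundary concordance is itself strong
evidence.  The calling thresholds exploit this: both boundaries →
`minPartnerEnds_BothExonJunction` (1) partner end suffices; one boundary →
`minPartnerEnds_OneExonJunction` (3); no boundary → only reportable
through the Target-mode whitelist.

## Frame status

Let `c5` be the number of coding bases of the 5′ transcript from its CDS
start through the last retained base, and `c3` the number of coding bases
of the 3′ transcript from its CDS start up to but excluding the first
retained base.  The fusion is in-frame iff `c5 ≡ c3 (mod 3)`; the call is
NA whenever either junction-adjacent base lies outside its CDS (5′UTR,
intron, non-coding partner).  This through-last-base / before-first-base
convention is validated exclusively against an independent translation
oracle (below), never against assumed exon tables.  If the canonical pair
is NA but some isoform pair is in frame, that isoform's call is reported
and flagged (`isoform_rescued`) — a fusion transcribed from a minor
isoform is still actionable.

## Special modes

*Pseudogene mode*: a MAPQ-0 segment whose primary placement overlaps a
user-designated repeat region is kept there; otherwise the first `XA`
entry (file order — the aligner's own ranking; a deterministic choice
where no better ranking exists) overlapping a region replaces its
coordinates, flagged `remapped`.  Segments with MAPQ > 0 are never
touched, so on repeat-free data the mode is a no-op.

*Target mode*: whitelisted events are junction patterns — `exon:<n5>-<n3>`
(donor of exon n5 to acceptor of exon n3, exact boundary match) or
`coord:` pairs matched within ±`target_window` (5) bases for cryptic exons
absent from models.  Same-chromosome, same-strand, sub-threshold splits
(normal splice geometry, invisible to the fusion path) are matched against
the patterns and called at each event's own `min_partner_ends` (default 3;
whether such events should bypass evidence thresholds entirely was open —
a per-event threshold was chosen so a single noisy splice read cannot
create a reportable event).  A panel BED restricts reporting to calls
touching panel genes; a blacklist removes recurring artifacts by gene pair
or exact junction.

## Reporting and statistics

The summary TSV has a fixed column order, is sorted by (fusion name, UMI
reads desc, junction), and is byte-identical across runs.  Supporting
reads (default `n_extract_reads` = 10) are sampled without replacement
using a generator derived from the run seed and the junction string (CRC,
not Python's salted hash), so extraction is reproducible.  Subclones are
counted as distinct exact junction strings per gene pair per sample.  The
two-sided Fisher's exact test enumerates all tables with the observed
margins in exact rational arithmetic and sums the probabilities ≤ the
observed table's — the convention under which the probability comparison
has no floating-point ties; the test suite cross-checks against an
independent library implementation.

## The synthetic-data generator

The generator emulates AMP geometry: read 1 starts at the ligation site in
the partner gene and ends toward the primer in the panel gene; each
fusion-crossing read is emitted as a primary row (ligation side mapped,
anchored side soft-clipped) plus a reciprocal hard-clipped supplementary
row with consistent `SA` tags, on either strand of either gene.  Molecule
plans are explicit — k distinct split points (ligation sites), m molecules
cycling over them, n reads cycling over molecules — so truth tables
(junction, distinct UMI-LS count, partner ends, boundary and frame
expectations) are bookkeeping, independent of the pipeline under test.
Repeat scenarios append ≥3 decoy copies of a gene's span and report the
anchored side at a decoy with MAPQ 0 and `XA` alternatives including the
true locus.  Default read length is 100 bases with 20 reads / 12 molecules
/ 5 partner ends per scenario and substitution error rate 0 (an
`error_rate` knob injects uniform substitutions); these sizes keep every
scenario's evidence comfortably above the calling thresholds while staying
small enough to regenerate in milliseconds.

Synthetic coding sequences are built from T-free codons ({A,C,G}³, 27
codons, none a stop) between an ATG start and a TAA stop.  Consequence: no
stop codon can arise by chance at a junction codon or in a shifted frame
within the CDS, which makes frame phase arithmetic *provably* equivalent
to direct translation on these fixtures.  The translation oracle builds
the fused mRNA from truth (5′ cDNA prefix + 3′ cDNA suffix), translates
from the 5′ start codon, and declares in-frame iff translation terminates
with the 3′ gene's C-terminal peptide; it abstains when a
junction-adjacent base is outside a CDS.

What the generator does **not** emulate: real codon usage and stop-codon
statistics (see above), FFPE degradation beyond uniform substitution
error, chimeric artifacts of reverse transcription, paired-end mates,
overlapping genes, alternative isoform collections per gene (except where
a test constructs them directly), and genuine aligner behavior —
alignments are constructed, not recomputed, so aligner-specific clipping
heuristics are untested.  Passing fixture tests therefore demonstrates the
correctness of the pipeline's logic on the stated contract, not robustness
to every artifact of real libraries.

## Numerical and procedural choices

- Coordinates are SAM-style 1-based inclusive everywhere internally; BED
  is converted on load, refFlat's 0-based half-open on load.
- Duplicate-representative choice, segment-ordering ties (by chromosome
  then reference start), and group iteration order are all fixed, making
  outputs byte-deterministic for identical inputs + config + seed.
- Degenerate inputs: reads without `SA` carry no fusion evidence and are
  dropped from the junction path (they still participate in dedup);
  malformed `SA` tags skip the record with a warning; malformed gene-model
  lines are skipped with a warning; an empty model set is a hard error;
  zero-split input yields a header-only summary and exit 0.
- The acceptance script scales every recomputation to seconds: 4
  strand-combination recovery runs, 200 frame trials, one 20-read dedup
  fixture, one six-junction subclone fixture, two targeted events, one
  repeat-rescue fixture.  Sizes are fixed in the script and reported as
  `n` alongside each value.

## Known limitations

- Paired-end-only fusion evidence (mates on different genes, no split
  read) is out of scope by design: without a junction-crossing read the
  frame cannot be inferred conclusively.
- Non-reference fusion partners (e.g. viral sequence) require extending
  the reference genome upstream of this tool.
- The per-side direction of the inward annotation shift is an
  interpretation (isolated in one function, `_shifted_lookup_pos`) and the
  shift does not help when micro-homology exceeds the shift length.
- Intronic junction-adjacent bases yield frame NA even when the retained
  intron would in fact be translated; resolving that would require
  genomic-continuation translation, which the clinical convention here
  avoids.
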