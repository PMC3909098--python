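# Methods

## Scope and data model

The pipeline starts from splice-junction read counts, one table per
sample. Junctions are stored with 1-based, inclusive intronic bounds:
`intron_start` is the first intronic base and `intron_end` the last, so
on the plus strand the donor is `intron_start` and the acceptor
`intron_end`, and vice versa on the minus strand. STAR `SJ.out.tab`
already uses this convention; BED12 junction tracks are converted on
read (`intron = chromStart + blockSize1 + 1 .. chromEnd − blockSize2`).
Unstranded junction records are dropped with a warning because the −3
trinucleotide classification is strand-dependent. Duplicate junction
records within a table are summed, with a warning.

Annotation is a GTF with exon features. It contributes three things:
the deduplicated intron set (for intron-retention candidates and the
"annotated" flag on splice sites), the terminal exon of each transcript
(for alternative-last-exon classification), and the per-transcript exon
chains (for the mutually-exclusive-exon co-occurrence check).

## Event classification

Events are assembled from junctions pooled across samples; an event is
kept only if every member junction has at least `min_event_count`
pooled reads (default 2).

* **Cassette exon (CE).** An internal exon with upstream junction
  (s, a), downstream junction (b, e), and an exon-bridging exclusion
  junction (s, e). Detection is purely genomic and therefore
  strand-symmetric.
* **Alternative 3′ splice site (A3SS).** Two junctions sharing
  (chrom, strand, donor) with distinct acceptors, excluding pairs
  already explained by a cassette exon's donor-side flank or by
  mutually exclusive exons. With more than two acceptor choices the
  donor group is split into pairwise sub-events against the most-used
  (highest pooled count) acceptor.
* **A5SS.** Symmetric on the shared acceptor.
* **Alternative last exon (ALE).** A shared-donor acceptor pair whose
  two acceptors belong to distinct annotated terminal exons.
* **Intron retention (IR).** An annotated intron with junction evidence
  (exclusion) *and* intron-body evidence (inclusion). Because junction
  tables are the ingestion boundary, intron-body counts enter as an
  optional second table per sample (same 5-column format, keyed by the
  intron's bounds); without body counts no IR events are emitted.
* **Mutually exclusive exons (MXE).** Two internal exons sharing outer
  splice sites, non-overlapping, never co-occurring in any annotated
  transcript, with no junction bridging them. The genomically leftmost
  exon defines isoform 1. MXE events carry no proximal/distal acceptor
  labels and are excluded from the 3′ss sequence analyses.

For CE, A3SS and ALE events the two competing acceptors are labelled
**proximal**/**distal** by distance from the shared donor in the
direction of transcription (the distal site has the longer intron); for
CE the proximal site is the cassette exon's own acceptor and the distal
one the acceptor used by the skipping junction. The labelling is
invariant under mirroring the coordinate axis with a strand flip, which
is enforced by a property test.

## PSI

PSI = 100·I/(I+E), undefined when I+E < `psi_min_total` (default 10;
25 for the switch analysis). CE (and MXE) inclusion support averages
the two flanking junctions, rounded half-up, so one cDNA fragment
spanning both junctions is not counted twice. IR inclusion scales the
intron-body count by `jcn_seq_len / intron_length` to place body
coverage on the scale of junction-spanning reads; `jcn_seq_len`
(default 88) is the effective junction read length and enters nowhere
else. Two invariants pin the definition down: swapping
inclusion/exclusion roles maps PSI to 100 − PSI, and PSI is
non-increasing in E at fixed I.

## Differential splicing

Group designs: per event, samples with undefined PSI are dropped
(pairwise-complete; no imputation), and events with fewer than two
defined values per group are skipped. Events whose |median ΔPSI| is
below `delta_thresh` (5 points) are not tested at all; the rest get a
two-sided Wilcoxon rank-sum p — exact enumeration when n₀+n₁ ≤ 12 with
no ties, otherwise the normal approximation with tie correction and
(by default; configurable) a continuity correction. The switchover at
12 keeps the exact path for oracle-verifiable small designs while the
realistic 8-vs-many designs use the approximation. BH runs across all
tested events; a significant call additionally needs |ΔPSI| >
`median_delta_filter` (10 points). ΔPSI is condition − reference on
the inclusion (proximal) isoform, so negative means skipping/distal
usage.

Two-library designs (no replicates): per event, a two-sided Fisher's
exact test on [[I_a, E_a], [I_b, E_b]], restricted to events with ≥ 25
reads in both libraries, BH-corrected, with a 5-point PSI-difference
requirement.

A specificity filter intersects three comparisons (case vs control,
wild-type-induction vs control, control vs control) and keeps events
significant only in the case comparison. Events significant in the
wild-type comparison with the opposite ΔPSI sign are still removed —
the conservative choice — but reported under an
`opposite_direction_in_wt` flag, since an overexpression effect running
counter to the mutant effect is evidence for, not against, mutant
specificity.

BH is delegated to `statsmodels.multipletests(method="fdr_bh")` behind
the package's own `benjamini_hochberg` surface; tests verify it against
a hand-written step-up computation. The rank-sum and Fisher paths are
`scipy.stats.mannwhitneyu`/`fisher_exact`, cross-checked in the test
suite against brute-force permutation enumeration (all tie-free inputs
with n₀+n₁ ≤ 10) and exhaustive hypergeometric sums (margins ≤ 12).

## 3′ splice-site sequence analysis

The acceptor window is 23 nt — 20 intronic + 3 exonic bases in
transcript orientation: plus strand `acceptor−19 .. acceptor+3`, minus
strand the reverse complement of `acceptor−3 .. acceptor+19`. Windows
whose intronic end is not AG are kept with a warning (non-canonical
sites occur in real data). The −3..−1 trinucleotide defines the site
classes TAG/CAG/AAG; everything else (including GAG) is "other".

Direction of splicing is the sign of ΔPSI on the inclusion isoform;
zero-ΔPSI events are excluded. Direction bias per event class is an
exact two-sided binomial test against 0.5 — two-sided because no
directional alternative is assumed a priori, which is the conservative
choice.

Motif matrices are per-column base frequencies with information content
2 − H − e(n), using the standard small-sample correction
e(n) = 3/(2·ln2·n); groups with fewer than 10 sequences yield no
matrix. Rendering is out of scope — the matrices are the artifact.

Splice-site switches are enumerated over annotated CE/A3SS events with
exactly two acceptor choices whose classes are one of each queried pair
(e.g. TAG vs CAG), requiring ≥ 25 reads in both conditions. Replicate
libraries within a condition are pooled by summing counts (the
single-library design is the one-replicate special case; unpooled
multi-library designs are rejected rather than silently averaged). A
switch is |ΔPSI| > 5 points, directed toward the site whose usage
increased; swapping the two conditions provably reverses every
direction and preserves the switched set. Because the eligible-event
and site-pair countings can differ when several events share a site
pair, the summary reports both.

## Cross-cohort comparison

Events from two cohorts match when chrom, strand, and both splice-site
coordinates are identical. Coordinate matches with differing event
types are *flagged* for review rather than dropped or silently kept —
a shared location does not guarantee the same event. Overlap enrichment
is a two-sided Fisher's exact test on [[both, A only], [B only,
neither]] restricted to events expressed in both cohorts; "expressed"
is defined as PSI having support in at least 50% of each cohort's
samples (the restriction is principled, the 50% threshold is this
package's choice). Gene-list intersection normalises symbols to
uppercase. The qRT-PCR relative-inclusion level is
2^−(Ct_inclusion − Ct_total), normalised by the median fold of
non-transfected controls, so a control cohort self-normalises to
median 1.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at desk scale. Each gene sits on its own chromosome (padded so acceptor
windows stay in bounds) and carries one event of a requested class;
strands alternate. Sequences are random with canonical GT donors and AG
acceptors planted at the splice sites; the −3 base of each competing
acceptor is set per the event's assigned classes.

Defaults describe the target scenario: 200 events (100 CE + 100 A3SS),
8 mutant vs 20 control samples, baseline PSI uniform on [5, 95], 25% of
events planted with a 30-point PSI shift toward the distal site, 80% of
planted events oriented TAG-proximal/CAG-distal (the rest reversed),
and per-event totals NegBin(mean 100, size 10) split
Binomial(total, PSI/100) between isoforms. The negative-binomial
total/binomial split is the standard overdispersed model for junction
counts; the size parameter 10 gives a realistic ~30% coefficient of
variation in per-event depth. Planted shifts that would leave [0, 100]
are clipped to [1, 99] and the realised (smaller) shift recorded in the
truth table; recovery statistics that promise a full 30-point effect
therefore condition on the realised shift.

What the generator does **not** emulate: read-level errors and mapping
ambiguity, correlated depth across events within a sample (library
size), annotation incompleteness, co-regulated event modules, and
partial intron-body coverage for IR. Passing tests therefore
demonstrate correctness of the inference machinery under the assumed
noise model, not robustness to real-data artifacts upstream of junction
counting.

## Problem sizes used in tests

Error-rate and recovery suites run on the default 200-event cohort:
power over 10 replicate count draws (planted, full-shift events),
type-I over 20–50 replicate null cohorts, orientation recovery on one
cohort with a 95% binomial interval. These sizes give standard errors
small enough to resolve the asserted bounds (e.g. ±3·SE ≈ ±0.01 on the
null call rate at 4,000 tests).

## Known limitations

* PSI denominators for ALE and the IR normalisation constant are this
  package's documented choices; alternative conventions exist.
* The event classifier is designed for desk-scale inputs (thousands of
  junctions); the flanked-exon search is quadratic per shared splice
  site and not tuned for transcriptome-wide junction sets.
* Multi-mapped and non-canonical junction reads are accepted as
  provided; any filtering must happen upstream.
* The 30-event cross-cohort fixture transcribes its source table
  verbatim, including a duplicated gene symbol with two coordinate
  pairs and one event with two distal-site choices (the first listed is
  used for coordinate matching).
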