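# Methods

## Gap-site model and evidence accumulators

A gap-site is the genomic location of an alignment gap, keyed by
`(seqid, lend, rstart)` in 1-based inclusive coordinates; the intron is
`[lend+1, rstart−1]`. Gaps are read from N operations of SAM/BAM CIGAR
strings under reference-consumption rules: M/=/X consume reference and
count as matches, D consumes reference without matching, I/S consume query
only, H/P nothing. A gap's *mcl* is the smaller of the two flanking
matched-segment totals, segments being delimited by read ends and adjacent
N operations; match runs interrupted by short I/D within a segment are
summed, since the statistic is meant to capture how much nucleotide match
evidence flanks the gap, not the length of a single run. Gaps flanked by a
zero-match segment (e.g. an N adjacent to a D) are rejected and tallied in
a diagnostics counter. Unmapped, secondary and supplementary records are
skipped by default; no mapping-quality filter is applied unless requested.
Both choices are configurable.

Two requirements shape the per-site record. *Monotonicity*: adding
alignments or merging samples must never decrease a score, which rules out
means/medians and motivates max-style accumulators. *Bounded storage*:
information per site saturates at a static size so records pack into small
integers and merge cheaply at scale. Concretely the record keeps: nAligns
(count), nProbes (samples seen in), the set of distinct left alignment
start positions saturating at capacity `n = 8`, the four largest mcl values
(each capped at 255; irrelevant below read length 255) whose sum is qsm,
and the alignment footprint `[range_start, range_end]` used later for
annotation overlap. The capacity is fixed at 8 for reproducibility across
machines; a legacy 4-value variant exists only as a configuration knob.
Record merge sums the counts, keeps the top-4 mcl of the union, and
truncates the lstart-set union to the `n` smallest values — a deterministic
rule that is commutative and associative and coincides with exact set
semantics whenever the distinct starts fit the capacity; streaming
accumulation instead stops inserting at capacity, so chunk-split results
can differ from whole-stream results only in which starts a saturated set
retains, never in nlstart itself once saturated.

The gap-site TSV carries the thirteen standard columns (seqid, lend,
rstart, nAligns, nlstart, mcl1–mcl4, qsm, nProbes, range_start, range_end)
plus a trailing `lstarts` column listing the retained start positions, so
that merging TSVs from different samples reproduces record-level
distinct-start semantics exactly instead of approximating the union; the
column is optional on import (nlstart placeholder positions are
synthesised when it is absent, adequate for scoring but not for further
exact merging).

## gqs

`gqs = trunc(10 · (2·min(nlstart, n)/n) · qsm/4)`, computed in exact
integer arithmetic as `5·min(nlstart, n)·qsm // n` to avoid float
truncation artifacts. At read length 100, mcl ≤ 50 so qsm ≤ 200 and
gqs ≤ 1000. The validation predicate is `gqs ≥ 1000` rather than equality
so longer reads (qsm > 200) cannot un-validate sites. gqs is insensitive
for low-coverage sites by construction — 1000 requires ≥ 8 supporting
alignments — which is what wgis addresses.

## Splice-site models and windows

Donor (5′) windows are 9-mers over positions −3..+6 (3 exonic + 6 intronic
bases), acceptor (3′) windows 23-mers over −20..+3 (20 intronic + 3
exonic). Both boundaries are extracted in both orientations: on the plus
hypothesis the donor sits at *lend* and the acceptor at *rstart*, read
forward; on the minus hypothesis the donor is at *rstart* and the acceptor
at *lend*, both reverse-complemented. Windows running past a chromosome
end, or containing non-ACGT characters, are *unscorable*; an unscorable
window zeroes wgis for the site with the reason recorded. This edge policy
is our decision (degenerate inputs must behave deterministically), and the
non-ACGT rule reflects that aligners do emit junctions inside assembly N
runs, which no sequence model can meaningfully score.

Two interchangeable model kinds implement `score5`/`score3` as total,
deterministic functions on ACGT windows of the declared width:

* **maxent-table**: pre-computed probability-ratio tables consumed by
  k-mer rank lookup (A=0, C=1, G=2, T=3). Layout: `donor_9mer.tsv`, one
  positive ratio per line for all 4⁹ donor 9-mers,
  `score5 = log2(ratio)`; and `acceptor_t0.tsv`..`acceptor_t8.tsv` for the
  factorised acceptor — the intronic AG consensus slot (window positions
  19–20) is removed and the remaining 21-mer is scored as the product of
  five fragment ratios divided by four overlap ratios
  (fragments 1–7, 8–14, 15–21, 5–11, 12–18 over 5–7, 8–11, 12–14, 15–18,
  1-based), the standard maximal-dependence factorisation that makes a
  23-mer model tractable. Model *estimation* is out of scope; tables are
  consumed, never fitted, and tests use generated fixture tables.
* **wmm**: a position-weight log-odds model,
  `score = log2(P_signal(seq)/P_background(seq))` with per-position signal
  frequencies smoothed by a pseudocount (default 0.5) and a uniform
  default background. It can be trained from example windows or built
  directly from probability profiles, and is the self-contained path used
  throughout the synthetic-data tests. Increasing the pseudocount shrinks
  every per-position weight monotonically toward 0 without sign flips.
  The plain-text model file holds `>donor` and `>acceptor` sections of
  `position A C G T` probability rows.

## wgis, strand and gql

`wgis = fnls·fqsm·fs5·fs3·sstr` with `fnls = log2(log2(nlstart)+1)+1`
(range (0, 3] at capacity 8), `fqsm = log2(log2(max(qsm−13, 2)))` (0 at
qsm ≤ 15, ≈ 2.916 at 200), and `fs5/fs3 = log2(max(score, 1))` (clamped at
score ≤ 1, maxima ≈ 3.56/4.01 at the largest scores observed on annotated
sites, 11.8 and 16.1, giving the 124.9 product maximum). Strand: `sstr =
+1` iff the acceptor score at the right boundary read forward is ≥ the
acceptor score at the left boundary read in reverse complement, ties plus;
the magnitude factors use the chosen strand's score pair (not the maximum
over strands), keeping the reported scores coherent with the reported
strand. Consequently `wgis = 0` exactly when `qsm ≤ 15` or either
chosen-strand score is ≤ 1, the sign of any nonzero wgis equals the strand
sign, and strand is reported only for validated sites. Full double
precision is kept internally; output tables round wgis to 3 decimals.
Levels: gql 0 at `|wgis| = 0`, 1 at `0 < |wgis| ≤ 30`, 2 at
`30 < |wgis| ≤ 80`, 3 above 80.

## Annotation

Ensembl-style GTFs list exons as independent rows, so intron-connected
exon pairs are built per transcript (ordered by `exon_number` when
present, genomic order strand-aware otherwise), adjacent exons paired,
pairs with overlapping or abutting exons skipped with a warning count, and
identical introns shared by several transcripts collapsed into one pair
carrying all transcript ids and the widest flanking spans. A
simultaneous-traversal sweep then matches each site (footprint
`[range_start, range_end]`, falling back to `lend/rstart ± read_length`
for minimal imports) against pairs whose span `[left_exon_start,
right_exon_end]` intersects it, reporting the pair minimising
`sod = |lend − left_exon_end| + |rstart − right_exon_start|`; no overlap
means no annotation (NA). Matching ignores reference strand — sites are
unstranded before wgis — and reports the matched pair's strand for
comparison. Ties on minimal sod break on the lexicographically smallest
(first transcript id, left exon end) for determinism. The sweep is checked
against a brute-force scan in the test suite.

## IDIN statistics and logos

Left IDIN = `genome[lend+1..lend+2]`, right IDIN =
`genome[rstart−2..rstart−1]`; introns shorter than 4 bases are excluded
(the two dinucleotides would overlap). Strand correction maps plus-strand
sites to (5′, 3′) = (left, right) and minus-strand sites to
(revcomp(right), revcomp(left)); applying the correction twice returns the
raw orientation. The GT-AG upper bound of an unstranded pair table adds
the GT-AG and CT-AC proportions, CT-AC being the genome-orientation
reading of a minus-strand GT-AG intron. Sites are counted by occurrence,
once each, not by alignment abundance. Logo matrices are per-position
relative frequencies over strand-corrected windows (rows sum to 1;
non-ACGT windows dropped with a count) plus a per-position base ordering
by descending frequency, ties alphabetical; default windows are the donor
9-mer (junction after position 3) and an acceptor window of 8 intronic +
4 exonic bases (*rstart* at position 9), both configurable since no single
extent is canonical. Rendering is left to plotting tools; the package
emits matrices only.

## Synthetic universe

The generator emulates exactly the features the scores consume: multi-exon
genes on random strands with canonical donor/acceptor motifs written into
a random genome, an Ensembl-dialect GTF whose exon boundaries coincide
with the planted junctions, and spliced reads emitted directly as aligned
SAM records (M-N-M CIGARs with exact coordinates and genome-matching
sequence), so no aligner runs. Defaults: read length 100; per true
junction, coverage 12 with four centred reads (50/50 flanks, mcl 50) and
the rest fanning out to distinct start positions — the minimal evidence
pattern that reaches gqs = 1000 (≥ 8 distinct starts, qsm = 200); noise
junctions at 0.3 per true junction, coverage 1–3 with random flank splits,
placed ≥ 50 bases from any true boundary and resampled away from
GT-AG/CT-AC so truth labels stay unambiguous; exons 60–200 bp, introns
80–400 bp. Donor sampling profiles peak at the CAGGTAAGT consensus with
the intronic GT fixed; acceptor profiles are pyrimidine-rich with the
terminal AG fixed. A single seeded generator drives everything; equal
seeds give byte-identical outputs.

What the generator does *not* emulate — sequencing errors, base
qualities, paired ends, expression-level variation, repetitive genomes,
alignment ambiguity, non-canonical junctions — bounds what passing tests
show: they validate the statistics, coordinate arithmetic and recovery
logic, not aligner behaviour on real transcriptomes. Noise junctions here
are structurally easy (random boundaries score poorly under any trained
model); real false positives can be sequence-similar to true sites, so the
observed noise validation rate on synthetic data is a sanity check, not a
false-discovery-rate estimate.

## Numerical and interface choices

gqs in integer arithmetic; wgis in double precision, rounded to 3 decimals
only on output. Strand ties go to plus. Empty inputs yield empty tables
and zero-count summaries rather than errors; empty IDIN tables and empty
logo inputs are errors (a proportion of nothing is undefined). The
pipeline (`run`) composes extract → merge → score → annotate → idin
deterministically — all randomness lives in `simulate` — and writes a JSON
summary (site counts, gql counts, validation percentages, GT-AG upper
bound, annotation counts) alongside the TSVs. Exit codes: 0 success, 1
usage/config error, 2 data error. Test problem sizes (universes of 5–20
genes on a 100 kb chromosome, exhaustive sweeps over the full printed
score domains) are chosen so every property is checked end to end in
seconds.

## Known limitations

Minor-spliceosome (AT-AC) junctions score poorly under any major-splice
consensus model; a dedicated second model would be needed (the maximum of
the two scores), and the threshold constants used here were calibrated on
major-spliceosome data. The wgis thresholds (qsm 15; score 1; gql limits
30/80) are adopted as published constants, not re-derived. TSV import
without the `lstarts` column cannot participate in further exact merging.
BAM files are supported via pysam but the repository's own fixtures are
plain SAM.
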