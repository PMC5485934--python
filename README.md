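# gapsites

Validation of splice junctions (gap-sites) in gapped RNA-seq alignments.

## The problem

Spliced aligners (TopHat, STAR, HISAT2, ...) map reads that cross an
exon–exon boundary as gapped alignments: two matched segments separated by
an N-gap spanning the intron. Each distinct gap location — keyed by the
last aligned base left of the gap (*lend*) and the first aligned base right
of it (*rstart*), with the intron occupying `[lend+1, rstart−1]` — is a
candidate splice junction, a **gap-site**. Aligners report gap-sites with a
substantial false-discovery rate, and because standard library preparation
loses strand information, the transcribed strand of each junction is also
unknown. `gapsites` scores every gap-site with two validation statistics
and infers its strand, for anyone filtering junction catalogues before
downstream splicing analysis.

## The scores

**gqs — gap quality score** (alignment evidence only). Per site, two
saturating, monotone accumulators are kept: *nlstart*, the number of
distinct left alignment start positions (capped at the capacity *n* = 8),
and *qsm*, the sum of the four largest *mcl* values, where *mcl* is the
smaller of the two matched-segment lengths flanking one alignment's gap.
Then

```
gqs = trunc( 10 · (2·min(nlstart, n)/n) · qsm/4 )
```

At read length 100, `gqs ∈ [0, 1000]`; reaching 1000 requires at least 8
distinct start positions and four gaps matched by ≥ 50 bases on both sides.
Sites with `gqs ≥ 1000` are *gqs-validated*. Monotonicity guarantees that
merging more samples can never un-validate a site.

**wgis — weighted gap information score** (alignment plus sequence
evidence). The genomic sequence at both boundaries is scored with a
splice-site model — donor 9-mers over positions −3..+6 and acceptor
23-mers over −20..+3 — in both strand orientations, and

```
wgis = fnls · fqsm · fs5 · fs3 · sstr

fnls = log2(log2(nlstart) + 1) + 1
fqsm = log2(log2(max(qsm − 13, 2)))
fs5  = log2(max(score5, 1))
fs3  = log2(max(score3, 1))
```

The strand sign `sstr` is +1 when the acceptor window at *rstart* read
forward scores at least as high as the acceptor window at *lend* read in
reverse complement (the site then resembles a plus-strand 3′ splice-site),
−1 otherwise; the score factors are evaluated on the chosen strand.
`wgis = 0` exactly when `qsm ≤ 15` or either chosen-strand score is ≤ 1;
nonzero sites are *wgis-validated* and carry their strand in the sign. The
theoretical maximum is 124.9 (at `nlstart = 8`, `qsm = 200`,
`score5 = 11.8`, `score3 = 16.1`). |wgis| is cut at 30 and 80 into **gap
quality levels** gql 1–3 (gql 0 = not validated).

Scoring models: pre-computed maximum-entropy probability-ratio tables
(`maxent:DIR`), or a trainable log-odds position-weight model
(`wmm:FILE`) for fully self-contained use. See `docs/methods.md` for the
table layout and model details.

Around the scores, the package annotates each site against
intron-connected exon pairs built from an Ensembl-dialect GTF, reporting
the pair minimising `sod = |lend − left_exon_end| + |rstart −
right_exon_start|` (`sod = 0` means an annotated junction), and summarises
intronic dinucleotides (IDIN): strand-corrected pairs such as *GT-AG*, the
GT-AG upper bound (GT-AG plus CT-AC proportions of the unstranded table),
and sequence-logo frequency matrices.

A seeded synthetic-data generator (`gapsites simulate`) produces a genome,
GTF and pre-aligned spliced SAM reads with planted true and noise
junctions, so the whole pipeline can be exercised and validated without
any external data.

## Worked example

Simulate a small universe, train the position-weight model from the
generator's own motif profiles, and run the full pipeline:

```
$ gapsites simulate --outdir universe --seed 7 --n-genes 5
$ python -c "
from gapsites.synthetic_data import UniverseConfig, generate_universe
from gapsites.splice_models import save_wmm
u = generate_universe(UniverseConfig(n_genes=5, seed=7))
save_wmm(u.trained_model(), 'model.wmm')"
$ gapsites run --bam universe/reads.sam --genome universe/genome.fa \
    --gtf universe/genes.gtf --model wmm:model.wmm --outdir results
{
  "n_sites": 13,
  "n_samples": 1,
  "gql_counts": { "0": 3, "2": 4, "3": 6 },
  "pct_gqs_validated": 76.92,
  "pct_wgis_validated": 76.92,
  "n_annotated": 10,
  "n_exact": 10,
  "gtag_upper_bound_pct": 76.92
}
```

The universe planted 10 true junctions (5 genes × 2 introns, coverage 12)
and 3 noise junctions (coverage 1–3): all 10 true junctions are gqs- and
wgis-validated and annotate exactly (`n_exact = 10`, hence 76.92% of the
13 sites), while no noise junction validates. `results/scored.tsv` holds
the per-site evidence and scores:

```
seqid  lend  rstart  gqs   wgis    gql  gqs_validated  wgis_validated
chr1   450   693     1000  90.544  3    True           True
chr1   805   936     1000  58.332  2    True           True
```

and `results/idin_pairs.tsv` the unstranded dinucleotide table — true
junctions appear as GT-AG (plus-strand genes) or CT-AC (minus-strand
genes), noise as random pairs, giving the 76.92% GT-AG upper bound:

```
pair   count  percent
CT-AC  6      46.154
GT-AG  4      30.769
TT-CA  1      7.692
...
```

The individual stages are also available as `extract`, `merge`, `score`,
`annotate`, `idin` and `logo` subcommands, and everything is importable as
a library (`import gapsites`).

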