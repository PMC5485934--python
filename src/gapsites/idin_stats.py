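"""Intronic dinucleotide (IDIN) statistics and sequence-logo matrices.

The two intron bases just inside each gap boundary (left IDIN after *lend*,
right IDIN before *rstart*) classify a junction: canonical major-spliceosome
introns read GT..AG in transcription orientation.  Because raw gap-sites
are unstranded, the genome-orientation pairs mix plus-strand GT-AG with
minus-strand CT-AC; once wgis assigns a strand, IDIN are reported
strand-corrected (5'IDIN/3'IDIN).  Adding the GT-AG and CT-AG proportions
of the raw table gives an upper bound on the true GT-AG fraction.

Sites are counted by occurrence (each gap-site once), not by alignment
abundance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from gapsites.splice_models import fetch, revcomp

_BASES = "ACGT"

#: minimum intron length for non-overlapping left/right dinucleotides
MIN_INTRON_FOR_IDIN = 4

#: default logo windows: the donor 9-mer (3 exonic + 6 intronic; junction
#: after position 3) and an acceptor window of 8 intronic + 4 exonic bases
#: (rstart at position 9)
DONOR_LOGO_WIDTH = (3, 6)
ACCEPTOR_LOGO_WIDTH = (8, 4)


@dataclass(frozen=True)
class IdinRecord:
    """Raw and strand-corrected intronic dinucleotides for one gap-site."""

    left_idin: str
    right_idin: str
    idin5: str | None
    idin3: str | None


@dataclass(frozen=True)
class LogoMatrix:
    """Per-position nucleotide frequencies with junction position marked."""

    freq: pd.DataFrame  # index: 1-based positions, columns A C G T
    order: list[str]  # per position, bases by descending frequency
    junction_after: int | None = None
    n_windows: int = 0
    n_dropped: int = 0


def idin(genome, seqid: str, lend: int, rstart: int) -> tuple[str, str] | None:
    """Raw (left, right) intronic dinucleotides in genome orientation.

    left = genome[lend+1 .. lend+2], right = genome[rstart-2 .. rstart-1].
    Returns None (flagged, excluded from tables) for introns shorter than
    4 bases, where the two dinucleotides would overlap, or at chromosome
    edges.
    """
    if rstart - lend - 1 < MIN_INTRON_FOR_IDIN:
        return None
    left = fetch(genome, seqid, lend + 1, lend + 2)
    right = fetch(genome, seqid, rstart - 2, rstart - 1)
    if left is None or right is None:
        return None
    return left, right


def strand_correct(left_idin: str, right_idin: str, strand: str | None) -> tuple[str | None, str | None]:
    """Map genome-orientation IDIN to (5'IDIN, 3'IDIN) given a strand.

    Plus strand: 5' = left, 3' = right.  Minus strand: 5' = revcomp(right),
    3' = revcomp(left).  Undefined strand yields (None, None).
    """
    if strand == "+":
        return left_idin, right_idin
    if strand == "-":
        return revcomp(right_idin), revcomp(left_idin)
    return None, None


def idin_record(genome, seqid: str, lend: int, rstart: int, strand: str | None) -> IdinRecord | None:
    raw = idin(genome, seqid, lend, rstart)
    if raw is None:
        return None
    idin5, idin3 = strand_correct(raw[0], raw[1], strand)
    return IdinRecord(left_idin=raw[0], right_idin=raw[1], idin5=idin5, idin3=idin3)


def idin_pair_table(records: Iterable[IdinRecord], corrected: bool = False) -> Counter:
    """Count IDIN pairs by occurrence; keys like 'GT-AG'.

    ``corrected=True`` tabulates strand-corrected pairs (sites without a
    strand are skipped); otherwise raw genome-orientation pairs.
    """
    counts: Counter = Counter()
    for rec in records:
        if corrected:
            if rec.idin5 is None:
                continue
            counts[f"{rec.idin5}-{rec.idin3}"] += 1
        else:
            counts[f"{rec.left_idin}-{rec.right_idin}"] += 1
    return counts


def _normalize_pair_key(key) -> str:
    if isinstance(key, tuple):
        return f"{key[0]}-{key[1]}"
    return str(key)


def gtag_upper_bound(pair_counts: Mapping) -> float:
    """Upper bound (%) for GT-AG sites: GT-AG plus CT-AC proportions.

    CT-AC in genome orientation is the reverse complement of a GT-AG intron
    read on the opposite strand, so adding the two unstranded readings
    bounds the true (stranded) GT-AG percentage from above.
    """
    counts = {_normalize_pair_key(k): v for k, v in pair_counts.items()}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty IDIN pair table")
    return 100.0 * (counts.get("GT-AG", 0) + counts.get("CT-AC", 0)) / total


def logo_matrix(windows: Sequence[str], junction_after: int | None = None) -> LogoMatrix:
    """Per-position nucleotide frequency matrix from equal-width windows.

    Windows containing non-ACGT characters are dropped (tallied in
    ``n_dropped``).  Per position, ``order`` lists bases by descending
    frequency, ties broken alphabetically.
    """
    if not windows:
        raise ValueError("no windows supplied")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("logo windows have mixed widths")
    kept = []
    dropped = 0
    for w in windows:
        w = w.upper()
        if all(ch in _BASES for ch in w):
            kept.append(w)
        else:
            dropped += 1
    if not kept:
        raise ValueError("all windows contained non-ACGT characters")
    counts = pd.DataFrame(0, index=range(1, width + 1), columns=list(_BASES), dtype=float)
    for w in kept:
        for pos, ch in enumerate(w, start=1):
            counts.at[pos, ch] += 1
    freq = counts / len(kept)
    order = [
        "".join(sorted(_BASES, key=lambda b: (-freq.at[pos, b], b)))
        for pos in freq.index
    ]
    return LogoMatrix(
        freq=freq, order=order, junction_after=junction_after,
        n_windows=len(kept), n_dropped=dropped,
    )


def donor_logo_windows(
    genome,
    sites: Iterable[tuple[str, int, int, str]],
    exonic: int = DONOR_LOGO_WIDTH[0],
    intronic: int = DONOR_LOGO_WIDTH[1],
) -> list[str]:
    """Strand-corrected 5'-junction windows for (seqid, lend, rstart, strand)."""
    out = []
    for seqid, lend, rstart, strand in sites:
        if strand == "+":
            seq = fetch(genome, seqid, lend - exonic + 1, lend + intronic)
        elif strand == "-":
            seq = fetch(genome, seqid, rstart - intronic, rstart + exonic - 1)
            seq = revcomp(seq) if seq is not None else None
        else:
            continue
        if seq is not None:
            out.append(seq)
    return out


def acceptor_logo_windows(
    genome,
    sites: Iterable[tuple[str, int, int, str]],
    intronic: int = ACCEPTOR_LOGO_WIDTH[0],
    exonic: int = ACCEPTOR_LOGO_WIDTH[1],
) -> list[str]:
    """Strand-corrected 3'-junction windows for (seqid, lend, rstart, strand)."""
    out = []
    for seqid, lend, rstart, strand in sites:
        if strand == "+":
            seq = fetch(genome, seqid, rstart - intronic, rstart + exonic - 1)
        elif strand == "-":
            seq = fetch(genome, seqid, lend - exonic + 1, lend + intronic)
            seq = revcomp(seq) if seq is not None else None
        else:
            continue
        if seq is not None:
            out.append(seq)
    return out


def write_logo_matrix(matrix: LogoMatrix, path: str) -> None:
    """Write a logo matrix TSV: position, A, C, G, T (frequencies)."""
    out = matrix.freq.copy()
    out.insert(0, "position", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bed6(rows: Iterable[dict], path: str) -> None:
    """Export sites as BED6: name = idin5-idin3, score = gql, wgis strand.

    Each row dict needs seqid, lend, rstart, idin5, idin3, gql, strand.
    BED is 0-based half-open; the feature spans the intron.
    """
    with open(path, "w") as fh:
        for r in rows:
            name = f"{r.get('idin5', 'NA')}-{r.get('idin3', 'NA')}"
            strand = r.get("strand") or "."
            fh.write(
                f"{r['seqid']}\t{r['lend']}\t{r['rstart'] - 1}\t{name}\t{r['gql']}\t{strand}\n"
            )
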