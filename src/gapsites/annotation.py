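"""Annotation of gap-sites against intron-connected exon pairs from a GTF.

Ensembl-style GTF files list exons as independent features tied together
only by ``transcript_id`` and ``exon_number``, so introns must first be
reconstructed by pairing adjacent exons of each transcript.  Each gap-site
is then matched to the overlapping exon pair minimising *sod*, the sum of
distances between the gap boundaries and the annotated intron boundaries:

    sod = |lend - left_exon_end| + |rstart - right_exon_start|

sod == 0 means the gap-site sits exactly on an annotated splice junction.
Overlap is tested between the site's alignment footprint
``[range_start, range_end]`` and the pair's span
``[left_exon_start, right_exon_end]``; a site overlapping no pair gets no
annotation (reported as NA downstream).  Matching ignores the reference
strand — gap-sites carry no strand before wgis scoring — but the matched
pair's strand is reported for comparison with the wgis strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils

from gapsites.gap_extraction import GapSiteRecord

DEFAULT_READ_LENGTH = 100


@dataclass(frozen=True)
class ExonPair:
    """One intron-connected exon pair (possibly shared by transcripts)."""

    seqid: str
    strand: str
    left_exon_start: int
    left_exon_end: int
    right_exon_start: int
    right_exon_end: int
    transcript_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    left_exon_number: int | None = None

    @property
    def transcript_id(self) -> str:
        return self.transcript_ids[0]

    @property
    def gene_id(self) -> str:
        return self.gene_ids[0]


@dataclass(frozen=True)
class AnnotationResult:
    """Best (sod-minimising) exon pair for one gap-site, if any overlap."""

    best_pair: ExonPair | None
    sod: int | None

    @property
    def annotated(self) -> bool:
        return self.best_pair is not None


def sod(lend: int, rstart: int, pair: ExonPair) -> int:
    """Sum of distances between gap boundaries and intron boundaries."""
    return abs(lend - pair.left_exon_end) + abs(rstart - pair.right_exon_start)


def _exons_from_gtf(gtf_path: str, warnings: dict[str, int] | None = None):
    db = gffutils.create_db(
        gtf_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    for feature in db.features_of_type("exon"):
        tids = feature.attributes.get("transcript_id")
        if not tids:
            if warnings is not None:
                warnings["exon_without_transcript_id"] = warnings.get("exon_without_transcript_id", 0) + 1
            continue
        gids = feature.attributes.get("gene_id", [""])
        numbers = feature.attributes.get("exon_number")
        yield {
            "seqid": feature.seqid,
            "strand": feature.strand,
            "start": feature.start,
            "end": feature.end,
            "transcript_id": tids[0],
            "gene_id": gids[0],
            "exon_number": int(numbers[0]) if numbers else None,
        }


def build_exon_pairs(
    gtf: str | Iterable[dict],
    warnings: dict[str, int] | None = None,
) -> list[ExonPair]:
    """Build deduplicated, sorted intron-connected exon pairs.

    ``gtf`` is a GTF path or an iterable of exon dicts with keys seqid,
    strand, start, end, transcript_id, gene_id, exon_number.  Exons of a
    transcript are ordered by exon_number when present (genomic order,
    strand-aware, otherwise); pairs shared by several transcripts collapse
    to one entry carrying all transcript ids and the widest exon span.
    """
    exons = _exons_from_gtf(gtf, warnings) if isinstance(gtf, str) else gtf
    by_transcript: dict[str, list[dict]] = {}
    for exon in exons:
        if not exon.get("transcript_id"):
            if warnings is not None:
                warnings["exon_without_transcript_id"] = warnings.get("exon_without_transcript_id", 0) + 1
            continue
        by_transcript.setdefault(exon["transcript_id"], []).append(exon)

    # deduplicate on the intron key; keep widest flanking spans
    dedup: dict[tuple, dict] = {}
    for tid, tx_exons in by_transcript.items():
        if all(e["exon_number"] is not None for e in tx_exons):
            tx_exons = sorted(tx_exons, key=lambda e: e["exon_number"])
        else:
            reverse = tx_exons[0]["strand"] == "-"
            tx_exons = sorted(tx_exons, key=lambda e: e["start"], reverse=reverse)
        for a, b in zip(tx_exons, tx_exons[1:]):
            left, right = (a, b) if a["start"] <= b["start"] else (b, a)
            if left["end"] >= right["start"]:
                if warnings is not None:
                    warnings["overlapping_adjacent_exons"] = warnings.get("overlapping_adjacent_exons", 0) + 1
                continue
            key = (left["seqid"], left["strand"], left["end"], right["start"])
            entry = dedup.setdefault(
                key,
                {
                    "left_start": left["start"],
                    "right_end": right["end"],
                    "transcripts": set(),
                    "genes": set(),
                    "left_number": a["exon_number"],
                },
            )
            entry["left_start"] = min(entry["left_start"], left["start"])
            entry["right_end"] = max(entry["right_end"], right["end"])
            entry["transcripts"].add(tid)
            entry["genes"].add(left["gene_id"])

    pairs = [
        ExonPair(
            seqid=seqid,
            strand=strand,
            left_exon_start=entry["left_start"],
            left_exon_end=left_end,
            right_exon_start=right_start,
            right_exon_end=entry["right_end"],
            transcript_ids=tuple(sorted(entry["transcripts"])),
            gene_ids=tuple(sorted(entry["genes"])),
            left_exon_number=entry["left_number"],
        )
        for (seqid, strand, left_end, right_start), entry in dedup.items()
    ]
    pairs.sort(key=lambda p: (p.seqid, p.left_exon_start, p.right_exon_end, p.transcript_ids))
    return pairs


def _site_range(rec: GapSiteRecord, read_length: int) -> tuple[int, int]:
    # imported minimal tables may lack alignment footprints
    start = rec.range_start if rec.range_start is not None else max(1, rec.lend - read_length)
    end = rec.range_end if rec.range_end is not None else rec.rstart + read_length
    return start, end


def annotate(
    sites: Sequence[GapSiteRecord],
    pairs: Sequence[ExonPair],
    read_length: int = DEFAULT_READ_LENGTH,
) -> list[AnnotationResult]:
    """Annotate sorted gap-sites against sorted exon pairs by a sweep.

    Both inputs must be sorted by (seqid, start coordinate): sites by
    range_start, pairs by left_exon_start.  Among pairs whose span
    intersects the site's alignment footprint, the minimal-sod pair is
    reported; ties break on the lexicographically smallest
    (transcript_id, left_exon_end).  Results align with the input order.
    """
    site_keys = [(rec.seqid, _site_range(rec, read_length)[0]) for rec in sites]
    if any(site_keys[i] > site_keys[i + 1] for i in range(len(site_keys) - 1)):
        raise ValueError("gap-site table is not sorted by (seqid, range_start)")
    pair_keys = [(p.seqid, p.left_exon_start) for p in pairs]
    if any(pair_keys[i] > pair_keys[i + 1] for i in range(len(pair_keys) - 1)):
        raise ValueError("exon-pair list is not sorted by (seqid, left_exon_start)")

    results: list[AnnotationResult] = []
    i = 0  # next pair not yet activated
    active: list[ExonPair] = []
    current_seqid: str | None = None
    for rec in sites:
        start, end = _site_range(rec, read_length)
        if rec.seqid != current_seqid:
            current_seqid = rec.seqid
            active = []
            while i < len(pairs) and pairs[i].seqid < current_seqid:
                i += 1
        while i < len(pairs) and pairs[i].seqid == current_seqid and pairs[i].left_exon_start <= end:
            active.append(pairs[i])
            i += 1
        # sites are sorted by range_start, so pairs ending before this
        # site's start can never overlap a later site on this seqid
        active = [p for p in active if p.right_exon_end >= start]
        best: ExonPair | None = None
        best_sod: int | None = None
        for p in active:
            d = sod(rec.lend, rec.rstart, p)
            if (
                best_sod is None
                or d < best_sod
                or (d == best_sod and (p.transcript_id, p.left_exon_end) < (best.transcript_id, best.left_exon_end))
            ):
                best, best_sod = p, d
        results.append(AnnotationResult(best_pair=best, sod=best_sod))
    return results


def annotate_brute_force(
    sites: Sequence[GapSiteRecord],
    pairs: Sequence[ExonPair],
    read_length: int = DEFAULT_READ_LENGTH,
) -> list[AnnotationResult]:
    """Reference implementation scanning every pair for every site."""
    results = []
    for rec in sites:
        start, end = _site_range(rec, read_length)
        best, best_sod = None, None
        for p in pairs:
            if p.seqid != rec.seqid or p.left_exon_start > end or p.right_exon_end < start:
                continue
            d = sod(rec.lend, rec.rstart, p)
            if (
                best_sod is None
                or d < best_sod
                or (d == best_sod and (p.transcript_id, p.left_exon_end) < (best.transcript_id, best.left_exon_end))
            ):
                best, best_sod = p, d
        results.append(AnnotationResult(best_pair=best, sod=best_sod))
    return results
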