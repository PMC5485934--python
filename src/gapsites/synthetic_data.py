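"""Self-contained synthetic test universe: genome, GTF and gapped SAM.

The generator plants multi-exon genes with canonical splice motifs into a
random genome, writes an Ensembl-dialect GTF for them, and emits spliced
reads directly as aligned SAM records (M-N-M CIGARs with exact
coordinates), so no external aligner is ever needed.  True junctions carry
GT..AG intron ends in strand orientation with donor 9-mers and
pyrimidine-rich acceptor 23-mers sampled from configurable position-weight
profiles; noise junctions are placed away from genes, get low coverage and
random non-consensus boundaries.  A truth table of every planted junction
supports round-trip and recovery tests.

Everything is driven by a single seeded pseudo-random stream: the same
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from gapsites.splice_models import (
    ACCEPTOR_WIDTH,
    DONOR_WIDTH,
    PositionWeightModel,
    SpliceScoreModel,
    revcomp,
    wmm_from_profile,
    wmm_model,
)

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _profile(rows: list[tuple[str, float]]) -> np.ndarray:
    """Build a probability profile from (consensus base, weight) rows.

    The consensus base gets ``weight``; the remainder splits evenly.
    """
    out = np.empty((len(rows), 4))
    for i, (base, w) in enumerate(rows):
        out[i] = (1.0 - w) / 3.0
        out[i, _BASE_INDEX[base]] = w
    return out


def _pyrimidine(weight_c: float, weight_t: float) -> np.ndarray:
    row = np.empty(4)
    rest = (1.0 - weight_c - weight_t) / 2.0
    row[_BASE_INDEX["A"]] = rest
    row[_BASE_INDEX["G"]] = rest
    row[_BASE_INDEX["C"]] = weight_c
    row[_BASE_INDEX["T"]] = weight_t
    return row


#: donor profile, 9 positions (-3..+6), consensus CAG|GTAAGT; the intronic
#: GT is fixed so every true plant is canonical
DEFAULT_DONOR_PROFILE = _profile(
    [("C", 0.40), ("A", 0.60), ("G", 0.80),
     ("G", 1.00), ("T", 1.00),
     ("A", 0.60), ("A", 0.70), ("G", 0.80), ("T", 0.50)]
)

#: acceptor profile, 23 positions (-20..+3): branch-distal intron, a
#: pyrimidine-rich tract, the fixed AG, then 3 exonic bases (G consensus)
DEFAULT_ACCEPTOR_PROFILE = np.vstack(
    [_profile([("T", 0.40)] * 5)]
    + [_pyrimidine(0.40, 0.45) for _ in range(12)]
    + [_profile([("C", 0.65), ("A", 1.00), ("G", 1.00), ("G", 0.50), ("C", 0.30), ("C", 0.30)])]
)

#: IDIN pairs a noise junction is never allowed to mimic
_CONSENSUS_PAIRS = {("GT", "AG"), ("CT", "AC")}


@dataclass(frozen=True)
class JunctionPlant:
    """Ground truth for one planted junction."""

    seqid: str
    lend: int
    rstart: int
    strand: str
    truth_class: str  # {"true-splice", "noise"}
    coverage: int
    donor_window: str
    acceptor_window: str
    gene_id: str = ""
    transcript_id: str = ""

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.seqid, self.lend, self.rstart)


@dataclass
class UniverseConfig:
    """Study conditions for the synthetic universe.

    Defaults are desk-scale but structurally faithful: read length 100,
    true-junction coverage 12 (at least eight distinct alignment starts
    plus four centred reads with 50-base flanks, the minimal evidence that
    can reach gqs = 1000), noise junctions covered by 1-3 alignments.
    """

    n_chrom: int = 1
    chrom_length: int = 100_000
    n_genes: int = 20
    exons_per_gene: int = 3
    read_length: int = 100
    coverage_true: int = 12
    coverage_noise: tuple[int, int] = (1, 3)
    noise_fraction: float = 0.3
    seed: int = 0
    exon_length: tuple[int, int] = (60, 200)
    intron_length: tuple[int, int] = (80, 400)
    intergenic: int = 300
    noise_min_distance: int = 50
    donor_profile: np.ndarray = field(default_factory=lambda: DEFAULT_DONOR_PROFILE.copy())
    acceptor_profile: np.ndarray = field(default_factory=lambda: DEFAULT_ACCEPTOR_PROFILE.copy())


@dataclass
class Universe:
    """In-memory synthetic universe plus writers for the standard formats."""

    genome: dict[str, str]
    gtf_lines: list[str]
    sam_lines: list[str]
    plants: list[JunctionPlant]
    config: UniverseConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.plants])

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "genome.fa"),
            "gtf": os.path.join(outdir, "genes.gtf"),
            "sam": os.path.join(outdir, "reads.sam"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        with open(paths["fasta"], "w") as fh:
            for seqid in sorted(self.genome):
                fh.write(f">{seqid}\n")
                seq = self.genome[seqid]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(paths["gtf"], "w") as fh:
            fh.write("\n".join(self.gtf_lines) + ("\n" if self.gtf_lines else ""))
        with open(paths["sam"], "w") as fh:
            fh.write("\n".join(self.sam_lines) + ("\n" if self.sam_lines else ""))
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths

    def trained_model(self) -> SpliceScoreModel:
        """WMM splice model built from the generator's own profiles."""
        donor = wmm_from_profile(self.config.donor_profile)
        acceptor = wmm_from_profile(self.config.acceptor_profile)
        return wmm_model(donor, acceptor)


class PlacementError(RuntimeError):
    """Raised when genes or noise junctions cannot be placed."""


def _sample_window(rng: np.random.Generator, profile: np.ndarray) -> str:
    idx = [rng.choice(4, p=profile[i]) for i in range(profile.shape[0])]
    return "".join(_BASES[i] for i in idx)


def _splice_offsets(coverage: int, read_length: int) -> list[int]:
    """Left-flank lengths for reads over a true junction.

    The first four reads sit centred (flank = read_length/2, the maximal
    mcl) and the rest fan out to distinct start positions, so coverage >= 12
    guarantees >= 8 distinct starts and qsm = 4 * (read_length/2).
    """
    half = read_length // 2
    offsets = [half] * min(4, coverage)
    fan = []
    step = 1
    while len(fan) < max(0, coverage - 4):
        fan.append(half - step)
        if len(fan) < coverage - 4:
            fan.append(half + step)
        step += 1
    return offsets + fan


def generate_universe(config: UniverseConfig) -> Universe:
    """Generate the synthetic universe; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    read_length = config.read_length
    half = read_length // 2
    min_exon = max(config.exon_length[0], half + 10)
    max_exon = max(config.exon_length[1], min_exon + 1)
    min_intron = max(config.intron_length[0], ACCEPTOR_WIDTH + DONOR_WIDTH + 10)

    genome_arr = {
        f"chr{c + 1}": rng.integers(0, 4, size=config.chrom_length)
        for c in range(config.n_chrom)
    }

    gtf_lines: list[str] = []
    plants: list[JunctionPlant] = []
    sam_records: list[tuple[str, int, str]] = []  # (seqid, pos, line) for sorting
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in genome_arr}

    def write_bases(seqid: str, start: int, seq: str) -> None:
        # start 1-based inclusive
        genome_arr[seqid][start - 1 : start - 1 + len(seq)] = [_BASE_INDEX[ch] for ch in seq]

    # --- place genes round-robin over chromosomes, left to right
    chrom_names = sorted(genome_arr)
    cursors = {s: config.intergenic for s in chrom_names}
    read_counter = 0
    for g in range(config.n_genes):
        gene_id = f"g{g + 1}"
        tid = f"{gene_id}.t1"
        placed = False
        for attempt in range(len(chrom_names)):
            seqid = chrom_names[(g + attempt) % len(chrom_names)]
            exon_lens = rng.integers(min_exon, max_exon + 1, size=config.exons_per_gene)
            intron_lens = rng.integers(min_intron, max(config.intron_length[1], min_intron + 1) + 1,
                                       size=max(0, config.exons_per_gene - 1))
            span = int(exon_lens.sum() + intron_lens.sum())
            start = cursors[seqid]
            if start + span + config.intergenic > len(genome_arr[seqid]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            # exon coordinates
            exons = []
            pos = start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el) - 1))
                pos += int(el)
                if i < len(intron_lens):
                    pos += int(intron_lens[i])
            gene_start, gene_end = exons[0][0], exons[-1][1]
            cursors[seqid] = gene_end + config.intergenic
            occupied[seqid].append((gene_start, gene_end))

            attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'
            gtf_lines.append(f"{seqid}\tsynth\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\tgene_id \"{gene_id}\";")
            gtf_lines.append(f"{seqid}\tsynth\ttranscript\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t{attrs}")
            n_ex = len(exons)
            for i, (es, ee) in enumerate(exons):
                number = i + 1 if strand == "+" else n_ex - i
                gtf_lines.append(
                    f"{seqid}\tsynth\texon\t{es}\t{ee}\t.\t{strand}\t.\t{attrs} exon_number \"{number}\";"
                )

            # plant splice motifs and reads for each intron
            for i in range(n_ex - 1):
                lend = exons[i][1]
                rstart = exons[i + 1][0]
                donor = _sample_window(rng, config.donor_profile)
                acceptor = _sample_window(rng, config.acceptor_profile)
                if strand == "+":
                    write_bases(seqid, lend - 2, donor)
                    write_bases(seqid, rstart - 20, acceptor)
                else:
                    write_bases(seqid, rstart - 6, revcomp(donor))
                    write_bases(seqid, lend - 2, revcomp(acceptor))
                plants.append(
                    JunctionPlant(
                        seqid=seqid, lend=lend, rstart=rstart, strand=strand,
                        truth_class="true-splice", coverage=config.coverage_true,
                        donor_window=donor, acceptor_window=acceptor,
                        gene_id=gene_id, transcript_id=tid,
                    )
                )
                for o in _splice_offsets(config.coverage_true, read_length):
                    read_counter += 1
                    sam_records.append(_spliced_read(
                        f"read{read_counter}", seqid, lend, rstart, o, read_length))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"cannot place gene {gene_id}: chromosome length {config.chrom_length} too small "
                f"for {config.n_genes} genes of ~{span} bases"
            )

    # --- noise junctions, away from genes and from each other
    n_true = len(plants)
    n_noise = int(round(config.noise_fraction * n_true)) if n_true else int(round(config.noise_fraction * config.n_genes))
    taken: list[tuple[str, int, int]] = [(p.seqid, p.lend, p.rstart) for p in plants]
    for j in range(n_noise):
        placed = False
        for _ in range(200):
            seqid = chrom_names[int(rng.integers(0, len(chrom_names)))]
            lend = int(rng.integers(read_length + 30, len(genome_arr[seqid]) - 2000))
            intron = int(rng.integers(max(80, MIN_NOISE_INTRON), 800))
            rstart = lend + intron + 1
            if rstart + read_length + 30 > len(genome_arr[seqid]):
                continue
            near_gene = any(
                gs - config.noise_min_distance <= p <= ge + config.noise_min_distance
                for gs, ge in occupied[seqid] for p in (lend, rstart)
            )
            near_plant = any(
                s == seqid and (abs(lend - pl) < config.noise_min_distance or abs(rstart - pr) < config.noise_min_distance)
                for s, pl, pr in taken
            )
            if near_gene or near_plant:
                continue
            pair = (
                "".join(_BASES[genome_arr[seqid][lend : lend + 2]]),
                "".join(_BASES[genome_arr[seqid][rstart - 3 : rstart - 1]]),
            )
            if pair in _CONSENSUS_PAIRS:
                continue  # keep truth labels unambiguous
            coverage = int(rng.integers(config.coverage_noise[0], config.coverage_noise[1] + 1))
            for _ in range(coverage):
                o = int(rng.integers(20, read_length - 19))
                read_counter += 1
                sam_records.append(_spliced_read(
                    f"noise{read_counter}", seqid, lend, rstart, o, read_length))
            donor_w = "".join(_BASES[genome_arr[seqid][lend - 3 : lend + 6]])
            acceptor_w = "".join(_BASES[genome_arr[seqid][rstart - 21 : rstart + 2]])
            plants.append(
                JunctionPlant(
                    seqid=seqid, lend=lend, rstart=rstart, strand=".",
                    truth_class="noise", coverage=coverage,
                    donor_window=donor_w, acceptor_window=acceptor_w,
                )
            )
            taken.append((seqid, lend, rstart))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"cannot place noise junction {j + 1}/{n_noise} at distance "
                f">= {config.noise_min_distance} from existing plants"
            )

    genome = {s: "".join(_BASES[arr]) for s, arr in genome_arr.items()}

    # fill in actual read sequences now that motifs are planted
    sam_lines = [f"@HD\tVN:1.6\tSO:coordinate"]
    for seqid in chrom_names:
        sam_lines.append(f"@SQ\tSN:{seqid}\tLN:{len(genome[seqid])}")
    sam_records.sort(key=lambda r: (r[0], r[1]))
    for seqid, pos, line in sam_records:
        qname, flag, rname, p, mapq, cigar, o, lend, rstart = line
        left = genome[seqid][pos - 1 : pos - 1 + o]
        right = genome[seqid][rstart - 1 : rstart - 1 + (read_length - o)]
        seq = left + right
        sam_lines.append(
            f"{qname}\t{flag}\t{rname}\t{p}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{'I' * len(seq)}"
        )

    plants.sort(key=lambda p: p.key)
    return Universe(genome=genome, gtf_lines=gtf_lines, sam_lines=sam_lines,
                    plants=plants, config=config)


MIN_NOISE_INTRON = 80


def _spliced_read(qname: str, seqid: str, lend: int, rstart: int, left_flank: int,
                  read_length: int) -> tuple[str, int, tuple]:
    """Build a deferred SAM record tuple for a read spanning one junction."""
    pos = lend - left_flank + 1
    intron = rstart - lend - 1
    right = read_length - left_flank
    cigar = f"{left_flank}M{intron}N{right}M"
    return (seqid, pos, (qname, 0, seqid, pos, 60, cigar, left_flank, lend, rstart))
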