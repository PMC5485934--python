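"""Splice-site sequence windows and pluggable donor/acceptor scoring models.

Donor (5') sites are scored on 9-mers covering positions -3..+6 around the
exon|intron boundary (3 exonic, 6 intronic bases); acceptor (3') sites on
23-mers covering -20..+3 (20 intronic, 3 exonic bases).  Because alignments
carry no strand information, both boundary windows are extracted in both
orientations: the donor hypothesis sits at ``lend`` on the plus strand and
at ``rstart`` (reverse-complemented) on the minus strand, and vice versa
for the acceptor.

Two model kinds satisfy the same scoring contract (a deterministic real
score for every ACGT window of the declared width):

* ``maxent-table`` — pre-computed probability-ratio tables consumed by
  rank lookup; the acceptor uses the published 9-fragment factorisation of
  the 23-mer (product of five fragment ratios over four overlap ratios).
* ``wmm`` — a trainable log-odds position-weight model,
  ``score = log2(P_signal(seq) / P_background(seq))``, the self-contained
  alternative when no score tables are available.

Windows containing non-ACGT characters (e.g. assembly N runs) or running
past a chromosome end are unscorable; downstream, an unscorable strand
fails wgis validation.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

DONOR_WIDTH = 9
ACCEPTOR_WIDTH = 23

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_RC = str.maketrans("ACGTacgt", "TGCAtgca")

#: acceptor 23-mer fragment factorisation: the intronic AG consensus at
#: window positions 19-20 (0-based 18,19) is removed, leaving 21 bases;
#: the first five fragments multiply, the last four (overlaps) divide.
ACCEPTOR_FRAGMENTS = [
    (0, 7), (7, 14), (14, 21), (4, 11), (11, 18),
    (4, 7), (7, 11), (11, 14), (14, 18),
]
_ACCEPTOR_NUMERATOR = 5


class ModelError(ValueError):
    """Raised for malformed model inputs or table files."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving alphabet)."""
    return seq.translate(_RC)[::-1]


def kmer_rank(seq: str) -> int | None:
    """Base-4 rank of a k-mer (A=0, C=1, G=2, T=3); None if non-ACGT."""
    rank = 0
    for ch in seq:
        i = _BASE_INDEX.get(ch)
        if i is None:
            return None
        rank = rank * 4 + i
    return rank


# ---------------------------------------------------------------------------
# window extraction

@dataclass(frozen=True)
class SpliceWindows:
    """Boundary windows of one gap-site in both strand orientations.

    A window is None when it would run past the chromosome end or the
    sequence store could not provide it (unscorable).
    """

    donor_plus: str | None
    acceptor_plus: str | None
    donor_minus: str | None
    acceptor_minus: str | None


def fetch(genome, seqid: str, start: int, end: int) -> str | None:
    """Fetch genome[start..end] (1-based inclusive), None if out of bounds.

    Accepts a pyfaidx.Fasta, a plain dict of strings, or any mapping whose
    values support slicing.
    """
    if start < 1:
        return None
    try:
        chrom = genome[seqid]
    except KeyError:
        return None
    piece = chrom[start - 1 : end]
    seq = piece if isinstance(piece, str) else str(piece)
    if len(seq) != end - start + 1:
        return None
    return seq.upper()


def windows(genome, seqid: str, lend: int, rstart: int) -> SpliceWindows:
    """Extract donor/acceptor windows for a gap-site in both orientations.

    Plus strand: donor 9-mer ``[lend-2, lend+6]``, acceptor 23-mer
    ``[rstart-20, rstart+2]``.  Minus strand: donor at ``rstart`` and
    acceptor at ``lend``, both reverse-complemented.
    """
    dp = fetch(genome, seqid, lend - 2, lend + 6)
    ap = fetch(genome, seqid, rstart - 20, rstart + 2)
    dm = fetch(genome, seqid, rstart - 6, rstart + 2)
    am = fetch(genome, seqid, lend - 2, lend + 20)
    return SpliceWindows(
        donor_plus=dp,
        acceptor_plus=ap,
        donor_minus=revcomp(dm) if dm is not None else None,
        acceptor_minus=revcomp(am) if am is not None else None,
    )


# ---------------------------------------------------------------------------
# position-weight (log-odds) model

class PositionWeightModel:
    """Per-position log2-odds model over a fixed-width ACGT window."""

    def __init__(self, signal: np.ndarray, background: np.ndarray):
        signal = np.asarray(signal, dtype=float)
        background = np.asarray(background, dtype=float)
        if signal.shape != background.shape or signal.ndim != 2 or signal.shape[1] != 4:
            raise ModelError("signal/background must both be (width, 4)")
        self.width = signal.shape[0]
        self.log_odds = np.log2(signal) - np.log2(background)

    def score(self, seq: str) -> float | None:
        if len(seq) != self.width:
            raise ModelError(f"window width {len(seq)} != model width {self.width}")
        total = 0.0
        for pos, ch in enumerate(seq):
            i = _BASE_INDEX.get(ch)
            if i is None:
                return None
            total += self.log_odds[pos, i]
        return total


def train_wmm(
    signal_windows: Sequence[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> PositionWeightModel:
    """Train a position-weight model from fixed-width signal windows.

    Per-position base frequencies are smoothed with ``pseudocount``;
    background defaults to uniform 0.25.  Deterministic given inputs.
    """
    if not signal_windows:
        raise ModelError("empty training set")
    width = len(signal_windows[0])
    if any(len(w) != width for w in signal_windows):
        raise ModelError("training windows have mixed widths")
    counts = np.zeros((width, 4), dtype=float)
    for w in signal_windows:
        for pos, ch in enumerate(w.upper()):
            i = _BASE_INDEX.get(ch)
            if i is None:
                raise ModelError(f"non-ACGT character {ch!r} in training window")
            counts[pos, i] += 1
    signal = (counts + pseudocount) / (len(signal_windows) + 4 * pseudocount)
    if background is None:
        background = np.full((width, 4), 0.25)
    return PositionWeightModel(signal, background)


def wmm_from_profile(profile: np.ndarray, background: np.ndarray | None = None) -> PositionWeightModel:
    """Build a position-weight model directly from probability profiles."""
    profile = np.asarray(profile, dtype=float)
    # guard exact zeros (hard consensus positions) with a floor
    profile = np.clip(profile, 1e-4, None)
    profile = profile / profile.sum(axis=1, keepdims=True)
    if background is None:
        background = np.full(profile.shape, 0.25)
    return PositionWeightModel(profile, background)


# ---------------------------------------------------------------------------
# maximum-entropy table model

DONOR_TABLE_FILE = "donor_9mer.tsv"
ACCEPTOR_TABLE_PREFIX = "acceptor_t"


class _MaxEntDonor:
    def __init__(self, table: np.ndarray):
        if table.shape != (4**DONOR_WIDTH,):
            raise ModelError(f"donor table must have 4^9 = {4**DONOR_WIDTH} entries, got {table.shape[0]}")
        self.table = table
        self.width = DONOR_WIDTH

    def score(self, seq: str) -> float | None:
        if len(seq) != DONOR_WIDTH:
            raise ModelError(f"donor window must be {DONOR_WIDTH} bases, got {len(seq)}")
        rank = kmer_rank(seq)
        if rank is None:
            return None
        return float(np.log2(self.table[rank]))


class _MaxEntAcceptor:
    def __init__(self, tables: list[np.ndarray]):
        if len(tables) != len(ACCEPTOR_FRAGMENTS):
            raise ModelError(f"acceptor model needs {len(ACCEPTOR_FRAGMENTS)} fragment tables")
        for t, (a, b) in zip(tables, ACCEPTOR_FRAGMENTS):
            if t.shape != (4 ** (b - a),):
                raise ModelError(f"acceptor fragment table for [{a},{b}) must have 4^{b-a} entries, got {t.shape[0]}")
        self.tables = tables
        self.width = ACCEPTOR_WIDTH

    def score(self, seq: str) -> float | None:
        if len(seq) != ACCEPTOR_WIDTH:
            raise ModelError(f"acceptor window must be {ACCEPTOR_WIDTH} bases, got {len(seq)}")
        if any(ch not in _BASE_INDEX for ch in seq):
            return None
        core = seq[:18] + seq[20:]  # drop the intronic AG consensus slot
        log_ratio = 0.0
        for i, (a, b) in enumerate(ACCEPTOR_FRAGMENTS):
            rank = kmer_rank(core[a:b])
            val = math.log2(self.tables[i][rank])
            log_ratio += val if i < _ACCEPTOR_NUMERATOR else -val
        return log_ratio


@dataclass
class SpliceScoreModel:
    """A donor model plus an acceptor model under one scoring contract."""

    kind: str  # {"maxent-table", "wmm"}
    donor: object
    acceptor: object

    def score5(self, donor_window: str) -> float | None:
        return self.donor.score(donor_window)

    def score3(self, acceptor_window: str) -> float | None:
        return self.acceptor.score(acceptor_window)


def score5(model: SpliceScoreModel, donor_window: str) -> float | None:
    """Donor (5') splice-site score of a 9-mer; None if unscorable."""
    return model.score5(donor_window)


def score3(model: SpliceScoreModel, acceptor_window: str) -> float | None:
    """Acceptor (3') splice-site score of a 23-mer; None if unscorable."""
    return model.score3(acceptor_window)


def _read_table(path: str, expected: int) -> np.ndarray:
    if not os.path.exists(path):
        raise ModelError(f"missing score table: {path}")
    values = np.loadtxt(path, dtype=float, ndmin=1)
    if values.shape[0] != expected:
        raise ModelError(f"{path}: expected {expected} entries, found {values.shape[0]}")
    if np.any(values <= 0):
        raise ModelError(f"{path}: probability ratios must be positive")
    return values


def load_maxent_tables(path: str) -> SpliceScoreModel:
    """Load a maximum-entropy table directory.

    Layout: ``donor_9mer.tsv`` with 4^9 positive probability ratios, one per
    line in k-mer rank order (A=0, C=1, G=2, T=3), and ``acceptor_t0.tsv``
    .. ``acceptor_t8.tsv`` fragment tables sized 4^(fragment width) for the
    factorised 23-mer (fragments of the 21-mer left after removing the
    intronic AG consensus).
    """
    if not os.path.isdir(path):
        raise ModelError(f"not a table directory: {path}")
    donor = _MaxEntDonor(_read_table(os.path.join(path, DONOR_TABLE_FILE), 4**DONOR_WIDTH))
    tables = [
        _read_table(os.path.join(path, f"{ACCEPTOR_TABLE_PREFIX}{i}.tsv"), 4 ** (b - a))
        for i, (a, b) in enumerate(ACCEPTOR_FRAGMENTS)
    ]
    return SpliceScoreModel(kind="maxent-table", donor=donor, acceptor=_MaxEntAcceptor(tables))


# ---------------------------------------------------------------------------
# WMM model file I/O (plain text: sections ">donor"/">acceptor", rows of
# "position A C G T" signal probabilities)

def save_wmm(model: SpliceScoreModel, path: str) -> None:
    if model.kind != "wmm":
        raise ModelError("can only save wmm models")
    with open(path, "w") as fh:
        for name, sub in (("donor", model.donor), ("acceptor", model.acceptor)):
            fh.write(f">{name}\n")
            probs = np.power(2.0, sub.log_odds) * 0.25  # uniform background
            probs = probs / probs.sum(axis=1, keepdims=True)
            for pos in range(sub.width):
                fh.write(f"{pos + 1}\t" + "\t".join(f"{p:.6g}" for p in probs[pos]) + "\n")


def load_wmm(path: str) -> SpliceScoreModel:
    sections: dict[str, list[list[float]]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].strip().lower()
                sections[current] = []
            else:
                if current is None:
                    raise ModelError(f"{path}: data before section header")
                parts = line.split()
                if len(parts) != 5:
                    raise ModelError(f"{path}: expected 'position A C G T' rows")
                sections[current].append([float(x) for x in parts[1:]])
    for name, width in (("donor", DONOR_WIDTH), ("acceptor", ACCEPTOR_WIDTH)):
        if name not in sections:
            raise ModelError(f"{path}: missing >{name} section")
        if len(sections[name]) != width:
            raise ModelError(f"{path}: >{name} must have {width} rows, found {len(sections[name])}")
    donor = wmm_from_profile(np.array(sections["donor"]))
    acceptor = wmm_from_profile(np.array(sections["acceptor"]))
    return SpliceScoreModel(kind="wmm", donor=donor, acceptor=acceptor)


def wmm_model(donor: PositionWeightModel, acceptor: PositionWeightModel) -> SpliceScoreModel:
    """Pair donor/acceptor position-weight models into a splice score model."""
    if donor.width != DONOR_WIDTH or acceptor.width != ACCEPTOR_WIDTH:
        raise ModelError("donor must be 9 wide and acceptor 23 wide")
    return SpliceScoreModel(kind="wmm", donor=donor, acceptor=acceptor)
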