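"""Gap-site quality scores: gqs, wgis factors, strand sign and gql levels.

``gqs`` uses alignment evidence alone:

    gqs = trunc(10 * (2 * min(nlstart, n) / n) * qsm / 4)

with capacity ``n = 8``; at read length 100 (mcl <= 50, qsm <= 200) the
score lies in [0, 1000], and 1000 requires at least 8 distinct alignment
start positions and four mcl values of 50.  Sites with gqs >= 1000 are
"gqs-validated".

``wgis`` combines the same alignment evidence with splice-site model scores
of the genomic sequence at both boundaries:

    wgis = fnls * fqsm * fs5 * fs3 * sstr

    fnls = log2(log2(nlstart) + 1) + 1        (nlstart saturated at n)
    fqsm = log2(log2(max(qsm - 13, 2)))
    fs5  = log2(max(score5, 1))
    fs3  = log2(max(score3, 1))

The strand sign ``sstr`` is +1 when the acceptor window at the right
boundary read forward scores at least as high as the acceptor window at the
left boundary read in reverse complement (the site then looks like a
plus-strand 3' splice-site), else -1.  wgis is zero exactly when qsm <= 15
or the chosen strand's score5 <= 1 or score3 <= 1; nonzero sites are
"wgis-validated" and carry strand information in the sign.  |wgis| is cut
at 30 and 80 into gap quality levels (gql) 1..3, with gql 0 the unvalidated
sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from gapsites.gap_extraction import DEFAULT_CAPACITY, GapSiteRecord
from gapsites.splice_models import SpliceScoreModel, windows

GQS_VALIDATION_THRESHOLD = 1000
QSM_THRESHOLD = 15
SCORE_THRESHOLD = 1.0
GQL_LIMITS = (30.0, 80.0)


@dataclass(frozen=True)
class StrandScores:
    """Splice-model scores of one gap-site under both strand hypotheses.

    Plus strand: donor window at lend, acceptor window at rstart, both read
    forward.  Minus strand: donor at rstart, acceptor at lend, both read in
    reverse complement.  None marks an unscorable window.
    """

    score5_plus: float | None
    score3_plus: float | None
    score5_minus: float | None
    score3_minus: float | None

    @property
    def scorable(self) -> bool:
        return None not in (
            self.score5_plus, self.score3_plus, self.score5_minus, self.score3_minus
        )


@dataclass(frozen=True)
class ScoreResult:
    """All quality statistics for one gap-site."""

    gqs: int
    fnls: float
    fqsm: float
    fs5: float
    fs3: float
    sstr: int
    wgis: float
    gql: int
    strand: str | None  # '+', '-', or None when wgis == 0
    reason: str | None = None  # set when a site is unscorable


def gqs(nlstart: int, qsm: int, n: int = DEFAULT_CAPACITY) -> int:
    """Gap quality score, truncated to an integer.

    Exact integer arithmetic: 10 * (2*min(nlstart,n)/n) * qsm/4
    == 5 * min(nlstart, n) * qsm / n.
    """
    if nlstart < 1:
        raise ValueError("nlstart must be >= 1")
    if qsm < 0:
        raise ValueError("qsm must be >= 0")
    return (5 * min(nlstart, n) * qsm) // n


def fnls(nlstart: int, n: int = DEFAULT_CAPACITY) -> float:
    """nlstart factor, in (0, 3] for capacity 8."""
    return math.log2(math.log2(min(nlstart, n)) + 1) + 1


def fqsm(qsm: int) -> float:
    """qsm factor; 0 for qsm <= 15, ~2.916 at qsm = 200."""
    return math.log2(math.log2(max(qsm - 13, 2)))


def fs5(score5: float) -> float:
    """Donor-score factor; clamped to 0 for score5 <= 1."""
    return math.log2(max(score5, 1.0))


def fs3(score3: float) -> float:
    """Acceptor-score factor; clamped to 0 for score3 <= 1."""
    return math.log2(max(score3, 1.0))


def strand_sign(scores: StrandScores) -> int:
    """Strand sign from the two opposing acceptor-site scores.

    +1 when the right boundary read forward resembles a 3' splice-site at
    least as much as the left boundary read in reverse complement (ties are
    plus); -1 otherwise.
    """
    if scores.score3_plus is None or scores.score3_minus is None:
        raise ValueError("both acceptor scores required for strand assignment")
    return 1 if scores.score3_plus >= scores.score3_minus else -1


def wgis(
    record: GapSiteRecord,
    scores: StrandScores,
    n: int = DEFAULT_CAPACITY,
) -> ScoreResult:
    """Weighted gap information score for one accumulated gap-site.

    The strand is chosen by :func:`strand_sign`; the score factors are
    evaluated on the chosen strand's donor/acceptor scores and the product
    is signed by the strand.  Unscorable windows yield wgis 0 with the
    reason recorded.
    """
    g = gqs(record.nlstart, record.qsm, n=n)
    if not scores.scorable:
        return ScoreResult(
            gqs=g, fnls=fnls(record.nlstart, n), fqsm=fqsm(record.qsm),
            fs5=0.0, fs3=0.0, sstr=0, wgis=0.0, gql=0, strand=None,
            reason="unscorable window",
        )
    sstr = strand_sign(scores)
    s5 = scores.score5_plus if sstr > 0 else scores.score5_minus
    s3 = scores.score3_plus if sstr > 0 else scores.score3_minus
    f1, f2, f3, f4 = fnls(record.nlstart, n), fqsm(record.qsm), fs5(s5), fs3(s3)
    value = f1 * f2 * f3 * f4 * sstr
    level = gql(value)
    return ScoreResult(
        gqs=g, fnls=f1, fqsm=f2, fs5=f3, fs3=f4, sstr=sstr,
        wgis=value, gql=level,
        strand=("+" if sstr > 0 else "-") if value != 0 else None,
    )


def gql(wgis_value: float) -> int:
    """Gap quality level: |wgis| partitioned at 0, 30 and 80."""
    a = abs(wgis_value)
    if a == 0:
        return 0
    if a <= GQL_LIMITS[0]:
        return 1
    if a <= GQL_LIMITS[1]:
        return 2
    return 3


def is_gqs_validated(record: GapSiteRecord, n: int = DEFAULT_CAPACITY) -> bool:
    """gqs validation: gqs >= 1000 (so longer reads cannot un-validate)."""
    return gqs(record.nlstart, record.qsm, n=n) >= GQS_VALIDATION_THRESHOLD


def is_wgis_validated(result: ScoreResult) -> bool:
    """wgis validation: any nonzero wgis."""
    return result.wgis != 0


# ---------------------------------------------------------------------------
# table-level scoring

def strand_scores(genome, model: SpliceScoreModel, seqid: str, lend: int, rstart: int) -> StrandScores:
    """Extract both-strand windows for a site and score them."""
    w = windows(genome, seqid, lend, rstart)
    return StrandScores(
        score5_plus=model.score5(w.donor_plus) if w.donor_plus is not None else None,
        score3_plus=model.score3(w.acceptor_plus) if w.acceptor_plus is not None else None,
        score5_minus=model.score5(w.donor_minus) if w.donor_minus is not None else None,
        score3_minus=model.score3(w.acceptor_minus) if w.acceptor_minus is not None else None,
    )


def score_sites(
    table: dict[tuple[str, int, int], GapSiteRecord],
    genome,
    model: SpliceScoreModel,
    n: int = DEFAULT_CAPACITY,
) -> pd.DataFrame:
    """Score every record; returns one row per site with score columns.

    wgis is reported at full precision internally and rounded to 3 decimals
    in the output table.
    """
    rows = []
    for rec in sorted(table.values(), key=lambda r: r.key):
        sc = strand_scores(genome, model, rec.seqid, rec.lend, rec.rstart)
        res = wgis(rec, sc, n=n)
        rows.append(
            {
                "seqid": rec.seqid,
                "lend": rec.lend,
                "rstart": rec.rstart,
                "gqs": res.gqs,
                "score5_plus": sc.score5_plus,
                "score3_plus": sc.score3_plus,
                "score5_minus": sc.score5_minus,
                "score3_minus": sc.score3_minus,
                "strand": res.strand if res.strand is not None else ".",
                "wgis": round(res.wgis, 3),
                "gql": res.gql,
                "gqs_validated": res.gqs >= GQS_VALIDATION_THRESHOLD,
                "wgis_validated": res.wgis != 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seqid", "lend", "rstart", "gqs",
            "score5_plus", "score3_plus", "score5_minus", "score3_minus",
            "strand", "wgis", "gql", "gqs_validated", "wgis_validated",
        ],
    )
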