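"""Motif catalog: PFM -> log-odds PWM conversion, two-strand genome scanning
with relative scoring, and the exclusion filters used to build the CBS track.

Scores are log2 odds against a zeroth-order background; the relative score
(score - min achievable) / (max achievable - min achievable) is the [0, 1]
affinity proxy used throughout.  Absolute log base and pseudocount largely
cancel in relative scores and allelic score differences.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _seq
from .io import GenomeIndex, GenomicInterval

UNIFORM_BACKGROUND = np.full(4, 0.25)

#: default total pseudocount, distributed by background (JASPAR-ecosystem convention)
DEFAULT_PSEUDOCOUNT = 0.8


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Observed base counts per motif position (rows A, C, G, T)."""
    motif_id: str
    counts: np.ndarray  # (4, L)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("PFM counts must be a 4 x L matrix with L >= 1")
        if (counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("every PFM column must have positive total count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return _seq.decode(np.argmax(self.counts, axis=0))


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2-odds scoring matrix with its achievable score range.

    ``probs`` holds the pseudocounted per-column base probabilities; the
    importance-sampling proposal in :mod:`cbskit.allelic` draws from them.
    """
    motif_id: str
    log_odds: np.ndarray  # (4, L), bits
    background: np.ndarray  # (4,)
    pseudocount: float
    probs: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "log_odds", np.asarray(self.log_odds, dtype=float))
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if self.probs is None:
            # reconstruct column probabilities from the log-odds
            p = self.background[:, None] * 2.0 ** self.log_odds
            object.__setattr__(self, "probs", p / p.sum(axis=0, keepdims=True))

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def score_min(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def score_max(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return _seq.decode(np.argmax(self.log_odds, axis=0))

    @property
    def rc_log_odds(self) -> np.ndarray:
        """Matrix scoring the reverse complement when applied to plus-strand text."""
        return self.log_odds[::-1, ::-1]

    def score(self, seq: str) -> float:
        """Plus-strand log-odds score of a sequence of exactly motif length."""
        codes = _seq.encode(seq)
        if len(codes) != self.length:
            raise ValueError("sequence length must equal motif length")
        if (codes >= 4).any():
            return float("-inf")
        return float(self.log_odds[codes, np.arange(self.length)].sum())

    def relative(self, score: float) -> float:
        rng = self.score_max - self.score_min
        if rng == 0:
            return 1.0
        return (score - self.score_min) / rng


@dataclass
class MotifHit:
    """A scored motif match in plus-strand genomic coordinates."""
    chrom: str
    start: int  # 0-based
    end: int  # half-open; end - start == motif length
    strand: str  # '+' or '-'
    score: float  # bits
    relative_score: float  # in [0, 1]
    motif_id: str = ""
    activity: float | None = None
    quantile: int | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.motif_id, strand=self.strand)


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PositionWeightMatrix:
    """Convert a count matrix to a log2-odds PWM.

    Per column j: p[b] = (counts[b,j] + pseudocount*background[b]) / (colsum +
    pseudocount), and log_odds[b,j] = log2(p[b] / background[b]).
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background probabilities must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = pfm.counts
    adjusted = counts + pseudocount * background[:, None]
    probs = adjusted / adjusted.sum(axis=0, keepdims=True)
    log_odds = np.log2(probs / background[:, None])
    return PositionWeightMatrix(
        motif_id=pfm.motif_id, log_odds=log_odds,
        background=background, pseudocount=pseudocount, probs=probs,
    )


def window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every L-length window of an encoded sequence.

    Windows containing an N (code 4) score -inf.  Returns an array of length
    ``len(codes) - L + 1`` (empty when the sequence is shorter than L).
    """
    L = log_odds.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    lo5 = np.vstack([log_odds, np.full((1, L), -np.inf)])
    scores = np.zeros(n)
    for j in range(L):
        scores += lo5[codes[j:j + n], j]
    return scores


def scan_sequence(
    seq: str | np.ndarray,
    pwm: PositionWeightMatrix,
    report_threshold: float = 0.8,
    chrom: str = "chr1",
) -> list[MotifHit]:
    """Score every motif-length window on both strands of a sequence.

    Minus-strand windows are scored on their reverse complement but reported
    in plus-strand coordinates.  Hits with relative score >= the threshold are
    returned sorted by (chrom, start, strand).  Windows containing N are
    skipped; sequences shorter than the motif yield an empty list.
    """
    codes = _seq.encode(seq) if isinstance(seq, str) else np.asarray(seq, np.uint8)
    rng = pwm.score_max - pwm.score_min
    hits: list[MotifHit] = []
    for strand, matrix in (("+", pwm.log_odds), ("-", pwm.rc_log_odds)):
        scores = window_scores(codes, matrix)
        if rng == 0:
            rel = np.where(np.isfinite(scores), 1.0, -np.inf)
        else:
            rel = (scores - pwm.score_min) / rng
        for i in np.flatnonzero(rel >= report_threshold):
            hits.append(MotifHit(
                chrom=chrom, start=int(i), end=int(i) + pwm.length, strand=strand,
                score=float(scores[i]), relative_score=float(rel[i]),
                motif_id=pwm.motif_id,
            ))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def scan_genome(
    genome: GenomeIndex,
    pwm: PositionWeightMatrix,
    report_threshold: float = 0.8,
) -> list[MotifHit]:
    """Scan every contig of a genome; see :func:`scan_sequence`."""
    hits: list[MotifHit] = []
    for chrom in genome.contigs:
        codes = genome.codes(chrom, 0, genome.length(chrom))
        hits.extend(scan_sequence(codes, pwm, report_threshold, chrom=chrom))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


@dataclass
class MotifFilterResult:
    kept: list[MotifHit]
    tallies: dict[str, int]


def filter_motifs(
    hits: Iterable[MotifHit],
    autosomes: Sequence[str],
    exclusions: Mapping[str, Sequence[GenomicInterval]],
) -> MotifFilterResult:
    """Drop hits on non-autosomal contigs or overlapping any exclusion track.

    Overlap means >= 1 shared base in half-open coordinates.  Tallies count
    per-track membership, so a hit inside both a gap and a blacklist interval
    increments both tallies while being removed once.  Non-autosomal hits are
    tallied only under ``non_autosome``.
    """
    from intervaltree import IntervalTree

    autoset = set(autosomes)
    trees: dict[str, dict[str, IntervalTree]] = {}
    for track, intervals in exclusions.items():
        per_chrom: dict[str, IntervalTree] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        trees[track] = per_chrom

    tallies = {name: 0 for name in exclusions}
    tallies["non_autosome"] = 0
    kept: list[MotifHit] = []
    for hit in hits:
        if hit.chrom not in autoset:
            tallies["non_autosome"] += 1
            continue
        removed = False
        for track, per_chrom in trees.items():
            tree = per_chrom.get(hit.chrom)
            if tree is not None and tree.overlaps(hit.start, hit.end):
                tallies[track] += 1
                removed = True
        if not removed:
            kept.append(hit)
    return MotifFilterResult(kept=kept, tallies=tallies)


def write_motif_bed(hits: Sequence[MotifHit], path) -> None:
    """Write hits as BED6+2 (name=motif_id, score column = log-odds, extra
    columns relative_score and activity/quantile when present)."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.chrom, h.start, h.strand)):
            extra = [f"{h.relative_score:.6g}"]
            if h.activity is not None:
                extra.append(f"{h.activity:.6g}")
                extra.append(str(h.quantile) if h.quantile is not None else ".")
            fh.write("\t".join([
                h.chrom, str(h.start), str(h.end), h.motif_id or ".",
                f"{h.score:.6g}", h.strand, *extra,
            ]) + "\n")


def read_motif_bed(path) -> list[MotifHit]:
    hits = []
    for iv_line in open(path):
        f = iv_line.rstrip("\n").split("\t")
        hit = MotifHit(
            chrom=f[0], start=int(f[1]), end=int(f[2]), strand=f[5],
            score=float(f[4]), relative_score=float(f[6]), motif_id=f[3],
        )
        if len(f) > 7 and f[7] != ".":
            hit.activity = float(f[7])
        if len(f) > 8 and f[8] != ".":
            hit.quantile = int(f[8])
        hits.append(hit)
    return hits
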