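"""Per-locus CTCF binding-activity summarization.

An rDHS x biosample matrix of ChIP-seq Z-scores is first masked (entries with
zero raw signal are stored with the sentinel -10), then each locus's score
distribution across biosamples is collapsed into a single binding-activity
value.  The printed meta-analysis formula is sum(z_i)/N over the N non-masked
biosamples — the arithmetic mean — which is the default; the conventional
Stouffer combination sum(z_i)/sqrt(N) is available as an option.

Activity values are rank-binned into equal-sized quantiles (100 bins by
default, deciles elsewhere) for all stratified downstream analyses.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataIntegrityError, GenomicInterval
from .motifs import MotifHit

log = logging.getLogger("cbskit")

#: sentinel stored at masked (zero raw signal) matrix entries
MASK_SENTINEL = -10.0

#: ENCODE cCRE-framework threshold for calling a locus CTCF-bound
DEFAULT_BOUND_Z = 1.64


@dataclass
class BindingActivityMatrix:
    """rDHS x biosample Z-scores with an explicit mask for zero-signal entries.

    The boolean mask is authoritative; the -10 sentinel in ``z`` merely mirrors
    it so that written matrices round-trip.
    """
    rdhs_ids: list[str]
    biosample_ids: list[str]
    z: np.ndarray
    masked: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.masked = np.asarray(self.masked, dtype=bool)
        n, m = len(self.rdhs_ids), len(self.biosample_ids)
        if self.z.shape != (n, m) or self.masked.shape != (n, m):
            raise DataIntegrityError("matrix dimensions do not match id lists")
        if not np.all(self.z[self.masked] == MASK_SENTINEL):
            raise DataIntegrityError("masked entries must hold the -10 sentinel")

    @property
    def n_unmasked(self) -> np.ndarray:
        return (~self.masked).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=pd.Index(self.rdhs_ids, name="rdhs_id"),
                            columns=self.biosample_ids)

    @classmethod
    def from_tsv(cls, path) -> "BindingActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return mask_zero_signal(df)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class RDHSRecord:
    """An rDHS interval carrying its activity summary and quantile bin."""
    rdhs_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    activity: float | None = None
    quantile: int | None = None
    n_unmasked: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise DataIntegrityError(
                f"invalid rDHS interval {self.chrom}:{self.start}-{self.end}")
        if (self.quantile is None) != (self.activity is None):
            raise DataIntegrityError("quantile present iff activity present")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.rdhs_id)


def mask_zero_signal(matrix) -> BindingActivityMatrix:
    """Flag every entry equal to the -10 sentinel as masked; values unchanged.

    Accepts a DataFrame (index = rDHS ids, columns = biosample ids) or a plain
    rectangular array (ids synthesized).
    """
    if isinstance(matrix, pd.DataFrame):
        rdhs_ids = [str(i) for i in matrix.index]
        biosample_ids = [str(c) for c in matrix.columns]
        z = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix)
        if arr.dtype == object:
            raise DataIntegrityError("non-rectangular or non-numeric matrix")
        z = arr.astype(float)
        if z.ndim != 2:
            raise DataIntegrityError("activity matrix must be 2-dimensional")
        rdhs_ids = [f"rDHS{i}" for i in range(z.shape[0])]
        biosample_ids = [f"B{j}" for j in range(z.shape[1])]
    masked = z == MASK_SENTINEL
    return BindingActivityMatrix(rdhs_ids, biosample_ids, z, masked)


def summarize_activity(
    matrix: BindingActivityMatrix, method: str = "paper_mean"
) -> dict[str, float]:
    """Collapse each locus's unmasked Z-scores into one binding-activity value.

    ``paper_mean``: sum(z_i)/N (the printed formula; the arithmetic mean).
    ``stouffer_sqrt``: sum(z_i)/sqrt(N) (the conventional Stouffer statistic).
    Loci with zero unmasked biosamples receive no score.
    """
    if method not in ("paper_mean", "stouffer_sqrt"):
        raise ValueError(f"unknown method {method!r}")
    import math

    unmasked = ~matrix.masked
    n = unmasked.sum(axis=1)
    scores: dict[str, float] = {}
    skipped = 0
    for i, rid in enumerate(matrix.rdhs_ids):
        if n[i] == 0:
            skipped += 1
            continue
        # exactly-rounded sum: the result is independent of summation order
        total = math.fsum(matrix.z[i, unmasked[i]])
        denom = int(n[i]) if method == "paper_mean" else math.sqrt(n[i])
        scores[rid] = total / denom
    if skipped:
        log.info("summarize_activity: %d loci fully masked, no score assigned",
                 skipped)
    return scores


def assign_activity_quantiles(
    scores: Mapping[str, float], k: int = 100
) -> dict[str, int]:
    """Rank-based equal-sized binning of activity scores into bins 1..k.

    Ties are broken by a stable sort on (activity, rdhs_id); bin sizes differ
    by at most one; bin 1 holds the lowest activities.
    """
    n = len(scores)
    if n < k:
        raise ValueError(f"need at least k={k} scored loci, got {n}")
    ordered = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    return {rid: int(rank * k // n) + 1 for rank, (rid, _) in enumerate(ordered)}


@dataclass(frozen=True)
class BoundCall:
    bound: bool
    n_biosamples_bound: int


def call_bound(
    matrix: BindingActivityMatrix, z_threshold: float = DEFAULT_BOUND_Z
) -> dict[str, BoundCall]:
    """Call a locus CTCF-bound if any unmasked Z strictly exceeds the threshold.

    Also reports how many biosamples exceed it (the replication count behind
    the sensitivity analysis of threshold choice).
    """
    exceeding = (~matrix.masked) & (matrix.z > z_threshold)
    counts = exceeding.sum(axis=1)
    return {
        rid: BoundCall(bound=bool(counts[i] > 0), n_biosamples_bound=int(counts[i]))
        for i, rid in enumerate(matrix.rdhs_ids)
    }


def annotate_motifs_with_activity(
    motifs: Iterable[MotifHit], rdhs: Sequence[RDHSRecord]
) -> list[MotifHit]:
    """Assign each motif the activity of its overlapping scored rDHS.

    Overlap requires >= 1 shared base in half-open coordinates.  A motif
    overlapping several scored rDHSs (e.g. bookended elements) takes the
    maximum activity among them; motifs with no scored overlap are excluded
    from the returned catalog.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for rec in rdhs:
        if rec.activity is None:
            continue
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec)
    out: list[MotifHit] = []
    for hit in motifs:
        tree = trees.get(hit.chrom)
        if tree is None:
            continue
        overlapping = tree.overlap(hit.start, hit.end)
        if not overlapping:
            continue
        best = max((iv.data for iv in overlapping),
                   key=lambda r: (r.activity, r.rdhs_id))
        annotated = MotifHit(**{**hit.__dict__})
        annotated.activity = best.activity
        annotated.quantile = best.quantile
        out.append(annotated)
    return out


def build_rdhs_records(
    intervals: Sequence[GenomicInterval],
    scores: Mapping[str, float],
    quantiles: Mapping[str, int],
    n_unmasked: Mapping[str, int] | None = None,
) -> list[RDHSRecord]:
    """Combine rDHS intervals with activity scores and quantile assignments."""
    records = []
    for iv in intervals:
        rid = iv.name
        records.append(RDHSRecord(
            rdhs_id=rid, chrom=iv.chrom, start=iv.start, end=iv.end,
            activity=scores.get(rid), quantile=quantiles.get(rid),
            n_unmasked=int(n_unmasked.get(rid, 0)) if n_unmasked else 0,
        ))
    return records


def write_rdhs_summary(records: Sequence[RDHSRecord], path) -> None:
    rows = [{
        "rdhs_id": r.rdhs_id, "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_unmasked": r.n_unmasked, "activity": r.activity, "quantile": r.quantile,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
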