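"""Readers and writers for the on-disk formats used across the pipeline.

All coordinates are 0-based half-open (BED convention) internally.  The only
place 1-based coordinates exist is the ``pos`` column of variant tables, which
mirrors VCF; conversion to 0-based happens exactly once, at the point of use.

Gzip-compressed text inputs are handled transparently for BED, TSV and
bedGraph (via pandas) and for VCF (via pysam).
"""
from __future__ import annotations

import dataclasses
import gzip
import hashlib
import io as _stdio
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq

log = logging.getLogger("cbskit")

#: canonical column order for variant tables
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "AC", "AN", "AF",
    "filter", "consequence", "cadd_phred",
]


class DataIntegrityError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED convention)."""
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise DataIntegrityError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into sorted :class:`GenomicInterval` records.

    Malformed lines raise :class:`DataIntegrityError` naming the line number.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataIntegrityError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataIntegrityError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise DataIntegrityError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from exc
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
            try:
                out.append(GenomicInterval(fields[0], start, end, name, score, strand))
            except DataIntegrityError as exc:
                raise DataIntegrityError(f"{path}: line {lineno}: {exc}") from exc
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(records: Iterable[GenomicInterval], path) -> None:
    records = sorted(records, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with _open_text(path, "wt") as fh:
        for iv in records:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(repr(iv.score) if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Random access to genome sequence by (contig, 0-based start, half-open end).

    Holds sequences in memory as uint8 codes; suitable for the simulated
    genomes this package targets (megabases, not gigabases).
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise DataIntegrityError("empty genome")
        self._codes: dict[str, np.ndarray] = {
            name: _seq.encode(s) for name, s in sequences.items()
        }

    @classmethod
    def from_fasta(cls, path) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @classmethod
    def from_codes(cls, codes: Mapping[str, np.ndarray]) -> "GenomeIndex":
        obj = cls.__new__(cls)
        obj._codes = {k: np.asarray(v, dtype=np.uint8) for k, v in codes.items()}
        if not obj._codes:
            raise DataIntegrityError("empty genome")
        return obj

    @property
    def contigs(self) -> list[str]:
        return list(self._codes)

    def length(self, chrom: str) -> int:
        return len(self._codes[chrom])

    def _check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self._codes:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 0 or end > len(self._codes[chrom]) or start > end:
            raise DataIntegrityError(
                f"slice {chrom}:{start}-{end} outside contig bounds "
                f"(length {len(self._codes[chrom])})"
            )

    def codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        self._check(chrom, start, end)
        return self._codes[chrom][start:end]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return _seq.decode(self.codes(chrom, start, end))

    def codes_padded(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Like :meth:`codes` but N-pads slices extending past contig ends."""
        if chrom not in self._codes:
            raise KeyError(f"unknown contig {chrom!r}")
        arr = self._codes[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        out = np.full(end - start, _seq.N_CODE, dtype=np.uint8)
        if hi > lo:
            out[lo - start: hi - start] = arr[lo:hi]
        return out

    def base(self, chrom: str, pos0: int) -> str:
        return self.fetch(chrom, pos0, pos0 + 1)

    def to_dict(self) -> dict[str, str]:
        return {name: _seq.decode(c) for name, c in self._codes.items()}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Variants (VCF v4.x or TSV dialect)
# ---------------------------------------------------------------------------

def _variant_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df["consequence"] = df["consequence"].where(
        pd.notna(df["consequence"]), np.nan)
    df["pos"] = df["pos"].astype(np.int64)
    df["AC"] = df["AC"].astype(np.int64)
    df["AN"] = df["AN"].astype(np.int64)
    df["AF"] = df["AF"].astype(float)
    df["cadd_phred"] = df["cadd_phred"].astype(float)
    return df


def read_variants(path) -> pd.DataFrame:
    """Read variants from a VCF (v4.x) or TSV file into a canonical table.

    Multi-allelic VCF rows are split into one record per ALT allele with
    per-allele AC/AF.  Positions stay 1-based as in VCF.  TSV input must
    carry the columns CHROM, POS, REF, ALT, FILTER, AC, AN, AF (case
    insensitive; ``consequence`` and ``cadd_phred`` optional).
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path)
    return _read_variant_tsv(path)


def _read_vcf(path: str) -> pd.DataFrame:
    import pysam

    rows: list[dict] = []
    missing: dict[str, int] = {}
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = dict(rec.info)
            an = info.get("AN")
            acs = info.get("AC")
            afs = info.get("AF")
            if an is None or acs is None or afs is None:
                for key in ("AC", "AN", "AF"):
                    if info.get(key) is None:
                        missing[key] = missing.get(key, 0) + 1
                continue
            if not isinstance(acs, tuple):
                acs = (acs,)
            if not isinstance(afs, tuple):
                afs = (afs,)
            filters = list(rec.filter.keys()) or ["PASS"]
            csq = info.get("CSQ") or info.get("consequence")
            cadd = info.get("CADD") or info.get("cadd_phred")
            for alt, ac, af in zip(rec.alts or (), acs, afs):
                rows.append({
                    "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                    "alt": alt, "AC": int(ac), "AN": int(an), "AF": float(af),
                    "filter": ";".join(filters),
                    "consequence": csq,
                    "cadd_phred": float(cadd) if cadd is not None else np.nan,
                })
    if missing:
        raise DataIntegrityError(
            f"{path}: missing required INFO keys (rows affected): {missing}"
        )
    return _variant_frame(rows)


_TSV_ALIASES = {
    "chrom": "chrom", "#chrom": "chrom", "pos": "pos", "ref": "ref",
    "alt": "alt", "ac": "AC", "an": "AN", "af": "AF", "filter": "filter",
    "consequence": "consequence", "cadd_phred": "cadd_phred", "cadd": "cadd_phred",
}


def _read_variant_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [_TSV_ALIASES.get(c.lower(), c) for c in df.columns]
    required = ["chrom", "pos", "ref", "alt", "AC", "AN", "AF", "filter"]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise DataIntegrityError(f"{path}: missing required columns {absent}")
    for col in ("consequence", "cadd_phred"):
        if col not in df.columns:
            df[col] = np.nan if col == "cadd_phred" else None
    return _variant_frame(df.to_dict("records"))


def write_variants_tsv(df: pd.DataFrame, path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def read_pfm_jaspar(path):
    """Parse a JASPAR-format PFM (4 labeled rows with bracketed counts).

    Rows may appear in any order; they are assigned by their A/C/G/T label.
    """
    from Bio import motifs as bio_motifs

    from .motifs import PositionFrequencyMatrix

    with _open_text(path) as fh:
        text = fh.read()
    try:
        m = bio_motifs.read(_stdio.StringIO(text), "jaspar")
    except Exception as exc:  # Bio raises bare Exceptions on bad rows
        raise DataIntegrityError(f"{path}: cannot parse JASPAR PFM: {exc}") from exc
    counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
        raise DataIntegrityError(f"{path}: PFM rows have mismatched lengths")
    return PositionFrequencyMatrix(motif_id=m.matrix_id or m.name or "PFM",
                                   counts=counts)


def write_pfm_jaspar(pfm, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f">{pfm.motif_id} {pfm.motif_id}\n")
        for i, b in enumerate("ACGT"):
            vals = " ".join(f"{int(v):6d}" for v in pfm.counts[i])
            fh.write(f"{b} [{vals} ]\n")


# ---------------------------------------------------------------------------
# Per-base score tracks (bedGraph required; bigWig optional)
# ---------------------------------------------------------------------------

class ScoreTrack:
    """Per-base score accessor over (contig, 0-based position).

    Backed by sorted non-overlapping [start, end) runs per contig; positions
    not covered by any run are reported missing.
    """

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # runs: chrom -> (starts, ends, values), starts sorted
        self._runs = {
            c: (np.asarray(s), np.asarray(e), np.asarray(v, dtype=float))
            for c, (s, e, v) in runs.items()
        }

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        runs = {}
        for chrom, g in df.groupby("chrom", sort=True):
            g = g.sort_values("start")
            runs[chrom] = (
                g["start"].to_numpy(np.int64),
                g["end"].to_numpy(np.int64),
                g["value"].to_numpy(float),
            )
        return cls(runs)

    @classmethod
    def from_bigwig(cls, path) -> "ScoreTrack":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        runs = {}
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom) or []
            if ivs:
                s, e, v = (np.array(x) for x in zip(*ivs))
                runs[chrom] = (s.astype(np.int64), e.astype(np.int64), v.astype(float))
        bw.close()
        return cls(runs)

    @classmethod
    def from_dense(cls, arrays: Mapping[str, np.ndarray]) -> "ScoreTrack":
        runs = {}
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            runs[chrom] = (
                np.arange(len(arr), dtype=np.int64),
                np.arange(1, len(arr) + 1, dtype=np.int64),
                arr,
            )
        return cls(runs)

    def query(self, chrom: str, pos0: int) -> float | None:
        if chrom not in self._runs:
            raise KeyError(f"contig {chrom!r} not in track")
        starts, ends, values = self._runs[chrom]
        i = np.searchsorted(starts, pos0, side="right") - 1
        if i >= 0 and pos0 < ends[i]:
            return float(values[i])
        return None

    def values_at(self, chrom: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup; returns (values, missing_mask)."""
        if chrom not in self._runs:
            raise KeyError(f"contig {chrom!r} not in track")
        starts, ends, values = self._runs[chrom]
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out = np.full(len(positions), np.nan)
        out[ok] = values[idx[ok]]
        return out, ~ok


def write_bedgraph(arrays: Mapping[str, np.ndarray], path) -> None:
    """Write dense per-base arrays as bedGraph, merging equal adjacent runs."""
    with _open_text(path, "wt") as fh:
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def dataclass_from_dict(cls, data: Mapping, where: str = "config"):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise DataIntegrityError(f"{where}: unknown keys {sorted(unknown)}")
    return cls(**data)
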