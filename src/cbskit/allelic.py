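"""Allelic PWM scoring of candidate SNVs inside CTCF binding sites.

For each (variant, motif) pair a window of ``flank`` bases on each side of the
variant is extracted from the reference genome.  Both alleles are scored as
the maximum log-odds over every motif-length subwindow that fits inside the
window and covers the variant position, on both strands.  The score change
dPWM = ref_best - alt_best classifies the variant: dPWM <= 0 is a putative
gain of binding, dPWM > 0 a putative loss.

Significance of an observed dPWM is its one-sided tail probability under an
explicit null: the window drawn i.i.d. from a zeroth-order background and the
substituted allele drawn uniformly from the three non-reference bases.  The
tail is estimated by importance sampling from a background/motif-embedding
mixture proposal (the approach popularized for allele-specific TF binding
tests), with an exact enumeration oracle available for small motifs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .io import DataIntegrityError, GenomeIndex
from .motifs import MotifHit, PositionWeightMatrix

log = logging.getLogger("cbskit")

DEFAULT_FLANK = 14
DEFAULT_MIN_AN = 76_000
DEFAULT_DUMMY_FLOOR = 1e-7
DEFAULT_ALPHA = 0.05

#: exact enumeration bounds: 4^window sequences must stay countable
MAX_EXACT_MOTIF_LEN = 8
MAX_EXACT_WINDOW = 13

_TAIL_TOL = 1e-9  # tolerance for tail inclusion of float-identical atoms


@dataclass(frozen=True)
class VariantRecord:
    """A single SNV with its population-genetic annotations (pos is 1-based)."""
    chrom: str
    pos: int
    ref: str
    alt: str
    AC: int
    AN: int
    AF: float
    filter: str = "PASS"
    consequence: str | None = None
    cadd_phred: float | None = None
    context3: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise DataIntegrityError("ref and alt alleles must differ")
        if self.AC < 1 or self.AN < self.AC:
            raise DataIntegrityError("require AC >= 1 and AN >= AC")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class BackgroundModel:
    """Zeroth-order nucleotide background for the significance null."""
    base_probs: np.ndarray = None
    order: int = 0

    def __post_init__(self):
        probs = (np.full(4, 0.25) if self.base_probs is None
                 else np.asarray(self.base_probs, dtype=float))
        object.__setattr__(self, "base_probs", probs)
        if probs.shape != (4,) or (probs <= 0).any():
            raise ValueError("background needs 4 strictly positive probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        if self.order != 0:
            raise ValueError("only zeroth-order backgrounds are supported")


@dataclass
class AllelicScore:
    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    motif_chrom: str
    motif_start: int
    motif_end: int
    motif_strand: str
    ref_best: float
    alt_best: float
    delta_pwm: float
    binding_class: str  # 'gain' (delta <= 0) or 'loss' (delta > 0)
    p_value: float | None = None
    neglog10_rank: float | None = None
    confident: bool | None = None
    activity: float | None = None
    quantile: int | None = None


def classify_delta(delta: float) -> str:
    return "gain" if delta <= 0 else "loss"


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

@dataclass
class VariantFilterResult:
    kept: pd.DataFrame
    removed: dict[str, int]


def filter_variants(records: pd.DataFrame, min_AN: int = DEFAULT_MIN_AN
                    ) -> VariantFilterResult:
    """Apply the population-genetic QC used for all downstream analyses.

    Retains bi-allelic SNVs (single-base ref and alt), AC > 0, AF > 0,
    FILTER == PASS and AN strictly greater than ``min_AN`` (half-cohort
    coverage).  Rules are applied in that order and removals tallied under
    the first failing rule.
    """
    required = ["chrom", "pos", "ref", "alt", "AC", "AN", "AF", "filter"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise DataIntegrityError(f"variant table missing columns {missing}")
    df = records.copy()
    counts: dict[str, int] = {}
    rules = [
        ("not_snv", ~(df["ref"].astype(str).str.fullmatch("[ACGT]")
                      & df["alt"].astype(str).str.fullmatch("[ACGT]"))),
        ("ac_zero", df["AC"] <= 0),
        ("af_zero", df["AF"] <= 0),
        ("not_pass", df["filter"] != "PASS"),
        ("low_an", df["AN"] <= min_AN),
    ]
    dropped = pd.Series(False, index=df.index)
    for name, bad in rules:
        newly = bad & ~dropped
        counts[name] = int(newly.sum())
        dropped |= bad
    kept = df.loc[~dropped].reset_index(drop=True)
    log.info("filter_variants: kept %d / %d (%s)", len(kept), len(df), counts)
    return VariantFilterResult(kept=kept, removed=counts)


def intersect_variants_with_cbs(
    variants: pd.DataFrame, cbs_catalog: Sequence[MotifHit]
) -> pd.DataFrame:
    """One row per (variant, motif) pair whose 0-based position lies in the motif.

    A variant inside k motifs yields k rows, each carrying that motif's
    activity and quantile annotations.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for hit in cbs_catalog:
        trees.setdefault(hit.chrom, IntervalTree()).addi(hit.start, hit.end, hit)
    rows = []
    for rec in variants.itertuples(index=False):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        pos0 = int(rec.pos) - 1
        for iv in tree.at(pos0):
            hit: MotifHit = iv.data
            row = rec._asdict()
            row.update({
                "variant_id": f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}",
                "motif_chrom": hit.chrom, "motif_start": hit.start,
                "motif_end": hit.end, "motif_strand": hit.strand,
                "motif_score": hit.score, "motif_relative_score": hit.relative_score,
                "activity": hit.activity, "quantile": hit.quantile,
            })
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Window scoring core
# ---------------------------------------------------------------------------

def _center_offsets(window_len: int, motif_len: int, flank: int) -> np.ndarray:
    """Start offsets of motif-length subwindows that fit in the window and
    cover its center position."""
    lo = max(0, flank - motif_len + 1)
    hi = min(flank, window_len - motif_len)
    return np.arange(lo, hi + 1) if hi >= lo else np.empty(0, dtype=int)


def _pad_matrix(matrix: np.ndarray) -> np.ndarray:
    # 5th row scores code 4 (N) as -inf
    return np.vstack([matrix, np.full((1, matrix.shape[1]), -np.inf)])


def best_allele_scores(
    windows: np.ndarray, alt_codes: np.ndarray,
    pwm: PositionWeightMatrix, flank: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Best subwindow log-odds for REF windows and their center-substituted ALTs.

    ``windows`` is an (n, 2*flank+1) uint8 array of encoded REF sequence
    (N-padded at contig edges); ``alt_codes`` the ALT base code per row.
    Returns (ref_best, alt_best); rows with no valid subwindow yield -inf.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=np.uint8))
    n, W = windows.shape
    L = pwm.length
    offsets = _center_offsets(W, L, flank)
    ref_best = np.full(n, -np.inf)
    alt_best = np.full(n, -np.inf)
    if offsets.size == 0:
        return ref_best, alt_best
    center = windows[:, flank].astype(np.intp)
    if (center >= 4).any():
        raise DataIntegrityError("variant position falls outside the contig")
    alt_codes = np.asarray(alt_codes, dtype=np.intp)
    for matrix in (pwm.log_odds, pwm.rc_log_odds):
        m5 = _pad_matrix(matrix)
        for s in offsets:
            score = np.zeros(n)
            for j in range(L):
                score += m5[windows[:, s + j].astype(np.intp), j]
            jc = flank - s
            # grouped so that alt == ref yields an exact zero contribution
            alt_score = score + (m5[alt_codes, jc] - m5[center, jc])
            np.maximum(ref_best, score, out=ref_best)
            np.maximum(alt_best, alt_score, out=alt_best)
    return ref_best, alt_best


def score_alleles(
    variant, motif: MotifHit | None, genome: GenomeIndex,
    pwm: PositionWeightMatrix, flank: int = DEFAULT_FLANK,
) -> AllelicScore | None:
    """Score one (variant, motif) pair; see module docstring for the rule.

    Raises :class:`DataIntegrityError` when the REF allele disagrees with the
    genome.  Returns None (with a log entry) when no motif-length subwindow
    fits — e.g. at contig edges where N-padding invalidates every subwindow.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    chrom, pos, ref, alt = variant.chrom, int(variant.pos), variant.ref, variant.alt
    pos0 = pos - 1
    genome_base = genome.base(chrom, pos0)
    if genome_base != ref:
        raise DataIntegrityError(
            f"REF mismatch at {chrom}:{pos}: genome has {genome_base}, "
            f"variant claims {ref}")
    window = genome.codes_padded(chrom, pos0 - flank, pos0 + flank + 1)
    ref_best, alt_best = best_allele_scores(
        window[None, :], _seq.encode(alt), pwm, flank)
    if not np.isfinite(ref_best[0]):
        log.info("score_alleles: no valid subwindow for %s:%d, pair dropped",
                 chrom, pos)
        return None
    delta = float(ref_best[0] - alt_best[0])
    return AllelicScore(
        variant_id=f"{chrom}:{pos}:{ref}>{alt}",
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        motif_chrom=motif.chrom if motif else chrom,
        motif_start=motif.start if motif else pos0,
        motif_end=motif.end if motif else pos0 + 1,
        motif_strand=motif.strand if motif else "+",
        ref_best=float(ref_best[0]), alt_best=float(alt_best[0]),
        delta_pwm=delta, binding_class=classify_delta(delta),
        activity=motif.activity if motif else None,
        quantile=motif.quantile if motif else None,
    )


def score_pairs_table(
    pairs: pd.DataFrame, genome: GenomeIndex,
    pwm: PositionWeightMatrix, flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Vectorized allelic scoring for a (variant, motif) pair table.

    Adds ref_best / alt_best / delta_pwm / binding_class columns; pairs with
    no valid subwindow are dropped with a log entry.  REF mismatches with the
    genome are a hard error naming the first offending position.
    """
    if pairs.empty:
        out = pairs.copy()
        for col in ("ref_best", "alt_best", "delta_pwm", "binding_class"):
            out[col] = []
        return out
    W = 2 * flank + 1
    windows = np.empty((len(pairs), W), dtype=np.uint8)
    pos0 = pairs["pos"].to_numpy(np.int64) - 1
    chroms = pairs["chrom"].to_numpy()
    for i in range(len(pairs)):
        windows[i] = genome.codes_padded(chroms[i], pos0[i] - flank, pos0[i] + flank + 1)
    ref_codes = _seq.encode("".join(pairs["ref"]))
    if (windows[:, flank] != ref_codes).any():
        bad = int(np.flatnonzero(windows[:, flank] != ref_codes)[0])
        raise DataIntegrityError(
            f"REF mismatch at {chroms[bad]}:{int(pairs['pos'].iloc[bad])}")
    alt_codes = _seq.encode("".join(pairs["alt"]))
    ref_best, alt_best = best_allele_scores(windows, alt_codes, pwm, flank)
    out = pairs.copy()
    out["ref_best"] = ref_best
    out["alt_best"] = alt_best
    out["delta_pwm"] = ref_best - alt_best
    out["binding_class"] = np.where(out["delta_pwm"] > 0, "loss", "gain")
    invalid = ~np.isfinite(ref_best)
    if invalid.any():
        log.info("score_pairs_table: dropped %d pairs with no valid subwindow",
                 int(invalid.sum()))
        out = out.loc[~invalid].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Null distribution of the score change
# ---------------------------------------------------------------------------

def _all_windows(W: int, chunk: int) -> Iterable[np.ndarray]:
    """Yield all 4^W windows as (m, W) uint8 arrays in chunks."""
    total = 4 ** W
    place = 4 ** np.arange(W - 1, -1, -1, dtype=np.int64)
    for lo in range(0, total, chunk):
        idx = np.arange(lo, min(lo + chunk, total), dtype=np.int64)
        yield ((idx[:, None] // place) % 4).astype(np.uint8)


class ExactScoreChangeNull:
    """Exact null distribution of dPWM by full enumeration.

    Enumerates every window of length 2*flank+1 under the background and every
    single-base substitution at the center (weight 1/3 each); feasible only
    for small motifs (L <= 8, window <= 13).
    """

    def __init__(self, pwm: PositionWeightMatrix, background: BackgroundModel,
                 flank: int, chunk: int = 1 << 16):
        W = 2 * flank + 1
        if pwm.length > MAX_EXACT_MOTIF_LEN or W > MAX_EXACT_WINDOW:
            raise ValueError(
                f"exact enumeration limited to motif length <= "
                f"{MAX_EXACT_MOTIF_LEN} and window <= {MAX_EXACT_WINDOW}")
        if pwm.length > W:
            raise ValueError("window shorter than the motif: no valid subwindow")
        self.flank = flank
        logbg = np.log(background.base_probs)
        deltas: list[np.ndarray] = []
        weights: list[np.ndarray] = []
        for wins in _all_windows(W, chunk):
            logp = logbg[wins.astype(np.intp)].sum(axis=1)
            center = wins[:, flank]
            for a in range(4):
                sel = center != a
                if not sel.any():
                    continue
                ref_best, alt_best = best_allele_scores(
                    wins[sel], np.full(int(sel.sum()), a), pwm, flank)
                deltas.append(ref_best - alt_best)
                weights.append(np.exp(logp[sel]) / 3.0)
        d = np.concatenate(deltas)
        w = np.concatenate(weights)
        d = np.round(d, 12)
        uniq, inv = np.unique(d, return_inverse=True)
        agg = np.zeros(len(uniq))
        np.add.at(agg, inv, w)
        self.deltas = uniq
        self.weights = agg
        self._cum = np.cumsum(agg)  # P(Delta <= deltas[i])

    def tail_ge(self, d: float) -> float:
        i = np.searchsorted(self.deltas, d - _TAIL_TOL, side="left")
        total = self._cum[-1]
        return float(total - (self._cum[i - 1] if i > 0 else 0.0))

    def tail_le(self, d: float) -> float:
        i = np.searchsorted(self.deltas, d + _TAIL_TOL, side="right")
        return float(self._cum[i - 1]) if i > 0 else 0.0

    def pvalue(self, delta_obs: float) -> float:
        """One-sided tail probability in the observed direction."""
        if delta_obs > 0:
            return self.tail_ge(delta_obs)
        return self.tail_le(delta_obs)


def exact_change_pvalue(
    delta_obs: float, pwm: PositionWeightMatrix,
    background: BackgroundModel, flank: int,
) -> float:
    """P(dPWM_null >= delta_obs) for delta_obs > 0, else P(dPWM_null <= delta_obs),
    by exact enumeration (small motifs only)."""
    return ExactScoreChangeNull(pwm, background, flank).pvalue(delta_obs)


class ImportanceSamplingNull:
    """Importance-sampling estimate of the dPWM null tail.

    The proposal draws each window from a mixture of (a) the background model
    and (b) the pseudocounted motif-probability model embedded at a uniformly
    chosen offset; per-draw weights are background density / proposal density.
    Built once per (PWM, background, flank), then any number of observed
    deltas can be evaluated against the same draws.
    """

    def __init__(self, pwm: PositionWeightMatrix, background: BackgroundModel,
                 flank: int, n_samples: int, seed: int,
                 motif_weight: float = 0.5):
        if n_samples < 1000:
            raise ValueError("need at least 1000 importance samples")
        if not 0.0 < motif_weight < 1.0:
            raise ValueError("motif mixture weight must be in (0, 1)")
        W = 2 * flank + 1
        L = pwm.length
        if L > W:
            raise ValueError("window shorter than the motif: no valid subwindow")
        rng = np.random.default_rng(seed)
        bg = background.base_probs
        logbg = np.log(bg)
        logmp = np.log(pwm.probs)
        n_off = W - L + 1

        windows = rng.choice(4, size=(n_samples, W), p=bg).astype(np.uint8)
        from_motif = rng.random(n_samples) < motif_weight
        n_m = int(from_motif.sum())
        if n_m:
            embed_at = rng.integers(0, n_off, size=n_m)
            rows = np.flatnonzero(from_motif)
            for j in range(L):
                col = rng.choice(4, size=n_m, p=pwm.probs[:, j])
                windows[rows, embed_at + j] = col

        wi = windows.astype(np.intp)
        logp_bg = logbg[wi].sum(axis=1)
        # log density of the embedded-motif component, per embedding offset
        comp = np.full((n_samples, n_off), -np.inf)
        for o in range(n_off):
            term = logp_bg.copy()
            for j in range(L):
                b = wi[:, o + j]
                term += logmp[b, j] - logbg[b]
            comp[:, o] = term
        from scipy.special import logsumexp

        log_q = np.logaddexp(
            np.log1p(-motif_weight) + logp_bg,
            np.log(motif_weight) - np.log(n_off) + logsumexp(comp, axis=1),
        )
        self.weights = np.exp(logp_bg - log_q)

        center = windows[:, flank].astype(np.intp)
        alt = (center + rng.integers(1, 4, size=n_samples)) % 4
        ref_best, alt_best = best_allele_scores(windows, alt, pwm, flank)
        self.deltas = ref_best - alt_best
        self.n = n_samples

    def _tail(self, mask: np.ndarray) -> tuple[float, float]:
        x = self.weights * mask
        p = float(x.mean())
        se = float(x.std(ddof=1) / np.sqrt(self.n))
        return p, se

    def pvalue(self, delta_obs: float) -> tuple[float, float]:
        """(estimate, standard error) of the one-sided tail in the observed
        direction."""
        if delta_obs > 0:
            return self._tail(self.deltas >= delta_obs - _TAIL_TOL)
        return self._tail(self.deltas <= delta_obs + _TAIL_TOL)


def importance_sampling_pvalue(
    delta_obs: float, pwm: PositionWeightMatrix, background: BackgroundModel,
    flank: int, n_samples: int, seed: int, motif_weight: float = 0.5,
) -> tuple[float, float]:
    """One-shot importance-sampling tail estimate; deterministic given seed."""
    null = ImportanceSamplingNull(pwm, background, flank, n_samples, seed,
                                  motif_weight)
    return null.pvalue(delta_obs)


# ---------------------------------------------------------------------------
# p-value bookkeeping
# ---------------------------------------------------------------------------

def encode_truncated_pvalues(p: float, dummy_floor: float = DEFAULT_DUMMY_FLOOR
                             ) -> float:
    """Floor truncated (approximately zero) p-values at the dummy value."""
    if p < 0:
        raise ValueError("p-value must be >= 0")
    return max(p, dummy_floor)


def neglog10_rank(p: float, dummy_floor: float = DEFAULT_DUMMY_FLOOR) -> float:
    return float(-np.log10(encode_truncated_pvalues(p, dummy_floor)))


def flag_confident(scores: Iterable[AllelicScore], alpha: float = DEFAULT_ALPHA
                   ) -> list[AllelicScore]:
    """Mark scores with p strictly below alpha as high-confidence."""
    out = []
    for s in scores:
        if s.p_value is None:
            raise ValueError(f"score {s.variant_id} has no p-value")
        s.confident = s.p_value < alpha
        out.append(s)
    return out


def dedupe_per_variant(scored: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per variant across overlapping motifs.

    Preference order: smallest p-value, then largest |dPWM|, then motif
    coordinates (chrom, start, end, strand) for determinism.
    """
    df = scored.copy()
    df["_absd"] = -df["delta_pwm"].abs()
    sort_cols = ["variant_id", "_absd", "motif_chrom", "motif_start",
                 "motif_end", "motif_strand"]
    if "p_value" in df.columns:
        sort_cols.insert(1, "p_value")
    df = df.sort_values(sort_cols, kind="stable")
    df = df.drop_duplicates("variant_id", keep="first").drop(columns="_absd")
    return df.reset_index(drop=True)
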