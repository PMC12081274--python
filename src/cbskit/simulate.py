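"""Synthetic-data generators for every input the pipeline consumes.

The generators produce a genome with planted motif instances, an rDHS x
biosample Z-score matrix with planted active loci, a gnomAD-like variant
table whose singleton probabilities follow a known mutability + selection
structure, a trinucleotide mutation-rate table, exclusion tracks, and a
per-base conservation track — together with a :class:`TruthTable` recording
every planted fact, so each downstream stage can be tested against ground
truth without external downloads.

Every generator is a pure function of (config, seed): streams are derived
from ``config.seed`` with fixed per-generator stream ids.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .activity import BindingActivityMatrix, mask_zero_signal
from .io import GenomeIndex, GenomicInterval
from .motifs import MotifHit, PositionFrequencyMatrix, PositionWeightMatrix

# stream ids for deriving independent RNG streams from one seed
_STREAM_GENOME = 1
_STREAM_RDHS = 2
_STREAM_MOTIFS = 3
_STREAM_MATRIX = 4
_STREAM_RATES = 5
_STREAM_VARIANTS = 6
_STREAM_CONSERVATION = 7
_STREAM_EXCLUSIONS = 8


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study conditions.

    Sizes are desk-scale: a few megabases of genome, thousands of loci,
    214 biosamples (the breadth of the real CTCF ChIP compendium).
    ``selection_effect_by_decile`` plants an excess singleton probability for
    loss-of-binding variants as a function of their locus's activity decile;
    the all-zero default is the no-selection null.
    """
    seed: int = 0
    genome_length: int = 400_000  # per chromosome
    n_chromosomes: int = 4
    gc_content: float = 0.41
    n_rdhs: int = 3000
    rdhs_length: int = 300
    n_biosamples: int = 214
    frac_active_rdhs: float = 0.4
    z_active_mean: float = 4.0
    z_active_sd: float = 1.5
    mask_rate_inactive: float = 0.9
    mask_rate_active: float = 0.3
    n_motif_instances: int = 2600
    frac_motifs_in_rdhs: float = 0.85
    motif_planting_fidelity: float = 0.95
    fidelity_active_boost: float = 0.04  # extra fidelity at active host rDHSs
    n_variants: int = 150_000
    n_control_variants: int = 75_000
    singleton_base_rate: float = 0.40
    mutation_rate_slope: float = -0.03  # singletons deplete at mutable sites
    selection_effect_by_decile: tuple = (0.0,) * 10
    an_total: int = 152_000
    fail_filter_rate: float = 0.02
    flank: int = 14
    frac_controls_synonymous: float = 0.6
    cadd_neutral_mean: float = 3.0
    cadd_sd: float = 4.0
    cadd_loss_shift: float = 8.0
    conservation_effect: float = 2.0
    conservation_sd: float = 1.0
    n_gap_intervals: int = 4
    gap_length: int = 2000
    n_blacklist_intervals: int = 8
    blacklist_length: int = 1000
    n_exon_intervals: int = 30
    exon_length: int = 500

    def __post_init__(self):
        fracs = {
            "gc_content": self.gc_content,
            "frac_active_rdhs": self.frac_active_rdhs,
            "mask_rate_inactive": self.mask_rate_inactive,
            "mask_rate_active": self.mask_rate_active,
            "motif_planting_fidelity": self.motif_planting_fidelity,
            "singleton_base_rate": self.singleton_base_rate,
            "fail_filter_rate": self.fail_filter_rate,
            "frac_motifs_in_rdhs": self.frac_motifs_in_rdhs,
            "frac_controls_synonymous": self.frac_controls_synonymous,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        effects = tuple(self.selection_effect_by_decile)
        if len(effects) != 10 or any(e < 0 for e in effects):
            raise ValueError(
                "selection_effect_by_decile needs exactly 10 entries >= 0")
        object.__setattr__(self, "selection_effect_by_decile", effects)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


@dataclass
class TruthTable:
    """Ground truth for everything planted by the generators."""
    rdhs_truth: dict[str, str] = field(default_factory=dict)  # id -> active|inactive
    motif_truth: list[dict] = field(default_factory=list)
    variant_truth: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def default_ctcf_pfm(total: int = 1000) -> PositionFrequencyMatrix:
    """A synthetic 19-bp CTCF-like PFM: high-information GC-rich core,
    degenerate edges, heterogeneous columns.

    Constructed, not downloaded.  Real binding-site count matrices are
    heterogeneous in two ways that matter for allelic scoring: column
    information content varies along the motif, and the three non-consensus
    bases of a column are unequally tolerated.  Both features are built in
    (varying consensus fractions; rotating uneven minor-base splits), so
    score changes take many distinct values instead of collapsing onto a few
    shared atoms.
    """
    consensus = "CCACCAGGTGGCAGCACCT"
    fractions = [0.55, 0.70, 0.80, 0.88, 0.95, 0.85, 0.92, 0.75, 0.62, 0.90,
                 0.96, 0.82, 0.88, 0.93, 0.78, 0.85, 0.72, 0.65, 0.55]
    minor_splits = [(0.58, 0.30, 0.12), (0.45, 0.35, 0.20),
                    (0.62, 0.24, 0.14), (0.50, 0.32, 0.18)]
    counts = np.zeros((4, len(consensus)), dtype=float)
    for j, (base, f) in enumerate(zip(consensus, fractions)):
        b = "ACGT".index(base)
        rest = total - round(total * f)
        split = minor_splits[j % len(minor_splits)]
        minors = [i for i in range(4) if i != b]
        for k, m in enumerate(minors):
            counts[m, j] = max(round(rest * split[k]), 1)
        counts[b, j] = total - counts[minors, j].sum()
    return PositionFrequencyMatrix(motif_id="SYN_CTCF", counts=counts)


# ---------------------------------------------------------------------------
# Genome, rDHSs, motifs
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random genome of ``n_chromosomes`` sequences with the configured GC."""
    if config.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    rng = _rng(config, _STREAM_GENOME)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return {
        f"chr{i + 1}": _seq.decode(
            rng.choice(4, size=config.genome_length, p=probs))
        for i in range(config.n_chromosomes)
    }


def simulate_rdhs_intervals(config: SimulationConfig) -> list[GenomicInterval]:
    """Non-overlapping rDHS intervals laid out on a jittered grid."""
    if config.n_rdhs < 1:
        raise ValueError("need at least one rDHS")
    rng = _rng(config, _STREAM_RDHS)
    per_chrom = [config.n_rdhs // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_rdhs % config.n_chromosomes):
        per_chrom[i] += 1
    out: list[GenomicInterval] = []
    idx = 0
    for c, count in enumerate(per_chrom):
        if count == 0:
            continue
        spacing = config.genome_length / count
        if spacing < config.rdhs_length + 2:
            raise ValueError("genome too short for the requested rDHS density")
        for k in range(count):
            slack = int(spacing) - config.rdhs_length - 1
            start = int(k * spacing) + int(rng.integers(0, max(slack, 1)))
            out.append(GenomicInterval(
                f"chr{c + 1}", start, start + config.rdhs_length,
                name=f"rDHS{idx:06d}"))
            idx += 1
    return out


def assign_rdhs_truth(rdhs: Sequence[GenomicInterval],
                      config: SimulationConfig) -> dict[str, str]:
    rng = _rng(config, _STREAM_RDHS + 100)
    active = rng.random(len(rdhs)) < config.frac_active_rdhs
    return {iv.name: ("active" if a else "inactive")
            for iv, a in zip(rdhs, active)}


def plant_motifs(
    genome: Mapping[str, str],
    pfm: PositionFrequencyMatrix,
    config: SimulationConfig,
    within: Sequence[GenomicInterval] | None = None,
    host_truth: Mapping[str, str] | None = None,
    max_retries: int = 200,
) -> tuple[GenomeIndex, list[dict]]:
    """Overwrite non-overlapping genomic intervals with motif instances.

    Each instance is drawn per-position: the consensus base with probability
    ``motif_planting_fidelity``, otherwise one of the other three bases
    uniformly; minus-strand instances (strand chosen uniformly) are written
    as the reverse complement.  When ``within`` intervals are supplied, a
    fraction ``frac_motifs_in_rdhs`` of instances is placed inside them (at
    most one per interval) and the rest anywhere.  When ``host_truth`` marks
    a host interval active, planting fidelity is raised by
    ``fidelity_active_boost`` — active loci carry better motifs, the
    affinity-activity coupling the annotation is meant to recover.  Truth
    entries use BED convention and record the containing interval's name
    when applicable.
    """
    L = pfm.length
    if config.genome_length < 10 * L:
        raise ValueError("genome_length must be >= 10 x motif length")
    codes = {c: _seq.encode(s).copy() for c, s in genome.items()}
    rng = _rng(config, _STREAM_MOTIFS)
    n = config.n_motif_instances
    truth: list[dict] = []
    if n == 0:
        return GenomeIndex.from_codes(codes), truth

    consensus_idx = np.argmax(pfm.counts, axis=0)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in codes}

    def overlaps_any(chrom: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in occupied[chrom])

    n_inside = int(round(n * config.frac_motifs_in_rdhs)) if within else 0
    host_pool = []
    if within:
        eligible = [iv for iv in within if len(iv) >= L]
        order = rng.permutation(len(eligible))
        host_pool = [eligible[i] for i in order[:n_inside]]
        if len(host_pool) < n_inside:
            n_inside = len(host_pool)

    placements: list[tuple[str, int, str | None]] = []  # chrom, start, host name
    for host in host_pool:
        for _ in range(max_retries):
            start = host.start + int(rng.integers(0, len(host) - L + 1))
            if not overlaps_any(host.chrom, start, start + L):
                occupied[host.chrom].append((start, start + L))
                placements.append((host.chrom, start, host.name))
                break
        else:
            raise RuntimeError("could not place a non-overlapping motif "
                               f"inside {host.name} after {max_retries} tries")
    chrom_names = list(codes)
    for _ in range(n - len(placements)):
        for _ in range(max_retries):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = int(rng.integers(0, len(codes[chrom]) - L + 1))
            if not overlaps_any(chrom, start, start + L):
                occupied[chrom].append((start, start + L))
                placements.append((chrom, start, None))
                break
        else:
            raise RuntimeError(
                f"could not place {n} non-overlapping motifs after "
                f"{max_retries} retries each")

    for chrom, start, host_name in placements:
        fidelity = config.motif_planting_fidelity
        if (host_truth is not None and host_name is not None
                and host_truth.get(host_name) == "active"):
            fidelity = min(1.0, fidelity + config.fidelity_active_boost)
        keep = rng.random(L) < fidelity
        shift = rng.integers(1, 4, size=L)
        bases = np.where(keep, consensus_idx,
                         (consensus_idx + shift) % 4).astype(np.uint8)
        strand = "+" if rng.random() < 0.5 else "-"
        written = bases if strand == "+" else _seq.revcomp_codes(bases)
        codes[chrom][start:start + L] = written
        truth.append({
            "chrom": chrom, "start": int(start), "end": int(start + L),
            "strand": strand, "planted": True, "rdhs_id": host_name,
        })
    return GenomeIndex.from_codes(codes), truth


# ---------------------------------------------------------------------------
# Activity matrix
# ---------------------------------------------------------------------------

def simulate_activity_matrix(
    rdhs_intervals: Sequence[GenomicInterval],
    truth: TruthTable,
    config: SimulationConfig,
) -> BindingActivityMatrix:
    """Z-score matrix with planted active loci.

    Active rDHSs are unmasked in (1 - mask_rate_active) of biosamples with
    Z ~ Normal(z_active_mean, z_active_sd); inactive rDHSs are mostly masked,
    their unmasked entries ~ Normal(0, 1).  Masked entries hold the -10
    sentinel.
    """
    if not rdhs_intervals:
        raise ValueError("empty rDHS set")
    if config.n_biosamples < 2:
        raise ValueError("need at least 2 biosamples")
    rng = _rng(config, _STREAM_MATRIX)
    n, m = len(rdhs_intervals), config.n_biosamples
    active = np.array([truth.rdhs_truth[iv.name] == "active"
                       for iv in rdhs_intervals])
    mask_rate = np.where(active, config.mask_rate_active,
                         config.mask_rate_inactive)
    masked = rng.random((n, m)) < mask_rate[:, None]
    z = rng.normal(0.0, 1.0, size=(n, m))
    z[active] = rng.normal(config.z_active_mean, config.z_active_sd,
                           size=(int(active.sum()), m))
    z[masked] = -10.0
    df = pd.DataFrame(z, index=[iv.name for iv in rdhs_intervals],
                      columns=[f"B{j:03d}" for j in range(m)])
    return mask_zero_signal(df)


# ---------------------------------------------------------------------------
# Mutation rates and variants
# ---------------------------------------------------------------------------

def simulate_mutation_rate_table(config: SimulationConfig) -> pd.DataFrame:
    """Relative mutation rates for all 64 x 3 (context, alt) combinations.

    Rates are lognormal around 1 with CpG transitions boosted several-fold,
    echoing the dominant feature of real trinucleotide rate tables.
    """
    rng = _rng(config, _STREAM_RATES)
    rows = []
    for c1 in "ACGT":
        for ref in "ACGT":
            for c3 in "ACGT":
                context = c1 + ref + c3
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    mu = float(rng.lognormal(mean=0.0, sigma=0.4))
                    is_cpg_ts = (
                        (ref == "C" and c3 == "G" and alt == "T")
                        or (ref == "G" and c1 == "C" and alt == "A"))
                    if is_cpg_ts:
                        mu *= 6.0
                    rows.append({"context": context, "ref": ref,
                                 "alt": alt, "mu": mu})
    return pd.DataFrame(rows)


def _decile_of(hit: MotifHit) -> int | None:
    if hit.quantile is None:
        return None
    return (hit.quantile + 9) // 10


def simulate_variants(
    cbs_catalog: Sequence[MotifHit],
    mutation_rate_table: pd.DataFrame,
    config: SimulationConfig,
    genome: GenomeIndex,
    pwm: PositionWeightMatrix,
) -> tuple[pd.DataFrame, dict[str, dict], int]:
    """SNVs inside CBS motifs plus a control set outside them.

    Each variant's singleton indicator is drawn with probability
    p = singleton_base_rate + mutation_rate_slope * (mu - mean mu)
      + selection_effect_by_decile[d - 1]   (loss-of-binding CBS variants),
    clipped to [0, 1].  Loss/gain is determined with the same deterministic
    allelic scorer used downstream.  Controls carry the calibration-class
    consequence ("synonymous_variant") or a neutral held-out label.
    Returns (variant table, truth entries, number of clipped probabilities).
    """
    from .allelic import score_pairs_table
    from .maps import validate_rate_table

    rng = _rng(config, _STREAM_VARIANTS)
    rates = validate_rate_table(mutation_rate_table)
    if config.n_variants > 0 and not cbs_catalog:
        raise ValueError("empty CBS catalog")

    rows: list[dict] = []
    if config.n_variants > 0:
        midx = rng.integers(0, len(cbs_catalog), size=config.n_variants)
        for i in midx:
            hit = cbs_catalog[i]
            pos0 = hit.start + int(rng.integers(0, hit.end - hit.start))
            # keep the full scoring window inside the contig so every motif
            # variant is scorable downstream
            margin = max(1, config.flank)
            if pos0 < margin or pos0 + margin + 1 > genome.length(hit.chrom):
                continue
            ref = genome.base(hit.chrom, pos0)
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            rows.append({
                "chrom": hit.chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
                "consequence": "cbs_variant", "decile": _decile_of(hit),
                "in_motif": True,
            })

    # control set outside any motif
    if config.n_control_variants > 0:
        from intervaltree import IntervalTree

        motif_trees: dict[str, IntervalTree] = {}
        for hit in cbs_catalog:
            motif_trees.setdefault(hit.chrom, IntervalTree()).addi(
                hit.start, hit.end)
        contigs = genome.contigs
        placed = 0
        attempts = 0
        while placed < config.n_control_variants:
            attempts += 1
            if attempts > 50 * config.n_control_variants:
                raise RuntimeError("could not place control variants outside "
                                   "motifs; genome too dense")
            chrom = contigs[int(rng.integers(0, len(contigs)))]
            pos0 = int(rng.integers(1, genome.length(chrom) - 1))
            tree = motif_trees.get(chrom)
            if tree is not None and tree.overlaps(pos0):
                continue
            ref = genome.base(chrom, pos0)
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            synonymous = rng.random() < config.frac_controls_synonymous
            rows.append({
                "chrom": chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
                "consequence": ("synonymous_variant" if synonymous
                                else "intergenic_variant"),
                "decile": None, "in_motif": False,
            })
            placed += 1

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "consequence", "decile", "in_motif"])
    df = df.drop_duplicates(["chrom", "pos", "alt"]).reset_index(drop=True)
    if df.empty:
        from .io import VARIANT_COLUMNS
        empty = pd.DataFrame(columns=VARIANT_COLUMNS + ["context3"])
        return empty, {}, 0

    # trinucleotide context and mutation rate
    ctx = []
    for rec in df.itertuples(index=False):
        pos0 = rec.pos - 1
        ctx.append(genome.fetch(rec.chrom, pos0 - 1, pos0 + 2))
    df["context3"] = ctx
    merged = df.merge(
        rates.rename(columns={"context": "context3"})[["context3", "alt", "mu"]],
        on=["context3", "alt"], how="left")
    if merged["mu"].isna().any():
        raise ValueError("mutation-rate table does not cover every context")
    mu = merged["mu"].to_numpy()

    # loss/gain classification for planted selection (same scorer as pipeline)
    in_motif = df["in_motif"].to_numpy()
    is_loss = np.zeros(len(df), dtype=bool)
    if in_motif.any():
        scored = score_pairs_table(df.loc[in_motif, ["chrom", "pos", "ref", "alt"]]
                                   .reset_index(drop=True),
                                   genome, pwm, flank=config.flank)
        # row order is preserved and no rows can drop: the placement loop
        # keeps every motif variant's scoring window inside its contig
        assert len(scored) == int(in_motif.sum())
        is_loss[np.flatnonzero(in_motif)] = (
            scored["binding_class"].to_numpy() == "loss")

    effects = np.zeros(len(df))
    decile = df["decile"].to_numpy()
    effect_table = np.asarray(config.selection_effect_by_decile)
    has_decile = in_motif & is_loss & pd.notna(decile)
    effects[has_decile] = effect_table[
        decile[has_decile].astype(int) - 1]

    p_raw = (config.singleton_base_rate
             + config.mutation_rate_slope * (mu - mu.mean()) + effects)
    p = np.clip(p_raw, 0.0, 1.0)
    n_clipped = int((p_raw != p).sum())

    singleton = rng.random(len(df)) < p
    ac = np.where(singleton, 1, 2 + rng.geometric(0.3, size=len(df)) - 1)
    an = config.an_total
    fail = rng.random(len(df)) < config.fail_filter_rate

    cadd = rng.normal(config.cadd_neutral_mean, config.cadd_sd, size=len(df))
    loss_scale = np.where(has_decile, decile, 0).astype(float) / 10.0
    cadd = cadd + np.where(is_loss, config.cadd_loss_shift * loss_scale, 0.0)

    out = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"], "ref": df["ref"],
        "alt": df["alt"], "AC": ac.astype(np.int64), "AN": np.int64(an),
        "AF": ac / an, "filter": np.where(fail, "LowQual", "PASS"),
        "consequence": df["consequence"], "cadd_phred": cadd,
        "context3": df["context3"],
    })
    truth = {}
    for i, rec in enumerate(out.itertuples(index=False)):
        vid = f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}"
        truth[vid] = {
            "selection_effect": float(effects[i]),
            "p_singleton": float(p[i]),
            "in_motif": bool(in_motif[i]),
            "is_loss": bool(is_loss[i]),
        }
    return out, truth, n_clipped


# ---------------------------------------------------------------------------
# Conservation and exclusion tracks
# ---------------------------------------------------------------------------

def simulate_conservation_track(
    genome: GenomeIndex, truth: TruthTable, config: SimulationConfig,
) -> dict[str, np.ndarray]:
    """Per-base scores ~ Normal(0, sd), shifted upward by
    ``conservation_effect`` inside planted motifs whose host rDHS is active."""
    rng = _rng(config, _STREAM_CONSERVATION)
    tracks = {c: rng.normal(0.0, config.conservation_sd,
                            size=genome.length(c))
              for c in genome.contigs}
    for entry in truth.motif_truth:
        host = entry.get("rdhs_id")
        if host is None or truth.rdhs_truth.get(host) != "active":
            continue
        tracks[entry["chrom"]][entry["start"]:entry["end"]] += \
            config.conservation_effect
    return tracks


def simulate_exclusion_tracks(
    config: SimulationConfig,
) -> dict[str, list[GenomicInterval]]:
    """Small random gap / blacklist / coding-exon tracks on the autosomes."""
    rng = _rng(config, _STREAM_EXCLUSIONS)
    tracks: dict[str, list[GenomicInterval]] = {}
    track_defs = [("gaps", config.n_gap_intervals, config.gap_length),
            ("blacklist", config.n_blacklist_intervals, config.blacklist_length),
            ("coding_exons", config.n_exon_intervals, config.exon_length)]
    for name, count, length in track_defs:
        ivs = []
        for _ in range(count):
            chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
            start = int(rng.integers(0, max(config.genome_length - length, 1)))
            ivs.append(GenomicInterval(chrom, start, start + length))
        tracks[name] = ivs
    return tracks
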