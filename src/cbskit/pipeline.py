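"""End-to-end pipeline: simulate inputs, annotate activity, build the CBS
catalog, score allelic binding changes, and evaluate constraint with MAPS.

The stages mirror the CLI subcommands and can be re-run individually; this
module wires them together for the ``run-all`` entry point and records the
headline statistics (activity/affinity/conservation correlations and the
MAPS-by-decile relationship for confident loss-of-binding variants).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import yaml

from . import activity as act
from . import allelic, maps, motifs, simulate, stats
from .io import GenomeIndex, dataclass_from_dict

log = logging.getLogger("cbskit")

CONSERVATION_THRESHOLD = 1.0  # per-base conservation cutoff (phyloP-like)
CADD_PATHOGENIC = 10.0


@dataclass
class PipelineConfig:
    """Resolved settings for a full run; mirrors every CLI flag."""
    sim: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    activity_method: str = "paper_mean"
    n_quantile_bins: int = 100
    z_threshold: float = act.DEFAULT_BOUND_Z
    scan_threshold: float = 0.8
    flank: int = allelic.DEFAULT_FLANK
    alpha: float = allelic.DEFAULT_ALPHA
    dummy_floor: float = allelic.DEFAULT_DUMMY_FLOOR
    min_AN: int = allelic.DEFAULT_MIN_AN
    n_null_samples: int = 200_000
    min_stratum_n: int = 100
    bootstrap_B: int = 2000
    bootstrap_iterations: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim_data = data.pop("sim", {})
        cfg = dataclass_from_dict(cls, {**data, "sim": None}, where=str(path))
        cfg.sim = dataclass_from_dict(simulate.SimulationConfig, sim_data,
                                      where=f"{path}:sim")
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_run_config(seed: int = 0) -> PipelineConfig:
    """The seeded study conditions for an end-to-end run: a monotone planted
    selection effect on loss-of-binding variants across activity deciles."""
    sim = simulate.SimulationConfig(
        seed=seed,
        selection_effect_by_decile=tuple(0.01 * d for d in range(10)),
    )
    return PipelineConfig(sim=sim)


@dataclass
class PipelineResult:
    config: PipelineConfig
    rdhs_records: list
    truth: simulate.TruthTable
    cbs_catalog: list
    n_motif_matches: int
    motif_filter_tallies: dict
    variants: pd.DataFrame
    variant_qc: dict
    scored: pd.DataFrame  # deduped per-variant allelic scores
    calibration: maps.CalibrationModel
    maps_by_stratum: pd.DataFrame
    maps_neutral: maps.MAPSResult
    maps_calibration_self: maps.MAPSResult
    headline: dict


def _deciles_from_quantiles(q: pd.Series) -> pd.Series:
    return ((q + 9) // 10).astype("Int64")


def run_all(config: PipelineConfig) -> PipelineResult:
    sim = config.sim
    log.info("run_all: seed=%d", sim.seed)

    # --- simulate genome, loci, planted motifs -----------------------------
    genome_seqs = simulate.simulate_genome(sim)
    rdhs_ivs = simulate.simulate_rdhs_intervals(sim)
    truth = simulate.TruthTable()
    truth.rdhs_truth = simulate.assign_rdhs_truth(rdhs_ivs, sim)
    pfm = simulate.default_ctcf_pfm()
    pwm = motifs.pfm_to_pwm(pfm)
    genome, truth.motif_truth = simulate.plant_motifs(
        genome_seqs, pfm, sim, within=rdhs_ivs, host_truth=truth.rdhs_truth)

    # --- binding activity ---------------------------------------------------
    matrix = simulate.simulate_activity_matrix(rdhs_ivs, truth, sim)
    scores = act.summarize_activity(matrix, method=config.activity_method)
    quantiles = act.assign_activity_quantiles(scores, k=config.n_quantile_bins)
    n_unmasked = dict(zip(matrix.rdhs_ids, matrix.n_unmasked))
    rdhs_records = act.build_rdhs_records(rdhs_ivs, scores, quantiles,
                                          n_unmasked)

    # --- CBS catalog --------------------------------------------------------
    exclusions = simulate.simulate_exclusion_tracks(sim)
    hits = motifs.scan_genome(genome, pwm, config.scan_threshold)
    filt = motifs.filter_motifs(hits, autosomes=genome.contigs,
                                exclusions=exclusions)
    cbs = act.annotate_motifs_with_activity(filt.kept, rdhs_records)
    log.info("CBS catalog: %d scanned, %d after exclusion, %d with activity",
             len(hits), len(filt.kept), len(cbs))

    # --- variants -----------------------------------------------------------
    rates = simulate.simulate_mutation_rate_table(sim)
    variants, truth.variant_truth, _ = simulate.simulate_variants(
        cbs, rates, sim, genome, pwm)
    qc = allelic.filter_variants(variants, min_AN=config.min_AN)

    # --- allelic scoring ----------------------------------------------------
    pairs = allelic.intersect_variants_with_cbs(qc.kept, cbs)
    scored = allelic.score_pairs_table(pairs, genome, pwm, flank=config.flank)
    null = allelic.ImportanceSamplingNull(
        pwm, allelic.BackgroundModel(), config.flank,
        n_samples=config.n_null_samples,
        seed=(sim.seed * 1000003 + 17) & 0x7FFFFFFF)
    pvals, _ = _null_pvalues(null, scored["delta_pwm"].to_numpy())
    scored["p_value"] = [
        allelic.encode_truncated_pvalues(p, config.dummy_floor) for p in pvals]
    scored["neglog10_rank"] = -np.log10(scored["p_value"])
    scored["confident"] = scored["p_value"] < config.alpha
    scored = allelic.dedupe_per_variant(scored)
    scored["decile"] = _deciles_from_quantiles(scored["quantile"])

    # --- MAPS ---------------------------------------------------------------
    controls = qc.kept[qc.kept["consequence"].isin(
        ["synonymous_variant", "intergenic_variant"])]
    calib = controls[controls["consequence"] == "synonymous_variant"]
    neutral = controls[controls["consequence"] == "intergenic_variant"]
    model = maps.calibrate(calib, rates)
    maps_table = maps.maps_by_stratum(
        scored, ["binding_class", "confident", "decile"], model, rates,
        min_stratum_n=config.min_stratum_n)
    maps_neutral = maps.maps_score(neutral, model, rates,
                                   class_label="intergenic_variant")
    maps_self = maps.maps_score(calib, model, rates,
                                class_label="synonymous_variant")

    # --- headline statistics ------------------------------------------------
    headline = _headline_stats(config, genome, truth, rdhs_records, cbs,
                               scored, maps_table, maps_neutral, maps_self)
    return PipelineResult(
        config=config, rdhs_records=rdhs_records, truth=truth,
        cbs_catalog=cbs, n_motif_matches=len(filt.kept),
        motif_filter_tallies=filt.tallies, variants=variants,
        variant_qc=qc.removed, scored=scored, calibration=model,
        maps_by_stratum=maps_table, maps_neutral=maps_neutral,
        maps_calibration_self=maps_self, headline=headline,
    )


def _null_pvalues(null: allelic.ImportanceSamplingNull, deltas: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-sided tails for many observed deltas against one null."""
    order = np.argsort(null.deltas)
    d_sorted = null.deltas[order]
    w_sorted = null.weights[order]
    cum = np.cumsum(w_sorted)
    total = cum[-1]
    n = null.n
    deltas = np.asarray(deltas, dtype=float)
    p = np.empty(len(deltas))
    pos = deltas > 0
    idx_ge = np.searchsorted(d_sorted, deltas[pos] - 1e-9, side="left")
    below = np.where(idx_ge > 0, cum[np.clip(idx_ge - 1, 0, None)], 0.0)
    p[pos] = (total - below) / n
    idx_le = np.searchsorted(d_sorted, deltas[~pos] + 1e-9, side="right")
    p[~pos] = np.where(idx_le > 0, cum[np.clip(idx_le - 1, 0, None)], 0.0) / n
    return p, np.zeros_like(p)


def _headline_stats(config, genome, truth, rdhs_records, cbs, scored,
                    maps_table, maps_neutral, maps_self) -> dict:
    out: dict[str, float] = {}
    seed = config.sim.seed

    # MAPS vs activity decile for confident loss-of-binding variants
    sel = maps_table[(maps_table["binding_class"] == "loss")
                     & (maps_table["confident"])
                     & maps_table["decile"].notna()]
    if len(sel) >= 3:
        r, p = stats.correlate(sel["decile"].astype(float), sel["maps"],
                               "pearson")
        out["pearson_r_maps_vs_decile_loss_confident"] = r
        out["pearson_p_maps_vs_decile_loss_confident"] = p
        top = sel[sel["decile"] == 10]
        if len(top):
            out["maps_loss_confident_decile10"] = float(top["maps"].iloc[0])
    out["maps_neutral_control"] = maps_neutral.maps
    out["maps_calibration_self"] = maps_self.maps

    # relative PWM score vs activity quantile
    by_q: dict[int, list[float]] = {}
    for hit in cbs:
        if hit.quantile is not None:
            by_q.setdefault(hit.quantile, []).append(hit.relative_score)
    qs = stats.per_quantile_mean(by_q, statistic_name="mean_relative_pwm")
    if len(qs) >= 3:
        r, p = stats.correlate([s.quantile for s in qs],
                               [s.statistic for s in qs], "pearson")
        out["pearson_r_relative_pwm_vs_quantile"] = r

    # conservation vs activity quantile
    track = simulate.simulate_conservation_track(genome, truth, config.sim)
    cons_by_q: dict[int, np.ndarray] = {}
    for hit in cbs:
        if hit.quantile is None:
            continue
        vals = track[hit.chrom][hit.start:hit.end]
        cons_by_q.setdefault(hit.quantile, []).append(vals)
    props = {}
    for q, chunks in cons_by_q.items():
        vals = np.concatenate(chunks)
        props[q] = stats.proportion_above(vals, CONSERVATION_THRESHOLD)
    if len(props) >= 3:
        qs_sorted = sorted(props)
        r, p = stats.correlate(qs_sorted, [props[q] for q in qs_sorted],
                               "pearson")
        out["pearson_r_conserved_vs_quantile"] = r
        rs, ps = stats.correlate(qs_sorted, [props[q] for q in qs_sorted],
                                 "spearman")
        out["spearman_r_conserved_vs_quantile"] = rs

    # CADD-based pathogenic proportion for confident loss variants by decile
    conf_loss = scored[(scored["binding_class"] == "loss") & scored["confident"]
                       & scored["decile"].notna()]
    if len(conf_loss):
        by_d = {int(d): g["cadd_phred"].to_numpy()
                for d, g in conf_loss.groupby("decile")}
        summ = stats.per_quantile_proportion(
            by_d, CADD_PATHOGENIC, B=config.bootstrap_B,
            iterations=config.bootstrap_iterations, seed=seed + 7,
            statistic_name="prop_cadd_ge_10")
        if len(summ) >= 3:
            r, p = stats.correlate([s.quantile for s in summ],
                                   [s.statistic for s in summ], "pearson")
            out["pearson_r_cadd_pathogenic_vs_decile_loss_confident"] = r

    out["n_motif_matches"] = len(cbs)
    out["n_candidate_snvs"] = int(scored["variant_id"].nunique())
    out["frac_loss_of_binding"] = float(
        (scored["binding_class"] == "loss").mean()) if len(scored) else np.nan
    out["frac_confident_loss"] = float(
        (scored.loc[scored["binding_class"] == "loss", "confident"]).mean()
    ) if len(scored) else np.nan
    return out


def write_outputs(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "resolved_config.yaml")
    act.write_rdhs_summary(result.rdhs_records, outdir / "rdhs_activity.tsv")
    motifs.write_motif_bed(result.cbs_catalog, outdir / "cbs_catalog.bed")
    from .io import write_variants_tsv

    write_variants_tsv(result.variants, outdir / "variants.tsv")
    result.scored.to_csv(outdir / "allelic_scores.tsv", sep="\t", index=False)
    maps.write_maps_tsv(result.maps_by_stratum, outdir / "maps_by_stratum.tsv")
    result.truth.to_json(outdir / "truth.json")
    with open(outdir / "headline.json", "w") as fh:
        json.dump(result.headline, fh, indent=2)
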