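"""Mutability-adjusted proportion of singletons (MAPS).

The raw singleton proportion of a variant class (singleton: allele count
AC = 1) confounds selection with mutability: transition-rich, CpG-heavy
classes accumulate recurrent mutations and look common for reasons that have
nothing to do with fitness.  MAPS removes that confound by calibrating the
expected singleton proportion as a function of the trinucleotide mutation
rate on a presumed-neutral class (synonymous variants) and reporting

    MAPS = observed singleton proportion - expected singleton proportion.

Positive MAPS indicates an excess of singletons over the mutability
expectation, i.e. negative selection.  The calibration is a weighted least
squares of per-(context, alt) singleton proportions on the relative mutation
rate, with per-group variant counts as weights; by WLS orthogonality the
calibration class scores exactly zero against its own model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataIntegrityError, GenomeIndex

log = logging.getLogger("cbskit")

CALIBRATION_CLASS = "synonymous_variant"

RATE_COLUMNS = ["context", "ref", "alt", "mu"]


def validate_rate_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Check the trinucleotide mutation-rate table contract.

    Columns: context (3-mer), ref (= middle base of context), alt, mu > 0;
    (context, alt) unique.  Duplicated rows (identical key and rate) are
    tolerated and collapsed, so merges stay keyed rather than positional.
    """
    missing = [c for c in RATE_COLUMNS if c not in rates.columns]
    if missing:
        raise DataIntegrityError(f"rate table missing columns {missing}")
    df = rates[RATE_COLUMNS].drop_duplicates().reset_index(drop=True)
    if df.duplicated(["context", "alt"]).any():
        raise DataIntegrityError("conflicting rates for the same (context, alt)")
    if not (df["context"].str.len() == 3).all():
        raise DataIntegrityError("contexts must be trinucleotides")
    if not (df["context"].str[1] == df["ref"]).all():
        raise DataIntegrityError("ref must equal the middle base of context")
    if (df["ref"] == df["alt"]).any():
        raise DataIntegrityError("ref and alt must differ")
    if (df["mu"] <= 0).any():
        raise DataIntegrityError("mutation rates must be positive")
    return df


def annotate_context(variants: pd.DataFrame, genome: GenomeIndex
                     ) -> tuple[pd.DataFrame, int]:
    """Attach the plus-strand trinucleotide context (base before, ref, base
    after) to each variant.

    Contexts are literal plus-strand 3-mers; no collapsing to
    pyrimidine-centered contexts.  Variants at contig edges cannot be
    annotated and are excluded with a log entry; a REF allele disagreeing
    with the genome is a hard error.
    """
    contexts: list[str | None] = []
    n_edge = 0
    for rec in variants.itertuples(index=False):
        pos0 = int(rec.pos) - 1
        if pos0 - 1 < 0 or pos0 + 2 > genome.length(rec.chrom):
            contexts.append(None)
            n_edge += 1
            continue
        tri = genome.fetch(rec.chrom, pos0 - 1, pos0 + 2)
        if tri[1] != rec.ref:
            raise DataIntegrityError(
                f"REF mismatch at {rec.chrom}:{rec.pos}: genome has {tri[1]}")
        contexts.append(tri)
    out = variants.copy()
    out["context3"] = contexts
    if n_edge:
        log.info("annotate_context: excluded %d contig-edge variants", n_edge)
        out = out.loc[out["context3"].notna()].reset_index(drop=True)
    return out, n_edge


@dataclass
class CalibrationModel:
    """Linear singleton-proportion model: E[singleton] = intercept + slope * mu."""
    intercept: float
    slope: float
    fitted_on: str
    n_contexts: int
    weights: Mapping[str, int] | None = None

    def predict(self, mu: np.ndarray) -> np.ndarray:
        """Per-variant singleton probability, clipped to [0, 1]."""
        return np.clip(self.intercept + self.slope * np.asarray(mu, float), 0.0, 1.0)


def _merge_mu(variants: pd.DataFrame, rates: pd.DataFrame) -> pd.DataFrame:
    rates = validate_rate_table(rates)
    if "context3" not in variants.columns or variants["context3"].isna().any():
        raise DataIntegrityError("variants must carry annotated trinucleotide "
                                 "contexts (run annotate_context first)")
    merged = variants.merge(
        rates.rename(columns={"context": "context3"})[["context3", "alt", "mu"]],
        on=["context3", "alt"], how="left",
    )
    if merged["mu"].isna().any():
        absent = sorted(
            merged.loc[merged["mu"].isna(), ["context3", "alt"]]
            .drop_duplicates().itertuples(index=False, name=None))
        raise DataIntegrityError(
            f"rate table missing (context, alt) combinations: {absent[:10]}"
            + ("..." if len(absent) > 10 else ""))
    return merged


def calibrate(calibration_variants: pd.DataFrame, rates: pd.DataFrame,
              class_label: str = CALIBRATION_CLASS) -> CalibrationModel:
    """Fit the singleton-proportion ~ mutation-rate calibration by WLS.

    Variants are grouped by (context, alt); each group contributes its
    singleton proportion, weighted by its variant count.
    """
    import statsmodels.api as sm

    merged = _merge_mu(calibration_variants, rates)
    if merged.empty:
        raise DataIntegrityError("empty calibration set")
    merged["singleton"] = merged["AC"] == 1
    groups = (merged.groupby(["context3", "alt"], sort=True)
              .agg(mu=("mu", "first"), prop=("singleton", "mean"),
                   n=("singleton", "size")).reset_index())
    if groups["mu"].nunique() < 2:
        raise DataIntegrityError(
            "calibration requires >= 2 distinct mutation rates")
    X = sm.add_constant(groups["mu"].to_numpy())
    fit = sm.WLS(groups["prop"].to_numpy(), X,
                 weights=groups["n"].to_numpy()).fit()
    return CalibrationModel(
        intercept=float(fit.params[0]), slope=float(fit.params[1]),
        fitted_on=class_label, n_contexts=len(groups),
        weights={f"{c}>{a}": int(n) for c, a, n in
                 zip(groups["context3"], groups["alt"], groups["n"])},
    )


@dataclass
class ExpectedSingletons:
    expected: float
    n: int
    n_clipped: int
    mean_mu: float


def expected_singletons(class_variants: pd.DataFrame, model: CalibrationModel,
                        rates: pd.DataFrame) -> ExpectedSingletons:
    """Expected singleton count: sum over variants of the clipped prediction.

    Because the model is linear this equals n * (intercept + slope * mean mu)
    whenever no clipping occurs; the identity is asserted in that case.
    """
    merged = _merge_mu(class_variants, rates)
    mu = merged["mu"].to_numpy()
    raw_pred = model.intercept + model.slope * mu
    clipped = np.clip(raw_pred, 0.0, 1.0)
    n_clipped = int((raw_pred != clipped).sum())
    expected = float(clipped.sum())
    if n_clipped == 0 and len(mu):
        at_mean = len(mu) * (model.intercept + model.slope * mu.mean())
        assert abs(expected - at_mean) < 1e-6 * max(1.0, abs(expected)), \
            "linear-model identity violated"
    if n_clipped:
        log.info("expected_singletons: %d predictions clipped to [0, 1]",
                 n_clipped)
    return ExpectedSingletons(expected=expected, n=len(mu),
                              n_clipped=n_clipped, mean_mu=float(mu.mean()))


@dataclass
class MAPSResult:
    class_label: str
    n_variants: int
    n_singletons: int
    raw_proportion: float
    expected_proportion: float
    maps: float
    sem: float
    wide_uncertainty: bool = False


def maps_score(class_variants: pd.DataFrame, model: CalibrationModel,
               rates: pd.DataFrame, class_label: str = "") -> MAPSResult:
    """MAPS = raw singleton proportion - expected proportion, with its SEM."""
    n = len(class_variants)
    if n < 1:
        raise DataIntegrityError("cannot score an empty variant class")
    singletons = int((class_variants["AC"] == 1).sum())
    raw = singletons / n
    exp = expected_singletons(class_variants, model, rates)
    expected_prop = exp.expected / n
    sem = float(np.sqrt(raw * (1.0 - raw) / n))
    return MAPSResult(
        class_label=class_label, n_variants=n, n_singletons=singletons,
        raw_proportion=raw, expected_proportion=expected_prop,
        maps=raw - expected_prop, sem=sem,
    )


def maps_by_stratum(
    scored: pd.DataFrame, strata: Sequence[str], model: CalibrationModel,
    rates: pd.DataFrame, min_stratum_n: int = 100,
) -> pd.DataFrame:
    """One MAPS result per non-empty stratum of a scored-variant table.

    ``strata`` names grouping columns (e.g. binding_class, confident, decile,
    or a consequence label).  Strata below ``min_stratum_n`` variants are kept
    but flagged wide-uncertainty rather than dropped.
    """
    for col in strata:
        if col not in scored.columns:
            raise DataIntegrityError(f"stratum column {col!r} missing")
    rows = []
    for key, group in scored.groupby(list(strata), sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        res = maps_score(group, model, rates,
                         class_label="/".join(str(k) for k in key))
        res.wide_uncertainty = res.n_variants < min_stratum_n
        row = dict(zip(strata, key))
        row.update(res.__dict__)
        rows.append(row)
    return pd.DataFrame(rows)


def write_maps_tsv(results: pd.DataFrame | Sequence[MAPSResult], path) -> None:
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([r.__dict__ for r in results])
    results.to_csv(path, sep="\t", index=False)
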