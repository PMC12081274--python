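# cbskit

Prioritization of CTCF binding-site (CBS) variants from population
sequencing data.

CTCF organizes the 3D genome by binding a ~19-bp DNA motif at hundreds of
thousands of loci; single-nucleotide variants that disrupt these sites are an
important but hard-to-prioritize class of noncoding variation.  `cbskit`
implements a hypothesis-driven framework for that prioritization and a
synthetic-data generator that emulates every input with known ground truth,
so the whole pipeline is testable end to end without external downloads.

The framework has four parts:

1. **Binding activity.**  Cross-biosample ChIP-seq Z-scores at each
   regulatory locus (rDHS) are masked at zero-signal entries (sentinel −10)
   and collapsed to a single activity score, Σzᵢ/N over the N unmasked
   biosamples, then rank-binned into 100 equal-sized quantiles.
2. **CBS catalog.**  The genome is scanned on both strands with a log₂-odds
   PWM; matches are filtered against non-autosomal contigs, assembly gaps,
   blacklist and coding exons, and kept only where they overlap a scored
   rDHS (inheriting its activity; maximum on multiple overlaps).  Each
   motif's affinity is its relative PWM score,
   (score − min)/(max − min) ∈ [0, 1].
3. **Allelic scoring.**  For each SNV in a CBS, both alleles are scored as
   the best log-odds over all motif-length subwindows of a 29-bp window
   (14-bp flanks) covering the variant, on both strands;
   ΔPWM = ref_best − alt_best classifies the variant (ΔPWM > 0: loss of
   binding, ≤ 0: gain).  Significance is the one-sided tail of ΔPWM under an
   explicit background null, estimated by importance sampling with an exact
   enumeration oracle for small motifs; p < 0.05 marks high-confidence
   calls.
4. **Constraint (MAPS).**  The mutability-adjusted proportion of singletons
   per variant class: observed singleton proportion (AC = 1) minus the
   proportion expected from trinucleotide mutation rates, calibrated on
   synonymous variants by weighted least squares;
   SEM = √(p(1 − p)/n).  Positive MAPS indicates negative selection.

See `docs/methods.md` for model details, parameter defaults, and what the
synthetic data does and does not emulate.

## Worked example

Run the full pipeline on synthetic data with a monotone planted selection
effect on loss-of-binding variants (excess singleton probability 0.00 →
0.09 across activity deciles 1 → 10):

```python
from cbskit.pipeline import default_run_config, run_all

result = run_all(default_run_config(seed=1))
for key in ("pearson_r_maps_vs_decile_loss_confident",
            "maps_loss_confident_decile10", "maps_neutral_control",
            "frac_loss_of_binding", "frac_confident_loss"):
    print(f"{key}: {result.headline[key]:.4f}")
```

prints

```
pearson_r_maps_vs_decile_loss_confident: 0.9784
maps_loss_confident_decile10: 0.0934
maps_neutral_control: 0.0050
frac_loss_of_binding: 0.9025
frac_confident_loss: 0.2327
```

Reading: across ~90,000 scored candidate SNVs, MAPS for high-confidence
loss-of-binding variants rises almost linearly with the activity decile of
the disrupted site (Pearson R = 0.98), reaching 0.093 in the top decile —
recovering the planted selection gradient (0.09 in decile 10) — while the
held-out neutral class sits at 0.005, indistinguishable from zero.  Most
scored variants weaken the motif (90% loss of binding) and about a quarter
of those are statistically confident at p < 0.05.

The same run is available from the shell:

```bash
cbskit run-all --seed 1 --out results/run1
```

which writes the rDHS activity table, the CBS catalog BED, scored variants,
MAPS-by-stratum table, the ground-truth JSON and a `headline.json` with the
numbers above.  Individual stages are exposed as `cbskit simulate`,
`activity`, `motifs`, `score-variants`, `maps` and `enrich`.

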