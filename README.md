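# chiprx

Spike-in normalised differential histone-mark analysis (ChIP-Rx) as a
reusable, tested Python pipeline.

## The problem

Conventional ChIP-seq cannot detect genome-wide gains or losses of a histone
mark, because library-size normalisation erases global differences between
samples. ChIP-Rx fixes this by mixing a constant proportion of exogenous
(spike-in, e.g. drosophila) chromatin into every sample before
immunoprecipitation: the exogenous read yield then calibrates IP efficiency
across samples. `chiprx` implements the downstream quantitative analysis for
experiments of this kind — for example comparing histone H3.3 mutant
(H3.3-G34W), wild-type and empty-vector cell lines across H3K27ac, H3K36me3
and epitope-tagged H3.3 ChIP:

* **Spike-in scaling** — per-sample scaling factors from spike-in IP read
  counts (optionally corrected by the input spike-in fraction), max-adjusted
  to 1 within each antibody group, applied by seeded Bernoulli downsampling.
* **Global mark level** — the depth-invariant ratio of ratios
  `(H_IP / D_IP) / (H_in / D_in)`, where `H`/`D` are target-genome and
  spike-in read counts in the IP and input libraries.
* **Windowed differential detection** — fragment extension (default 300 bp),
  sliding-window counting, a per-window negative-binomial likelihood-ratio
  test with binned method-of-moments dispersion, Benjamini–Hochberg
  correction, and merging of significant same-direction windows into
  differential regions filtered by `padj < 0.05` and `log2FC > 0`.
* **Peak-set algebra** — k-of-n replicate consensus at base resolution,
  intersections keeping only pieces longer than 50 bp (for enhancer /
  H3K4me1 overlap), and *exclusive* differential peaks that share no base
  with the other pairwise comparisons.
* **Motif analysis** — PWM scanning with exact score p-values (dynamic
  programming over discretised log-odds scores), hypergeometric ZOOPS
  enrichment of known motifs in 300 bp re-centred regions, and assembly of
  the union-of-top-20 enrichment heatmap (missing p-values set to 1).
* **ChIP-qPCR** — percent-of-input enrichment normalised to total H3.
* **Synthetic data** — seeded generators for every input (two-genome read
  populations, replicate count matrices with planted fold changes, enhancer
  intervals, sequences with planted motifs) with ground-truth records, so
  the whole pipeline is testable without external downloads.

## Worked example

```python
from chiprx import *
from chiprx.spikein import initial_scaling_factors, adjust_scaling_factors, global_mark_level
from chiprx.synthetic_data import simulate_spikein_experiment, simulate_differential_tags

# Two samples; the mutant has lost half its genome-wide mark.
counts, frags, truth = simulate_spikein_experiment(
    7, {"WT": 1.0, "G34W": 0.5}, depth=100_000)
sf = adjust_scaling_factors(initial_scaling_factors(counts, input_correct=True))
print(sf)
for s in ("WT", "G34W"):
    print(s, "global level:", round(global_mark_level(counts[s]), 3))

# Windowed NB differential test with one planted 4-fold region.
grid = WindowGrid(300, 300, {"chr1": 300_000})
planted = [(GenomicInterval("chr1", 60_000, 63_000), 4.0)]
windows, cmat, _, _ = simulate_differential_tags(
    7, grid, {"wt": ["wt1", "wt2", "wt3"], "gw": ["gw1", "gw2", "gw3"]},
    planted=planted, emit_fragments=False)
res = nb_test(cmat, ["wt"] * 3 + ["gw"] * 3)
kept = filter_differential(merge_windows(windows, res, 0.05))
for r in kept:
    print(f"{r.chrom}:{r.start}-{r.end} {r.direction} log2FC={r.log2fc:.2f} padj={r.padj:.3g}")
```

prints

```
sample   initial_sf  adjusted_sf
    WT 2.466841e+07     1.000000
  G34W 1.243404e+07     0.504047
WT global level: 1.004
G34W global level: 0.503
chr1:60000-63000 up log2FC=2.02 padj=1.72e-07
```

The adjusted scaling factor of the mutant is ~0.5 (its spike-in-calibrated
signal is half the wild type's), the global mark levels recover the true
occupancies 1.0 and 0.5, and the one planted 4-fold region is recovered
exactly, with log2FC ≈ 2 and a strongly significant adjusted p.

The same stages are exposed as a CLI
(`chiprx simulate | scale | track | diffwindows | consensus | intersect |
exclusive | annotate | motifscan | motifenrich | heatmap | qpcr`); every
subcommand logs its parameters and seed and reruns bit-identically.

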