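# Methods

## Spike-in (ChIP-Rx) normalisation

Every sample is assumed to contain a fixed proportion of exogenous
(spike-in) chromatin added before immunoprecipitation. Per-sample read
tallies are split four ways: target-genome IP (`H_IP`), spike-in IP
(`D_IP`), target input (`H_in`) and spike-in input (`D_in`).

**Initial scaling factors.** The default factor is `C / D_IP` with an
arbitrary positive constant `C` (10^6 by default, reads-per-million style);
`C` cancels after max-adjustment, so only the relative factors matter. An
input-corrected variant, enabled with `input_correct=True`, normalises the
IP spike-in fraction by the input spike-in fraction:

    sf_i = C * (H_IP_i / D_IP_i) * (H_in_i / D_in_i)

The corrected form is the one that recovers true occupancy ratios when the
spike-in proportion of the sequenced input differs between samples; the
uncorrected form is appropriate when inputs are not sequenced. Both are
deliberately exposed because published spike-in pipelines differ on this
point and the two coincide (up to the cancelled constant) when input
spike-in fractions are equal.

**Adjustment.** Within one antibody group, every factor is divided by the
group maximum, so the largest becomes exactly 1 and the rest lie in (0, 1].
The adjusted factor is a downsampling probability: scaling is applied by
seeded per-fragment Bernoulli thinning, never by multiplying track values,
so it cannot be double-applied. Bernoulli thinning (rather than exact
without-replacement subsampling) was chosen because it is a pure function of
(seed, input) and matches the behaviour contract of standard downsampling
tools; the kept count fluctuates binomially around `fraction * n`.

**Global mark level.** The depth-invariant occupancy estimate is

    global = (H_IP / D_IP) / (H_in / D_in)

Multiplying all four counts by a constant leaves it unchanged; it equals 1
when IP and input have the same target/spike-in composition.

**ChIP-qPCR.** Percent-of-input is `100 * 2^((Ct_input - log2(1/f)) -
Ct_IP)` where `f` is the input fraction (default 0.01); the `log2(1/f)` term
moves the diluted input onto the IP scale. Mark enrichment is reported both
raw and divided by the total-H3 enrichment of the same region and sample.

## Windowed negative-binomial differential testing

Reads are extended to a fixed fragment length (default 300 bp) from their 5'
end, strand-aware; records without strand are treated as complete fragments.
The fragment midpoint is the assignment point. Windows of size `w` tile each
chromosome from 0 at step `s` (defaults: `w = 300`, `s = 100` sliding for
histone marks, `w = 250` for the tagged-H3.3 mode; the synthetic benchmarks
use `s = w` so windows are independent). A point increments every window
containing it.

Counts are modelled as negative binomial with variance `mu + alpha * mu^2`.
The dispersion `alpha` is estimated by method of moments — pooled
within-group variance `v` and overall mean `m` give `(v - m) / m^2` — and
stabilised by averaging raw estimates within 20 quantile bins of the window
mean, floored at 1e-4. Pooling across similar-mean windows is what makes the
estimate usable at 2–3 replicates per group; the raw per-window estimate has
only ~4 degrees of freedom. With all window means identical the bins
degenerate to a single pooled bin.

Each window is tested with a likelihood-ratio test of a shared NB mean
against separate group means, with the binned dispersion treated as known,
referred to chi-square with 1 df. All-zero windows return p = 1 and
log2FC = 0. The fold change is `log2((m2 + c) / (m1 + c))` with pseudocount
`c = 1` (configurable) to avoid infinities at zero counts. p-values are
Benjamini–Hochberg adjusted across all windows.

Significant windows (padj threshold for the marks mode; raw p < 0.001 then
region-level padj < 0.05 and log2FC > 0 for the tagged-H3.3 mode) of the
same direction that overlap or abut are merged into differential regions
carrying the minimum window p, minimum window padj, and the count-weighted
mean log2FC. Regions of the same direction are pairwise disjoint by
construction.

**Calibration and the FDR unit.** On 5000 independent null windows
(NB mean 50, dispersion 0.1, 3 vs 3) the test's p < 0.05 rate is ~0.05, and
planted 4-fold regions are recovered with recall ≥ 0.9. Empirical FDR is
measured at the called-window level — the unit BH actually controls: among
windows passing `padj < 0.05` and `log2FC > 0`, the fraction outside planted
regions (~0.02–0.03 under the benchmark conditions). Counting instead at the
merged-region level would mechanically inflate FDR, because each true region
merges ~10 significant windows into one call while each false window stays a
singleton region; BH makes no promise about that ratio.

## Coverage tracks and TSS profiles

Per-base coverage is the number of fragments covering each base, computed by
difference arrays; bins larger than 1 bp sum the per-base coverage so the
track total always equals the summed kept-fragment length. Tracks are
written as run-length-compressed bedGraph. TSS profiles average the track in
fixed-width bins (default 10 bp) across a flank around each TSS, reversing
bins for minus-strand genes; TSSs whose flank runs off the chromosome are
excluded from the mean profile.

## Peak-set algebra

All coordinates are 0-based half-open; chromosome names match by exact
string equality (a rename map is available at the reader boundary).

* **Consensus** is base-level: the k-of-n consensus is the set of maximal
  intervals covered by at least k internally-merged replicates. It is
  antitone in k; k = 1 is the merged union and k = n the n-way intersection.
  Base-level coverage (rather than peak-level voting) was chosen because it
  is order-independent and verifiable against a trivial per-base oracle.
* **Minimum-overlap intersection** keeps base-wise intersection pieces
  strictly longer than the threshold (default 50 bp: a 50-base piece is
  dropped, 51 kept). Inputs are merged first, so output pieces never abut.
* **Exclusive peaks** use the strictest rule: a focal differential peak is
  excluded if it shares even one base with any differential peak of the
  other two pairwise comparisons. The two overlap rules are deliberately
  different operations.
* **Feature classification** assigns each peak by its midpoint with
  precedence promoter > exon > intron > distal; the promoter is TSS ± 2 kb
  (configurable — no universal definition exists). **Nearest-gene**
  assignment minimises |TSS − midpoint|, ties to the lower-coordinate TSS,
  distance signed by gene strand.

## Motif machinery

Position probability matrices (MEME minimal text) are converted to log2-odds
against the background with a small pseudocount (1e-4) and discretised onto
an integer grid of granularity `g = total score range / 1000`, so any k-mer
score moves by less than `g·k`. The exact null distribution of the score of
a random background k-mer is computed by convolving per-position score
distributions (dynamic programming), giving exact tail p-values at the grid
resolution — verified against exhaustive 4^k enumeration for k ≤ 6.

Scanning covers both strands; windows containing non-ACGT characters are
skipped; hits are occurrences with exact p ≤ 1e-4 (default). Enrichment
between a target and a background peak list re-centres every region to a
fixed 300 bp width, extracts sequences, counts sequences with ≥ 1 hit
(ZOOPS), and reports the one-sided hypergeometric tail for
over-representation of hit-bearing sequences among the targets.
Hypergeometric ZOOPS was chosen as the enrichment statistic; a cumulative
binomial would behave nearly identically at these sizes, and the choice is
recorded in the output metadata. The enrichment heatmap takes the union of
each list's top-20 motifs (ascending p, ties by name) and fills each cell
with that list's p, assigning exactly 1 where a motif is absent from a
list's table.

## Synthetic data

Generators are pure functions of (seed, parameters); identical calls are
bit-identical. Defaults are chosen to emulate the designed experimental
regime:

* spike-in fraction 0.20 (exogenous cells at 20% of target cells);
* sequencing depth 10^5 reads per sample for spike-in benchmarks, with
  Poisson count noise;
* window counts NB(mean 50, dispersion 0.1), 3 replicates per genotype,
  planted 4-fold regions — a mid-coverage, moderately overdispersed regime
  typical of histone-mark windows;
* fragments emitted as fixed-length 300 bp midpoint-resolved records so the
  extension logic round-trips exactly;
* planted motifs are consensus instances at recorded offsets.

What the generators do **not** emulate: mappability and GC bias, duplicate
reads, fragment-length variation, peak-shaped (non-uniform) within-region
read placement, chromatin input structure, or sequence composition beyond
i.i.d. bases at a stated GC. Passing tests therefore demonstrate
correctness of the statistical machinery under its own model assumptions,
not robustness to alignment artefacts or real-genome sequence structure.

## Numerical and edge-case choices

* BH adjustment via the standard step-up procedure (`statsmodels`).
* Dispersion floor 1e-4; LRT statistic clipped at 0 before the chi-square
  tail.
* Downsampling, genome, count and motif-planting randomness all flow through
  `numpy.random.default_rng(seed)`.
* Zero-length intervals are rejected at construction; BED parsing errors
  name the offending line.
* Points at or beyond the declared chromosome length are counted in the last
  window with a warning.
* Benchmark problem sizes (5000 windows, 200 sequences, 1000 random
  interval instances, depth 10^5) keep the full suite and the acceptance
  script to a few seconds while leaving Monte-Carlo fluctuations well inside
  the asserted bands.

## Known limitations

* No GLM covariates, paired designs or input-subtraction in the window test.
* The window test assumes pre-scaled (downsampled) inputs; no internal
  library-size normalisation is applied.
* Exact motif p-values are exact at the discretisation grid, not in the
  continuum; granularity is configurable.
* BigWig output is out of scope (bedGraph only); SAM/BAM ingestion is left
  to a thin upstream conversion into the fragment-table contract.
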