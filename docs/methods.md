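# Methods

This note records the model, the simulation conditions, the numerical
choices, and the limits of what the desk-scale experiments show.

## Simulation engine

Genealogies are sampled with msprime (`sim_ancestry`, binary mutations via
`sim_mutations`), under a single-population piecewise-constant demography.
The engine owns everything around the sampler:

* **Ascertainment.** Sites with exactly one mutation are kept (clean
  ancestral/derived polarity and a well-defined mutation time per site) and
  must be polymorphic in the analysis panel; optionally also in a random
  reference subset of configurable diploid size, emulating the "polymorphic
  in a reference sample" filter of sequencing studies. SNP-array data are
  emulated by subsampling sites to a target MAF spectrum (10 equal-width
  bins on (0, 0.5]) and per-cM density, with largest-remainder allocation
  and warn-and-renormalize behavior for infeasible bins. The built-in
  default spectrum is a synthetic stand-in shaped like a genotyping array
  (mass increasing toward common variants); real deployments should pass
  the spectrum observed on their target array.
* **Error models.** Phasing switch errors occur independently at each
  heterozygous site of a diploid with the given rate and swap the two
  haplotypes from that site onward (until a later switch reverses them);
  genotyping errors flip individual allele calls independently. Labels are
  extracted before error injection, so they remain the truth. Polymorphism
  filtering precedes error injection.
* **Labels.** Per-pair piecewise TMRCA segments and breakpoint sites are
  read directly off the simulated tree sequence; a site carries a
  breakpoint label iff its TMRCA segment differs from the previous site's
  (site 0 is never a breakpoint). The mean pairwise TMRCA matrix used by
  relatedness sampling is tskit's branch-mode divergence / 2, i.e. weighted
  by genomic span rather than by retained sites — the appropriate
  expectation-based summary, and fast.
* **Extensions.** Multiple-merger genealogies via msprime's Beta-coalescent
  (α ∈ (1, 2]; small α compresses the timescale and produces bursts of
  recent coalescence) and non-crossover gene conversion with geometric
  tract lengths (default mean 300 bp). `simulate_pairwise_tmrcas` exposes
  single-locus TMRCA draws without mutations for distributional studies.

## Features

Six channels per site and pair: XOR, AND, panel MAF, distance in bp and cM
to the previous retained site (0 at the first site), and the length of the
maximal run of constant XOR value containing the site. The run length is a
single channel covering both directions; together with the five other
features this fixes the input at six channels. Distances are left raw — the
network's leading batch-normalization layer owns standardization. Windows
at chromosome ends are padded: zeros for XOR/AND and distances,
edge-replication for MAF and IBS run, keeping shapes fixed for the
convolutional stack. On error-injected panels a site can drift to
monomorphic; its MAF is floored at the singleton frequency 1/n so the
channel stays in (0, 0.5]. A raw modality substitutes the two haplotype
tracks for XOR/AND (same six-channel layout), used by the
representation-probing analysis.

## Network

Input batch norm → n blocks of (valid 1-D convolution → batch norm → ReLU)
→ 1×1 convolution with two outputs per site: log-TMRCA (natural log,
generations, labels floored at 1 generation) and a breakpoint logit.
Stride and dilation are 1, so the receptive field is 1 + Σ(kᵢ − 1) and the
window context is fixed at (RF − 1)/2: the output covers exactly the L
central sites. Two presets:

* **full** — 5 blocks, channels (8, 16, 32, 64, 80), kernels 15:
  118,614 parameters, receptive field 71 sites. Block count, first-block
  width and the overall parameter budget follow the printed architecture
  constraints; per-block widths/kernels beyond that are this package's
  choice and fully config-exposed.
* **desk** — 3 blocks, channels (8, 16, 16), kernels (11, 9, 9): 4,150
  parameters, receptive field 27. All CPU experiments use this preset.

The implementation is pure NumPy with hand-written backward passes
(im2col-style convolutions via stride tricks), which keeps training and the
gradient-based interpretability honest to ~1e-10 against finite
differences, and makes checkpoints plain `.npz` files with the config and
provenance embedded.

## Training

* **Loss.** exp(−s_r)·Huber(δ=1 on log scale) + exp(−s_c)·weighted BCE +
  (s_r + s_c)/2, averaged per site; BCE class weights w_c = n/(2 n_c) per
  batch. The uncertainty scalars get a larger Adam step (0.05 vs the 0.001
  used for weights): Adam's scale-invariant updates would otherwise move
  two scalar parameters imperceptibly over a short run.
* **Output-bias initialization.** The head's regression bias is set to the
  mean log-TMRCA of the first epoch's labels and the classification bias to
  the empirical breakpoint log-odds. The Huber gradient is clipped at δ, so
  without this the output level would need thousands of Adam steps to reach
  the log-TMRCA scale (~10).
* **Epochs.** Each epoch runs `sims_per_epoch` (default 64) independent
  simulations and takes a single pair from each: epochs alternate uniform
  pairing with relatedness-informed pairing (see below); the pair's
  sequence is tiled into stride-L windows (trailing partial window dropped
  in training; inference stitches it). With a non-constant genetic map each
  simulation draws a different sub-region of the map.
* **Relatedness pairing.** The first pair is uniform. Each next pair picks
  an anchor uniformly among already-paired haplotypes, takes the remaining
  haplotype closest to the anchor in mean TMRCA, and pairs it with the
  remaining haplotype closest to *it* (ties to the lowest index), until all
  haplotypes are paired. This yields a disjoint perfect matching whose mean
  TMRCA is stochastically below a uniform matching's, oversampling recent
  coalescence.
* **Validation.** Held-out simulations (disjoint seed stream); pairs ranked
  by mean true TMRCA, top 5% kept (floor; at least one pair, with a warning
  below 20 candidates). Score: Huber on log-TMRCA with per-site weights
  inversely proportional to bin occupancy over 20 equal-width bins of true
  log-TMRCA, clipped at 100× the median occupied-bin weight and normalized
  to mean 1 — emphasizing under-represented recent and very old TMRCAs.
  The checkpoint at minimum validation score is returned.
* **Seeding.** A single master seed feeds named `SeedSequence` streams
  (init / training sims / validation / batching / diagnostics); training
  seeds are drawn from one stream across epochs, so no seed is reused and
  validation/test seeds never appear in training. Two runs with the same
  config are bit-identical.
* **Transfer.** `finetune` initializes every layer from a donor checkpoint
  (window/channel layout must match) and updates all layers under the new
  configuration.

## Postprocessing

A site whose predicted breakpoint probability strictly exceeds the
threshold *starts* a new segment (the boundary sits between it and its left
neighbor); each segment's value is the arithmetic mean of the raw TMRCA
over its sites, on the natural scale. This preserves the site-weighted
track mean exactly and nests segmentations across thresholds. Default
thresholds when tuning is skipped: 0.7 (sequencing), 0.55 (array);
`tune_threshold` grid-searches the mean absolute TMRCA error on labelled
held-out pairs and reports the full curve. Predicted log-TMRCAs are clipped
to [0, 30] before exponentiation (e³⁰ generations is far beyond any
coalescent time; untrained models can emit arbitrary values).

## Dating

Concordant/discordant comparisons as in the README. Numerical choices:
"above"/"below" the rejection threshold are strict comparisons; candidate
thresholds are the observed TMRCA values (the rejection count is piecewise
constant between observations, which the test suite verifies against an
O(n²) sweep over a dense threshold grid); ties break by smallest rejected
fraction, then smallest threshold. If filtering empties one side the
estimate degenerates to the surviving bound and is flagged; if the kept
bounds still cross (possible under noise) the midpoint is reported with a
consistency flag. Pair lists larger than `max_pairs` (default 10,000 —
pair counts grow quadratically in sample size) are subsampled uniformly
with a fixed seed. Variants without a high-confidence ancestral call, and
singletons, are excluded. Multi-population aggregation weights each
population's lower (upper) bound by its retained concordant (discordant)
pair count; a zero-weight side drops out of that side's average.

## Interpretability

Saliency is input×gradient against the *normalized* input (the output of
the leading batch-norm layer, captured from the forward pass), with the
predicted TMRCA rescaled by 10⁶ before differentiation to avoid vanishing
gradients; only absolute values are reported. MAF perturbations shift the
MAF channel at AND=1 (down) or XOR=1 (up) sites by 0.05, snapping values
below 0.05 to the singleton frequency and above 0.45 to 0.5. The
representation probe correlates each first-block channel of a raw-input
model with the XOR/AND tracks over the central sites, averaging Pearson r
over pairs; constant channels report NaN rather than 0, and alongside the
one-to-one reading the max-|r| assignment per channel is reported.

## Annotation

Equal-width MAF bins on [0.05, 0.5] (config-overridable; the canonical
baseline's exact edges are not published). Within-bin quantile
normalization uses the rank-based inverse-normal transform with offset
(rank − 0.5)/n — the Blom offset differs only at O(1/n) — with average
ranks for ties, so tied ages share a value and the map is invariant to
monotone transforms. A single-variant bin normalizes to 0 with a warning.

## Desk-scale conditions, and what the tests do and do not show

CPU experiments use: constant Ne = 10,000, μ = 1.65×10⁻⁸, uniform
crossover rate 10⁻⁸/bp/gen, 2 cM (2 Mb) regions, 20 haplotypes, the desk
preset with L = 512, 15 epochs of 64 simulations (training ≈ 3 minutes on
one CPU); dating oracles use 20 recombination-free 200-kb replicates of 30
haplotypes; the transfer experiment fine-tunes onto a two-epoch bottleneck
demography (Ne 3,000 until generation 2,000, then 15,000). Under these
conditions the desk model reaches held-out Spearman ≈ 0.87 between
predicted and true log-TMRCA and roughly halves the log-scale MAE of the
best constant predictor, and fine-tuning reaches the donor's validation
score in fewer epochs than cold start.

The generator draws from the same neutral coalescent process the network
is trained on. Passing tests therefore demonstrate the correctness of the
machinery and the learnability of the map under matched conditions — an
idealized setting. They do not quantify robustness to demographic
misspecification, selection, real phasing/genotyping error structure, or
reference-bias effects in real data, and desk-scale accuracy is far from
what full-scale training achieves. Known limitations: the receptive field
bounds how much flanking haplotype sharing the model can see (long IBD
segments of very recent ancestry saturate it); dating requires quadratic
pairwise work; the Beta-coalescent exploration covers a small parameter
range; and the "imputed" data modality is supported only as dosage-rounded
binary input.
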