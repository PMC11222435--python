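# Methods

This note records the modeling choices, simulator design, numerical
decisions and known limitations of squigmeth, at the level of detail a
maintainer needs to change any of them deliberately.

## Feature extraction

A read arrives as raw signal, a stride-*b* move table (one 0/1 entry per
*b* samples; 1 marks the first stride of a new base), basecalls and,
optionally, a SAM-convention alignment. Signal is normalized per read by
median/MAD (scale 1.4826·MAD, standard-deviation fallback when the MAD is
zero, zeros for a constant signal); raw current scale varies per pore and
per read, and the model needs scale stability. Nothing else is calibrated —
all signal is in arbitrary normalized units.

For every CpG in the anchoring sequence (reference via CIGAR in
reference-anchored mode, basecalls in basecall-anchored mode) we cut an
*l*-base window centred on the assayed cytosine. Features are built in read
orientation: a minus-strand site's window is the reverse complement of the
forward reference, so the C always sits at ⌊l/2⌋ followed by G, and the
call is reported at the forward-strand coordinate of that C with strand
`-`. Windows that overrun the read or alignment are dropped rather than
padded, matching the fixed-length architecture.

The signal blocks of an example are all move-table steps whose anchoring
base falls in the window. The published block-count quality filter is
stated in terms of the block count itself, which is self-referential; we
interpret it per window base: examples with fewer than ⌈0.5·l⌉ or more than
5·l blocks are discarded (and counted). Insertions carry the previous
aligned reference coordinate and are flagged; deletions advance the
reference only; window-relative query indices subtract the window's first
query index and clip to [0, l−1]. Whether the query index should be
window-relative or read-relative is not fixed by the published description;
window-relative keeps both index vectors on the same scale, which the
positional encoding assumes.

## Architecture

Pre-LN transformer, encoder over signal blocks, decoder over the token
window with cross-attention into the encoder output. The positional term
function pt is published with denominator "d", a symbol also used for the
per-head dimension f/H; we use the full latent dimension f (the standard
sinusoidal convention), and in 2-term mode pair frequencies per 2
(exponent −2⌊j/2⌋/f) so cos/sin stay frequency-matched. Weights initialize
truncated-normal(0, 0.02) with zero biases; dropout (default 0.1) applies
after attention and feed-forward sublayers during training only. Batches
pad blocks to the batch maximum with an attention mask; padded positions
neither attend nor are attended. A config switch (`use_decoder=False`)
bypasses the decoder for the signal-only ablation, predicting from the
masked mean of the encoder output.

There is no final layer norm after the last encoder/decoder layer: the
contract "zero layers ⇒ output equals embedding + positional encoding" is
part of the module's tested surface.

The whole network runs on an in-repo reverse-mode autodiff engine over
float64 numpy arrays (`autograd.py`): broadcast-aware arithmetic, batched
matmul, softmax/layer-norm/GELU primitives with analytic backward passes,
embedding scatter-add, and fused stable BCE/cross-entropy losses. Float64
keeps finite-difference gradient checks meaningful; the acceptance battery
verifies analytic gradients to 1e−4 relative error.

## Training

Total loss `L_mod + α(L_bases + L_signal + L_diversity)`. Defaults
p_mask = 0.15, p_flip = 0.05, p_signal = 0.15, K = 64, α = 0.1 — the
published text defers the actual values to supplementary material, so these
follow common masked-pretraining practice and are config-exposed and
logged. Flipped bases draw uniformly from the four canonical bases;
non-canonical originals can be masked but are excluded from the base-task
targets (the base head has four classes).

Codeword targets are the argmax codeword probability of the *local* block
representation (B·W^S), computed before masking with gradients blocked;
predictions come from the *contextualized* representation. This
local-vs-contextual split prevents the trivial solution where encoder and
targets collapse together. The diversity term uses the *soft* batch-average
assignment distribution, log K − H(p̄): the published description says
"average hard probability", but the hard version has zero gradient; the
hard usage histogram is still logged per step as a diagnostic.

Optimization is Adam with decoupled weight decay (lr 3e−4, wd 1e−4,
β = 0.9/0.999, no schedule); decay applies to weight matrices only.
Training batches bucket examples of similar block count to minimize
padding, then shuffle the bucket order per epoch; everything (data order,
masking, dropout, init) derives from the config seed, so identical
configurations reproduce identical loss histories bit for bit.

Distillation soft-labels an example stream with the teacher's sigmoid
probabilities and trains the student with BCE on those probabilities
directly (no temperature). A stratified sampler draws exactly balanced
modified/unmodified pools by thresholded label, mirroring the balanced
distillation set construction used at production scale.

Training labels come from truth frequencies the way bisulfite training sets
are built: sites ≥ 0.99 are positives, ≤ 0.01 negatives, partially
methylated sites are excluded because their per-molecule state is
ambiguous.

## Simulator

The simulator emulates what a basecaller emits, not pore physics. Current
levels are per k-mer (default k = 6, standard-normal levels; a "spaced"
mode places the 4^k levels on an even grid over [−2, 2] so every k-mer is
resolvable from its mean level — the clean "signal determines base"
condition used in the learnability experiments, where k = 1 keeps the
inversion learnable by a 2+2-layer model in minutes). Methylation adds
`mod_shift` to every k-mer overlapping the methylated C, making context
informative; the default shift of 1.0 is twice the mean noise sd (0.5), a
clearly but not trivially separable effect. Dwell is shifted-geometric in
stride units (minimum one step per base, mean `dwell_mean/stride` = 2 by
default), producing the realistic variable block counts the block filter
acts on.

References are generated by a Markov walk whose P(G|C) realises a target
CpG observed/expected ratio, elevated (0.8, GC 0.6) inside evenly spaced
planted islands and suppressed (0.2) in the background. Island CpGs are
mostly unmethylated and background CpGs mostly methylated (mixture weights
(0.8, 0.1, 0.1) and (0.2, 0.7, 0.1) over frequency {0, 1, partial},
partials uniform on [0.2, 0.8]); both strands of a CpG share one frequency
(symmetric maintenance methylation). Basecalling errors are substitutions
and single-base indels at configured rates with an exactly consistent
CIGAR; substituted bases keep the true template's signal (the error is the
basecaller's, not the pore's), and inserted bases reuse the neighbouring
k-mer context. Bisulfite truth is Poisson coverage with binomial methylated
counts at probability f(1−ε) + (1−f)ε.

What the simulator does *not* model: event stalls, adapter sequence,
homopolymer-specific dwell, quality strings, mappability structure, or
correlated noise. Passing tests therefore demonstrate that the
implementation is internally correct and that the method recovers planted
signal under idealized noise — not that it matches production accuracy on
real flowcells.

## Calling, aggregation, evaluation

Per-read probabilities are emitted for every extractable example with no
confidence filtering, so site coverage counts every usable molecule. A call
is methylated iff its probability is strictly above 0.5 (ties to
unmethylated, for determinism); strands aggregate separately.

Evaluation follows the standard WGBS-anchored protocol: classification
truth keeps coverage ≥ max(P₅, 5) (nearest-rank percentiles, for
determinism) and drops frequencies strictly inside (0.01, 0.99);
correlation additionally caps coverage at P₉₅ and keeps partials;
site-level comparisons require ONT coverage > 5. Average precision uses the
ranked-sweep definition (scikit-learn's implementation; tests cross-check a
brute-force sweep). Context annotation: promoter (TSS ± 2000) > exon >
intron (gene minus exon) > intergenic; repeat classes resolve
SINE→LINE→LTR→DNA→Other on overlap; islands beat shores (2 kb flanks) beat
shelves (next 2 kb); GC content buckets the 5-base window's G+C fraction
into the smallest bucket ≥ 100·g among {20, 40, 60, 80, 100}; a singleton
CpG has no other CpG within ±10 bp. TSS profiles bin signed distance as
⌊(pos − P + ⌊B/2⌋)/B⌋ with minus-strand offsets negated so upstream is
always negative, filtering ONT coverage < 3 and WGBS coverage < 5 per
tool. Confident-site comparison classifies every site of the A/B universe
(positive: coverage ≥ 5 and frequency > 50%; negative: ≥ 5 and ≤ 50%;
uncalled below 5) into concordant, supported-discordant, unresolved
discordant, unique and uncalled categories that provably partition the
universe. The filtering-bias analysis classes a site by overall vs valid
coverage: missing-low-overall (< 5 overall), missing-due-to-filtering
(valid < 5 ≤ overall), high-filtering (valid ≥ 5 but more than 10% of
calls filtered), else ok.

## Problem sizes

The test and acceptance runs use desk-scale configurations chosen so the
full battery trains real models end to end: window l = 15, k = 1 spaced
pore table, 20k training examples for the recovery experiment (f = 64,
4 heads, 2+2 layers, five epochs), 12k for the acceptance script's
pipeline, ~8k-example distillation pools, and 8–20 kb references with a few
hundred reads for site-level closure. These sizes are the package's own
scaling of the method; the architecture accepts the published full-scale
hyperparameters (f = 384, 12+12 layers, l = 31) unchanged.

## Known limitations

- No GPU or mixed-precision path; the numpy engine is single-threaded and
  meant for desk-scale experiments, not production training.
- Basecall-anchored examples on unaligned reads carry read-local
  coordinates; genomic aggregation needs an alignment.
- The simulator's basecall errors are independent per base; real
  basecallers make correlated, context-dependent errors.
- FAST5/POD5 and BAM binary ingestion are out of scope; the JSON-lines and
  SAM-text dialects are the two ingestion paths.
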