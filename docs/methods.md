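# Methods

`capreg` predicts whether a fixed-length DNA window contains a
CAGE-peak-associated capping region, and extracts candidate capping motifs
from the attention maps of the trained classifier. This note documents the
model, the training procedure, the synthetic benchmark, and the design
choices that were genuinely open.

## Problem setting and dataset construction

CAGE (cap analysis of gene expression) peaks mark genomic positions where
capped RNA 5' ends accumulate. The prediction task is binary: given a
window of `W` nucleotides (default 512; 128 at benchmark scale, 256/1024
supported), does it contain a CAGE peak?

Positive windows are centred on the peak start: `[start − W/2, start +
W/2)`, label 1. A window that would leave the chromosome, or that carries
more than 10 % `N` bases, is skipped. For each peak one negative window is
drawn with its start uniform on `[start − 20,000, start − 10,000 − W]`, so
that *every base* of the negative keeps the stated 10–20 kb upstream
distance ("upstream" is read as lower coordinate regardless of strand; no
reverse-complementing is performed anywhere, since the classification
target is strand-symmetric under our generator). Candidate negatives that
share any base with any positive window on the same chromosome are
resampled up to 10 times, then dropped; any positive still overlapping a
retained negative is removed afterwards. All coordinates are 0-based
half-open throughout; touching intervals do not overlap. The result is an
approximately 1:1 dataset with zero cross-class base overlap and slightly
more negatives than positives when collisions occurred.

Evaluation uses leave-one-chromosome-out cross-validation (LOCOCV): each
fold holds out one whole chromosome, eliminating positional leakage
between train and validation.

## Tokenization

A window is pre-tokenized into overlapping 8-nt **words** starting every
4 nt, so consecutive words within one pass share exactly 4 nt; the pass is
repeated at offsets 1, 2 and 3, which puts a word start at *every*
position of the sequence. A byte-pair-encoding vocabulary is then trained
from single characters: at each step the most frequent adjacent token pair
(weighted by word frequency; overlapping occurrences each count) is
merged, ties breaking to the lexicographically smallest pair, stopping
after `k` merges or when no pair occurs twice. Merges never cross word
boundaries, and ambiguity codes (`N` and friends) stay atomic. The
desk-scale default is 505 merges (vocabulary 512 including `<pad>`,
`<unk>` and the five single-character tokens); the full-scale figure of
50,254 is available as configuration.

Every token records its `(offset, start, end)` nucleotide span, which is
what lets attention peaks be located on the sequence later. Frequencies
are counted corpus-wide, not per sequence.

## Model

A decoder-only transformer implemented in NumPy with hand-written
gradients (forward caches plus explicit backward passes; correctness is
pinned by finite-difference tests over every parameter group). Desk-scale
defaults: d_model 64, 2 layers, 2 heads, gated-MLP width 4·d; the
full-scale preset (d_model 256, 4 heads, 4 layers, vocabulary 50,254) is
provided but not exercised by the test suite.

* **Rotary positional embeddings.** θ_i = 10000^(−2i/d) over the head
  dimension; coordinate pairs (2i, 2i+1) of queries and keys are rotated
  by p·θ_i. Rotation preserves norms and makes q·k depend only on the
  relative offset, both asserted numerically.
* **Grouped multi-query attention.** Heads are partitioned into kv-groups
  sharing key/value projections; the default is one group per head (plain
  multi-head), with grouping available (`n_kv_groups`). Scores are
  softmax(RoPE(Q)·RoPE(K)ᵀ/√d_k) under a causal mask; padding sits at the
  end of a batch row and padded keys are masked out.
* **Gated MLP.** W_down(SiLU(x·W_gate) ⊙ x·W_up), no biases.
* **Blocks.** Pre-norm residual blocks with RMS normalization (the
  standard Llama arrangement).
* **Heads.** A causal-LM head (initialized at std 0.02 so the initial
  loss sits at ln V) and a 2-class classification head reading the hidden
  state of the **last non-padding position**. Mean and per-dimension max
  pooling are selectable (`ModelConfig.pooling`); see "Pooling and motif
  discovery" below for why last-position pooling is the default.

## LoRA and ReLoRA

Every one of the seven projection matrices per block (q, k, v, o, gate,
up, down) can carry a rank-r adapter: effective weight W + s·A·B with
s = α/r (default α = 2r, i.e. s = 2), A Kaiming-initialized, B zero — so a
fresh adapter never changes the layer's function. Embedding, norms and
heads are never replaced by adapters.

Pre-training (causal LM on token streams cut into fixed-length chunks)
follows the ReLoRA schedule: full-rank training for a warm start, then
adapter-mode training with a **restart** every `restart_interval` steps —
adapters are merged into the frozen base, re-initialized, and the
adapters' Adam moments are pruned (default: zeroed entirely;
`optimizer_prune_fraction < 1` zeroes the smallest-magnitude fraction).
The learning rate runs linear warmup → cosine decay, with a drop to zero
and a linear re-warm over `adapter_warmup_steps` after each restart (the
"downward spikes"). A restart never moves the model: forward outputs are
identical before and after, asserted to 1e−6 on the assembled model.

Fine-tuning merges any pre-training adapters, attaches fresh adapters
(default rank 8) and trains **only** adapters + classification head with
Adam (β₁ 0.9, β₂ 0.999, ε 1e−8), global-norm gradient clipping at 1.0,
and a linearly decaying learning rate; the checkpoint with the best
validation loss at an epoch boundary is kept. Class calls are the argmax
of the 2-class softmax; there is no tunable threshold. Full-scale
defaults (batch 64, peak 5e−5, 5 epochs) are kept in `TrainConfig`; the
desk preset uses batch 16, peak 5e−3, 12 epochs, because a fresh
~1M-parameter model needs a far larger step than a converged 28M-parameter
base — at 5e−5 nothing measurable happens in 5 epochs at this scale.

## Attention-based motif discovery

For each classified sample, the attention received by each token is
computed from the final layer: mean over heads, summed over query
positions, renormalized to 1 (per-head max and other layers are
selectable). Under a causal mask earlier keys are visible to more
queries, so uniform attention gives early positions slightly more mass;
the bias is shared across samples and does not affect within-sample
ranking of genuinely peaked attention.

From the top-3 attention tokens, all N-free octamers in the token span
± flank (5 nt by default, 10 supported) are counted per sample. Per
octamer, the per-sample count vector of predicted-positive samples is
compared with that of predicted-negative samples (negatives scaled by the
class-total ratio so totals match) using the two-sided Mann–Whitney U
test — exact by enumeration for tie-free pooled samples of ≤ 12 values,
otherwise the normal approximation with midrank tie correction and
continuity correction (delegated to `scipy.stats.mannwhitneyu`; an
exhaustive permutation oracle in the test suite pins both regimes). The
table is sorted by ascending p; octamers with raw p < 0.01 are flagged,
and a Benjamini–Hochberg q-value column is emitted alongside for users
who prefer FDR control (the raw filter mirrors standard practice for this
pipeline and is the default). Aggregate tests compare normalized
per-octamer frequency vectors: positive peak windows vs their full
context windows, negative peaks vs context, and positive vs negative
peaks. "Token count vectors" are per-sample counts per octamer — the only
reading that admits a two-sample rank-sum test per motif. Tokens that
cover identical nucleotides via different offsets each contribute once
per (sample, token) occurrence; tokens are ranked, not positions.

Flagged motifs are exported as a TSV plus a FASTA of their resident
peak-window sites, ready for external FIMO/JASPAR scanning (running FIMO
is out of scope).

### Pooling and motif discovery interact

Which hidden state the classifier reads determines whether attention maps
carry motif information. With last-position pooling, the *only* route
from a motif occurrence to the logits is attention from the final
position, so fine-tuning concentrates attention exactly on discriminative
tokens — on the benchmark, the implanted octamer tops the motif table
well below the 0.01 flag. With max pooling the classifier reads motif
evidence directly from the motif position's own hidden state — it learns
the occurrence task more directly, but leaves the attention maps
uninformative: in development runs the implanted octamer did not even
enter the candidate table. Last-position pooling is therefore the
default; max pooling is a reasonable choice only when motif discovery is
not needed.

## Synthetic benchmark

The generator emulates FANTOM5-style inputs at desk scale: an i.i.d.
uniform-composition genome (GC-skewed presets available), 1-nt CAGE-like
peaks (width configurable to 50), and the octamer `TTTTTATT` — one of the
capping-associated motifs this pipeline reports at full scale — written
into the genome at peak start + U(−20, +20) with probability 1. Peaks are
placed ≥ 20 kb from the chromosome start so each has a full negative
band. Defaults: 2 chromosomes × 200 kb, 250 peaks per chromosome,
window 128, spacing ≥ 600 nt. The benchmark size follows the fine-tuning
regime this method needs: with ~500 training windows the classifier
reaches ≥ 0.97 held-out-chromosome accuracy, while at a few dozen
training windows gradient-trained models (and L2-regularized linear
probes on token counts) memorize the training set instead of finding the
motif — only sparsity-biased learners separate out of sample there — so a
much smaller benchmark would measure sample starvation rather than the
method.

With inter-peak spacing below 20 kb + W, a negative window can fall near
*other* peaks; negatives stay clean of implants because the overlap
filter resamples any negative touching any candidate positive window and
implants lie strictly inside positive windows (|jitter| + 8 ≤ W/2).

What the generator does **not** emulate: promoter grammar (TATA/Inr/DPE
placement), GC-content structure around real TSS, repeat content,
soft-masking, strand effects, CAGE expression levels, or multiple
overlapping peak clusters. Passing the benchmark therefore shows that the
pipeline recovers a planted, perfectly informative signal at realistic
sizes — not that it attains any particular accuracy on real genomes.

The seeded benchmark (`capreg.benchmark.run_benchmark`) measures: held-out
chromosome accuracy/precision/recall/F1; a label-shuffled control (same
protocol, permuted training labels — stays at chance); the implanted
octamer's rank and p-value in the motif table; the three aggregate
rank-sum p-values; and the pre-training loss drop.

## Numerical choices and degenerate inputs

* Everything is float64; softmax is max-subtracted; rank-sum p-values are
  floored at 1e−300 (the normal tail underflows to 0 for the aggregate
  tests, violating p ∈ (0,1]).
* Argmax ties in BPE break lexicographically; attention-score ties break
  to the earlier token; identical-constant rank-sum inputs return p = 1.
* Determinism: one integer seed drives genome simulation, negative
  sampling, initialization, batch order, the ReLoRA re-inits and the
  control's label shuffle; runs are bit-reproducible.
* Empty corpora, empty datasets, single-chromosome LOCOCV, T < 2 causal
  loss, labels outside {0,1}, and zero class totals raise; out-of-bounds
  windows and over-short sequences are skips/warnings, not errors.

## Known limitations

* CPU-only NumPy training: practical up to ~10⁶ parameters and ~10³
  samples; the full-scale configuration is expressible but not trainable
  in reasonable time here.
* One negative is attempted per peak; peak clustering/merging and
  expression-score thresholds are out of scope.
* Minus-strand peaks are not reverse-complemented (the field is split on
  this; the generator is strand-symmetric so the benchmark cannot decide
  it).
* The attention aggregation (final layer, head mean, received mass) is a
  documented default, not a derived optimum; alternatives are exposed.
* Per-motif p-values are reported raw with a p < 0.01 flag; the BH
  q-values are informational.
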