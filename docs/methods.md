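# Methods

## Task encoding

A sentence of n words with flat entity mentions is encoded as an n×n grid of
relation labels. The label set is ordered: `NONE` (index 0), `NNW` (index 1),
then one `THW-<type>` label per entity type. A k-token mention (s, e, t)
contributes k−1 `NNW` cells on the adjacent upper off-diagonal — (k, k+1) for
s ≤ k < e — and a single `THW-t` cell at (e, s). Single-token mentions occupy
the diagonal cell (i, i): the diagonal is the only self-pair, and treating it
as part of the THW (lower) region keeps the two relation families in disjoint
triangles. Coordinates are 0-based with inclusive ends throughout.

Decoding is written more generally than encoding: `NNW` cells are directed
edges i→j (i < j), and a mention (s, e, t) is emitted whenever cell (e, s)
holds `THW-t` and a strictly increasing NNW path from s to e exists
(depth-first search). THW cells with no path are dropped and counted in a
diagnostics object. When predicted probabilities are available, overlapping
decoded candidates are resolved greedily by THW cell probability, ties broken
by smaller start and then longer span; without probabilities all path-valid
candidates are returned (encoded gold grids never conflict). The test suite
checks the decoder against an independent brute-force path enumerator on
exhaustively sampled small grids.

## Model

**Prefix-guided encoder.** A compact transformer encoder (token + position +
segment embeddings, pre-classifier layer norm, GELU feed-forward blocks). In
every layer each head's key and value matrices are extended with P trainable
prefix rows φ_k, φ_v (independent per layer, initialized like the
embeddings, never acting as queries). The post-softmax attention weight
matrix is therefore L×(L+P); the layer output applies it to [V; φ_v]. With
P=0 the layer is exactly standard scaled dot-product attention (asserted to
1e-6 against an independent NumPy reference). Padded key positions get −inf
logits; prefix columns are always attendable. Attention maps from the guided
layers (default: the last four, clipped to the model depth) are kept in the
autodiff graph so the guidance loss shapes them during training.

**Word pipeline.** Subword pieces come from a greedy longest-match WordPiece
tokenizer with `##` continuations whose vocabulary is built from the training
corpus (whole words plus characters; unknown characters map to `[UNK]`).
Piece vectors are pooled to word vectors by elementwise max (mean available);
boundary specials are excluded from pooling but included in the attention
length L. A BiLSTM (half the width per direction, padded steps carry state
through unchanged) produces the word representations h_i of width d_h.

**Pair grid head.** Conditional layer normalization builds cell (i, j) as
γ(h_i) ⊙ standardize(h_j) + λ(h_i), where γ and λ are affine maps of the
condition vector initialized to produce gain 1 and bias 0 — CLN therefore
starts as plain layer normalization (variance floor ε = 1e-5). Cells are
concatenated with a signed log-bucketed distance embedding (19 buckets,
magnitudes 0, 1, 2, 3–4, 5–8, …, ≥65, clamped; width 20) and a 3-way region
embedding (upper/diagonal/lower; width 20), projected by a one-hidden-layer
GELU perceptron to d_g channels, refined by a single shape-preserving 3×3
convolution with dilation 2 and GELU, and classified per cell by another
one-hidden-layer perceptron with softmax. The grid loss is the per-sentence
mean over its n² valid cells of the cross-entropy against the one-hot gold
label (padded cells masked out), averaged over the batch. Class imbalance
from the dominant `NONE` label is left unweighted by default.

**Attention guidance.** For each guided head's map, the "received attention"
vector sums each key column over the unmasked query rows: p ∈ R^{L+P} over
all columns, o = the first L entries. Column sums (not row sums) are the
only reading consistent with the declared vector lengths, and L2
normalization makes any constant pooling scale irrelevant. Rows are
normalized to exact unit norm (an all-zero row from a fully masked map is
replaced by the uniform unit vector and logged). Each head is its own class
in a non-parametric softmax over head–head dot products with temperature τ
(default 2.0); the loss is the summed negative log-likelihood of each head
classifying as itself, computed once on the o view and once on the p view and
fused as their plain mean. Batches are handled by pooling per sentence (L =
the batch's longest piece sequence) and averaging the fused loss over
sentences. Closed forms used as oracles: two identical unit rows give
2·ln 2; two orthogonal unit rows give 2·ln(1+e^{−1/τ}), i.e. 2·ln(1+e^{−1/2})
at τ=2; m identical rows give m·ln m; for m=2 rows at cosine c the loss is
2·ln(1+e^{(c−1)/τ}), strictly increasing in c.

**Training.** `Loss_total = Loss_grid + α·Loss_guidance` (α=0 disables
guidance — the ablation baseline). AdamW (β = 0.9/0.999, decoupled weight
decay 0.1 skipping 1-D parameters) at learning rate 1e-3 with linear warm-up
over the first 10% of steps and linear decay, batch size 8, everything
seeded. Model selection supports dev-F1 logging and fixed-epoch training; a
training-F1 early stop is available for overfitting experiments. All
parameter updates, including the backbone, use one rate by default; a
separate scale for backbone parameters is exposed because the printed single
rate plausibly applies only to the non-backbone group in the full-scale
setting.

## Implementation

The package carries its own reverse-mode autodiff over NumPy float64 arrays
(`gridner._autodiff`) and a small layer/optimizer toolkit (`gridner._nn`):
broadcasted arithmetic, batched matmul, masked softmax, embedding gathers,
an im2col dilated 2-D convolution, and finite-difference-checked gradients
for every primitive. Models are deliberately compact (defaults: 2 layers, 2
heads, width 32, prefix 4, d_h = d_g = 32–64) and randomly initialized; the
encoder is structurally a BERT-family stack so pretrained weights could be
mapped in, but checkpoint import is out of scope. Checkpoints are `.npz`
archives holding all weights (prefix banks included) plus JSON metadata.

## Synthetic corpus

The generator emulates the traits of BioNER corpora that matter for this
model: moderately long sentences with sparse entities (defaults: Poisson
mean length 12 capped at 20, 1.2 expected mentions per sentence), a mix of
single- and multi-token mentions (multi fraction 0.5), and alphanumeric-
hyphen chemical patterns that split into ≥2 tokens ("XQ - 417"; fraction
0.3). Filler tokens are drawn from a Zipf-skewed pseudoword vocabulary;
entity surface forms come from a disjoint lexicon so the toy task is
solvable from lexical identity. Chemical-like mentions are always
multi-token, so the effective multi-token fraction is
c + (1−c)·m for chemical fraction c and multi fraction m. Mentions are
placed by rejection sampling (100 retries per mention); the generator fails
hard if more than 20% of requested placements fail corpus-wide. What passing
tests show is representational and optimization adequacy of the codec and
architecture — not performance on real PubMed text, whose vocabulary,
ambiguity and annotation noise the generator does not imitate.

## Problem sizes and numerical choices

Tests and the acceptance script run deliberately small problems chosen once:
codec checks on 10,000 random sentences and 100,000 random n ≤ 5 grids;
learnability on a 200-sentence corpus with the toy encoder (2 layers, 2
heads, width 32, prefix 4), early-stopped at training F1 ≥ 99 within a
60-epoch budget; the guidance-direction comparison on an 80-sentence corpus,
8 epochs, α ∈ {0, 0.1}, three seeds, measured as the mean off-diagonal
cosine similarity of the pooled o vectors. Softmax and log-sum-exp are
max-shifted; the CLN/layer-norm variance floor is 1e-5; overlap resolution
ties break deterministically; all randomness flows from explicit
`numpy.random.Generator` seeds, making repeated runs bit-identical.

## Known limitations

Flat NER only (no nested or discontinuous mentions); no pretrained-weight
import or tokenizer training; no document-level context; single-threaded
NumPy training is practical only at toy scale; the in-batch discrimination
loss has no memory bank or negative queue. Whether the guidance loss should
pool maps from all layers or only the guided subset is genuinely ambiguous
in the lineage this design follows; the package defaults to the guided
subset and exposes `guided_layers` to choose otherwise.
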