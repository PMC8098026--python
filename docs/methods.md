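# Methods

## Problem and model

Drug–target interaction (DTI) prediction is cast as binary classification
over pairs (S, A): S a SMILES string (characters = atoms/bonds from a
depth-first traversal of the molecular graph), A an amino-acid sequence
(23-letter alphabet plus an explicit unknown symbol X). The model maps the
pair to an interaction probability P ∈ (0, 1) through four stages: FCS
tokenization, content+positional embedding with transformer augmentation,
an explicit pairwise interaction map with CNN aggregation, and a logistic
decoder. The premise throughout is that interactions are sub-structural:
a particular chemical group meeting a particular protein motif.

### FCS mining

Mining maintains a vocabulary V (PAD index 0, UNK index 1, then the
observed single characters) and a tokenized corpus W. Each round counts
adjacent token pairs, merges the most frequent pair (A, B) into AB
everywhere, appends AB to V, and repeats until the best count drops below
θ or |V| reaches ℓ. Choices the mining loop's definition leaves open, and
how this implementation fixes them:

- **Overlap handling.** Pair occurrences are counted greedily
  left-to-right without overlap ("AAA" holds one (A, A)), so a pair's count
  equals the number of replacements its merge will realize. Counting and
  rewriting can therefore never disagree.
- **Ties.** Equally frequent pairs are broken by the lexicographically
  smallest concatenated string, then the smallest (left, right) pair —
  deterministic across platforms.
- **Encoding new sequences** replays the merge list in learned order
  (merge-rank priority), the standard scheme for this family of
  tokenizers. Characters unseen at mining time are kept verbatim in the
  token list (they map to UNK at indexing time), which makes
  join(tokenize(s)) == s hold unconditionally.
- **SMILES pre-tokenization.** Initial tokens are single characters, so
  two-character atoms such as Cl must be learned as merges.
- **ℓ defaults to unbounded** (θ-driven stopping); the full-scale θ is 500
  per corpus side. Drug and protein vocabularies are always mined
  separately.

The merge table is a plain TSV (`left<TAB>right<TAB>frequency` in merge
order, two header comment lines recording θ, ℓ and the alphabet) and is
hash-verified when a checkpoint is reloaded.

### Embedding and augmentation

A token sequence is cut/padded to a fixed length (Θ_d = 50 drug, Θ_p = 545
protein at full scale; truncation keeps the prefix). Embeddings are
E_i = W_cont·onehot(token_i) + W_pos·onehot(i), both tables learnable
(truncated normal, σ = 0.02), then Ẽ = Transformer(E): post-norm encoder
layers (self-attention + 2-layer ReLU feed-forward), full-scale defaults 2
layers, 12 heads, width 384, intermediate 1536, dropout 0.1. PAD positions
are excluded from attention (additive −1e9 mask on PAD keys) so padding
cannot leak into real-token context; this is verified by perturbation
tests. A zero-layer stack is the identity, which is also how the
no-transformer ablation is realized.

### Interaction head

I[j, i] = F(Ẽᵈ_j, Ẽᵖ_i) with F the dot product by default (sum and average
are available but collapse to rank-1 structure and are not recommended);
I is Θ_d × Θ_p with rows = drug positions. One convolution (3 filters, 3×3
kernel, stride 1, valid padding) with ReLU gives O; the decoder is a single
linear unit on flatten(O) with a logistic link. PAD rows/columns of I are
left unmasked and pass through the CNN; the decoder can learn to discount
them, and the labeled map exposed to users excludes them. The loss is mean
binary cross-entropy (the negative of the Bernoulli log-likelihood);
probabilities are clamped to [1e-7, 1 − 1e-7] before the log.

Ablation variants are model configurations, not separate code paths:
`no_cnn` flattens I straight into the decoder; `no_augembed` feeds the map
with E instead of Ẽ; `no_interaction` removes both the transformer and the
map, pooling each side by a masked mean over real positions and
concatenating into the decoder.

### Training and evaluation protocol

Adam (β = 0.9/0.999, ε = 1e-8) on shuffled minibatches; full-scale defaults
lr 1e-5, batch 64, 30 epochs. After every epoch the validation ROC-AUC is
computed and the single best epoch's weights are restored at the end.
Metrics are self-contained: ROC-AUC is the rank statistic
P(score_pos > score_neg) + ½P(tie); PR-AUC is average precision (step-wise
integral of precision over recall, tied scores as one block); the decision
threshold is chosen on the *validation* split as the best-F1 midpoint of
consecutive unique scores (ties to the lowest threshold), and sensitivity/
specificity are reported at that threshold on the test split. Dataset
assembly follows the standard protocol: Kd < 30 is positive (strict
inequality, boundary negative), negatives are drawn uniformly from unseen
drug×protein pairs — excluded against positives of *all* splits to avoid
label leakage — and splitting is a seeded permutation sliced 7:1:2 with
largest-remainder rounding. All randomness flows through explicitly seeded
`numpy.random.Generator`s.

## Numerical implementation

No GPU framework is used: `dtimap.nn` is a reverse-mode autograd on numpy
float64 arrays with exactly the operations the model needs (broadcasting
arithmetic, matmul, reductions, indexed gather/scatter, softmax with a
fused backward, an im2col-style valid convolution). float64 keeps the
finite-difference gradient check sharp: backprop agrees with central
differences to < 1e-3 relative error on every parameter tensor of a toy
model, and per-op gradients are tested the same way. Determinism: fixed
seeds give bitwise-identical training runs within a platform; dropout is
active only in training mode.

## Synthetic benchmark (what it does and does not show)

`dtimap.synthetic` generates uniform random strings over an 8-symbol
drug alphabet and the 20 amino acids, plants motifs by overwriting a
random window (lengths stay in range), and labels a pair positive iff the
drug contains the drug motif and the protein contains the protein motif,
flipping with probability ε. Defaults — the benchmark conditions used by
the tests and `scripts/acceptance.py` — are 80 drugs × 80 proteins, drug
lengths 16–24, protein lengths 40–60, motif insertion probability 0.5,
drug motif SNO (length 3), protein motif KWYF (length 4), 2000 balanced
pairs. Mining thresholds are θ = 30 (drug) and θ = 20 (protein), roughly
3× each corpus's expected background adjacent-pair count, so planted
motifs mine reliably while random pairings mostly do not.

The rule is deterministic given the strings, so with balanced classes the
Bayes-optimal held-out ROC-AUC is exactly 1 − ε; tests use this as a
leakage ceiling (a model beating it is broken, not good). What passing
shows: the miner finds frequent sub-structures, the interaction model can
learn a conjunctive sub-structural rule from labels alone, and the map
localizes the responsible pair. What it does not show: chemical validity
(SMILES here are arbitrary strings), realistic binding physics, class
imbalance of real assay panels, or generalization to unseen chemistry —
real-data performance requires the full-scale profile on real corpora.

## Desk profile

The full-scale architecture (embedding 384, Θ_p = 545) is the documented
default but is far larger than the synthetic benchmark warrants. The
`desk` profile — embedding 16, 1 layer, 4 heads, intermediate 64,
Θ_d = 24 / Θ_p = 48, lr 1e-3, batch 64, 30 epochs — is the package's
chosen configuration for the synthetic problem sizes above; the overfit
fixture (64 noise-free pairs, full-batch) memorizes in well under 100
steps at this profile.

## Known limitations

- Single-character SMILES initialization means multi-character atoms
  (Cl, Br, bracket atoms) are only units if mining merges them; an
  atom-aware pre-tokenizer is deliberately out of scope.
- The interaction map is position-indexed; the same sub-structure at two
  positions occupies two rows with different positional embeddings.
- Valid-padding CNN makes the decoder input size depend on Θ_d/Θ_p; the
  checkpoint records both so shapes always reproduce.
- Explanations rank map intensities; they are hypotheses about binding
  sub-structures, not mechanistic binding-site assignments.
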