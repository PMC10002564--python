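# Methods

## Scope and design

`mseddi` implements a three-channel neural architecture for multi-class
DDI event prediction under cold-start evaluation, plus the two
unsupervised embedders it consumes and a synthetic-study generator that
makes the whole pipeline testable offline.  No deep-learning framework is
used: a small reverse-mode autodiff engine (`mseddi._tensor`) provides
exactly the differentiable primitives the model needs, with analytic
gradients per operation (the molecular-graph tests verify them against
central finite differences at 1e-4).  TransE and CBOW use hand-derived
gradients in plain NumPy — both objectives are simple enough that a tape
brings no benefit.

## Unsupervised drug representations

**Knowledge-graph channel input.**  TransE embeds entities and relations
in one space so that `h + r ≈ t` for true triplets, scored by
`f = −‖h + r − t‖` (L2 by default; L1 available).  Training follows the
original recipe: uniform init in `±6/√dim`, relations normalized once at
init, entities renormalized to unit L2 at the start of every epoch,
minibatch SGD on the margin ranking hinge with one uniformly corrupted
negative per positive (head or tail side chosen 50/50, resampled up to
100 times so the negative is not itself a positive; a KG too dense to
corrupt raises a sampling error).  Defaults: dim 32, margin 1.0, lr 0.01,
500 epochs, batch 128 — sized for toy KGs of order 10²–10³ triplets.
Drugs absent from the KG receive the zero vector and a warning, so a
dataset can still be scored when its KG coverage is partial.  The
embedder is pretrained on the full KG and frozen; it never sees event
labels.

**Sequence channel input.**  SMILES tokenization is character-level with
three chemistry-aware merges: `Cl`, `Br`, and bracket atoms `[...]` are
single tokens (unbalanced brackets are a tokenization error).  The CBOW
embedder uses a full softmax over the token vocabulary — at SMILES
vocabulary sizes (tens of tokens) the negative-sampling approximation
would only add variance.  Context windows (half-width 5) truncate at
sequence boundaries rather than pad.  Defaults: dim 32, lr 0.025, 50
epochs, SGD in fixed iteration order, so training is bit-reproducible
from the seed.  Per-drug sequences are embedded by row lookup into `W1`
and brought to exactly 100 rows: shorter sequences are zero-padded;
longer ones are split into consecutive 100-row chunks whose rows are
averaged position-wise over the chunks that actually contain a row at
that offset.  This mask-aware mean was chosen over a plain chunk mean so
that a trailing short chunk never dilutes real signal with padding zeros;
the padding invariant (rows beyond the folded length are exactly zero)
is load-bearing for the sequence channel's convolution.

**Graph channel input.**  RDKit parses SMILES into heavy-atom graphs.
Atom features use the eight standard attribute groups (element one-hot
over {C,N,O,S,F,Cl,Br,I,P}+other, degree, formal charge, chirality tag,
attached-H count, hybridization, aromaticity, mass/100); bond features
are bond-type, conjugation, ring and stereo one-hots (36 and 12 slots
respectively).  All three encoders share a synchronous message-passing
scheme built from linear maps — aggregate `Σ_y (W_a h_y + W_e e_xy)`
over neighbors, update `LeakyReLU(W_h h + W_u a)` — run for T = 3 rounds
on states of width `dim_cse` (default 32).  Because the aggregation is
linear in the edge features, each node's incident-edge feature *sum* is
precomputed once per molecule; batching uses dense padded adjacency
tensors with masks, and every readout is mask-aware so padded atoms can
never influence the output (permutation invariance is asserted in tests).
The readouts give the three variants their character:

* `mpnn` — a recurrent attention pooling in the Set2Set spirit: a query
  vector attends over node states three times and is updated from the
  attended sum through a tanh linear layer.  The LSTM cell of the
  published Set2Set is deliberately omitted; the structural signature
  (iterative attention with a query carried across steps) is kept.
* `weave` — masked node-state sum followed by a linear tail.
* `afp` — three stacked gated-attention global pooling layers: per-node
  logits from `[graph state; node state]`, masked softmax, value-mapped
  context added to the graph state through LeakyReLU.

The encoders are trained **jointly with the pair model** (gradients flow
from the classification loss into the message passing); per-batch, each
distinct drug is encoded once and pairs gather rows, which both saves
compute and keeps the cold-start audit exact.

## The pair model

Hidden width `dim` (desk default 32; the published full-scale setting is
64) with dropout 0.2 applied to each channel output and inside both
attention blocks.  Batch norm uses the biased batch variance for both
normalization and its running buffers (momentum 0.1); a training batch
of one element is rejected rather than silently normalized.  Convolution
kernels are width 3, stride 1, zero padding 1 (length-preserving) in both
the sequence channel (over 200 spliced positions, then max-pool kernel 4
stride 4 → 50 rows) and the graph channel (along the 6-row stack axis);
the printed operation order Conv → BN → MaxPool → LeakyReLU is followed.
Self-attention uses 4 heads of width `dim/4` in both the sequence channel
and the fusion block (head count is a free choice; the two blocks have
separate weights).  The sequence channel's feed-forward block is
`dim → 2·dim → dim` with GELU; its output is layer-normalized and added
to the convolutional features when the residual flag is on.  Fusion
stacks the enabled channels' rows (2 + 50 + 6 = 58 with all channels),
applies self-attention + layer norm (or plain concatenation when
disabled), flattens row-major and predicts through a final MLP block.
The model is order-sensitive in the pair; an optional reverse-pair
augmentation flag duplicates training pairs in both orders.

## Training protocol

Loss is cross-entropy on logits with an L2 penalty of weight 1e-5 added
to gradients inside Adam ("loss weight" at its published scale).  The
desk profile trains 50 epochs at batch 64 with Adam lr 1e-3 annealed to
zero by a cosine schedule — without annealing, models hover just below
their accuracy ceiling at this short schedule; the annealing is applied
uniformly to every configuration.  The published full-scale profile
(batch 512, 350 epochs, lr 1e-4) is available as
`paper_train_config()`.  A trailing batch of size 1 is folded into the
previous batch (batch-norm constraint).  Every randomness source (init,
shuffling, dropout, corruption sampling) derives from explicit seeds;
identical seeds give bit-identical weights and predictions on the same
platform.

The cold-start split shuffles *drugs* into k near-equal subsets; for
each fold the subset is "new" and the rest "known"; DDI records route to
train / Task-1 / Task-2 by how many of their drugs are new.  The model
object records every drug index it touches during forward passes, and
tests assert the trained model's access set is contained in the known
drugs — features for all drugs may be pretrained (they are label-free),
but no new drug's representation ever enters a training step.

Metrics: top-1 accuracy with argmax ties resolved toward the lowest
class index; micro AUC/AUPR computed on the flattened `n×Nl` one-hot
indicator vs probability matrices; macro F1 as the unweighted mean over
all `Nl` classes with absent classes contributing zero; per-event
one-vs-rest AUC/AUPR reported as NaN when a class is absent from the
truth.  The implementations delegate to scikit-learn; the test suite
checks them against brute-force pairwise-concordance, threshold-stepping
and per-class oracles to 1e-9 on random instances.

## The synthetic study

The generator emulates the statistical shape the pipeline assumes, not
any real event-frequency distribution.  Each of `n_drugs` (default 40)
drugs gets a latent class (round-robin over `n_classes`, default 4); each
class draws SMILES from its own hard-coded family of 20 valid strings
(alkanes, diols, benzene derivatives, diamines, dichlorides, ethers,
acids, dithiols, bromoalkanes, pyridines) so tokens, graphs and lengths
all separate classes; the KG links every drug to its class node plus 60
uniform noise triplets over auxiliary entities; and every unordered drug
pair receives the event assigned to its class pair by a deterministic
round-robin map, redrawn uniformly over all events with probability
`label_noise` (default 0.05).  The expected fraction of pairs matching
the planted rule is therefore `(1−p) + p/Nl`, which gives the accuracy
ceiling (~0.956 in expectation at the defaults) against which results
should be read.  What the generator does **not** emulate: realistic
event-frequency imbalance, drugs with overlapping or ambiguous chemistry,
KGs whose relation structure carries more than class membership, and
DrugBank-scale sizes — so passing tests demonstrate that the machinery
learns and fuses recoverable multi-channel signal, not field performance
on real pharmacovigilance data.

## Problem sizes

The test suite and the acceptance script run the 40-drug study with the
desk profile: TransE 500 epochs on ~100 triplets, CBOW 50 epochs on 40
sequences, model training 50 epochs on ~500 pairs of fold 0 of the
5-fold split; the fusion-advantage check trains the full model and three
single-channel ablations on seeds 1–3.  These sizes were chosen so a
complete run takes minutes on a single CPU while leaving every planted
structure comfortably recoverable.

## Known limitations

* Set2Set and AttentiveFP readouts are structural simplifications (no
  LSTM / GRU cells); encoder depths and dimensions are package defaults,
  not published values.
* TransE hyperparameters for the full-scale biomedical KG (dimension,
  margin, schedule) are not published; desk defaults are chosen for toy
  KGs.
* Micro AUC at high class counts is dominated by easy negatives; the
  macro-F1 zero convention makes small test folds look pessimistic when
  some events never occur in them.
* The fold/pad averaging rule and the tokenizer granularity are
  documented choices among several defensible readings.
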