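# Methods

## The model

`dualdta` regresses a continuous binding affinity $\hat y_{d,t}$ (pIC50/pKd
scale) for a drug–target pair from two coupled views of the pair.

**Sequence branch.** The drug SMILES is tokenized at atom level (every heavy
atom is one token; ring digits, bond symbols, and branch parentheses are
their own tokens) and the protein at residue level; each sequence ends in a
special `[EOS]` token. Per entity the encoder applies

1. a learned embedding followed by an affine map,
2. a *group enhancement* step: channels are split into $G$ groups; per
   position each group is scored by the inner product of its features with
   the group's channel mean, the scores are normalized over (unmasked)
   positions ($t' = (t - \mu)/(\sigma + \varepsilon)$), and the features are
   gated with $\mathrm{sigmoid}(w_g t' + b_g)$,
3. a stack of bidirectional LSTMs (each direction half the width; padded
   steps carry state through unchanged).

The resulting per-token features $F_t \in \mathbb{R}^{L_t\times D}$ and
$F_d \in \mathbb{R}^{L_d\times D}$ are pooled by **masked multi-head link
attention**: a linear map scores every position per head, masked positions
are shielded with $-10^9$ before a per-head softmax over positions, and the
attention matrix multiplies the raw features ($H\times D$ pooled block per
stream). Three separately parameterized attention blocks pool the target,
the drug, and their concatenation (with concatenated masks). The three
pooled blocks are flattened head-major, concatenated to
$R_{seq} \in \mathbb{R}^{3HD}$, and passed through a residual feed-forward
layer, $\mathrm{out}_{seq} = \mathrm{ReLU}(W R_{seq} + b) + R_{seq}$.

**Structure branch.** The protein residue graph uses a binary contact map:
$C_{ij} = 1$ iff the distance between residue representative atoms (Cβ; Cα
for glycine) is strictly below 8 Å. Nodes are restricted to the *binding
range* — the contiguous envelope of the union of annotated binding-site
intervals (1-based inclusive in annotation files, 0-based half-open
internally), capped at 300 residues by symmetric truncation, falling back to
the full sequence when no annotation exists. The drug graph has heavy atoms
as nodes and bonds as edges, in the parser's native atom order — the same
order the tokenizer uses, so token features land on the right node. A single
**virtual node** joins the two graphs: it is adjacent to every residue and
atom node, and no direct target–drug edge exists, so any residue–atom pair
is exactly two hops apart. Residue and atom nodes read their features from
the sequence branch's per-token outputs; the virtual node takes the mean of
the two `[EOS]` features; a 3-channel one-hot source type (target / virtual
/ drug) is appended. The fusion graph is encoded by $L$ GIN convolutions,
each followed by batch normalization, and sum-pooled over all nodes
(including the virtual node) to $\mathrm{out}_{str}$.

The GIN update follows the printed form
$\mathrm{out}_i = \mathrm{MLP_{outer}}\big(x_i + \sum_{j\in N(i)}
\mathrm{MLP_{inner}}(x_j)\big)$, which applies an MLP to each neighbor
*inside* the sum. This differs from textbook GIN
($\mathrm{MLP}((1+\epsilon)x_i + \sum_j x_j)$); both variants are
implemented (`GnnConfig.variant`), the default is the former, and a
regression test pins that the two differ.

**Fusion head.** $\hat y = \mathrm{FFN}(\mathrm{concat}(\mathrm{out}_{str},
\mathrm{out}_{seq}))$, a two-layer MLP with one hidden layer.

**Training.** MSE loss, Adam. A *warm-up* stage first trains the sequence
branch alone through a temporary scalar head on $\mathrm{out}_{seq}$, so the
graph's node features start meaningful; joint training then optimizes
everything end to end (warm-up transfers weights, nothing is frozen), with
early stopping on validation MSE and best-checkpoint restoration. The
warm-up head doubles as the sequence-only ablation model. Labels are
centered by the train-set mean (stored with the checkpoint and added back at
prediction time); this is ordinary regression practice and saves the epochs
a near-zero-initialized network would otherwise spend learning the global
offset.

## Numerical core

No GPU tensor framework is used: the package ships a small reverse-mode
automatic-differentiation engine over numpy (`dualdta.nn`) with exactly the
operations the model needs (broadcasting arithmetic, matmul, elementwise
nonlinearities, stable softmax, gather/scatter for fixed-topology message
passing). Gradients of every composite path — including the BiLSTM
recurrence with padding masks and the scatter-based GIN aggregation — are
verified against central finite differences in the test suite. Everything
runs in float64 on a single CPU.

Numerical conventions worth knowing:

* masked attention uses $-10^9$ as $-\infty$; after the stable softmax the
  masked weights underflow to exactly 0, and an explicit multiply by the
  mask makes the exact-zero postcondition independent of score scale (tests
  assert both zero weights and zero gradients at masked positions);
* group-enhancement statistics are computed over unmasked positions only,
  which is what makes the encoder output invariant to padding; a
  zero-variance score vector (e.g. constant features) degrades gracefully
  via the $\varepsilon$ in the denominator;
* batch normalization uses batch statistics during training and running
  statistics in eval mode, so single-graph inference is deterministic;
* the virtual node's printed self-loop is available
  (`virtual_self_loop=True`) but defaults to off, since the GIN update
  already contains the self term.

## Ablations

Each component can be removed while keeping the rest intact, mirroring the
method's component grid: group enhancement off; link attention replaced by
masked mean pooling (replicated across heads); virtual node replaced by two
independent GIN encoders whose pooled outputs are summed; source one-hot
off; warm-up off (`warmup_epochs=0`); sequence-only (prediction from
$\mathrm{out}_{seq}$ alone); graph-only (node features from the raw
embedding map, prediction from $\mathrm{out}_{str}$ alone — warm-up is
skipped there because there is no sequence readout to warm).

## Synthetic data generator

The generator exists so that the full pipeline — tokenization, structure
parsing, contact maps, binding-range slicing, fusion, training, attention
analysis — is exercisable and testable without any downloads. What it
emulates, and what it deliberately does not:

* **Molecules** are assembled from a fragment grammar of
  concatenation-safe SMILES pieces (rings, chains, carbonyls, halogen
  branches), validated with RDKit and resampled on failure; 5–40 heavy
  atoms. This guarantees chemical validity without modeling valence
  explicitly. No stereochemistry, no conformers.
* **Targets** are sequences of 50–600 residues (the study uses 50–150) with
  representative-atom coordinates from a self-avoiding 3D random walk
  (step ≈ 3.8 Å, 4 Å exclusion radius, mild direction persistence). The
  walk is not a folded protein; it is tuned only to give 8 Å contact maps
  that are sparse but non-trivial (≈1–10% off-diagonal density, measured in
  tests). Each target carries 1–3 non-overlapping binding intervals whose
  envelope stays within the 300-residue cap.
* **Pocket composition bias.** Residues inside binding intervals are drawn
  from an alphabet enriched in H/W/Y/F/C/D (0.60 total probability vs 0.30
  under the uniform background). Real binding pockets are compositionally
  distinct from bulk sequence; this bias is also what gives a sequence-side
  attention mechanism a cue that can generalize to unseen targets.
* **Labels** are linear: intercept 4.0 plus element-count terms (C 0.04,
  N 0.12, O 0.10, S 0.08, F/Cl/Br 0.18 per atom) plus residue-count terms
  over the binding-range envelope (H 0.07, W 0.09, Y 0.05, F 0.04, C 0.04,
  D 0.06 per residue), plus N(0, 0.1²) noise. The label depends *only* on
  residues inside the binding range, so binding-site slicing provably
  preserves the signal, and at zero noise ordinary least squares on
  (element counts, range residue counts) recovers the planted weights
  exactly — a sanity oracle in the test suite.

Because the planted signal is linear and fully determined by compositions,
passing the end-to-end study shows that the pipeline wiring (token↔atom
correspondence, range slicing, feature routing through the fusion graph,
optimization) works — it does not show that the architecture captures the
nonlinear physics of real binding data.

## The end-to-end study

`dualdta.benchmark.run_end_to_end_study` fixes the study conditions:
200 drugs × 50 targets at pair density 0.2 (2,000 records), noise SD 0.1,
and a **cold unseen-target split** (5-fold 7:1:2 protocol, fold 0): no test
or validation target appears in any training pair. The cold split is the
regime the structure branch exists for — on a random pair split the
sequence branch can memorize per-target contributions and matches the full
model, so that split cannot separate the branches; on unseen targets the
binding-range graph is what transfers.

The study model is deliberately small (embedding 32, one BiLSTM layer, 4
heads, 4 groups, dropout 0.1; two GIN layers of width 32; head width 64;
warm-up 6 epochs, joint ≤ 20 with patience 6, batch 64, Adam lr 2·10⁻³):
the planted linear signal does not require more capacity, and the study
runs in minutes on one CPU. All of these are file-configurable
(`config.yaml`, see `dualdta.config`).

The study reports test MSE/CI/rm² of the full model, the mean-predictor
baseline MSE, the sequence-only ablation's MSE, and the attention region
statistic: z-scored per-residue attention (head-averaged target attention,
EOS dropped), pooled over held-out targets, compared inside vs outside the
binding range with a one-sided Welch t-test. Z-scoring per sequence is used
because raw attention rows sum to 1 and are not comparable across sequence
lengths; it also yields signed weights (negative outside the range when the
model concentrates inside).

## Metric conventions

* **CI**: over all pairs with $y_i > y_j$, credit 1 if
  $\hat y_i > \hat y_j$, 0.5 on prediction ties, 0 otherwise; undefined (and
  rejected) when all labels tie. Cross-checked against `lifelines`.
* **rm²**: single-direction Roy form
  $r_m^2 = r^2\,(1 - \sqrt{|r^2 - r_0^2|})$ with $r_0^2$ the coefficient of
  determination of the best through-origin fit $y \approx k\hat y$,
  $k = \sum y\hat y / \sum \hat y^2$. Note $r_m^2 \le r^2$ always, and a
  pure constant shift of perfect predictions strictly lowers it.

## Known limitations

* The autodiff engine is single-threaded numpy; it is sized for the study
  scale (thousands of pairs, sequences of a few hundred residues), not for
  benchmark-scale corpora.
* The binding range is the contiguous envelope of the annotated sites, not
  their exact union; sites far apart in sequence inflate the envelope (the
  generator keeps envelopes within the cap, real annotations may not).
* Attention statistics are descriptive, not causal explanations; the
  interpretation module reports them with their tests and nothing more.
* Structure input expects one residue per position with a Cβ (or Cα)
  atom; residues missing both are rejected rather than imputed, and
  multi-chain files require an explicit chain selection.
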