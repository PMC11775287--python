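# dualdta

Dual-modality drug–target affinity (DTA) regression with binding-site-focused
graph fusion.

Predicting how strongly a small molecule binds a protein (pIC50/pKd) from the
drug's SMILES and the protein's sequence/structure is a core step in virtual
screening. Sequence-only models ignore structure; drug-graph models ignore
protein structure; and joining a full protein residue graph (hundreds of
nodes) to a drug graph (tens of nodes) is both unbalanced and expensive.
`dualdta` addresses this with two coupled branches:

* a **sequence branch**: atom-level SMILES tokens and residue-level protein
  tokens → embedding → group-wise feature enhancement → BiLSTM → three masked
  multi-head *link attention* pooling blocks (target, drug, concatenated) →
  residual feed-forward → `out_seq`;
* a **structure branch**: a residue contact graph ($C_{ij}=1$ iff the Cβ–Cβ
  distance < 8 Å) restricted to the *binding range* — the contiguous envelope
  of annotated binding sites — joined to the RDKit bond graph of the drug by
  a single **virtual node** adjacent to every node of both graphs, encoded by
  stacked GIN convolutions with batch norm and sum pooling → `out_str`.

Node features of the fusion graph come from the sequence branch (per-token
features land on the matching residue/atom nodes; the virtual node takes the
averaged `[EOS]` features), so both graphs live in one feature space. The
affinity is read out as `FFN(concat(out_str, out_seq))`. Training is MSE +
Adam with a warm-up stage that first fits the sequence branch alone.
Evaluation covers random 5-fold cross-validation (7:1:2) and the cold-start
protocols (unseen drug / unseen target / both), with MSE, concordance index
(CI) and the Roy rm² metric. Attention weights over residues can be compared
across binding site / binding range / outside regions.

Everything runs on plain numpy — the package includes a small reverse-mode
autodiff core (`dualdta.nn`) that is gradient-checked against finite
differences — plus RDKit (molecules), gemmi/Biopython (structures, FASTA),
and scipy/pandas. A synthetic-data module generates valid molecules, protein
sequences with plausible 3D backbones, binding annotations, and affinities
from a planted function of binding-range and drug composition, so the entire
pipeline is testable offline. See `docs/methods.md` for the model and the
generator in detail.

## Worked example

Generate a small synthetic study (30 drugs × 10 targets, 150 records), train
on a cold unseen-target split, and inspect attention for one pair:

```sh
dualdta gen-data --n-drugs 30 --n-targets 10 --density 0.5 --seed 7 --out study
dualdta train --data study/records.csv --targets study/targets \
    --config config.yaml --split unseen-target --fold 0 --seed 7 --out run
dualdta explain --model run/model.npz --data study/records.csv \
    --targets study/targets --pair 0 --out explain
```

with `config.yaml`:

```yaml
model:
  encoder: {embed_dim: 32, lstm_layers: 1, heads: 4, gem_groups: 4, dropout: 0.1}
  gnn: {n_layers: 2, hidden_dim: 32, mlp_depth: 2, variant: paper_eq16}
  head_hidden: 64
train:
  warmup_epochs: 4
  joint_epochs: 12
  lr: 0.002
  batch_size: 32
  seed: 7
  patience: 6
```

The train command prints the held-out metrics (this run takes ~45 s on one
CPU):

```
{"mse": 0.5082173913851924, "ci": 0.9139784946236559, "rm2": 0.4499171349485994, "n": 31}
```

MSE is the squared error on the 31 test pairs, all of whose targets were
never seen in training; CI 0.91 means 91% of label-ordered test pairs are
ranked correctly. The explain command writes per-residue and per-atom
attention tables plus region statistics:

```
{"binding_site": {"mean": -0.28, "std": 0.98, "n": 53},
 "binding_range": {"mean": 0.62, "std": 0.77, "n": 17},
 "outside": {"mean": 0.19, "std": 1.00, "n": 23}}
```

(z-scored attention per region for that single pair; systematic elevation
inside the binding range is a population-level statement — see the
reproduction script below, which pools over all held-out targets).

The library mirrors the CLI: `gen_dataset`, `prepare_pairs`, `make_splits`,
`DTAModel`, `train_model`, `evaluate`, `extract_attention`, `region_stats`.

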