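# wfdta

Drug–target binding-affinity (DTA) regression from a word-frequency
dipeptide encoding of proteins and molecular graphs of drugs.

Virtual screening needs more than an interacts/doesn't-interact label: the
*strength* of a drug–target interaction (a pKd value, or a KIBA composite
score) is the quantity that ranks candidate compounds. `wfdta` is a
toolkit for researchers building such regressors on kinase-panel-style
benchmarks. It provides:

* **Protein encoding** — n-peptide composition vectors
  `v_i = n_i / (L − n + 1)` (widths 25 / 625 / 15,625 for n = 1/2/3),
  weighted by corpus word frequency `wf_i = (w_i/N) · p_i/(L − n + 1)`,
  where `w_i` counts the training sequences containing peptide *i*. Rare
  peptides are damped (the reverse of IDF weighting, also provided for
  comparison). Weights are fitted on training data only.
* **Drug graphs** — RDKit-parsed SMILES as graphs with 78-dim one-hot atom
  features (element, atomic rank, H count, implicit valence, aromaticity)
  and bidirectional bond edges.
* **Four hybrid regressors** — a graph branch (GCN, GIN, GAT, or GAT→GCN)
  and a 1D-convolutional protein branch, each embedding to 128 dims, fused
  through 512- and 128-unit dense layers to a scalar affinity. Built on a
  compact NumPy autodiff engine; fully deterministic under a seed.
* **Evaluation** — concordance index (CI), MSE, and Pearson r.
* **Feature analysis** — per-feature statistics and random-forest variable
  importance (VIM) with dipeptide labels, e.g. to ask *which* dipeptides
  drive predicted affinity.
* **Synthetic benchmarks** — planted-signal datasets
  `y = β0 + β_pep·v_PE(p) + β_size·heavyatoms(d) + ε` over random proteins
  and template-decorated drug-like SMILES, so the whole pipeline is
  testable without downloads.

Dataset utilities cover Davis-style dense Kd matrices (with
`pKd = −log10(Kd/10⁹)`) and KIBA-style long tables, the
≥ 10-interactions-per-drug-and-protein filter (iterated to a fixpoint),
and seeded 80/20 pair splits.

## Worked example

```python
import wfdta as w

# a 20-protein x 10-drug planted-signal benchmark
spec = w.SyntheticSpec(seed=1, n_proteins=20, n_drugs=10)
ds = w.make_dataset(spec)
train, test = w.train_test_split(ds, 0.8, seed=1)

feat = w.PairFeaturizer(n=2).fit(train)         # WF weights fit on train only
cfg = w.ModelConfig(branch_kind="gat_gcn", protein_input_dim=625,
                    batch_size=32, learning_rate=1e-3, epochs=30, seed=1)
model, history = w.train(w.DTAModel(cfg), feat.transform(train), cfg)
report = w.evaluate(test.affinities, w.predict(model, feat.transform(test)))
print(f"train MSE {history.train_mse[-1]:.3f}  "
      f"test: MSE {report.mse:.3f} CI {report.ci:.3f} r {report.pearson:.3f}")
```

```
train MSE 0.086  test: MSE 0.114 CI 0.718 r 0.771
```

Training MSE (0.086) falls well below the predict-the-mean baseline (the
label variance, 0.258 here), and on the 40 held-out pairs the model orders
affinities much better than chance (CI 0.5): the planted dipeptide and
molecular-size signals are being learned by both branches.

The same pipeline is scriptable from the shell:

```bash
wfdta simulate -o sim --seed 1
wfdta train -i sim/affinities.csv -o run --branch gat_gcn \
      --epochs 30 --batch 32 --lr 1e-3 --seed 1
wfdta vim -i sim/affinities.csv -o vim --trees 500 --seed 1
```

`wfdta vim` prints the top-ranked dipeptide — on synthetic data the
planted `PE`, with the large majority of the normalized importance — and
writes the full ranking plus a 25×25 dipeptide grid.

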