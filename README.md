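# mvfae

Multi-view factorization autoencoder with interaction-network constraints,
for integrating several feature spaces ("views", e.g. multi-omics assays)
measured on the same samples.

Each view gets a nonlinear multi-layer encoder into a shared latent space
and a **single linear decoder matrix** `Y`, so reconstruction is the exact
factorization `Z = X @ Y`. Two graph-Laplacian regularizers inject
structure:

- **feature-network term** `Trace(Y L_G Yᵀ)` — decoder columns (feature
  embeddings) of interacting features, per a symmetric non-negative
  feature–feature network `G`, are pulled together;
- **view-similarity term** `Trace(Xᵀ L_S X)` — each view's sample latents
  are pulled toward the fused absolute-cosine patient-similarity network
  averaged over all views and the summed latent.

Latents are fused by summation and classified by a linear head; the full
objective is `cross-entropy + η·reconstruction + α·feature-term +
β·view-term`. Networks are Frobenius-normalized and decoder columns are
projected to norm `1/√p` after every optimizer step so the regularizers
share a scale across views. Training is full-batch adaptive-moment descent
with decoupled weight decay (1e-4), a two-phase learning-rate schedule
(5e-4 then /10, 500 iterations each by default), and model selection by
best validation accuracy on a 70/10/20 split. Everything, including the
gradients of the composite objective, is implemented in NumPy; no deep
learning framework is required.

## Layout

| module | contents |
| --- | --- |
| `mvfae.netprep` | edge lists, confidence filtering, one-step random-walk densification, winsorization, cross-feature network derivation (`A G Aᵀ`), Frobenius normalization, graph Laplacians |
| `mvfae.model_core` | per-view encoders, linear decoders, latent fusion, classifier, decoder-column projection, checkpoints |
| `mvfae.losses` | every objective term, similarity networks, loss breakdowns |
| `mvfae.training` | splits, AdamW training loop with analytic gradients, AP/AUC/accuracy evaluation, experiment runner |
| `mvfae.synthdata` | synthetic multi-view bundles with planted factors, module-structured loadings, consistent networks; z-score/log/filter/winsorize preprocessing |
| `mvfae.cli_io` | delimited-file I/O, sample alignment, YAML configs, the `mvfae` CLI |

## CLI

```sh
# write a synthetic bundle (TSV views, networks, labels + manifest.json)
mvfae generate --n 200 --views 60:0.05,40:0.05 --k-true 6 --seed 1 --out data/bundle

# train; writes metrics.json, history.tsv, checkpoint.npz, run_config.yaml
mvfae train --data data/bundle --out runs/full --seed 1 \
    --alpha 100 --beta 1e-4 --lr 5e-3 --iters-per-phase 250

# ablations: --no-feat-int (alpha=0) and/or --no-view-sim (beta=0)
mvfae train --data data/bundle --out runs/plain --seed 1 --no-feat-int --no-view-sim

# score a run's checkpoint on its own stored split
mvfae evaluate --run-dir runs/full --data data/bundle --split test
```

`mvfae train --config run.yaml` accepts the same options from a YAML file
(flags override); a `synthetic:` section may replace `--data` to generate
the bundle on the fly.

Weight scales to know about: the reconstruction term is a raw squared
Frobenius norm (`O(N·p)`) while the normalized feature-network term is
`O(1)`, so `alpha` must be large (≈100 at benchmark scale) for the network
to shape the decoder, and `beta` small (≈1e-4) because the similarity
trace grows with the squared latent scale.

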