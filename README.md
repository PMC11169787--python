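# spalp

Prediction of unknown miRNA–disease associations from a known association
list, by combining:

1. **Disease semantic similarity** over an ontology DAG (per-ancestor
   contributions decaying by a factor Δ per hierarchy step, best path wins),
   and **miRNA functional similarity** (best-match average of disease
   similarities between two miRNAs' associated disease sets).
2. **Sparse autoencoder** latent features of the binary association matrix
   (rows → miRNA features) and of its transpose (rows → disease features);
   the objective is mean ½‖y(x) − x‖² plus a KL(ρ‖ρ̂) sparsity penalty,
   trained by Adam.
3. **Feature fusion**: each candidate pair (i, j) becomes
   `[M[i] ‖ Msim[i] ‖ D[j] ‖ Dsim[j]]`.
4. **MLP classifier** (ReLU hidden layers, softmax output, cross-entropy,
   Adam) producing an association probability per pair, with balanced
   negatives drawn via k-means cluster-proportional sampling of the unknown
   pairs.
5. **Ranking**: for one disease, score every miRNA, drop known positives,
   output the descending top-k.

A synthetic planted-structure generator makes the whole pipeline testable
without any external downloads. All training is pure numpy and bit-deterministic
given a seed.

## CLI

```sh
# generate a planted fixture dataset (assoc TSV, DAG TSV, held-out truth TSV)
spalp synth --preset default --seed 1 --out-dir fixtures/

# similarity matrices only
spalp similarity --assoc fixtures/associations.tsv --dag fixtures/dag.tsv \
    --delta 0.5 --out-dsim dsim.tsv --out-msim msim.tsv

# cross-validated evaluation (writes metrics.json, curves.csv, model.json, ...)
spalp evaluate --assoc fixtures/associations.tsv --dag fixtures/dag.tsv \
    --seed 7 --out-dir runs/eval

# train on all known associations, then rank candidates for one disease
spalp train --assoc fixtures/associations.tsv --dag fixtures/dag.tsv \
    --seed 7 --out model.json
spalp rank --model model.json --disease dis-0000 --top 30 --out rank.tsv

# everything in one go
spalp run --assoc fixtures/associations.tsv --dag fixtures/dag.tsv \
    --config config.yaml --out-dir runs/full
```

Configuration is a flat YAML file validated against `spalp.pipeline.RunConfig`
(unknown keys rejected); every key has a documented default (decay factor 0.5,
latent dimension 128, Adam at 0.001, 300 classifier iterations, 5 folds,
23 negative-sampling clusters). A precomputed disease similarity matrix
(`--dsim`) and/or miRNA similarity matrix (`--msim`) may replace the DAG.

## File formats

Everything is plain text: association lists and DAG edge lists are 2-column
TSV (`node<TAB>-` declares an isolated DAG node), similarity matrices are
labelled square TSV written with 17 significant digits (exact round-trip),
rankings are `rank/mirna/score` TSV, metrics are JSON, curves are CSV.
Model checkpoints are JSON-of-arrays with the config embedded.

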