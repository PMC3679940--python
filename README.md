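# gilnet

Pre-clustered gene co-expression network construction.

Large public expression compendia mix many biological conditions, which
dilutes pairwise correlations and shrinks the co-expression network a single
global threshold can recover. `gilnet` instead partitions the input samples
into K groups by expression similarity (K-means), builds one Pearson
co-expression network per group, and thresholds each network independently
with a random-matrix criterion: the correlation cutoff is placed at the
point where the nearest-neighbor spacing distribution of the thresholded
matrix's unfolded eigenvalues transitions from Poisson (modular signal) to
Gaussian-orthogonal-ensemble (noise) statistics. The resulting per-cluster
networks ("layers") are mined for modules (Markov clustering and
link-community detection), topology (degree, scale-free exponent,
clustering coefficient), Fisher-exact functional enrichment with Bonferroni
control, and keyword structure from free-text sample descriptions.

Everything runs on synthetic data: the `synthetic_data` module plants
condition-specific co-expressed modules with an exact within-module
correlation `b^2 / (b^2 + sigma^2)`, so thresholds, module recovery and
enrichment all have known ground truth.

## Layout

| module | contents |
| --- | --- |
| `gilnet.expression_io` | TSV/GMT readers and writers for matrices, probe maps, metadata, edge lists, modules, partitions |
| `gilnet.synthetic_data` | latent-factor compendium generator, power-law degree sampler, planted-partition graphs, matching annotation sets |
| `gilnet.preprocess` | control-probe removal, quantile normalization, 3-test outlier-sample removal, ambiguous-probe removal |
| `gilnet.partition` | multi-start Lloyd K-means over samples; size-preserving label randomization controls |
| `gilnet.network_build` | Pearson similarity, eigenvalue unfolding, NNSD chi-square, threshold scan, network extraction, probe-to-gene collapse |
| `gilnet.modules_detect` | Markov clustering (MCL) and link communities with partition-density dendrogram cut |
| `gilnet.stats` | degree/topology reports, power-law MLE, clustering coefficient, Fisher enrichment + Bonferroni |
| `gilnet.evaluate` | compendium orchestration, capture curves, randomization experiments, keyword assignment and ordering |

## CLI

```sh
gilnet simulate --out-dir data/                 # synthetic fixtures + truth
gilnet preprocess --matrix data/expression.tsv --out-matrix norm.tsv
gilnet partition --matrix norm.tsv --k 3 --seed 1 --out part.tsv
gilnet build --matrix data/expression.tsv --partition part.tsv \
             --cluster 0 --out-edges gil0.tsv --out-scan scan0.tsv
gilnet modules --edges gil0.tsv --method mcl --out modules0.tsv
gilnet enrich --modules modules0.tsv --gmt data/annotations.gmt --out enr0.tsv
gilnet sweep --matrix data/expression.tsv --k 1,3 --seed 1 --out sweep.json
```

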