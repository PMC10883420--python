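# stwmd

Spatio-temporal weighting and multi-step decision-tree analysis of
stage-by-region gene expression data.

## The problem

Brain development and neurodegenerative disease produce expression data with
two structured axes besides genes and samples: a *temporal* axis of discrete
stages (for example early/middle/late disease, or fetal / postnatal / adult
development) and a *spatial* axis of anatomical brain regions.  The same
gene is frequently up-regulated in some regions and down-regulated in
others, so collapsing the region axis by plain averaging cancels real
signal, while analysing each region separately fragments power and misses
genes whose evidence is spread across regions.

`stwmd` is for analysts with a four-way tensor `y[t, i, r, g]` (stage,
sample-within-stage, region, gene) who want stage-discriminative *gene
classes* rather than single-region gene lists.

## The method

**Step 1 — region weighting.**  Per sample and gene, regional values are
min-max normalized,

    y_norm = (y − min_r y) / (max_r y − min_r y) · a + 1,     a = 3,

constraining them to [1, 4].  Per (stage t, region r, gene g), the fold
change of stage means against the reference stage (t = 0) is

    FC_trg = mean_i y_norm(t, i, r, g) / mean_i y_norm(0, i, r, g),

and its log2 is rectified into a nonnegative weight,

    w = −log2 FC   if log2 FC < −log2 1.5
        log2 FC    if log2 FC ≥  log2 1.5
        0          otherwise,

so counterbalancing up/down regions both contribute positively and
non-differential regions are silenced.  The region axis is then collapsed by
the weighted average  y_fc(t, i, g) = Σ_r y_norm·w / Σ_r w  over the
sample's observed regions (all-zero weights fall back to the plain mean;
the plain mean over regions is also available as a comparison baseline).

**Step 2 — multi-step decision tree.**  On the weighted matrix: an
empirical-Bayes moderated-t screen per stage pair with BH correction; the
DEG union is clustered into k gene classes (z-scored profiles, optional
t-SNE/UMAP embedding, k-means, silhouette-selected k, classes named
ClusterA, ClusterB, … by size); each class is summarized by its first
principal component (PC1) and variance-contribution rate (VCR); the PC1
features feed a CART staging tree pruned at complexity parameter cp = 0.05,
evaluated by 20×5-fold cross-validation, pairwise stage trees, and 100
subsample-stability refits at 80%; finally each class can be tested for
gene-set over-representation (hypergeometric tail, GMT input).

## Worked example

The built-in synthetic reference study plants five gene classes (500 of
2000 genes) across three stages of 30 samples and eight regions, two of
them with clean regional territories that discriminate the late stage and
the early stage respectively, and three "mosaic" classes whose
per-individual regional up/down pattern varies:

```python
from stwmd import run_pipeline
from stwmd.synthetic import generate_tensor, reference_spec, reference_config, truth_eval

tensor, truth = generate_tensor(reference_spec(seed=7))
result = run_pipeline(tensor, reference_config(seed=7))
s = result.summary()
m = truth_eval(result, truth)
print("prescreened:", s["n_prescreened"])
print("DEGs:", s["n_degs"], s["deg_counts_per_contrast"])
print("k:", s["k"], "sizes:", s["cluster_sizes"])
print("VCR:", {k: round(v, 2) for k, v in s["vcr"].items()})
print("CV accuracy:", round(s["cv_mean_accuracy"], 4))
print("tree signature:", s["tree"]["signature"])
print("stability:", s["stability"]["modal_signature"],
      s["stability"]["modal_count"], "/", s["stability"]["runs"])
print("recall:", round(m["deg_recall"], 3), "ARI:", round(m["clustering_ari"], 3))
```

which prints:

```text
prescreened: 1118
DEGs: 517 {'early~middle': 309, 'early~late': 407, 'middle~late': 293}
k: 5 sizes: {'ClusterA': 119, 'ClusterB': 118, 'ClusterC': 101, 'ClusterD': 96, 'ClusterE': 83}
VCR: {'ClusterA': 0.53, 'ClusterB': 0.49, 'ClusterC': 0.76, 'ClusterD': 0.43, 'ClusterE': 0.55}
CV accuracy: 0.9983
tree signature: ['ClusterB', 'ClusterC']
stability: ['ClusterB', 'ClusterC'] 100 / 100
recall: 0.954 ARI: 0.994
```

Reading this: the top-fraction prescreen kept 1118 genes; 517 passed the
weighted differential test in at least one stage-pair contrast; silhouette
selected k = 5 classes whose sizes match the planted 120/110/100/90/80;
each class's PC1 explains roughly half or more of its variance (VCR); the
staging tree separates the three stages with 99.8% repeated-CV accuracy
using exactly two classes — ClusterB and ClusterC, which map onto the two
planted discriminative classes (`late_up` and `prog_down`) — and that same
two-class tree recurs in 100 of 100 stability refits on 80% subsamples.
DEG recall against the planted truth is 0.954 and the clustering matches
the planted classes at ARI 0.994.

The same analysis runs from the shell:

```sh
stwmd simulate --spec study.yaml --out data.tsv --truth truth.json
stwmd run --input data.tsv --config config.yaml --out summary.json
# or stepwise:
stwmd weight  --input data.tsv --out weighted.tsv --weights-out weights.tsv
stwmd de      --weighted weighted.tsv --contrast early:late --out de.tsv
stwmd cluster --weighted weighted.tsv --de-genes de.tsv --k 5 --out clusters.tsv --pc-out pc1.tsv
stwmd tree    --pc pc1.tsv --cp 0.05 --cv 20x5 --stability 100:0.8 --out tree.json
stwmd enrich  --clusters clusters.tsv --gmt sets.gmt --out enrichment.tsv
```

Input is a long-format TSV with columns `stage, sample, region, gene,
value` (a directory of per-sample gene×region wide matrices is also
accepted); configuration is a YAML file mirroring `AnalysisConfig`.

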