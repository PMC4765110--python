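# orthoscreen

Machine-learning post-processing for putative homology clusters.

Heuristic orthology tools — InParanoid-style reciprocal-best-BLAST-hit
chains, profile-HMM searches — group proteins into clusters of putative
homologs. When proteomes come from incomplete or low-coverage de novo
transcriptome assemblies, a substantial fraction of those clusters are
false positives: sets of sequences with no detectable common ancestry.
`orthoscreen` classifies each cluster as homology (H) or non-homology
(NH) from ten summary attributes of its multiple sequence alignment and
removes the predicted non-homologs, providing the cluster post-processing
step that heuristic pipelines lack.

## What it does

1. **Closure** — assembles clusters from pairwise homology calls by
   transitive closure (connected components of the relation graph; for
   *N* proteomes a pipeline performs *N(N−1)/2* pairwise queries).
2. **Alignment** — a built-in progressive aligner (UPGMA guide tree on
   3-mer cosine distances, profile–profile Needleman–Wunsch/Gotoh with
   affine gaps over BLOSUM62), or any external aligner via a command
   template.
3. **Features** — for each cluster MSA: the count of randomly aligned
   positions (a parametric Monte-Carlo sliding-window score), alignment
   length, number of sequences, total gaps, total amino-acid residues,
   the range of ungapped member lengths, and the between-sequence
   standard deviation of per-sequence amino-acid composition in each of
   four physicochemical classes (charged `DEKRH`, uncharged/polar
   `STNQY`, hydrophobic `AVLIMFW`, special `CGP`).
4. **Ground truth by construction** — labeled training data is generated:
   H clusters are conserved simulated protein families; NH decoys are
   either random draws from the whole protein pool with cluster size
   ~ Poisson(λ = 44.3056), or built by evolving each member of an H
   cluster along a random binary tree (tip count ~ discretized
   Normal(50, 15)) under WAG+I (invariable-site fraction 0/25/50 %) and
   keeping one random tip per tree.
5. **Learning** — five base classifiers (feed-forward network, linear
   SVM, 10-tree random forest, Gaussian Naive Bayes, logistic
   regression) and two stacking meta-classifiers whose meta-network is
   fed the out-of-fold (10-fold) probabilities of the bases. Datasets
   use an EQUAL (five classes in equal counts) or PROP (half H)
   composition and an 80/10/10 train/validation/test split.
6. **Filtering** — a trained model partitions any cluster directory into
   kept and removed, with a per-cluster manifest of decisions and scores.

## Worked example

```python
import numpy as np
from orthoscreen import (
    generate_pools, feature_table, DatasetSpec, SplitSpec,
    assemble_dataset, split, train, evaluate, filter_clusters, Provenance,
)

pools = generate_pools(n_h=25, n_nh_random=25, n_nh_evolved_each=25, seed=7)
nh = {p: c for p, c in pools.items() if p is not Provenance.H_SYNTH}
table = assemble_dataset(pools[Provenance.H_SYNTH], nh,
                         DatasetSpec(scheme="EQUAL", n_total=125, seed=7))
train_tbl, valid_tbl, test_tbl = split(table, SplitSpec(seed=7))
model = train("stack_with_lr", train_tbl, seed=7)
print(f"validation accuracy: {evaluate(model, valid_tbl).accuracy:.3f}")
print(f"test accuracy:       {evaluate(model, test_tbl).accuracy:.3f}")
```

prints

```
validation accuracy: 1.000
test accuracy:       1.000
```

i.e. on a 125-cluster EQUAL-composition synthetic dataset the stacking
meta-classifier separates conserved families from both decoy flavours
perfectly on the 12-cluster held-out partitions (at the full 625-cluster
study scale, validation accuracy is typically 98–100 %; see below). The
same flow is available from the shell:

```sh
orthoscreen --seed 7 simulate --out run/clusters --n-total 125
orthoscreen --seed 7 featurize --clusters run/clusters --out run/features.csv
orthoscreen --seed 7 train --features run/features.csv \
    --model-out run/model.joblib --kind stack_with_lr
orthoscreen --seed 7 filter --clusters run/clusters \
    --model run/model.joblib --manifest-out run/filtered.tsv
```

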