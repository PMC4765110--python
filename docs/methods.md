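# Methods

## Problem and model

`orthoscreen` treats homology-cluster quality control as binary
classification. A putative cluster — a set of amino-acid sequences that
an upstream orthology heuristic grouped together — is summarized by ten
attributes of its multiple sequence alignment, and a supervised
classifier decides whether the cluster looks like a real protein family
(H) or like an artifact of heuristic clustering (NH). The premise is
that non-homologous clusters betray themselves at the alignment level:
they accumulate gaps, their columns score no better than chance under a
substitution matrix, and their members' amino-acid compositions are not
held together by shared purifying selection.

## The ten attributes

For a cluster with members `s_1..s_n` and MSA of length `L`:

| attribute | definition |
|---|---|
| `aliscore` | count of columns flagged as randomly aligned (below) |
| `length` | `L` |
| `n_sequences` | `n` |
| `n_gaps` | total `-` characters in the matrix |
| `n_amino_acids` | total non-gap characters (`X` counts as a residue) |
| `range` | max − min ungapped member length |
| `sd_charged` … `sd_hydrophobic` | between-sequence SD of per-sequence class composition |

For the compositional dispersions, each sequence's proportion `p_i` of
residues in a physicochemical class is computed over that sequence's own
ungapped, non-`X` residue count — so sequences of different lengths are
directly comparable — and the dispersion is `sqrt(Σ(p_i − p̄)²/(n−1))`,
the square root of the unbiased (Bessel-corrected) variance. `X` is
excluded from class counts because an unknown residue has no
physicochemical class; it still counts toward `n_amino_acids` and
`range`. The class partition (charged `DEKRH`, uncharged/polar `STNQY`,
hydrophobic `AVLIMFW`, special `CGP`) is the conventional grouping and
is configurable (`AminoClassScheme`), as is reporting variance instead
of SD (`dispersion="variance"`).

## Randomly aligned positions

The `aliscore` attribute is produced by an in-package Monte-Carlo
sliding-window scorer built on the same principle as parametric
alignment-randomness tools: a window of aligned residue pairs is
informative only if it scores better than windows assembled by chance
from the same residue pools. Per unordered row pair and window start
(window `w = 6` columns), the observed score is the BLOSUM62 sum over
the window, with any gap-containing column contributing a flat penalty
(`gap_score = −1`); the pair's null is the score distribution of 100
windows whose residues are drawn i.i.d. from each row's own ungapped
residue frequencies; a window is non-random iff its observed score
exceeds the null's 0.95 quantile. Pooling over all pairs, a column is
flagged iff fewer than half of the windows covering it are non-random.
Alignments shorter than the window are scored as a single window.

Numerical/stream choices: each pair's random stream is seeded from a
hash of (seed, sorted pair of row strings), which makes the count
invariant to row order and to sequence relabeling. Gap-containing
columns are penalized rather than skipped because gap-rich decoys are
exactly what the feature must expose. This scorer is a self-contained
component with its own parameters; per-cluster counts from any external
tool can be attached (`attach_precomputed`) and take precedence.

## Alignment

The internal aligner exists so that the pipeline is self-contained and
deterministic; downstream features are alignment-level statistics, so
any reasonable MSA suffices. Pairwise and profile–profile alignment use
global Needleman–Wunsch with affine gaps (Gotoh; gap of length `k`
costs `gap_open + k·gap_extend`, defaults −10/−1) over BLOSUM62, with a
fixed tie-break (diagonal, then vertical, then horizontal) for
cross-platform determinism. Progressive order comes from UPGMA on
cosine distances between 3-mer count vectors; profiles are merged with
mean-of-pairs expected scores (`f_a^T · B · f_b` per column pair, with
gap frequencies scored at −1 against residues, 0 against gaps). The DP
kernel is numba-compiled. An external aligner (e.g. `mafft --auto`) can
be substituted through a `{in}`/`{out}` command template; its output is
validated by the same degap-identity contract the internal aligner
guarantees. Clusters that arrive already aligned are featurized as-is.

## Ground-truth generation

The generator reproduces the statistical structure of the reference
training study:

* **Cluster sizes** ~ Poisson(λ = 44.3056) — the average size of the
  curated homology clusters the study calibrated against — redrawn
  below the minimum size of 2 (a cluster must be alignable).
* **Random trees**: tip count = a rounded Normal(50, 15) draw (redrawn
  below 2); topology by random sequential coalescence; branch lengths
  i.i.d. Exponential. The tree-depth scale is not pinned down by the
  reference study, so edge means are parameters: 0.5 substitutions/site
  for decoy evolution (deep enough that tips lose detectable common
  ancestry) and 0.05 for H families (conserved, ~95 % pairwise
  identity).
* **Substitution model**: WAG exchangeabilities and equilibrium
  frequencies (embedded constants), rate matrix `q_ij = s_ij π_j`
  scaled to one expected substitution/site, transition matrices
  `P(t) = exp(Qt)` from a single eigendecomposition of the symmetrized
  reversible matrix. Invariable sites (+I): a Bernoulli(`p_inv`) site
  mask drawn once per root; masked sites never mutate; variable sites
  evolve at the normalized rate. Evolution is substitution-only — no
  indels — so evolved sequences keep their root's length.
* **NH_EVOLVED decoys**: for each member of an H cluster, sample a
  tree, evolve the member down it, keep one uniformly chosen tip; the
  decoy cluster therefore has exactly the source cluster's size and
  length profile, at `p_inv` ∈ {0, 0.25, 0.5}.
* **NH_RANDOM decoys**: Poisson-sized uniform draws without replacement
  from the union of all H members (the stand-in proteome).
* **H families** (`H_SYNTH`): tips of one shallow tree evolved from a
  root drawn i.i.d. from WAG equilibrium frequencies, root length
  uniform in 100–400 residues (a realistic protein-length band). These
  are a synthetic stand-in for curated single-copy ortholog clusters
  and are labeled as such in their provenance.

What the generator does *not* emulate: indel processes (real decoys are
gap-rich for alignment reasons, synthetic evolved decoys only through
misalignment), rate heterogeneity beyond the invariable class,
paralog-specific rate shifts, fragmentary transcripts, and assembly
artifacts. Consequently, high accuracy on synthetic data demonstrates
that the features separate the generative classes — not a performance
guarantee on real transcriptome-derived clusters.

## Classifiers

Hyperparameters map a conventional workbench configuration onto
scikit-learn: MLP (one hidden layer of `(features+classes)/2` units,
SGD, learning rate 0.1, momentum 0.05, ≤ 3000 epochs), linear-kernel
SVM (C = 1, Platt-calibrated for probabilities), random forest (10
trees), Gaussian Naive Bayes, logistic regression (effectively
unregularized, C = 10⁸). The two stacking meta-classifiers collect
10-fold out-of-fold class probabilities from their bases (with or
without logistic regression among them) and feed them to a smaller MLP
(learning rate 0.3, momentum 0.2, ≤ 500 epochs). Probabilities rather
than hard labels are stacked because every base supplies them. Features
feeding scale-sensitive models pass through standardization inside each
pipeline. Labels are strictly binary (H vs NH); the four NH flavours
are metadata. Filtering removes clusters with P(H) < 0.5 (threshold
configurable); clusters that cannot be featurized are quarantined and
reported, never silently dropped.

## Splits, curves, ablation

The 80/10/10 split is unstratified uniform sampling; fractional
remainders go to the training partition (10 rows → 8/1/1). Learning
curves resample `⌊fraction·n⌋` training rows with replacement (100
bootstrap replicates by default), refit, and score the fixed validation
set, reporting mean, SD and min/max envelope. Feature ablation refits
the chosen model on each single attribute.

## Reproducibility

Every stochastic component takes a seed; the CLI derives stage-scoped
seeds from one master seed via a stable hash, so a single integer
reproduces simulation, featurization, splitting and training
byte-identically. The acceptance script (`scripts/acceptance.py`)
recomputes the calibration means (100,000 Poisson draws; 10,000 trees),
the 625-cluster EQUAL-composition stacking experiment, and the
invariable-site column fraction (length-1000 root, `p_inv = 0.5`),
entirely from the given seed. The 625-cluster scale keeps the full
experiment at a few minutes on one CPU while leaving ~100 clusters per
class for training; the synthetic-separability conclusion is stable in
this regime.

## Known limitations

* The internal aligner is progressive-only (no iterative refinement);
  pathological low-complexity clusters may align suboptimally.
* The randomness scorer shares its scoring matrix with the aligner, so
  its counts on internally aligned clusters are not independent of the
  alignment step.
* Gap-free synthetic H families make `n_gaps` an unrealistically clean
  separator relative to real curated clusters.
* Transitive closure is deliberately aggressive: one spurious pairwise
  call merges two clusters; the classifier is the corrective, not the
  closure.
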