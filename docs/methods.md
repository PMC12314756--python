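# Methods

## Problem and approach

`treescreen` implements a graph-learning pipeline for screening high
suicidal ideation from coded Tree-Drawing Test (TDT) responses.  Each
drawing is coded with 98 binary features in 12 classes (canopy shape, trunk,
roots, line quality, attachments, ...).  Rather than classifying the
98-dimensional code vectors directly, the pipeline builds a *bipartite
semantic graph* — one vertex per drawing, one per feature, an edge wherever
a drawing exhibits a feature — and treats screening as transductive node
classification: drawings that share features are linked through feature
vertices, so label information propagates between structurally similar
respondents.

The reference study design this emulates: 806 school-age respondents, a
nine-item ideation scale (0–90 points, mean 17.19, SD 7.01) binarized at
mean + SD into 94 high- vs 712 low-ideation subjects (~7.57:1 imbalance),
and a graph of 904 vertices with ~15.4k edges (density ≈ 0.04).

## Pipeline stages

1. **Cohort** (`cohort`).  Synthetic cohorts replace the non-public data.
   Scores are drawn from a normal truncated to [0, 90]; with the default
   moments the truncation shifts the mean by about +0.14 points and shrinks
   the SD by about 0.17 — small against sampling noise at M = 806 and left
   uncorrected.  The top-`n_high` scores are assigned to the high-ideation
   subjects (rank assignment rather than re-thresholding, so the group size
   is exact by construction).  Feature presences are Bernoulli; per-class
   base prevalences were set so the expected number of present features per
   drawing is ≈ 19, reproducing the reference edge count.  For high-ideation
   subjects the log-odds of every feature in `signal_classes` (default
   "leaf and flower") shift by `effect_size` (default 2.0), and every
   feature receives a small random shift (SD 0.15 log-odds) so no class is
   exactly null.  A latent evidence matrix `signals = Z + N(0, 0.5)` stands
   in for raster images.
2. **Feature-extraction surrogate** (`extraction`).  The original pipeline
   fine-tunes an image CNN with 98 parallel binary heads; with no images to
   train on, each feature instead gets an independent logistic scorer on its
   latent evidence channel.  The losses are preserved exactly: mean-over-
   features of per-feature mean binary cross-entropy, and its cost-sensitive
   variant that multiplies the minority-class log-term of each feature by
   `w_f` (default 4.0; minority direction estimated on training rows only).
   The objective is convex, so training is plain full-batch gradient descent
   from zero initialization — deterministic without a seed.  Ties at p = 0.5
   predict presence.
3. **Semantic graph** (`graph`).  Vertex order is canonical: images by row,
   then features by catalog order.  `A_hat = D^{-1/2} A D^{-1/2}` with no
   self-loops by default (a flag adds the common A+I renormalization);
   isolated vertices get zero rows rather than raising.  The 80/20 node
   split uses round() (806 → 645/161); training-subset sizes use floor(),
   matching 580/516/451/387/322 at 90–50%.  Splits are uniform, not
   stratified.
4. **Embedding** (`embedding`).  node2vec-style initialization: second-order
   biased walks (p = q = 1 by default, i.e. unbiased, since no tuning is
   reported for the reference pipeline) and a from-scratch skip-gram with
   negative sampling — a numba-compiled sequential kernel in the classic
   word2vec style (dynamic window, unigram^0.75 noise, linear step decay,
   corpus-order streaming).  Single-threaded and bit-reproducible for a
   fixed seed.  Isolated vertices receive zero embeddings and contribute no
   noise mass.
5. **Detector** (`gcn`).  L-layer GCN (default 2, hidden width 64):
   `H^(l+1) = ReLU(A_hat H^(l) W^(l))` with no convolution bias, then a
   2-logit softmax head.  The detection loss weights *only* the
   positive-class log-term by `w_c` (default 7.0) — deliberately not a
   symmetric two-class weighting.  All vertices (including test images and
   features) participate in message passing; only labeled training image
   vertices enter the loss; feature vertices are never evaluated.
   Gradients are analytic (closed-form backprop; `A_hat` is symmetric so its
   transpose is free); the optimizer is Adam (lr 0.01) with decoupled L2
   decay 0.001 on weight matrices (not the head bias), 200 epochs, early
   stopping on training loss with patience 30 and best-parameter restore.
   Probability ties at 0.5 predict class 0.
6. **Metrics** (`metrics`).  precision/recall per class, per-class F1,
   macro-F1, G-mean = sqrt(recall_1 · recall_0), FPR.  Any ratio with a
   zero denominator is defined as 0 (and F1 = 0 when precision + recall =
   0): this keeps the all-negative predictor — the characteristic failure
   under heavy imbalance — well-defined with recall_1 = G-mean = 0.
   Displayed percentages round half-up to 2 decimals.
   `reconstruct_confusion` inverts printed recall_1/FPR pairs back to
   integer counts given the class totals; with 19 positives / 142 negatives
   it reproduces published metric panels exactly, which doubles as a strong
   cross-check of the metric formulas.

## Experiment protocols

`experiments` reruns the study's analyses end to end on synthetic cohorts:
model comparison (GCN + LR/DT/SVM/RF on true vs corrupted codes), per-class
ablation ("none" + 12 classes), sensitivity sweeps (w_c 1–16; w_f ∈
{1,2,4,8,16} with extractor retraining and graph rebuilding; depth 1–4),
and stability (training set shrunk to 50% with the test set fixed, dropped
training vertices removed from the graph by default; edges randomly thinned
to 50%).  Each condition runs `n_seeds` (default 5) fully independent
replicates — fresh cohort, split, embedding, and initialization — and
reports mean and SD of all nine metrics.  Every run writes a config echo,
a SHA-256 fingerprint of the replicate-0 coding matrix, and the report CSV;
reruns with the same config are bit-identical.

**Problem sizes.**  The multi-condition protocols default to a compact
embedding (k = 32, 5 walks × length 40, window 5, 3 epochs) so a full
battery is a few CPU-minutes; single-run embedding defaults follow the
common node2vec settings (k = 128, 10 × 80, window 10, 5 epochs).  The
acceptance battery runs recovery protocols at 400 subjects (47 high — the
same ~7.6:1 imbalance) and the planted-signal and cost-weight analyses at
the full 806.

## What the synthetic cohorts do and do not show

The generator reproduces the study's *design*: sample size, imbalance,
scale moments, feature-class structure, edge-count scale, and a
concentrated signal in "leaf and flower".  Passing recovery tests show the
pipeline detects a planted prevalence signal under realistic imbalance and
sparsity, that the cost weight is necessary (w_c = 1 collapses minority
recall to zero), that ablating the signal class causes the largest
performance drop, and that performance degrades gracefully as edges are
removed.  They do **not** show real-data effect sizes or the published
headline numbers: real per-feature prevalences are unpublished, real
signal is presumably spread across many correlated features, and the
extraction surrogate is far better behaved than an image CNN.  Two
consequences worth flagging: removing a large *non-signal* class can
slightly improve synthetic performance (noise removal), unlike the
universal degradation reported on real data; and because the logistic
surrogate does not collapse on minority features at w_f = 1, the benefit
of w_f > 1 appears at the extractor level (minority recall) but not
downstream.

## Numerical choices and degenerate inputs

Probabilities are clipped at 1e-12 inside logs.  Weight initialization is
symmetric uniform scaled by fan-in.  Constant score vectors trigger a
degenerate-threshold warning (threshold = the common value, all subjects
labeled high under the inclusive rule).  Zero-variance evidence channels
train to the prior and predict the majority coding.  Non-finite losses
abort training with a diagnostic rather than silently diverging.  All
randomness flows through `numpy.random.default_rng` (or the numba kernel's
seeded state) from explicit seeds; experiment sub-seeds derive from the run
seed by SHA-256 so protocols are reproducible as a whole.

## Known limitations

No rater-disagreement modeling, no raster images, no heterogeneous-graph
or CNN baselines, no AUROC/PR curves.  The comparison between the GCN and
tabular baselines on synthetic cohorts is conservative: a 3-feature planted
signal is nearly ideal for decision trees, so the GCN's margin here is
smaller than on real data.
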