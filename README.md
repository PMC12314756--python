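# treescreen

Graph-learning pipeline for suicidal-ideation screening from Tree-Drawing
Test (TDT) feature codes.

The TDT is a projective assessment: a respondent draws a tree, and coded
characteristics of the drawing (canopy shape, trunk, roots, leaves and
fruits, attachments, ...) correlate with psychological state.  `treescreen`
targets the screening setting where each of M drawings is coded with N = 98
binary features in 12 classes, and a small minority of respondents (~1 in
8.6) are high in suicidal ideation on a Beck-style scale binarized at
mean + SD.

Instead of classifying the 98-dimensional code vectors directly, the
pipeline builds a **bipartite image–feature semantic graph** G = (V_I ∪ V_F, E)
— an edge (i, j) whenever drawing i exhibits feature j (A(i,j) = 1 iff
e_ij ∈ E) — and performs **transductive node classification** with a
two-layer graph convolutional network:

    H^(0) = X,   H^(l+1) = ReLU(Â H^(l) W^(l)),   ŷ = softmax(W H^(L) + b)

where Â = D^(−1/2) A D^(−1/2) is the symmetric degree-normalized adjacency
and X are node2vec-style initial embeddings (biased random walks +
skip-gram with negative sampling).  Class imbalance is handled by a
cost-sensitive cross-entropy that up-weights only the positive (high
ideation) log-term:

    L = −(1/T) Σ_train [ w_c · y_j · log ŷ_j + (1 − y_j) · log(1 − ŷ_j) ],   w_c = 7 by default.

The same cost-sensitive idea applies per feature (weight w_f on each
feature's minority coding) in the multi-label feature-extraction stage,
implemented here as per-feature logistic scorers on latent evidence.
Evaluation uses imbalance-aware metrics: per-class precision/recall,
macro-F1, G-mean = √(recall_1 · recall_0), and FPR.

Because the kind of cohort this targets is not publicly available, the
package includes a first-class synthetic cohort generator reproducing the
study design (806 drawings, 94/712 class split, scale mean 17.19 / SD 7.01,
~19 present features per drawing → a 904-vertex graph of density ≈ 0.04,
signal concentrated in the "leaf and flower" class), plus an experiment
harness for ablation, sensitivity, and stability protocols.  See
`docs/methods.md` for the full model description and the limits of what
synthetic results show.

## Worked example

```python
from dataclasses import replace
from treescreen import simulate_cohort, build_semantic_graph, graph_density
from treescreen.experiments import RunConfig, gcn_run, subseed
from treescreen.graph import split_nodes

cfg = RunConfig(seed=1)
cohort = simulate_cohort(replace(cfg.cohort, seed=subseed(1, "cohort", 0)))
graph = build_semantic_graph(cohort.Z, labels=cohort.labels)
print(graph.n_vertices, graph.n_edges, round(graph_density(graph), 4))
train, test = split_nodes(cohort.n_subjects, 0.8, subseed(1, "split", 0))
report = gcn_run(cohort.Z, cohort.labels, train, test, cfg, rep=0)
print(report.as_percent())
```

Output (seed 1):

```
904 15552 0.0381
{'precision_0': 96.69, 'recall_0': 81.25, 'precision_1': 32.5,
 'recall_1': 76.47, 'F1_0': 88.3, 'F1_1': 45.61, 'macro_F1': 66.96,
 'G_mean': 78.82, 'FPR': 18.75}
```

Reading: the 806-drawing cohort yields the expected 904-vertex sparse
bipartite graph; on the held-out 161 drawings the cost-sensitive GCN
recovers 76% of high-ideation cases (recall_1) while keeping the false
positive rate at 19%, for a G-mean of 79% — under the default planted
effect of 2.0 log-odds on the three "leaf and flower" features.

The same pipeline is available from the shell:

```bash
treescreen simulate --seed 1 --out results/
treescreen build-graph --cohort results/cohort.csv --out results/
treescreen train --cohort results/cohort.csv --seed 1 --out results/
treescreen ablate --seed 1 --out results/       # per-class feature ablation
treescreen sweep-wc --seed 1 --out results/     # w_c = 1..16 sensitivity
treescreen stability-edges --seed 1 --out results/
```

Experiment commands accept `--config config.yaml` mirroring the
`RunConfig` structure and write a report CSV plus a config echo with a
cohort fingerprint.

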