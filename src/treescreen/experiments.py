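"""End-to-end experiment protocols on synthetic cohorts.

Each protocol mirrors one analysis of the screening pipeline: model
comparison (graph model vs classic ML, true vs corrupted codes), per-class
feature ablation, sensitivity to the two cost-sensitive weights and to GCN
depth, and stability under shrinking training sets or randomly missing
edges.  Every protocol runs ``n_seeds`` independent replicates (fresh
cohort, split, embedding and initialization per replicate) and reports the
mean and SD of the nine evaluation metrics per condition.

All randomness derives from the run seed through ``subseed``, so reruns with
the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import BASELINE_NAMES, BaselineSpec, fit_baseline, predict_baseline
from .cohort import Cohort, CohortConfig, corrupt_features, simulate_cohort
from .embedding import EmbeddingConfig, embed_graph
from .extraction import ExtractorTrainConfig, extract_features, train_extractor
from .gcn import TrainConfig, predict, train_detector
from .graph import (
    UNLABELED,
    build_semantic_graph,
    drop_edges,
    remove_feature_class,
    split_nodes,
    subset_training,
)
from .metrics import EvalReport, evaluate

WF_GRID = (1.0, 2.0, 4.0, 8.0, 16.0)
WC_GRID = tuple(range(1, 17))
LAYER_GRID = (1, 2, 3, 4)
KEEP_FRACTIONS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
TRAIN_FRACTIONS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)


def subseed(base: int, *tags) -> int:
    """Stable sub-seed derived from a base seed and string/int tags (< 2^31)."""
    h = hashlib.sha256(repr((base, tags)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _light_embedding() -> EmbeddingConfig:
    # Battery setting: smaller than the single-run defaults so that the
    # multi-seed, multi-condition protocols stay cheap on one CPU.
    return EmbeddingConfig(
        k=32, walks_per_node=5, walk_length=40, window=5, epochs=3
    )


@dataclass
class RunConfig:
    """Resolved configuration of one experiment protocol."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    embedding: EmbeddingConfig = field(default_factory=_light_embedding)
    train: TrainConfig = field(default_factory=TrainConfig)
    extractor: ExtractorTrainConfig = field(default_factory=ExtractorTrainConfig)
    self_loops: bool = False
    train_fraction: float = 0.8
    n_seeds: int = 5
    # corruption rates emulating imperfect automatic feature extraction
    flip_01: float = 0.02
    flip_10: float = 0.10
    baseline_cost_sensitive: bool = False
    # stability protocol: drop unused training vertices from the graph
    # (True) or only hide their labels (False)
    subset_removes_vertices: bool = True
    seed: int = 0


def _split(cohort: Cohort, cfg: RunConfig, rep: int):
    return split_nodes(
        cohort.n_subjects, cfg.train_fraction, subseed(cfg.seed, "split", rep)
    )


def _masked_labels(labels: np.ndarray, test_mask: np.ndarray) -> np.ndarray:
    out = np.asarray(labels, dtype=np.int8).copy()
    out[test_mask] = UNLABELED
    return out


def gcn_run(
    Z: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    cfg: RunConfig,
    rep: int,
    train_cfg: TrainConfig | None = None,
    graph=None,
) -> EvalReport:
    """One GCN replicate: build graph (unless given), embed, train, evaluate."""
    if graph is None:
        graph = build_semantic_graph(Z, labels=_masked_labels(labels, test_mask))
    emb_cfg = replace(cfg.embedding, seed=subseed(cfg.seed, "embed", rep))
    X = embed_graph(graph, emb_cfg).X
    tcfg = replace(
        train_cfg or cfg.train, seed=subseed(cfg.seed, "train", rep)
    )
    params, _ = train_detector(graph, X, train_mask, tcfg)
    _, hard = predict(graph, X, params)
    return evaluate(labels[test_mask], hard[test_mask])


def _baseline_run(
    name: str,
    Z: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    cfg: RunConfig,
    rep: int,
) -> EvalReport:
    spec = BaselineSpec(
        name=name,
        cost_sensitive=cfg.baseline_cost_sensitive,
        positive_weight=cfg.train.w_c if cfg.baseline_cost_sensitive else None,
        seed=subseed(cfg.seed, "baseline", name, rep),
    )
    model = fit_baseline(spec, Z[train_mask], labels[train_mask])
    pred = predict_baseline(model, Z[test_mask])
    return evaluate(labels[test_mask], pred)


def summarize(reports: list[EvalReport]) -> dict[str, float]:
    out: dict[str, float] = {}
    for m in EvalReport.METRICS:
        vals = np.array([getattr(r, m) for r in reports])
        out[m] = float(vals.mean())
        out[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return out


def _rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def run_comparison(cfg: RunConfig) -> pd.DataFrame:
    """GCN + 4 ML baselines, on true codes and on corrupted codes."""
    collected: dict[tuple[str, str], list[EvalReport]] = {}
    for rep in range(cfg.n_seeds):
        cohort = simulate_cohort(
            replace(cfg.cohort, seed=subseed(cfg.seed, "cohort", rep))
        )
        train_mask, test_mask = _split(cohort, cfg, rep)
        sources = {
            "manual": cohort.Z,
            "automatic": corrupt_features(
                cohort.Z, cfg.flip_01, cfg.flip_10, subseed(cfg.seed, "flip", rep)
            ),
        }
        for src, Z in sources.items():
            collected.setdefault(("GCN", src), []).append(
                gcn_run(Z, cohort.labels, train_mask, test_mask, cfg, rep)
            )
            for name in BASELINE_NAMES:
                collected.setdefault((name, src), []).append(
                    _baseline_run(
                        name, Z, cohort.labels, train_mask, test_mask, cfg, rep
                    )
                )
    rows = [
        {"model": model, "features": src, **summarize(reps)}
        for (model, src), reps in collected.items()
    ]
    return _rows_to_frame(rows)


def run_ablation(cfg: RunConfig) -> pd.DataFrame:
    """Retrain with each feature class removed from the graph ('none' = full)."""
    arms = ["none"] + list(simulate_cohort(cfg.cohort).catalog.classes)
    collected: dict[str, list[EvalReport]] = {a: [] for a in arms}
    for rep in range(cfg.n_seeds):
        cohort = simulate_cohort(
            replace(cfg.cohort, seed=subseed(cfg.seed, "cohort", rep))
        )
        train_mask, test_mask = _split(cohort, cfg, rep)
        full = build_semantic_graph(
            cohort.Z, labels=_masked_labels(cohort.labels, test_mask)
        )
        for arm in arms:
            g = (
                full
                if arm == "none"
                else remove_feature_class(full, cohort.catalog, arm)
            )
            collected[arm].append(
                gcn_run(
                    None, cohort.labels, train_mask, test_mask, cfg, rep, graph=g
                )
            )
    rows = [
        {"removed_feature": arm, **summarize(reps)}
        for arm, reps in collected.items()
    ]
    return _rows_to_frame(rows)


def run_sensitivity_wc(cfg: RunConfig) -> pd.DataFrame:
    """Sweep the detection cost weight w_c over 1..16 (one embed per seed)."""
    collected: dict[int, list[EvalReport]] = {w: [] for w in WC_GRID}
    for rep in range(cfg.n_seeds):
        cohort = simulate_cohort(
            replace(cfg.cohort, seed=subseed(cfg.seed, "cohort", rep))
        )
        train_mask, test_mask = _split(cohort, cfg, rep)
        graph = build_semantic_graph(
            cohort.Z, labels=_masked_labels(cohort.labels, test_mask)
        )
        emb_cfg = replace(cfg.embedding, seed=subseed(cfg.seed, "embed", rep))
        X = embed_graph(graph, emb_cfg).X
        for w_c in WC_GRID:
            tcfg = replace(
                cfg.train, w_c=float(w_c), seed=subseed(cfg.seed, "train", rep)
            )
            params, _ = train_detector(graph, X, train_mask, tcfg)
            _, hard = predict(graph, X, params)
            collected[w_c].append(
                evaluate(cohort.labels[test_mask], hard[test_mask])
            )
    rows = [{"w_c": w, **summarize(reps)} for w, reps in collected.items()]
    return _rows_to_frame(rows)


def run_sensitivity_wf(cfg: RunConfig) -> pd.DataFrame:
    """Sweep the extraction cost weight w_f: retrain the surrogate extractor,
    rebuild the graph from its predictions, retrain the GCN."""
    collected: dict[float, list[EvalReport]] = {w: [] for w in WF_GRID}
    for rep in range(cfg.n_seeds):
        cohort = simulate_cohort(
            replace(cfg.cohort, seed=subseed(cfg.seed, "cohort", rep))
        )
        train_mask, test_mask = _split(cohort, cfg, rep)
        for w_f in WF_GRID:
            ecfg = replace(cfg.extractor, w_f=w_f)
            model = train_extractor(cohort, ecfg, train_rows=train_mask)
            Z_auto = extract_features(model, cohort.signals)
            collected[w_f].append(
                gcn_run(
                    Z_auto, cohort.labels, train_mask, test_mask, cfg, rep
                )
            )
    rows = [{"w_f": w, **summarize(reps)} for w, reps in collected.items()]
    return _rows_to_frame(rows)


def run_layer_sweep(cfg: RunConfig) -> pd.DataFrame:
    """GCN depth 1-4 on a fixed graph/embedding per replicate."""
    collected: dict[int, list[EvalReport]] = {l: [] for l in LAYER_GRID}
    for rep in range(cfg.n_seeds):
        cohort = simulate_cohort(
            replace(cfg.cohort, seed=subseed(cfg.seed, "cohort", rep))
        )
        train_mask, test_mask = _split(cohort, cfg, rep)
        graph = build_semantic_graph(
            cohort.Z, labels=_masked_labels(cohort.labels, test_mask)
        )
        emb_cfg = replace(cfg.embedding, seed=subseed(cfg.seed, "embed", rep))
        X = embed_graph(graph, emb_cfg).X
        for L in LAYER_GRID:
            tcfg = replace(
                cfg.train, n_layers=L, seed=subseed(cfg.seed, "train", rep)
            )
            params, _ = train_detector(graph, X, train_mask, tcfg)
            _, hard = predict(graph, X, params)
            collected[L].append(
                evaluate(cohort.labels[test_mask], hard[test_mask])
            )
    rows = [{"n_layers": l, **summarize(reps)} for l, reps in collected.items()]
    return _rows_to_frame(rows)


def run_stability_train_size(cfg: RunConfig) -> pd.DataFrame:
    """Shrink the training set (floor rule) with the test set fixed.

    By default the dropped training images are removed from the graph
    entirely (vertices and edges); with ``subset_removes_vertices=False``
    only their labels are hidden.
    """
    collected: dict[float, list[EvalReport]] = {f: [] for f in TRAIN_FRACTIONS}
    for rep in range(cfg.n_seeds):
        cohort = simulate_cohort(
            replace(cfg.cohort, seed=subseed(cfg.seed, "cohort", rep))
        )
        train_mask, test_mask = _split(cohort, cfg, rep)
        for frac in TRAIN_FRACTIONS:
            sub = (
                train_mask
                if frac == 1.0
                else subset_training(
                    train_mask, frac, subseed(cfg.seed, "subset", rep, frac)
                )
            )
            if cfg.subset_removes_vertices:
                keep_rows = sub | test_mask
                idx = np.flatnonzero(keep_rows)
                Z = cohort.Z[idx]
                labels = cohort.labels[idx]
                new_train = sub[idx]
                new_test = test_mask[idx]
            else:
                Z, labels = cohort.Z, cohort.labels
                new_train, new_test = sub, test_mask
            collected[frac].append(
                gcn_run(Z, labels, new_train, new_test, cfg, rep)
            )
    rows = [
        {"train_fraction": f, **summarize(reps)}
        for f, reps in collected.items()
    ]
    return _rows_to_frame(rows)


def run_stability_edges(cfg: RunConfig) -> pd.DataFrame:
    """Randomly retain a fraction of graph edges, retrain and evaluate."""
    collected: dict[float, list[EvalReport]] = {f: [] for f in KEEP_FRACTIONS}
    for rep in range(cfg.n_seeds):
        cohort = simulate_cohort(
            replace(cfg.cohort, seed=subseed(cfg.seed, "cohort", rep))
        )
        train_mask, test_mask = _split(cohort, cfg, rep)
        full = build_semantic_graph(
            cohort.Z, labels=_masked_labels(cohort.labels, test_mask)
        )
        for frac in KEEP_FRACTIONS:
            g = (
                full
                if frac == 1.0
                else drop_edges(full, frac, subseed(cfg.seed, "edges", rep, frac))
            )
            collected[frac].append(
                gcn_run(None, cohort.labels, train_mask, test_mask, cfg, rep, graph=g)
            )
    rows = [
        {"keep_fraction": f, **summarize(reps)} for f, reps in collected.items()
    ]
    return _rows_to_frame(rows)


def cohort_fingerprint(cfg: RunConfig) -> str:
    """SHA-256 of the replicate-0 coding matrix (config/seed provenance)."""
    cohort = simulate_cohort(
        replace(cfg.cohort, seed=subseed(cfg.seed, "cohort", 0))
    )
    return hashlib.sha256(np.ascontiguousarray(cohort.Z).tobytes()).hexdigest()


def config_echo(cfg: RunConfig) -> dict:
    """All resolved settings as a plain dict (for YAML/JSON serialization)."""
    return asdict(cfg)


def write_outputs(df: pd.DataFrame, cfg: RunConfig, out_dir, name: str) -> None:
    """Write the report CSV, a config echo, and the cohort fingerprint."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    echo = config_echo(cfg)
    echo["cohort_fingerprint"] = cohort_fingerprint(cfg)
    with open(out / f"{name}_config.json", "w") as fh:
        json.dump(echo, fh, indent=2, default=str)
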