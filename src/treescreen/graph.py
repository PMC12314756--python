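"""Bipartite image-feature semantic graph.

A drawing cohort's binary coding matrix Z (M drawings x N features) defines a
bipartite graph: one vertex per drawing, one per catalog feature, and an edge
wherever z_ij = 1.  Vertex order is canonical: images first (row order), then
features (catalog order).  The GCN operates on the symmetric degree-normalized
adjacency ``A_hat = D^{-1/2} A D^{-1/2}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .catalog import FeatureCatalog

UNLABELED = -1


@dataclass
class SemanticGraph:
    """Bipartite graph over image vertices and feature vertices.

    ``edges`` holds (image_index, feature_index) pairs, both 0-based within
    their own vertex set.  ``labels`` is one entry per image vertex with
    ``UNLABELED`` (-1) marking vertices whose label is hidden.
    """

    image_ids: list[str]
    feature_ids: list[str]
    edges: set[tuple[int, int]]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.full(len(self.image_ids), UNLABELED, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.image_ids),):
            raise ValueError("labels must have one entry per image vertex")

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_vertices(self) -> int:
        return self.n_images + self.n_features

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def vertex_ids(self) -> list[str]:
        return list(self.image_ids) + list(self.feature_ids)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as sorted (image_index, feature_index) arrays."""
        if not self.edges:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        e = np.array(sorted(self.edges), dtype=np.int64)
        return e[:, 0], e[:, 1]

    def to_coding_matrix(self) -> np.ndarray:
        Z = np.zeros((self.n_images, self.n_features), dtype=np.int8)
        if self.edges:
            ii, jj = self.edge_arrays()
            Z[ii, jj] = 1
        return Z


@dataclass
class AdjacencyPair:
    """Adjacency A and its symmetric normalization A_hat (sparse CSR)."""

    A: sp.csr_matrix
    A_hat: sp.csr_matrix
    self_loops: bool


def build_semantic_graph(
    Z: np.ndarray,
    labels: np.ndarray | None = None,
    image_ids: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> SemanticGraph:
    """Build the bipartite graph from a binary coding matrix.

    One image vertex per row, one feature vertex per column, one edge per
    1-cell; isolated vertices (all-zero rows/columns) are retained.
    """
    Z = np.asarray(Z)
    if not np.isin(Z, (0, 1)).all():
        raise ValueError("coding matrix must be binary")
    m, n = Z.shape
    image_ids = image_ids or [f"img_{i + 1:04d}" for i in range(m)]
    feature_ids = feature_ids or [f"feat_{j + 1:03d}" for j in range(n)]
    if len(image_ids) != m or len(feature_ids) != n:
        raise ValueError("id lists must match coding-matrix shape")
    ii, jj = np.nonzero(Z)
    edges = set(zip(ii.tolist(), jj.tolist()))
    return SemanticGraph(
        image_ids=list(image_ids),
        feature_ids=list(feature_ids),
        edges=edges,
        labels=labels,
    )


def adjacency(graph: SemanticGraph, self_loops: bool = False) -> AdjacencyPair:
    """Assemble A and A_hat = D^{-1/2} A D^{-1/2} for a graph.

    With ``self_loops`` the identity is added to A before normalizing (the
    common GCN renormalization trick); the default follows the plain
    formula.  Degree-zero vertices get zero rows/columns in A_hat.
    """
    nv = graph.n_vertices
    ii, jj = graph.edge_arrays()
    rows = np.concatenate([ii, jj + graph.n_images])
    cols = np.concatenate([jj + graph.n_images, ii])
    data = np.ones(rows.size)
    A = sp.csr_matrix((data, (rows, cols)), shape=(nv, nv))
    if self_loops:
        A = (A + sp.identity(nv, format="csr")).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    D_inv_sqrt = sp.diags(d_inv_sqrt)
    A_hat = (D_inv_sqrt @ A @ D_inv_sqrt).tocsr()
    return AdjacencyPair(A=A, A_hat=A_hat, self_loops=self_loops)


def graph_density(graph: SemanticGraph) -> float:
    """Undirected simple-graph edge density |E| / (|V| choose 2)."""
    nv = graph.n_vertices
    if nv < 2:
        raise ValueError("density needs at least two vertices")
    return graph.n_edges / (nv * (nv - 1) / 2)


def drop_edges(graph: SemanticGraph, keep_fraction: float, seed: int) -> SemanticGraph:
    """Keep a uniform random subset of round(keep_fraction * |E|) edges.

    Vertices are unchanged (dropped-to-isolation vertices stay in the graph).
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    edges = sorted(graph.edges)
    n_keep = int(round(keep_fraction * len(edges)))
    rng = np.random.default_rng(seed)
    kept_idx = rng.choice(len(edges), size=n_keep, replace=False)
    kept = {edges[i] for i in kept_idx}
    return replace(graph, edges=kept)


def remove_feature_class(
    graph: SemanticGraph, catalog: FeatureCatalog, class_name: str
) -> SemanticGraph:
    """Delete one feature class's vertices and all incident edges.

    Used by the ablation protocol; image vertices are untouched.  Assumes the
    graph's feature vertices follow catalog order.
    """
    removed = set(catalog.class_indices(class_name))
    if graph.n_features != catalog.n_features:
        raise ValueError("graph feature set does not match catalog")
    keep = [j for j in range(graph.n_features) if j not in removed]
    remap = {old: new for new, old in enumerate(keep)}
    new_edges = {
        (i, remap[j]) for i, j in graph.edges if j not in removed
    }
    return SemanticGraph(
        image_ids=list(graph.image_ids),
        feature_ids=[graph.feature_ids[j] for j in keep],
        edges=new_edges,
        labels=graph.labels.copy(),
    )


def split_nodes(
    n_images: int, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform train/test split of image vertices (round() train count).

    Returns boolean masks over image vertices; the split is unstratified.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n_images))
    if n_train == 0 or n_train == n_images:
        raise ValueError("split leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_images)
    train = np.zeros(n_images, dtype=bool)
    train[perm[:n_train]] = True
    return train, ~train


def subset_training(
    train_mask: np.ndarray, fraction: float, seed: int
) -> np.ndarray:
    """Keep floor(fraction * |train|) training vertices uniformly at random."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    train_mask = np.asarray(train_mask, dtype=bool)
    idx = np.flatnonzero(train_mask)
    n_keep = int(np.floor(fraction * idx.size))
    if n_keep == 0:
        raise ValueError("subset would be empty")
    rng = np.random.default_rng(seed)
    kept = rng.choice(idx, size=n_keep, replace=False)
    out = np.zeros_like(train_mask)
    out[kept] = True
    return out


def write_graph(graph: SemanticGraph, edge_path, vertex_path) -> None:
    """Serialize as a TSV edge list plus a vertex table CSV."""
    ii, jj = graph.edge_arrays()
    pd.DataFrame(
        {
            "image_id": [graph.image_ids[i] for i in ii],
            "feature_id": [graph.feature_ids[j] for j in jj],
        }
    ).to_csv(edge_path, sep="\t", index=False)
    vtab = pd.DataFrame(
        {
            "vertex_id": graph.vertex_ids(),
            "type": ["image"] * graph.n_images + ["feature"] * graph.n_features,
            "label": list(graph.labels) + [UNLABELED] * graph.n_features,
        }
    )
    vtab.to_csv(vertex_path, index=False)


def read_graph(edge_path, vertex_path) -> SemanticGraph:
    vtab = pd.read_csv(vertex_path)
    image_ids = vtab.loc[vtab["type"] == "image", "vertex_id"].tolist()
    feature_ids = vtab.loc[vtab["type"] == "feature", "vertex_id"].tolist()
    labels = vtab.loc[vtab["type"] == "image", "label"].to_numpy(dtype=np.int8)
    img_idx = {v: i for i, v in enumerate(image_ids)}
    feat_idx = {v: j for j, v in enumerate(feature_ids)}
    etab = pd.read_csv(edge_path, sep="\t")
    edges = {
        (img_idx[a], feat_idx[b])
        for a, b in zip(etab["image_id"], etab["feature_id"])
    }
    return SemanticGraph(
        image_ids=image_ids, feature_ids=feature_ids, edges=edges, labels=labels
    )
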