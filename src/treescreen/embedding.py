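"""Initial node representations via biased random walks + skip-gram.

Vertices of the semantic graph get low-dimensional embeddings in the
node2vec style: second-order random walks (return parameter ``p``, in-out
parameter ``q``) generate a corpus of vertex sequences, and skip-gram with
negative sampling (SGNS) is trained on that corpus so that vertices that
co-occur on walks — i.e. structurally close vertices — end up with similar
vectors.  The resulting |V| x k matrix is the GCN's input representation.

The SGNS trainer is a numba-compiled sequential kernel in the classic
word2vec style: dynamic window, unigram^0.75 noise distribution, linearly
decaying step size, corpus-order streaming.  It is single-threaded and
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .graph import SemanticGraph, adjacency


@dataclass
class EmbeddingConfig:
    """node2vec-style hyperparameters.

    With p = q = 1 the walk is first-order (unbiased); p < 1 encourages
    backtracking, q < 1 encourages outward exploration.
    """

    k: int = 128
    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    negative_samples: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("embedding dimension k must be >= 2")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass
class NodeEmbeddings:
    """|V| x k representation matrix aligned with graph vertex order."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("embeddings must be finite")


def _csr_neighbors(graph: SemanticGraph):
    A = adjacency(graph, self_loops=False).A
    return A.indptr, A.indices


def transition_weights(
    prev: int, cur: int, neighbors: np.ndarray, neighbor_sets, p: float, q: float
) -> np.ndarray:
    """Unnormalized second-order weights for stepping from cur (came from prev).

    1/p to return to prev, 1 to a common neighbor of prev, 1/q otherwise.
    """
    w = np.empty(neighbors.size)
    prev_nbrs = neighbor_sets[prev]
    for idx, x in enumerate(neighbors):
        if x == prev:
            w[idx] = 1.0 / p
        elif x in prev_nbrs:
            w[idx] = 1.0
        else:
            w[idx] = 1.0 / q
    return w


def random_walks(graph: SemanticGraph, cfg: EmbeddingConfig) -> list[np.ndarray]:
    """Generate ``walks_per_node`` walks from every vertex.

    Isolated start vertices yield a length-1 walk (the vertex itself); a walk
    reaching a neighborless vertex stops early.  The unbiased case p = q = 1
    runs all walks in lock-step with vectorized neighbor sampling; the biased
    case falls back to a per-step loop.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    indptr, indices = _csr_neighbors(graph)
    nv = graph.n_vertices
    deg = np.diff(indptr)

    starts = np.repeat(np.arange(nv), cfg.walks_per_node)
    if cfg.p == 1.0 and cfg.q == 1.0:
        walks_mat = np.empty((starts.size, cfg.walk_length), dtype=np.int64)
        walks_mat[:, 0] = starts
        cur = starts.copy()
        alive = deg[cur] > 0
        if indices.size == 0:
            return [walks_mat[i, :1] for i in range(starts.size)]
        for t in range(1, cfg.walk_length):
            pick = rng.integers(0, np.maximum(deg[cur], 1))
            # dead walks (isolated starts) keep cur fixed; clamp their
            # lookup so the fancy index stays in range
            nxt = indices[np.minimum(indptr[cur] + pick, indices.size - 1)]
            cur = np.where(alive, nxt, cur)
            walks_mat[:, t] = cur
            alive = alive & (deg[cur] > 0)
        lengths = np.where(deg[starts] > 0, cfg.walk_length, 1)
        return [walks_mat[i, : lengths[i]] for i in range(starts.size)]

    neighbor_sets = [
        frozenset(indices[indptr[v]: indptr[v + 1]].tolist()) for v in range(nv)
    ]
    walks: list[np.ndarray] = []
    for s in starts:
        walk = [int(s)]
        if deg[s] == 0:
            walks.append(np.array(walk, dtype=np.int64))
            continue
        nbrs = indices[indptr[s]: indptr[s + 1]]
        walk.append(int(nbrs[rng.integers(0, nbrs.size)]))
        while len(walk) < cfg.walk_length:
            cur = walk[-1]
            nbrs = indices[indptr[cur]: indptr[cur + 1]]
            if nbrs.size == 0:
                break
            w = transition_weights(walk[-2], cur, nbrs, neighbor_sets, cfg.p, cfg.q)
            w /= w.sum()
            walk.append(int(rng.choice(nbrs, p=w)))
        walks.append(np.array(walk, dtype=np.int64))
    return walks


@njit(cache=True)
def _sgns_kernel(
    flat, offsets, W_in, W_out, noise_cdf, window, n_neg, epochs, lr0, seed
):  # pragma: no cover - exercised through skipgram_embed
    np.random.seed(seed)
    k = W_in.shape[1]
    n_walks = offsets.size - 1
    total = epochs * flat.size
    processed = 0
    neu = np.empty(k)
    for _ in range(epochs):
        for wi in range(n_walks):
            start, end = offsets[wi], offsets[wi + 1]
            n = end - start
            for t in range(n):
                processed += 1
                lr = lr0 * max(1.0 - processed / total, 1e-4)
                c = flat[start + t]
                b = np.random.randint(1, window + 1)
                lo = t - b if t - b > 0 else 0
                hi = t + b + 1 if t + b + 1 < n else n
                for u in range(lo, hi):
                    if u == t:
                        continue
                    o = flat[start + u]
                    for d in range(k):
                        neu[d] = 0.0
                    # one positive target, n_neg noise targets
                    for s in range(n_neg + 1):
                        if s == 0:
                            tgt, label = o, 1.0
                        else:
                            r = np.random.random()
                            tgt = np.searchsorted(noise_cdf, r)
                            if tgt == o:
                                continue
                            label = 0.0
                        f = 0.0
                        for d in range(k):
                            f += W_in[c, d] * W_out[tgt, d]
                        # g = (sigmoid(f) - label) * lr, with clamped logits
                        if f > 8.0:
                            sg = 1.0
                        elif f < -8.0:
                            sg = 0.0
                        else:
                            sg = 1.0 / (1.0 + np.exp(-f))
                        g = (sg - label) * lr
                        for d in range(k):
                            neu[d] += g * W_out[tgt, d]
                            W_out[tgt, d] -= g * W_in[c, d]
                    for d in range(k):
                        W_in[c, d] -= neu[d]


def skipgram_embed(
    walks: list[np.ndarray], cfg: EmbeddingConfig, n_vertices: int | None = None
) -> NodeEmbeddings:
    """Train SGNS on a walk corpus; vertices absent from all walks get zeros.

    Negative contexts are drawn from the unigram distribution raised to 0.75
    (singleton walks contribute neither training pairs nor noise mass).  The
    step size decays linearly over the corpus sweep.
    """
    cfg.validate()
    if not walks:
        raise ValueError("empty walk corpus")
    if n_vertices is None:
        n_vertices = int(max(int(w.max()) for w in walks)) + 1
    rng = np.random.default_rng(cfg.seed + 1)

    useful = [w for w in walks if w.size >= 2]
    counts = np.zeros(n_vertices)
    for w in useful:
        np.add.at(counts, w, 1.0)
    noise = counts**0.75
    if noise.sum() == 0:
        # Fully isolated graph: no co-occurrence evidence at all.
        return NodeEmbeddings(X=np.zeros((n_vertices, cfg.k)))
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0

    flat = np.concatenate(useful).astype(np.int64)
    offsets = np.zeros(len(useful) + 1, dtype=np.int64)
    np.cumsum([w.size for w in useful], out=offsets[1:])

    W_in = (rng.random((n_vertices, cfg.k)) - 0.5) / cfg.k
    W_out = np.zeros((n_vertices, cfg.k))
    _sgns_kernel(
        flat,
        offsets,
        W_in,
        W_out,
        noise_cdf,
        cfg.window,
        cfg.negative_samples,
        cfg.epochs,
        cfg.learning_rate,
        cfg.seed % (2**31),
    )
    W_in[counts == 0] = 0.0
    return NodeEmbeddings(X=W_in)


def embed_graph(graph: SemanticGraph, cfg: EmbeddingConfig) -> NodeEmbeddings:
    """Walks + SGNS in one call, aligned to the graph's vertex order."""
    walks = random_walks(graph, cfg)
    return skipgram_embed(walks, cfg, n_vertices=graph.n_vertices)


def write_embeddings(emb: NodeEmbeddings, vertex_ids: list[str], path) -> None:
    import pandas as pd

    df = pd.DataFrame(emb.X, index=vertex_ids)
    df.index.name = "vertex_id"
    df.to_csv(path)
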