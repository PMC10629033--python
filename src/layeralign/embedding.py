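"""Node embeddings from second-order biased random walks + skip-gram.

A node is characterised on the whole set of its interactions: walks run on
the *flat* representation of the multilayer network, traversing intralayer
and interlayer edges alike (edge types play no role during walking).  The
walk corpus is fed to a skip-gram model with negative sampling whose
hidden-layer size ``N`` is the embedding dimension.

Reproducibility contract: training is single-threaded, walks and negative
sampling are driven by the configured seed, and each node's input vector
is initialised from a stable hash of its identifier combined with the
seed.  Two identical graphs embedded with the same configuration therefore
produce bit-identical embedding matrices, and near-identical graphs that
share node identifiers produce embedding spaces that are directly
comparable by cosine similarity — the property the whole alignment
pipeline rests on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._sgns import sgns_train
from .graph_model import FlatGraph, MultilayerNetwork, to_flat

__all__ = [
    "EmbeddingConfig",
    "NodeEmbeddings",
    "WalkError",
    "CoverageError",
    "random_walks",
    "train_embeddings",
    "embed_network",
    "write_word2vec_text",
    "read_word2vec_text",
]


class WalkError(RuntimeError):
    """Random walks cannot be generated (e.g. an isolated node)."""


class CoverageError(RuntimeError):
    """The walk corpus does not cover every requested node."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the walk + skip-gram pipeline.

    Defaults follow the common node2vec settings: 128 dimensions, 10 walks
    of 80 nodes per start node, window 5, 5 epochs, and neutral
    second-order bias (``return_param = inout_param = 1`` reduces the walk
    to a uniform first-order random walk).
    """

    dimensions: int = 128
    num_walks: int = 10
    walk_length: int = 80
    window: int = 5
    epochs: int = 5
    seed: int = 0
    return_param: float = 1.0
    inout_param: float = 1.0
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 0.0001

    def __post_init__(self) -> None:
        for name in ("dimensions", "num_walks", "walk_length", "window", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.negative < 1:
            raise ValueError("negative must be >= 1")
        for name in ("return_param", "inout_param"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class NodeEmbeddings:
    """Per-node real vectors of dimension ``N`` plus the config that made them."""

    def __init__(self, labels, matrix: np.ndarray, config: EmbeddingConfig):
        self.labels: tuple[str, ...] = tuple(labels)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.labels), config.dimensions):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.labels)} labels x {config.dimensions} dimensions"
            )
        self.config = config
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __contains__(self, u: str) -> bool:
        return u in self._index

    def __len__(self) -> int:
        return len(self.labels)

    def node_vector(self, u: str, unit_norm: bool = False) -> np.ndarray:
        """The query vector of node ``u`` (its projection-weight row)."""
        try:
            vec = self.matrix[self._index[u]]
        except KeyError:
            raise KeyError(f"unknown node {u!r}") from None
        if unit_norm:
            norm = np.linalg.norm(vec)
            if norm == 0:
                raise ValueError(f"zero vector for node {u!r}")
            return vec / norm
        return vec.copy()

    def neighborhood_mean(self, u: str, graph: MultilayerNetwork) -> np.ndarray:
        """Mean of the node's vector and its neighbours' vectors (optional
        alternative query vector)."""
        members = [u, *sorted(graph.neighbors(u))]
        return np.mean([self.node_vector(x) for x in members], axis=0)


def _label_seed(label: str, seed: int) -> int:
    digest = hashlib.md5(label.encode("utf-8")).digest()
    return (int.from_bytes(digest[:4], "little") ^ (seed & 0xFFFFFFFF)) % (2**32)


def random_walks(
    g: FlatGraph | MultilayerNetwork,
    config: EmbeddingConfig,
    rng: np.random.Generator | None = None,
) -> list[list[str]]:
    """Generate ``num_walks`` biased walks of ``walk_length`` nodes per node.

    Transitions follow the second-order scheme: stepping from ``cur`` with
    predecessor ``prev``, a neighbour ``x`` is weighted ``1/return_param``
    if ``x == prev``, ``1`` if ``x`` is adjacent to ``prev``, and
    ``1/inout_param`` otherwise.  With both parameters at 1 this is the
    uniform random walk.  Edge types are ignored: all layers are traversed
    alike.
    """
    if isinstance(g, MultilayerNetwork):
        g = to_flat(g)
    adj = g.adjacency()
    if not adj:
        raise WalkError("cannot walk an empty graph")
    for node, nbrs in adj.items():
        if not nbrs:
            raise WalkError(f"node {node!r} is isolated; walks are undefined")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nodes = sorted(adj)
    nbr_sets = {n: frozenset(adj[n]) for n in nodes}
    p, q = config.return_param, config.inout_param
    uniform = p == 1.0 and q == 1.0

    walks: list[list[str]] = []
    for _ in range(config.num_walks):
        for start in nodes:
            walk = [start]
            prev: str | None = None
            cur = start
            for _ in range(config.walk_length - 1):
                nbrs = adj[cur]
                if uniform or prev is None or len(nbrs) == 1:
                    nxt = nbrs[int(rng.integers(len(nbrs)))]
                else:
                    w = np.empty(len(nbrs))
                    prev_nb = nbr_sets[prev]
                    for idx, x in enumerate(nbrs):
                        if x == prev:
                            w[idx] = 1.0 / p
                        elif x in prev_nb:
                            w[idx] = 1.0
                        else:
                            w[idx] = 1.0 / q
                    w /= w.sum()
                    nxt = nbrs[int(rng.choice(len(nbrs), p=w))]
                walk.append(nxt)
                prev, cur = cur, nxt
            walks.append(walk)
    return walks


def train_embeddings(
    walks: list[list[str]],
    config: EmbeddingConfig,
    expected_nodes=None,
) -> NodeEmbeddings:
    """Train skip-gram/negative-sampling vectors on a walk corpus.

    The vocabulary is the set of nodes occurring in the corpus; when
    ``expected_nodes`` is supplied, missing nodes raise ``CoverageError``.
    The noise distribution is the unigram frequency raised to 3/4, as in
    word2vec.  Learning rate decays linearly from ``alpha`` to
    ``min_alpha`` over all token positions.
    """
    if not walks:
        raise ValueError("empty walk corpus")
    counts: dict[str, int] = {}
    for walk in walks:
        for tok in walk:
            counts[tok] = counts.get(tok, 0) + 1
    labels = sorted(counts)
    if expected_nodes is not None:
        missing = set(expected_nodes) - set(labels)
        if missing:
            raise CoverageError(
                f"corpus does not cover node(s) {sorted(missing)[:5]}"
            )
    index = {lab: i for i, lab in enumerate(labels)}
    dim = config.dimensions

    # gensim-style per-label deterministic init keeps embedding spaces of
    # similar graphs comparable
    W = np.empty((len(labels), dim), dtype=np.float64)
    for lab, i in index.items():
        rs = np.random.default_rng(_label_seed(lab, config.seed))
        W[i] = (rs.random(dim) - 0.5) / dim
    C = np.zeros_like(W)

    freq = np.array([counts[lab] for lab in labels], dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())
    noise_cdf[-1] = 1.0

    tokens = np.fromiter(
        (index[tok] for walk in walks for tok in walk),
        dtype=np.int32,
        count=sum(len(w) for w in walks),
    )
    offsets = np.zeros(len(walks) + 1, dtype=np.int64)
    np.cumsum([len(w) for w in walks], out=offsets[1:])

    sgns_train(
        tokens,
        offsets,
        W,
        C,
        config.window,
        config.negative,
        noise_cdf,
        config.alpha,
        config.min_alpha,
        config.epochs,
        (config.seed * 2654435761 + 1) % (2**32),
    )
    return NodeEmbeddings(labels, W, config)


def embed_network(
    net: MultilayerNetwork | FlatGraph,
    config: EmbeddingConfig,
) -> NodeEmbeddings:
    """Walks + training in one call, with node-coverage checking."""
    flat = to_flat(net) if isinstance(net, MultilayerNetwork) else net
    walks = random_walks(flat, config)
    return train_embeddings(walks, config, expected_nodes=flat.nodes)


def write_word2vec_text(emb: NodeEmbeddings, path: str | Path) -> None:
    """Write embeddings in the word2vec text format (``V N`` header)."""
    with open(path, "w") as fh:
        fh.write(f"{len(emb.labels)} {emb.config.dimensions}\n")
        for lab in emb.labels:
            vec = " ".join(f"{x:.8g}" for x in emb.node_vector(lab))
            fh.write(f"{lab} {vec}\n")


def read_word2vec_text(path: str | Path, config: EmbeddingConfig | None = None) -> NodeEmbeddings:
    with open(path) as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1 : dim + 1]])
    if len(labels) != n:
        raise ValueError(f"header declares {n} vectors, found {len(labels)}")
    if config is None:
        config = EmbeddingConfig(dimensions=dim)
    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    matrix = np.asarray(rows, dtype=np.float64)[order]
    return NodeEmbeddings(labels, matrix, config)
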