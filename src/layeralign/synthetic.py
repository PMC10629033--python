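"""Synthetic multilayer benchmark networks with known ground-truth mapping.

Each layer is grown by an extended preferential-attachment process: a plain
Barabási–Albert growth (each new node attaches with ``m`` edges, targets
chosen proportionally to degree) augmented by two per-step events that
emulate duplication/divergence in biological networks — with probability
``p`` one extra edge is added between randomly chosen existing nodes, and
with probability ``q`` one existing edge is removed, chosen only among
edges whose removal isolates neither endpoint.  With ``p = q = 0`` the
process reduces exactly to the Barabási–Albert model, so a layer has
``m * (n - m)`` edges.

Layers get disjoint node namespaces; interlayer edges are then sampled
uniformly over cross-layer node pairs until they make up a configurable
fraction of the total edge count (default 20%).  Noisy counterparts are
produced either by deleting a fraction of edges (never isolating a node)
or by noising entries of a similarity matrix directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .graph_model import EdgeRecord, MultilayerNetwork

__all__ = [
    "GeneratorConfig",
    "TrueMapping",
    "PerturbationError",
    "generate_layer",
    "generate_multilayer",
    "perturb_edges",
    "perturb_similarity",
]


class PerturbationError(RuntimeError):
    """No admissible perturbation exists for the requested fraction."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic multilayer benchmark generator.

    ``n`` nodes per layer, ``m`` edges per new node, ``p`` the probability
    of adding one extra random edge after each attachment, ``q`` the
    probability of removing one non-isolating edge, ``num_layers`` layers,
    and ``interlayer_fraction`` the share of the final total edge count
    made up by interlayer edges.
    """

    n: int = 100
    m: int = 2
    p: float = 0.5
    q: float = 0.4
    num_layers: int = 2
    interlayer_fraction: float = 0.20
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.m < self.n:
            raise ValueError(f"need 1 <= m < n, got m={self.m}, n={self.n}")
        for name in ("p", "q"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if not 0.0 <= self.interlayer_fraction < 1.0:
            raise ValueError(
                f"interlayer_fraction must lie in [0, 1), got {self.interlayer_fraction}"
            )
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")


@dataclass(frozen=True)
class TrueMapping:
    """Injective ground-truth node mapping (identity for generated benchmarks)."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", dict(self.pairs))
        if len(set(self.pairs.values())) != len(self.pairs):
            raise ValueError("true mapping must be injective")

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, v: str) -> str:
        return self.pairs[v]

    def __contains__(self, v: str) -> bool:
        return v in self.pairs

    def items(self):
        return self.pairs.items()

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for v, u in sorted(self.pairs.items()):
                fh.write(f"{v}\t{u}\n")

    @classmethod
    def read_tsv(cls, path) -> "TrueMapping":
        pairs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                v, u = line.split("\t")[:2]
                pairs[v] = u
        return cls(pairs)


def _sample_targets(repeated: list[int], m: int, rng: np.random.Generator) -> set[int]:
    # degree-proportional sampling of m distinct targets via the repeated-node list
    targets: set[int] = set()
    while len(targets) < m:
        targets.add(repeated[rng.integers(len(repeated))])
    return targets


def generate_layer(
    config: GeneratorConfig,
    layer_id: int,
    rng: np.random.Generator,
    prefix: str = "",
) -> set[EdgeRecord]:
    """Grow one intralayer edge set of ``config.n`` nodes tagged ``layer_id``.

    Node identifiers are ``f"{prefix}{i}"`` for ``i`` in ``0..n-1``.  After
    each new node attaches, the ``p``-addition event fires first and the
    ``q``-removal second; the removal candidate pool contains only edges
    whose endpoints both keep degree >= 1 afterwards, so no node is ever
    isolated.
    """
    n, m, p, q = config.n, config.m, config.p, config.q
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    edges: set[tuple[int, int]] = set()

    def add(a: int, b: int) -> None:
        edges.add((a, b) if a < b else (b, a))
        adj[a].add(b)
        adj[b].add(a)

    def remove(a: int, b: int) -> None:
        edges.discard((a, b) if a < b else (b, a))
        adj[a].discard(b)
        adj[b].discard(a)

    # first growth node connects to all m seed nodes; afterwards targets are
    # drawn degree-proportionally from the repeated-endpoint list
    repeated: list[int] = []
    existing = m
    for new in range(m, n):
        targets = (
            set(range(m)) if not repeated else _sample_targets(repeated, m, rng)
        )
        for t in targets:
            add(new, t)
            repeated.extend((new, t))
        existing = new + 1

        if p > 0 and rng.random() < p:
            # one extra edge between randomly chosen existing, non-adjacent nodes
            for _ in range(20):
                a, b = rng.integers(existing), rng.integers(existing)
                if a != b and b not in adj[a]:
                    add(int(a), int(b))
                    repeated.extend((int(a), int(b)))
                    break
        if q > 0 and rng.random() < q:
            candidates = sorted(
                e for e in edges if len(adj[e[0]]) > 1 and len(adj[e[1]]) > 1
            )
            if candidates:
                a, b = candidates[rng.integers(len(candidates))]
                remove(a, b)

    return {
        EdgeRecord(f"{prefix}{a}", f"{prefix}{b}", layer_id) for a, b in edges
    }


def generate_multilayer(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MultilayerNetwork, TrueMapping]:
    """Generate a multilayer benchmark network and its identity true mapping.

    Layers use disjoint namespaces (``l1_*``, ``l2_*``, ...); interlayer
    edges are sampled uniformly without replacement over cross-layer node
    pairs until ``|E_b| = round(f / (1 - f) * |E_a|)``, i.e. interlayer
    edges are the fraction ``f`` of the final total edge count.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layer_ids = tuple(range(1, config.num_layers + 1))
    interlayer_id = config.num_layers + 1

    edges: set[EdgeRecord] = set()
    layer_nodes: list[list[str]] = []
    for lid in layer_ids:
        prefix = f"l{lid}_"
        edges |= generate_layer(config, lid, rng, prefix=prefix)
        layer_nodes.append([f"{prefix}{i}" for i in range(config.n)])

    n_intra = len(edges)
    f = config.interlayer_fraction
    n_inter = int(round(f / (1.0 - f) * n_intra)) if f > 0 else 0

    if n_inter > 0 and config.num_layers < 2:
        raise ValueError("interlayer edges require at least two layers")
    inter: set[EdgeRecord] = set()
    # cross-layer pairs sampled uniformly; duplicates rejected
    max_pairs = sum(
        len(layer_nodes[i]) * len(layer_nodes[j])
        for i in range(len(layer_nodes))
        for j in range(i + 1, len(layer_nodes))
    )
    if n_inter > max_pairs:
        raise ValueError("interlayer_fraction infeasible for this layer size")
    while len(inter) < n_inter:
        i, j = sorted(rng.choice(config.num_layers, size=2, replace=False))
        u = layer_nodes[i][rng.integers(config.n)]
        v = layer_nodes[j][rng.integers(config.n)]
        rec = EdgeRecord(u, v, interlayer_id)
        if rec not in inter:
            inter.add(rec)

    net = MultilayerNetwork(
        edges=frozenset(edges | inter),
        layer_ids=layer_ids,
        interlayer_id=interlayer_id,
    )
    truth = TrueMapping({node: node for node in net.nodes})
    return net, truth


def perturb_edges(
    net: MultilayerNetwork,
    fraction: float,
    rng: np.random.Generator,
) -> MultilayerNetwork:
    """Remove ``floor(fraction * |E_M|)`` uniformly chosen edges, never
    isolating a node; intralayer and interlayer edges are pooled.

    Candidates whose removal would isolate an endpoint are re-sampled; the
    node set of the result equals the input's.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    n_remove = math.floor(fraction * len(net.edges))
    if n_remove == 0:
        return MultilayerNetwork(
            edges=net.edges,
            layer_ids=net.layer_ids,
            interlayer_id=net.interlayer_id,
            nodes=net.nodes,
        )

    edges = sorted(net.edges)
    degree: dict[str, int] = {n: 0 for n in net.nodes}
    for e in edges:
        degree[e.u] += 1
        degree[e.v] += 1

    order = rng.permutation(len(edges))
    removed: set[EdgeRecord] = set()
    for idx in order:
        if len(removed) == n_remove:
            break
        e = edges[idx]
        if degree[e.u] > 1 and degree[e.v] > 1:
            removed.add(e)
            degree[e.u] -= 1
            degree[e.v] -= 1
    if len(removed) < n_remove:
        raise PerturbationError(
            f"cannot remove {n_remove} edges without isolating a node"
        )
    return MultilayerNetwork(
        edges=net.edges - removed,
        layer_ids=net.layer_ids,
        interlayer_id=net.interlayer_id,
        nodes=net.nodes,
    )


def perturb_similarity(
    S,
    fraction: float,
    rng: np.random.Generator,
    mode: str = "resample",
    jitter_sd: float = 0.1,
):
    """Noise a fraction of similarity-matrix entries in place of edge noise.

    A uniformly sampled ``floor(fraction * size)`` subset of entries is
    replaced.  In ``"resample"`` mode (default) replacements are drawn from
    the empirical distribution of the *untouched* entries, which preserves
    the matrix's value range; ``"jitter"`` adds Gaussian noise with
    standard deviation ``jitter_sd`` instead.  Shape and labels are kept.
    """
    from .alignment import SimilarityMatrix  # local import avoids cycle at import time

    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    values = np.array(S.values, dtype=float, copy=True)
    size = values.size
    k = math.floor(fraction * size)
    if k == 0:
        return SimilarityMatrix(S.row_labels, S.col_labels, values)
    flat = values.ravel()
    chosen = rng.choice(size, size=k, replace=False)
    if mode == "resample":
        mask = np.ones(size, dtype=bool)
        mask[chosen] = False
        pool = flat[mask]
        if pool.size == 0:
            raise PerturbationError("no untouched entries left to resample from")
        draws = pool[rng.integers(pool.size, size=k)]
        # redraw entries that happened to equal the original value
        for _ in range(16):
            same = flat[chosen] == draws
            if not same.any():
                break
            draws[same] = pool[rng.integers(pool.size, size=int(same.sum()))]
        flat[chosen] = draws
    elif mode == "jitter":
        flat[chosen] = flat[chosen] + rng.normal(0.0, jitter_sd, size=k)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    return SimilarityMatrix(S.row_labels, S.col_labels, flat.reshape(values.shape))
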