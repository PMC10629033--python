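"""Similarity matrix, greedy one-to-one pre-mapping, Jaccard refinement.

The pairwise global alignment maps every node ``v`` of the source network
``G = (V, ...)`` to a distinct node ``f(v)`` of the target ``H = (U, ...)``
(``|V| <= |U|``).  Candidate pairs are scored by the cosine similarity of
their embedding vectors; the pre-mapping accepts pairs in globally
descending similarity order, which resolves collisions by global
maximisation of the objective.  The pre-mapping is then refined by
permutations: pairs whose neighbourhood Jaccard coefficient is already 1
are final; the rest are revisited worst-first, and a swap between two
open pairs is accepted when it strictly raises the mapping's total Jaccard
overlap without lowering the total mapped similarity beyond a tolerance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .embedding import EmbeddingConfig, NodeEmbeddings, embed_network
from .graph_model import MultilayerNetwork

__all__ = [
    "SimilarityMatrix",
    "Alignment",
    "AlignmentConfigError",
    "cosine_similarity",
    "build_similarity_matrix",
    "identity_similarity",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "pre_mapping",
    "jaccard",
    "refine",
    "align",
]


class AlignmentConfigError(ValueError):
    """Inconsistent inputs to the alignment pipeline."""


@dataclass
class SimilarityMatrix:
    """Labelled |V| x |U| matrix of source-vs-target node similarities."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        self._ri = {lab: i for i, lab in enumerate(self.row_labels)}
        self._ci = {lab: i for i, lab in enumerate(self.col_labels)}

    def __getitem__(self, key: tuple[str, str]) -> float:
        v, u = key
        return float(self.values[self._ri[v], self._ci[u]])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "SimilarityMatrix":
        return SimilarityMatrix(self.col_labels, self.row_labels, self.values.T)


@dataclass
class Alignment:
    """A one-to-one node mapping with per-pair similarity scores.

    ``pairs`` is a list of ``(v, f(v), score)`` ordered by source node;
    ``jaccard_scores`` (when refined) holds the neighbourhood overlap of
    each pair in the same order.
    """

    pairs: list[tuple[str, str, float]]
    permutations_used: int = 0
    stop_reason: str = "pre-mapping"
    jaccard_scores: list[float] | None = None

    def __post_init__(self) -> None:
        sources = [v for v, _, _ in self.pairs]
        targets = [u for _, u, _ in self.pairs]
        if len(set(sources)) != len(sources) or len(set(targets)) != len(targets):
            raise ValueError("alignment is not one-to-one")

    @property
    def mapping(self) -> dict[str, str]:
        return {v: u for v, u, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def invert(self) -> "Alignment":
        inv = sorted((u, v, s) for v, u, s in self.pairs)
        return Alignment(
            pairs=inv,
            permutations_used=self.permutations_used,
            stop_reason=self.stop_reason,
            jaccard_scores=None,
        )

    def write_tsv(self, path: str | Path) -> None:
        jc = self.jaccard_scores or [float("nan")] * len(self.pairs)
        with open(path, "w") as fh:
            fh.write("source_node\ttarget_node\tsimilarity\tjaccard\n")
            for (v, u, s), j in zip(self.pairs, jc):
                fh.write(f"{v}\t{u}\t{s:.8g}\t{j:.8g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Alignment":
        pairs: list[tuple[str, str, float]] = []
        jc: list[float] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("source_node"):
                raise ValueError(f"{path}: missing alignment header")
            for line in fh:
                v, u, s, j = line.rstrip("\n").split("\t")
                pairs.append((v, u, float(s)))
                jc.append(float(j))
        return cls(pairs=pairs, jaccard_scores=jc, stop_reason="loaded")

    def write_report(self, path: str | Path, **extra) -> None:
        report = {
            "pairs": len(self.pairs),
            "permutations_used": self.permutations_used,
            "stop_reason": self.stop_reason,
            **extra,
        }
        Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# similarity


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """``dot(a, b) / (|a| |b|)`` in [-1, 1]; zero vectors are rejected."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def build_similarity_matrix(
    src: NodeEmbeddings, tgt: NodeEmbeddings
) -> SimilarityMatrix:
    """All-pairs cosine similarity between source and target node vectors."""
    if src.config.dimensions != tgt.config.dimensions:
        raise AlignmentConfigError(
            f"embedding dimensions differ: {src.config.dimensions} vs "
            f"{tgt.config.dimensions}"
        )
    values = np.clip(_sk_cosine(src.matrix, tgt.matrix), -1.0, 1.0)
    return SimilarityMatrix(src.labels, tgt.labels, values)


def identity_similarity(
    src_nodes, tgt_nodes, match_value: float = 1.0, mismatch_value: float = 0.0
) -> SimilarityMatrix:
    """Similarity matrix that is ``match_value`` where labels coincide."""
    rows = tuple(sorted(src_nodes))
    cols = tuple(sorted(tgt_nodes))
    values = np.full((len(rows), len(cols)), mismatch_value, dtype=np.float64)
    ci = {lab: j for j, lab in enumerate(cols)}
    for i, lab in enumerate(rows):
        if lab in ci:
            values[i, ci[lab]] = match_value
    return SimilarityMatrix(rows, cols, values)


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a labelled CSV/TSV matrix (first row/column hold the labels)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed similarity matrix: {exc}") from exc
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty similarity matrix")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cell in similarity matrix")
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing value in similarity matrix")
    return SimilarityMatrix(
        tuple(str(x) for x in df.index),
        tuple(str(x) for x in df.columns),
        values.astype(np.float64),
    )


def write_similarity_matrix(S: SimilarityMatrix, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(S.values, index=S.row_labels, columns=S.col_labels).to_csv(
        path, sep=sep
    )


# ---------------------------------------------------------------------------
# pre-mapping


def pre_mapping(S: SimilarityMatrix, method: str = "greedy") -> Alignment:
    """One-to-one mapping from the similarity matrix.

    The default ``"greedy"`` method accepts candidate pairs in globally
    descending similarity order: a pair is taken iff both endpoints are
    still unmatched, so no accepted pair is ever preceded by a better pair
    involving either of its endpoints.  Ties are broken lexicographically
    by (source label, target label) for determinism.  Stops when every
    source node (or, if there are more sources than targets, every target)
    is matched.  ``"optimal"`` solves the assignment problem exactly
    (Hungarian algorithm), for comparison; it maximises total similarity,
    which the greedy does not in general.
    """
    if method == "optimal":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(S.values, maximize=True)
        pairs = sorted(
            (S.row_labels[r], S.col_labels[c], float(S.values[r, c]))
            for r, c in zip(rows, cols)
        )
        return Alignment(pairs=pairs, stop_reason="pre-mapping")
    if method != "greedy":
        raise AlignmentConfigError(f"unknown pre-mapping method {method!r}")
    n_rows, n_cols = S.shape
    row_rank = np.empty(n_rows, dtype=np.int64)
    row_rank[np.argsort(np.asarray(S.row_labels, dtype=object))] = np.arange(n_rows)
    col_rank = np.empty(n_cols, dtype=np.int64)
    col_rank[np.argsort(np.asarray(S.col_labels, dtype=object))] = np.arange(n_cols)

    flat_rows, flat_cols = np.unravel_index(np.arange(S.values.size), S.values.shape)
    order = np.lexsort(
        (col_rank[flat_cols], row_rank[flat_rows], -S.values.ravel())
    )
    row_free = np.ones(n_rows, dtype=bool)
    col_free = np.ones(n_cols, dtype=bool)
    need = min(n_rows, n_cols)
    taken: list[tuple[str, str, float]] = []
    for idx in order:
        r, c = flat_rows[idx], flat_cols[idx]
        if row_free[r] and col_free[c]:
            row_free[r] = False
            col_free[c] = False
            taken.append((S.row_labels[r], S.col_labels[c], float(S.values[r, c])))
            if len(taken) == need:
                break
    taken.sort()
    return Alignment(pairs=taken, stop_reason="pre-mapping")


# ---------------------------------------------------------------------------
# Jaccard refinement


def _translated_jaccard(
    src_nbrs: set[str],
    tgt_nbrs: set[str],
    mapping: Mapping[str, str],
) -> float:
    translated = {mapping[x] for x in src_nbrs if x in mapping}
    n_unmapped = sum(1 for x in src_nbrs if x not in mapping)
    inter = len(translated & tgt_nbrs)
    union = len(translated | tgt_nbrs) + n_unmapped
    return inter / union if union else 0.0


def jaccard(
    src_net: MultilayerNetwork,
    tgt_net: MultilayerNetwork,
    v: str,
    u: str,
    current: Alignment | Mapping[str, str],
) -> float:
    """Neighbourhood overlap ``|Γ(u) ∩ Γ(v)| / |Γ(u) ∪ Γ(v)|`` in [0, 1].

    Neighbours of the source node ``v`` (across all layers) are translated
    into target space through the current mapping before the set
    comparison; untranslatable neighbours count toward the union only.
    """
    mapping = current.mapping if isinstance(current, Alignment) else dict(current)
    return _translated_jaccard(src_net.neighbors(v), tgt_net.neighbors(u), mapping)


def refine(
    S: SimilarityMatrix,
    pre: Alignment,
    src_net: MultilayerNetwork,
    tgt_net: MultilayerNetwork,
    max_permutations: int | None = None,
    similarity_tolerance: float = 1e-9,
) -> Alignment:
    """Permutation refinement of a pre-mapping, maximising Jaccard overlap.

    Pairs whose Jaccard coefficient is already 1 are frozen as final.  The
    remaining pairs are revisited in ascending-Jaccard order; for each, the
    best swap partner among the other open pairs is sought.  A swap
    ``(v1,u1),(v2,u2) -> (v1,u2),(v2,u1)`` is accepted when it strictly
    increases the mapping's total Jaccard (evaluated globally, i.e.
    including pairs whose translated neighbourhoods the swap touches)
    while not decreasing total mapped similarity by more than
    ``similarity_tolerance``.  The budget counts accepted swaps and
    defaults to ``ceil(0.5 * |pre|)``.
    """
    n = len(pre.pairs)
    if max_permutations is None:
        max_permutations = math.ceil(0.5 * n)
    if max_permutations < 0:
        raise AlignmentConfigError("max_permutations must be >= 0")

    sources = [v for v, _, _ in pre.pairs]
    assigned = {v: u for v, u, _ in pre.pairs}
    src_nbrs = {v: src_net.neighbors(v) for v in sources}
    tgt_nbrs = {u: tgt_net.neighbors(u) for _, u, _ in pre.pairs}
    # pairs whose Jaccard depends on v's assignment: those with v in Γ(source)
    dependents: dict[str, list[str]] = {v: [] for v in sources}
    for v in sources:
        for x in src_nbrs[v]:
            if x in dependents:
                dependents[x].append(v)

    def jc_of(v: str, u: str) -> float:
        return _translated_jaccard(src_nbrs[v], tgt_nbrs[u], assigned)

    jc = {v: jc_of(v, assigned[v]) for v in sources}
    used = 0
    converged = False

    while used < max_permutations and any(jc[v] < 1.0 for v in sources):
        open_pairs = sorted(
            (v for v in sources if jc[v] < 1.0), key=lambda v: (jc[v], v)
        )
        accepted_in_pass = False
        for v1 in open_pairs:
            if used >= max_permutations:
                break
            if jc[v1] >= 1.0:
                continue
            u1 = assigned[v1]
            best: tuple[float, str] | None = None
            for v2 in open_pairs:
                if v2 == v1 or jc[v2] >= 1.0:
                    continue
                u2 = assigned[v2]
                dsim = S[v1, u2] + S[v2, u1] - S[v1, u1] - S[v2, u2]
                if dsim < -similarity_tolerance:
                    continue
                # evaluate the swap's *global* Jaccard effect: the two pairs
                # plus every pair whose translated neighbourhood involves them
                affected = {v1, v2} | set(dependents[v1]) | set(dependents[v2])
                before = sum(jc[x] for x in affected)
                assigned[v1], assigned[v2] = u2, u1
                after = sum(jc_of(x, assigned[x]) for x in affected)
                assigned[v1], assigned[v2] = u1, u2
                delta = after - before
                if delta > 1e-12 and (best is None or delta > best[0]):
                    best = (delta, v2)
            if best is not None:
                v2 = best[1]
                assigned[v1], assigned[v2] = assigned[v2], assigned[v1]
                for x in {v1, v2} | set(dependents[v1]) | set(dependents[v2]):
                    jc[x] = jc_of(x, assigned[x])
                used += 1
                accepted_in_pass = True
        if not accepted_in_pass:
            converged = True
            break

    if all(jc[v] >= 1.0 for v in sources):
        stop_reason = "all-overlapping"
    elif converged:
        stop_reason = "converged"
    elif used >= max_permutations:
        stop_reason = "budget-exhausted"
    else:
        stop_reason = "converged"

    pairs = sorted((v, assigned[v], S[v, assigned[v]]) for v in sources)
    return Alignment(
        pairs=pairs,
        permutations_used=used,
        stop_reason=stop_reason,
        jaccard_scores=[jc[v] for v, _, _ in pairs],
    )


# ---------------------------------------------------------------------------
# full pipeline


def align(
    src_net: MultilayerNetwork,
    tgt_net: MultilayerNetwork,
    emb_cfg: EmbeddingConfig | None = None,
    external_S: SimilarityMatrix | None = None,
    max_permutations: int | None = None,
    similarity_tolerance: float = 1e-9,
) -> Alignment:
    """End-to-end pairwise global alignment of two multilayer networks.

    Embeddings are computed independently per network (same configuration
    and seed) unless an external similarity matrix is supplied, in which
    case the embedding stage is bypassed.  When the source has more nodes
    than the target the networks are swapped internally and the resulting
    mapping inverted, preserving the ``|V| <= |U|`` convention.
    """
    swapped = len(src_net.nodes) > len(tgt_net.nodes)
    if swapped:
        src_net, tgt_net = tgt_net, src_net
        if external_S is not None:
            external_S = external_S.transpose()

    if external_S is not None:
        if set(external_S.row_labels) != set(src_net.nodes):
            raise AlignmentConfigError(
                "similarity-matrix row labels do not match the source node set"
            )
        if set(external_S.col_labels) != set(tgt_net.nodes):
            raise AlignmentConfigError(
                "similarity-matrix column labels do not match the target node set"
            )
        S = external_S
    else:
        cfg = emb_cfg or EmbeddingConfig()
        src_emb = embed_network(src_net, cfg)
        tgt_emb = embed_network(tgt_net, cfg)
        S = build_similarity_matrix(src_emb, tgt_emb)

    pre = pre_mapping(S)
    refined = refine(
        S,
        pre,
        src_net,
        tgt_net,
        max_permutations=max_permutations,
        similarity_tolerance=similarity_tolerance,
    )
    return refined.invert() if swapped else refined
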