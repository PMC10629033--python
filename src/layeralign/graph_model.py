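"""Multilayer networks as attributed edge lists, and their flat typed-edge form.

A multilayer network ``G_M = (V_M, E_M)`` is stored as a set of undirected
edge tuples ``(u, v, l)`` where ``l`` is an integer layer attribute: one
identifier per intralayer plus one dedicated identifier for the interlayer
edges.  The intralayer edges ``E_a`` and the interlayer edges ``E_b``
partition ``E_M``.  The equivalent *flat* representation collapses all
layers into a single graph whose edges are typed by the originating layer
identifier, which keeps the whole topology reconstructible without loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "MultilayerNetwork",
    "FlatGraph",
    "EdgeListParseError",
    "NetworkValidationError",
    "read_edge_list",
    "write_edge_list",
    "read_layer_manifest",
    "to_flat",
    "from_flat",
]


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


class NetworkValidationError(ValueError):
    """A network or edge violates the multilayer model's invariants."""


@dataclass(frozen=True, order=True)
class EdgeRecord:
    """One undirected edge ``(u, v)`` carrying its layer attribute.

    The pair is canonicalised so that ``u <= v``; ``(a, b, l)`` and
    ``(b, a, l)`` compare equal.  Self-loops are rejected.
    """

    u: str
    v: str
    layer_id: int

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise NetworkValidationError(f"self-loop on node {self.u!r}")
        if self.v < self.u:
            u, v = self.u, self.v
            object.__setattr__(self, "u", v)
            object.__setattr__(self, "v", u)

    def endpoints(self) -> tuple[str, str]:
        return (self.u, self.v)


@dataclass
class MultilayerNetwork:
    """A validated multilayer network.

    Parameters
    ----------
    edges
        The undirected attributed edge set ``E_M``.
    layer_ids
        Ordered intralayer identifiers.
    interlayer_id
        The identifier tagging interlayer edges.  Every edge's
        ``layer_id`` must be one of ``layer_ids`` or ``interlayer_id``.
    nodes
        Optional explicit node set; defaults to the union of edge
        endpoints.  Isolated nodes (present but incident to no edge)
        are rejected: the generator contract guarantees none exist.
    """

    edges: frozenset[EdgeRecord]
    layer_ids: tuple[int, ...]
    interlayer_id: int
    nodes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.edges = frozenset(self.edges)
        self.layer_ids = tuple(self.layer_ids)
        endpoint_nodes = frozenset(n for e in self.edges for n in e.endpoints())
        if not self.nodes:
            self.nodes = endpoint_nodes
        else:
            self.nodes = frozenset(self.nodes)
            isolated = self.nodes - endpoint_nodes
            if isolated:
                raise NetworkValidationError(
                    f"isolated node(s) {sorted(isolated)[:5]}: every node must "
                    "appear in at least one edge"
                )
            if endpoint_nodes - self.nodes:
                raise NetworkValidationError("edge endpoint outside declared node set")
        valid_ids = set(self.layer_ids) | {self.interlayer_id}
        for e in self.edges:
            if e.layer_id not in valid_ids:
                raise NetworkValidationError(
                    f"edge ({e.u}, {e.v}) has unknown layer id {e.layer_id}"
                )
        self._adjacency: dict[str, set[str]] | None = None

    # -- derived sets -------------------------------------------------------

    @property
    def intralayer_edges(self) -> frozenset[EdgeRecord]:
        """``E_a``: edges whose layer id is an intralayer identifier."""
        return frozenset(e for e in self.edges if e.layer_id != self.interlayer_id)

    @property
    def interlayer_edges(self) -> frozenset[EdgeRecord]:
        """``E_b = E_M \\ E_a``: edges tagged with the interlayer identifier."""
        return frozenset(e for e in self.edges if e.layer_id == self.interlayer_id)

    def layer_edges(self, layer_id: int) -> frozenset[EdgeRecord]:
        return frozenset(e for e in self.edges if e.layer_id == layer_id)

    # -- adjacency ----------------------------------------------------------

    def _adj(self) -> dict[str, set[str]]:
        if self._adjacency is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for e in self.edges:
                adj[e.u].add(e.v)
                adj[e.v].add(e.u)
            self._adjacency = adj
        return self._adjacency

    def neighbors(self, u: str) -> set[str]:
        """All neighbours of ``u`` across every layer, intralayer and inter."""
        adj = self._adj()
        if u not in adj:
            raise KeyError(f"unknown node {u!r}")
        return set(adj[u])

    def degree(self, u: str) -> int:
        return len(self.neighbors(u))

    # -- dunder -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultilayerNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.layer_ids == other.layer_ids
            and self.interlayer_id == other.interlayer_id
        )

    def __repr__(self) -> str:
        return (
            f"MultilayerNetwork(|V|={len(self.nodes)}, |E|={len(self.edges)}, "
            f"layers={list(self.layer_ids)}, interlayer={self.interlayer_id})"
        )


@dataclass
class FlatGraph:
    """Equivalent flat representation: one typed edge per multilayer edge."""

    nodes: frozenset[str]
    typed_edges: frozenset[tuple[str, str, int]]
    layer_ids: tuple[int, ...] = ()
    interlayer_id: int | None = None

    def adjacency(self) -> dict[str, list[str]]:
        """Untyped adjacency with deterministically sorted neighbour lists."""
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v, _ in self.typed_edges:
            adj[u].add(v)
            adj[v].add(u)
        return {n: sorted(adj[n]) for n in adj}


def to_flat(net: MultilayerNetwork) -> FlatGraph:
    """Collapse intralayer and interlayer edges into one typed-edge graph."""
    return FlatGraph(
        nodes=net.nodes,
        typed_edges=frozenset((e.u, e.v, e.layer_id) for e in net.edges),
        layer_ids=net.layer_ids,
        interlayer_id=net.interlayer_id,
    )


def from_flat(flat: FlatGraph) -> MultilayerNetwork:
    """Reconstruct the multilayer network a flat graph was derived from."""
    if flat.interlayer_id is None:
        raise NetworkValidationError("flat graph carries no interlayer identifier")
    return MultilayerNetwork(
        edges=frozenset(EdgeRecord(u, v, t) for u, v, t in flat.typed_edges),
        layer_ids=flat.layer_ids,
        interlayer_id=flat.interlayer_id,
        nodes=flat.nodes,
    )


def read_layer_manifest(path: str | Path) -> tuple[tuple[int, ...], int]:
    """Read a JSON layer manifest ``{"layers": [...], "interlayer": id}``."""
    data = json.loads(Path(path).read_text())
    return tuple(int(x) for x in data["layers"]), int(data["interlayer"])


def read_edge_list(
    path: str | Path,
    layer_ids: Iterable[int] | None = None,
    interlayer_id: int | None = None,
) -> MultilayerNetwork:
    """Read a multilayer network from an attributed edge list.

    The dialect is ``u v layer_id`` per line, whitespace- or tab-separated,
    ``#`` comments, no header; extra columns are ignored.  Duplicate edges
    (including reversed duplicates) are collapsed with a logged warning.
    When no manifest is given, the interlayer identifier is taken to be the
    largest layer id present, following the convention that layer ids are
    assigned in increasing order with the interlayer last.
    """
    path = Path(path)
    edges: set[EdgeRecord] = set()
    seen_ids: set[int] = set()
    n_dupes = 0
    known = None if layer_ids is None else set(layer_ids) | (
        {interlayer_id} if interlayer_id is not None else set()
    )
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 3 fields, got {len(fields)}"
                )
            u, v, raw_layer = fields[0], fields[1], fields[2]
            try:
                layer = int(raw_layer)
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}:{lineno}: layer id {raw_layer!r} is not an integer"
                ) from exc
            if u == v:
                raise NetworkValidationError(
                    f"{path}:{lineno}: self-loop on node {u!r}"
                )
            if known is not None and layer not in known:
                raise NetworkValidationError(
                    f"{path}:{lineno}: layer id {layer} not in the supplied manifest"
                )
            rec = EdgeRecord(u, v, layer)
            if rec in edges:
                n_dupes += 1
            else:
                edges.add(rec)
                seen_ids.add(layer)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dupes)

    if layer_ids is None:
        all_ids = sorted(seen_ids)
        if interlayer_id is None:
            interlayer_id = all_ids[-1] if all_ids else 0
        intra = tuple(i for i in all_ids if i != interlayer_id)
    else:
        intra = tuple(layer_ids)
        if interlayer_id is None:
            interlayer_id = (max(intra) + 1) if intra else 0
    return MultilayerNetwork(
        edges=frozenset(edges), layer_ids=intra, interlayer_id=interlayer_id
    )


def write_edge_list(net: MultilayerNetwork, path: str | Path) -> None:
    """Write ``u<TAB>v<TAB>layer_id`` lines in deterministic sorted order."""
    path = Path(path)
    lines = [f"{e.u}\t{e.v}\t{e.layer_id}" for e in sorted(net.edges)]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def iter_layer_counts(net: MultilayerNetwork) -> Iterator[tuple[int, int]]:
    """Yield ``(layer_id, edge_count)`` for every intralayer plus the interlayer."""
    for lid in net.layer_ids:
        yield lid, len(net.layer_edges(lid))
    yield net.interlayer_id, len(net.interlayer_edges)
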