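"""Population-structure graphs for the Moran birth-death process.

Labelled, simple, connected, undirected graphs with equal link weights.
Includes generators for the six connected four-node motifs, the classical
families (complete, ring, line, star), square lattices with optional
periodic boundaries and diagonal links, exhaustive enumeration of small
connected graphs up to isomorphism, and a plain edge-list file format.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Graph",
    "make_named_graph",
    "make_lattice",
    "enumerate_connected_graphs",
    "read_edge_list",
    "write_edge_list",
    "NAMED_GRAPHS",
]

NAMED_GRAPHS = ("complete", "ring", "line", "star", "shovel", "diamond")

#: brute-force bound for enumeration / automorphism search (n! permutations)
MAX_BRUTE_FORCE_NODES = 6


@dataclass(frozen=True)
class Graph:
    """A simple connected undirected graph on nodes ``0..n_nodes-1``.

    Edges are stored as a frozenset of sorted 2-tuples.  Instances are
    immutable and hashable, so they can key caches of exact results.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("graph needs at least one node")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < v < self.n_nodes):
                raise ValueError(f"edge ({u},{v}) out of range or unsorted")
        if self.n_nodes > 1 and not _is_connected(self.n_nodes, self.edges):
            raise ValueError("graph is not connected")

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]],
                   name: str = "") -> "Graph":
        norm = frozenset((min(u, v), max(u, v)) for u, v in edges)
        return cls(n_nodes, norm, name)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: int) -> tuple[int, ...]:
        return self.adjacency[node]

    @cached_property
    def adjacency(self) -> tuple[tuple[int, ...], ...]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return tuple(tuple(sorted(a)) for a in adj)

    def degree(self, node: int) -> int:
        return len(self.adjacency[node])

    @property
    def degrees(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.adjacency)

    def is_regular(self) -> bool:
        degs = self.degrees
        return min(degs) == max(degs)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" {self.name!r}" if self.name else ""
        return f"Graph(n={self.n_nodes}, m={self.n_edges}{tag})"


def _is_connected(n: int, edges: frozenset[tuple[int, int]]) -> bool:
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


# ---------------------------------------------------------------------------
# Named families
# ---------------------------------------------------------------------------

def make_named_graph(name: str, n: int) -> Graph:
    """Build one of the named population structures.

    ``complete``, ``ring``, ``line`` and ``star`` accept any ``n >= 2``
    (``ring`` needs ``n >= 3``).  ``shovel`` (a triangle with a pendant
    node) and ``diamond`` (K4 minus one edge) are four-node motifs only.

    Diamond convention: nodes 0 and 1 are the degree-3 hubs, nodes 2 and 3
    the degree-2 nodes; the missing edge is (2, 3).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if name == "complete":
        edges = itertools.combinations(range(n), 2)
    elif name == "ring":
        if n < 3:
            raise ValueError("ring needs n >= 3")
        edges = [(i, (i + 1) % n) for i in range(n)]
    elif name == "line":
        edges = [(i, i + 1) for i in range(n - 1)]
    elif name == "star":
        edges = [(0, i) for i in range(1, n)]
    elif name == "shovel":
        if n != 4:
            raise ValueError("shovel is a four-node motif")
        edges = [(0, 1), (0, 2), (1, 2), (2, 3)]
    elif name == "diamond":
        if n != 4:
            raise ValueError("diamond is a four-node motif")
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]
    else:
        raise ValueError(f"unknown graph name {name!r}")
    return Graph.from_edges(n, edges, name=f"{name}:{n}")


def make_lattice(side: int, periodic: bool = False,
                 diagonals: bool | str = False) -> Graph:
    """A ``side x side`` square lattice with ``side**2`` nodes.

    ``periodic`` wraps both boundaries (torus; requires ``side >= 3`` so no
    multi-edges arise).  ``diagonals`` adds diagonal links (wrapped if
    periodic): ``"both"`` (or ``True``) links each cell to all four diagonal
    neighbours, so every unit square becomes a complete K4 motif (interior
    degree 8); ``"one"`` adds a single, consistently oriented diagonal per
    unit square, turning every square into a diamond motif (interior degree
    6).  Node ``(row, col)`` gets index ``row * side + col``.
    """
    if side < 2:
        raise ValueError("need side >= 2")
    if periodic and side < 3:
        raise ValueError("periodic boundaries need side >= 3 "
                         "(a periodic 2x2 lattice would have multi-edges)")
    steps = [(0, 1), (1, 0)]
    if diagonals in (True, "both"):
        steps += [(1, 1), (1, -1)]
    elif diagonals == "one":
        steps += [(1, 1)]
    elif diagonals is not False:
        raise ValueError("diagonals must be False, True, 'one' or 'both'")
    edges = set()
    for row in range(side):
        for col in range(side):
            for dr, dc in steps:
                r2, c2 = row + dr, col + dc
                if periodic:
                    r2 %= side
                    c2 %= side
                elif not (0 <= r2 < side and 0 <= c2 < side):
                    continue
                u, v = row * side + col, r2 * side + c2
                if u != v:
                    edges.add((min(u, v), max(u, v)))
    tag = "torus" if periodic else "grid"
    if diagonals == "one":
        tag += "+diag1"
    elif diagonals:
        tag += "+diag"
    return Graph.from_edges(side * side, edges, name=f"{tag}:{side}")


# ---------------------------------------------------------------------------
# Exhaustive enumeration (small n)
# ---------------------------------------------------------------------------

def _permute_edges(edges: frozenset[tuple[int, int]],
                   perm: tuple[int, ...]) -> frozenset[tuple[int, int]]:
    return frozenset(
        (min(perm[u], perm[v]), max(perm[u], perm[v])) for u, v in edges
    )


def are_isomorphic(a: Graph, b: Graph) -> bool:
    """Brute-force isomorphism test by trying all node permutations."""
    if a.n_nodes != b.n_nodes or a.n_edges != b.n_edges:
        return False
    if sorted(a.degrees) != sorted(b.degrees):
        return False
    if a.n_nodes > MAX_BRUTE_FORCE_NODES:
        raise ValueError(f"brute force limited to n <= {MAX_BRUTE_FORCE_NODES}")
    return any(
        _permute_edges(a.edges, perm) == b.edges
        for perm in itertools.permutations(range(a.n_nodes))
    )


def enumerate_connected_graphs(n: int) -> list[Graph]:
    """All connected graphs on ``n`` nodes, one per isomorphism class.

    Brute force over the :math:`2^{\\binom{n}{2}}` edge subsets with
    permutation-based isomorphism rejection; bounded at n <= 6.
    For n = 4 this yields the six motifs of the four-node analysis.
    """
    if not (1 <= n <= MAX_BRUTE_FORCE_NODES):
        raise ValueError(f"need 1 <= n <= {MAX_BRUTE_FORCE_NODES}")
    all_pairs = list(itertools.combinations(range(n), 2))
    seen_canon: set[tuple[tuple[int, int], ...]] = set()
    out: list[Graph] = []
    perms = list(itertools.permutations(range(n)))
    for k in range(n - 1, len(all_pairs) + 1):
        for subset in itertools.combinations(all_pairs, k):
            edges = frozenset(subset)
            if not _is_connected(n, edges):
                continue
            # frozensets order by inclusion, so canonicalise via sorted tuples
            canon = min(tuple(sorted(_permute_edges(edges, p))) for p in perms)
            if canon not in seen_canon:
                seen_canon.add(canon)
                out.append(Graph(n, edges))
    return out


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> Graph:
    """Read a graph from a whitespace-separated edge list.

    One ``u v`` pair per line, 0-based node indices, ``#`` comments allowed.
    Rejects self-loops and disconnected input.
    """
    edges: set[tuple[int, int]] = set()
    nodes: set[int] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two integers")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not integers: {line!r}") from exc
        if u < 0 or v < 0:
            raise ValueError(f"{path}:{lineno}: negative node index")
        if u == v:
            raise ValueError(f"{path}:{lineno}: self-loop at node {u}")
        nodes.update((u, v))
        edges.add((min(u, v), max(u, v)))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    n = max(nodes) + 1
    if len(nodes) != n:
        raise ValueError(f"{path}: node indices must cover 0..{n - 1}")
    return Graph(n, frozenset(edges), name=Path(path).stem)


def write_edge_list(graph: Graph, path: str | Path) -> None:
    """Write a graph as a sorted edge list; round-trips with read_edge_list."""
    lines = [f"{u} {v}" for u, v in sorted(graph.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def graph_from_spec(spec: str) -> Graph:
    """Parse a compact graph descriptor used by the command line.

    Formats: ``complete:4``, ``ring:5``, ``diamond`` (n defaults to 4 for
    motifs), ``lattice:5:open:diag`` (both diagonals), ``lattice:5:open:diag1``
    (one diagonal per cell), ``lattice:4:periodic:plain``, or a path to an
    edge-list file.
    """
    parts = spec.split(":")
    if parts[0] in NAMED_GRAPHS:
        n = int(parts[1]) if len(parts) > 1 else 4
        return make_named_graph(parts[0], n)
    if parts[0] == "lattice":
        side = int(parts[1])
        periodic = len(parts) > 2 and parts[2] == "periodic"
        diagonals: bool | str = False
        if len(parts) > 3:
            diagonals = {"diag": "both", "diag1": "one",
                         "plain": False}[parts[3]]
        return make_lattice(side, periodic=periodic, diagonals=diagonals)
    return read_edge_list(spec)
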