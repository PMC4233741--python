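"""State spaces of the Moran chain on a graph.

A state of the chain is a mutant configuration: the subset of nodes
currently occupied by mutants, encoded as a bit-set (bit i set = node i is
a mutant).  The empty set (extinction) and the full set (fixation) are the
two absorbing configurations.  On symmetric graphs, configurations related
by a graph automorphism are dynamically equivalent and can be lumped into
orbit states; on some graphs (e.g. the ring, where mutants can only invade
as a contiguous cluster) not every configuration is reachable from a
single-mutant start, and those states can be pruned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

from .graphs import Graph, MAX_BRUTE_FORCE_NODES

__all__ = [
    "StateSpace",
    "full_state_space",
    "automorphisms",
    "reduce_state_space",
    "prune_unreachable",
    "popcount",
]

#: default cap on full state-space enumeration (2**16 configurations)
MAX_FULL_SPACE_NODES = 16


def popcount(config: int) -> int:
    """Number of mutants in a bit-set configuration."""
    return config.bit_count()


@dataclass(frozen=True)
class StateSpace:
    """Ordered states of the Moran chain on ``graph``.

    Each state is an orbit: a tuple of configurations (singletons in the
    unreduced space).  Transient states come first, the two absorbing
    states last, in the fixed order (extinction, fixation) — the canonical
    form required by the absorbing-chain solver.  ``index_of`` maps every
    covered configuration to its state index.
    """

    graph: Graph
    states: tuple[tuple[int, ...], ...]
    n_transient: int
    reduced: bool = False
    pruned: bool = False

    @property
    def n_absorbing(self) -> int:
        return 2

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def index_of(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, orbit in enumerate(self.states):
            for config in orbit:
                out[config] = i
        return out

    def representative(self, i: int) -> int:
        """Lexicographically smallest configuration of state ``i``."""
        return self.states[i][0]

    def mutant_count(self, i: int) -> int:
        return popcount(self.representative(i))

    def orbit_size(self, i: int) -> int:
        return len(self.states[i])

    @property
    def extinction_index(self) -> int:
        return self.n_transient

    @property
    def fixation_index(self) -> int:
        return self.n_transient + 1

    def single_mutant_indices(self) -> list[int]:
        """Transient state indices that contain one-mutant configurations."""
        return [i for i in range(self.n_transient) if self.mutant_count(i) == 1]

    def __post_init__(self) -> None:
        n = self.graph.n_nodes
        ext, fix = self.states[self.n_transient], self.states[self.n_transient + 1]
        if ext != (0,) or fix != ((1 << n) - 1,):
            raise ValueError("absorbing states must be (extinction, fixation), last")


def _state_sort_key(orbit: tuple[int, ...]) -> tuple[int, int]:
    return (popcount(orbit[0]), orbit[0])


def _assemble(graph: Graph, transient: list[tuple[int, ...]],
              **flags) -> StateSpace:
    transient = sorted(transient, key=_state_sort_key)
    full = (1 << graph.n_nodes) - 1
    states = tuple(transient) + ((0,), (full,))
    return StateSpace(graph, states, n_transient=len(transient), **flags)


def full_state_space(graph: Graph, max_nodes: int = MAX_FULL_SPACE_NODES
                     ) -> StateSpace:
    """All ``2**n`` configurations as singleton states.

    Transient states are ordered by ascending mutant count, then ascending
    bit-set value; extinction and fixation close the list.
    """
    n = graph.n_nodes
    if n > max_nodes:
        raise ValueError(f"full state space capped at {max_nodes} nodes")
    transient = [(c,) for c in range(1, (1 << n) - 1)]
    return _assemble(graph, transient)


def automorphisms(graph: Graph) -> list[tuple[int, ...]]:
    """The automorphism group of ``graph`` as node permutations.

    Brute force over all n! permutations, checking edge-set preservation;
    the identity is always included.  Bounded at n <= 6 like the other
    brute-force graph routines.
    """
    n = graph.n_nodes
    if n > MAX_BRUTE_FORCE_NODES:
        raise ValueError(f"brute force limited to n <= {MAX_BRUTE_FORCE_NODES}")
    edges = graph.edges
    out = []
    for perm in itertools.permutations(range(n)):
        if all((min(perm[u], perm[v]), max(perm[u], perm[v])) in edges
               for u, v in edges):
            out.append(perm)
    return out


def _apply_perm(config: int, perm: tuple[int, ...]) -> int:
    out = 0
    for i, pi in enumerate(perm):
        if config >> i & 1:
            out |= 1 << pi
    return out


def reduce_state_space(graph: Graph, space: StateSpace | None = None
                       ) -> StateSpace:
    """Lump configurations into automorphism orbits.

    Two configurations belong to one orbit-state iff some automorphism of
    the graph maps one onto the other; they then have equal mutant counts
    and identical dynamics (lumpability is asserted downstream when the
    transition matrix is aggregated).  Orbit representatives are the
    lexicographically smallest members.
    """
    if space is None:
        space = full_state_space(graph)
    if space.reduced:
        raise ValueError("space is already reduced")
    group = automorphisms(graph)
    seen: set[int] = set()
    transient: list[tuple[int, ...]] = []
    for orbit in space.states[: space.n_transient]:
        (config,) = orbit
        if config in seen:
            continue
        members = sorted({_apply_perm(config, p) for p in group})
        seen.update(members)
        transient.append(tuple(members))
    return _assemble(graph, transient, reduced=True, pruned=space.pruned)


def prune_unreachable(space: StateSpace, adjacency: dict[int, set[int]] | None
                      = None) -> StateSpace:
    """Drop transient states unreachable from every single-mutant start.

    ``adjacency`` maps state index -> successor state indices with nonzero
    transition probability; by default it is computed from the chain at
    r = 1 (the zero-pattern of the Moran chain does not depend on r > 0).
    """
    if adjacency is None:
        from .chain import state_adjacency

        adjacency = state_adjacency(space.graph, space)
    reachable: set[int] = set()
    frontier = [i for i in space.single_mutant_indices()]
    reachable.update(frontier)
    while frontier:
        nxt = []
        for i in frontier:
            for j in adjacency.get(i, ()):
                if j < space.n_transient and j not in reachable:
                    reachable.add(j)
                    nxt.append(j)
        frontier = nxt
    transient = [space.states[i] for i in sorted(reachable)]
    return _assemble(space.graph, transient,
                     reduced=space.reduced, pruned=True)
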