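"""Exact transition probabilities of the birth-death Moran process on a graph.

Update rule: each time step one individual is chosen for birth with
probability proportional to its fitness (mutants have fitness r > 0,
wild-types fitness 1); its offspring then replaces a uniformly chosen
neighbour.  Replacing an individual of one's own kind leaves the
configuration unchanged, so the chain has positive staying probabilities.

The canonical-form matrix blocks Q (transient -> transient) and
R (transient -> absorbing, columns ordered extinction then fixation) are
assembled either in exact rational arithmetic (fractions.Fraction) or in
floating point.  On the complete graph the chain coincides with the
classical well-mixed Moran process, whose tridiagonal transition
probabilities are provided in closed form as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Union

import numpy as np

from .graphs import Graph
from .states import StateSpace, popcount

__all__ = [
    "CanonicalChain",
    "step_distribution",
    "build_canonical_chain",
    "wellmixed_transitions",
    "state_adjacency",
]

Number = Union[Fraction, float]

#: row-sum / lumpability tolerance in float mode (exact mode is bit-exact)
FLOAT_TOL = 1e-12


def _as_number(r, exact: bool) -> Number:
    if r <= 0:
        raise ValueError("mutant fitness r must be positive")
    if exact:
        return r if isinstance(r, Fraction) else Fraction(r)
    return float(r)


def step_distribution(graph: Graph, config: int, r,
                      exact: bool = True) -> dict[int, Number]:
    """One-step transition distribution from a mutant configuration.

    Returns a map successor-configuration -> probability, including the
    staying probability of ``config`` itself.  Absorbing configurations
    (no mutants, all mutants) map to themselves with probability 1.

    Derivation: node k reproduces with probability f_k / W where
    f_k = r for mutants, 1 for wild-types and W = r m + (n - m); the
    offspring lands on each of k's deg(k) neighbours with probability
    1/deg(k), converting the neighbour to k's type.
    """
    r = _as_number(r, exact)
    one = Fraction(1) if exact else 1.0
    n = graph.n_nodes
    full = (1 << n) - 1
    if config == 0 or config == full:
        return {config: one}
    m = popcount(config)
    W = r * m + (n - m)
    adj = graph.adjacency
    dist: dict[int, Number] = {}
    stay = one
    for k in range(n):
        k_mut = config >> k & 1
        f = r if k_mut else one
        per_neighbor = f / (W * len(adj[k]))
        for j in adj[k]:
            if (config >> j & 1) == k_mut:
                continue  # own kind replaced: no change
            succ = config | (1 << j) if k_mut else config & ~(1 << j)
            dist[succ] = dist.get(succ, 0) + per_neighbor
            stay -= per_neighbor
    dist[config] = dist.get(config, 0) + stay
    return dist


def state_adjacency(graph: Graph, space: StateSpace) -> dict[int, set[int]]:
    """Successor state indices with nonzero probability, per transient state.

    Evaluated at r = 1; the zero-pattern of the chain is the same for every
    r > 0, so reachability is r-independent.
    """
    index_of = space.index_of
    out: dict[int, set[int]] = {}
    for i in range(space.n_transient):
        dist = step_distribution(graph, space.representative(i), 1, exact=True)
        out[i] = {index_of[c] for c, p in dist.items() if p > 0} - {i}
    return out


@dataclass(frozen=True)
class CanonicalChain:
    """Canonical-form blocks of the absorbing Moran chain.

    ``Q`` is the t x t transient block and ``R`` the t x 2 absorbing block
    with columns (extinction, fixation), both following the state ordering
    of ``space``.  In exact mode the entries are ``fractions.Fraction`` held
    in object arrays and every row of [Q | R] sums to exactly 1.
    """

    space: StateSpace
    Q: np.ndarray
    R: np.ndarray
    r: Number
    exact: bool

    @property
    def n_transient(self) -> int:
        return self.space.n_transient

    def row_sums(self) -> np.ndarray:
        return self.Q.sum(axis=1) + self.R.sum(axis=1)


def _aggregate_row(graph: Graph, space: StateSpace, config: int, r,
                   exact: bool) -> dict[int, Number]:
    index_of = space.index_of
    row: dict[int, Number] = {}
    for succ, p in step_distribution(graph, config, r, exact=exact).items():
        try:
            j = index_of[succ]
        except KeyError:
            raise ValueError(
                f"successor {succ:b} not covered by the state space; "
                "a pruned state is reachable after all"
            ) from None
        row[j] = row.get(j, 0) + p
    return row


def build_canonical_chain(graph: Graph, space: StateSpace, r,
                          exact: bool = True,
                          check_lumpability: bool = True) -> CanonicalChain:
    """Assemble Q and R for the Moran chain on ``space``.

    For orbit states the row is computed from the orbit representative;
    with ``check_lumpability`` every other orbit member is verified to give
    the identical aggregated row (exactly in rational mode, to 1e-12 in
    float mode) — a failure would indicate states lumped across a
    non-automorphism, i.e. a state-space bug.
    """
    r = _as_number(r, exact)
    t = space.n_transient
    dtype = object if exact else float
    Q = np.zeros((t, t), dtype=dtype)
    R = np.zeros((t, 2), dtype=dtype)
    if exact:
        Q[:], R[:] = Fraction(0), Fraction(0)
    ext, fix = space.extinction_index, space.fixation_index
    for i in range(t):
        row = _aggregate_row(graph, space, space.representative(i), r, exact)
        if check_lumpability:
            for other in space.states[i][1:]:
                alt = _aggregate_row(graph, space, other, r, exact)
                if exact:
                    ok = alt == row
                else:
                    ok = set(alt) == set(row) and all(
                        abs(alt[j] - row[j]) <= FLOAT_TOL for j in row)
                if not ok:
                    raise ValueError(
                        f"orbit {i} is not lumpable: member {other:b} "
                        "disagrees with the representative row")
        for j, p in row.items():
            if j == ext:
                R[i, 0] += p
            elif j == fix:
                R[i, 1] += p
            else:
                Q[i, j] += p
    chain = CanonicalChain(space=space, Q=Q, R=R, r=r, exact=exact)
    sums = chain.row_sums()
    if exact:
        assert all(s == 1 for s in sums)
    elif not np.allclose(np.asarray(sums, dtype=float), 1.0, atol=FLOAT_TOL):
        raise ValueError("rows of [Q|R] do not sum to 1")
    return chain


def wellmixed_transitions(N: int, i: int, r, exact: bool = True
                          ) -> tuple[Number, Number]:
    """Up/down transition probabilities of the well-mixed Moran process.

    With i mutants among N individuals,

        T_i^+ = [r i / (r i + N - i)] * [(N - i) / (N - 1)]
        T_i^- = [(N - i) / (r i + N - i)] * [i / (N - 1)]

    so T_i^- / T_i^+ = 1/r at every interior state.  The boundaries i = 0
    and i = N are absorbing and return (0, 0).
    """
    if not 0 <= i <= N:
        raise ValueError("need 0 <= i <= N")
    r = _as_number(r, exact)
    zero = Fraction(0) if exact else 0.0
    if i == 0 or i == N:
        return zero, zero
    W = r * i + (N - i)
    up = (r * i / W) * Fraction(N - i, N - 1) if exact else \
        (r * i / W) * ((N - i) / (N - 1))
    down = ((N - i) / W) * Fraction(i, N - 1) if exact else \
        ((N - i) / W) * (i / (N - 1))
    return up, down
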