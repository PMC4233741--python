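"""Monte Carlo simulation of the birth-death Moran process on a graph.

Each elementary step: pick a birth node with probability proportional to
fitness (mutants r, wild-types 1), then replace a uniformly random
neighbour by the offspring.  Steps are counted whether or not the state
changes, so simulated times are directly comparable with the exact
discrete-time chain.  Used for populations too large for exact solves
(lattices) and as an independent check of the exact machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Optional, Union

import numpy as np

from .graphs import Graph

__all__ = ["SimulationResult", "run_once", "estimate"]

_BLOCK = 8192  # uniform variates drawn per RNG call; amortises call overhead


@dataclass(frozen=True)
class SimulationResult:
    """Summary of independent absorption runs of the Moran process."""

    graph: str
    r: float
    replicates: int
    seed: Optional[int]
    start: Union[int, str]
    fixations: int
    extinctions: int
    unconditional_time: float
    unconditional_se: float
    conditional_time: Optional[float]   # None if no run fixated
    conditional_se: Optional[float]

    @property
    def fixation_frequency(self) -> float:
        return self.fixations / self.replicates

    @property
    def fixation_frequency_se(self) -> float:
        p = self.fixation_frequency
        return sqrt(p * (1 - p) / self.replicates)

    def to_row(self) -> dict:
        """Flat dict for tabular (TSV) output."""
        return {
            "graph": self.graph, "r": self.r, "replicates": self.replicates,
            "seed": self.seed, "start": self.start,
            "fixations": self.fixations, "extinctions": self.extinctions,
            "fixation_frequency": self.fixation_frequency,
            "fixation_frequency_se": self.fixation_frequency_se,
            "unconditional_time": self.unconditional_time,
            "unconditional_se": self.unconditional_se,
            "conditional_time": self.conditional_time,
            "conditional_se": self.conditional_se,
        }


class _Population:
    """Mutable node-type state with O(1) updates per event.

    Mutant and wild node lists are maintained with swap-pop moves; the
    birth node is drawn by first choosing the fitness class (total mutant
    weight r*m against n-m wild-types) and then a uniform class member.
    """

    __slots__ = ("adj", "n", "is_mut", "members", "pos")

    def __init__(self, graph: Graph):
        self.adj = [list(a) for a in graph.adjacency]
        self.n = graph.n_nodes
        self.is_mut: list[bool] = []
        self.members: list[list[int]] = []
        self.pos: list[int] = []

    def reset(self, start_node: int) -> None:
        n = self.n
        self.is_mut = [False] * n
        self.members = [list(range(n)), []]  # [wild nodes, mutant nodes]
        self.pos = list(range(n))
        self.flip(start_node)

    def flip(self, node: int) -> None:
        old = self.is_mut[node]
        src, dst = self.members[old], self.members[not old]
        i = self.pos[node]
        last = src[-1]
        src[i] = last
        self.pos[last] = i
        src.pop()
        self.pos[node] = len(dst)
        dst.append(node)
        self.is_mut[node] = not old


def _simulate(pop: _Population, r: float, start_node: int,
              rng: np.random.Generator) -> tuple[bool, int]:
    pop.reset(start_node)
    n = pop.n
    adj = pop.adj
    is_mut = pop.is_mut
    members = pop.members
    steps = 0
    m = 1
    u = rng.random(_BLOCK)
    ui = 0
    while 0 < m < n:
        if ui + 3 > _BLOCK:
            u = rng.random(_BLOCK)
            ui = 0
        steps += 1
        wm = r * m
        birth_is_mutant = bool(u[ui] * (wm + n - m) < wm)
        cls = members[birth_is_mutant]
        birth = cls[int(u[ui + 1] * len(cls))]
        neigh = adj[birth]
        target = neigh[int(u[ui + 2] * len(neigh))]
        ui += 3
        if is_mut[target] != birth_is_mutant:
            pop.flip(target)
            m += 1 if birth_is_mutant else -1
    return m == n, steps


def run_once(graph: Graph, r: float, start_node: int,
             rng: np.random.Generator) -> tuple[bool, int]:
    """Simulate one invasion until absorption.

    Returns ``(fixed, steps)``; ``steps`` counts every elementary
    birth-death event, including those that do not change the state, so a
    fixation run takes at least n - 1 steps.
    """
    if r <= 0:
        raise ValueError("mutant fitness r must be positive")
    if not 0 <= start_node < graph.n_nodes:
        raise ValueError("invalid start node")
    return _simulate(_Population(graph), r, start_node, rng)


def estimate(graph: Graph, r: float, replicates: int,
             start: Union[int, str] = "uniform",
             seed: Optional[int] = None,
             rng: Optional[np.random.Generator] = None) -> SimulationResult:
    """Estimate fixation frequency and times over independent replicates.

    ``start`` is a node index or ``"uniform"`` (the first mutant arises on
    a uniformly random node, the convention of the analytical start
    averaging).  Given the same seed the result is bit-for-bit
    reproducible.  Standard errors come from the sample variance of the
    per-run step counts; if no replicate fixates, the conditional time is
    reported as ``None``.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if r <= 0:
        raise ValueError("mutant fitness r must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = graph.n_nodes
    if start != "uniform" and not 0 <= int(start) < n:
        raise ValueError("invalid start node")
    pop = _Population(graph)
    start_nodes = (rng.integers(0, n, size=replicates) if start == "uniform"
                   else np.full(replicates, int(start)))
    times = np.empty(replicates)
    fixed = np.empty(replicates, dtype=bool)
    for k in range(replicates):
        fixed[k], times[k] = _simulate(pop, r, int(start_nodes[k]), rng)
    fix_times = times[fixed]
    n_fix = int(fixed.sum())

    def mean_se(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return float("nan"), float("nan")
        se = float(x.std(ddof=1) / sqrt(x.size)) if x.size > 1 else float("nan")
        return float(x.mean()), se

    unc_mean, unc_se = mean_se(times)
    if n_fix:
        cond_mean, cond_se = mean_se(fix_times)
    else:
        cond_mean = cond_se = None
    return SimulationResult(
        graph=graph.name or f"n{n}m{graph.n_edges}", r=float(r),
        replicates=replicates, seed=seed, start=start,
        fixations=n_fix, extinctions=replicates - n_fix,
        unconditional_time=unc_mean, unconditional_se=unc_se,
        conditional_time=cond_mean, conditional_se=cond_se,
    )
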